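import numpy as np
import pytest

from cottonhydro.simulate import LAISchedule, SimConfig
from cottonhydro.soilphys import SoilTexture, pedotransfer
from cottonhydro.synthetic import SyntheticConfig, default_params, gen_meteo


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def species(params):
    return params["genotypes"]["species"]


@pytest.fixture(scope="session")
def soils(params):
    return {name: pedotransfer(tex) for name, tex in params["textures"].items()}


@pytest.fixture(scope="session")
def base_forcing():
    """Packaged 80-day synthetic forcing (seed 1)."""
    return gen_meteo(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def short_forcing():
    """Six-day forcing for fast loop tests."""
    return gen_meteo(SyntheticConfig(seed=1, n_days=6))


@pytest.fixture
def quick_config(species, soils):
    return SimConfig(genotype=species, soil=soils["mean"],
                     lai_schedule=LAISchedule.constant(3.5))
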