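"""Half-hourly season simulator.

Runs the soil-plant continuum over the DOY 160-240 window at half-hourly
resolution: infiltration of irrigation/rain into a five-layer (30 cm each)
bucket profile, stomatal demand, the supply-demand network solve, removal of
root uptake per layer, and drainage of any layer above field capacity.  The
step order is: infiltrate -> demand -> solve -> uptake -> drain, and the water
balance closes to numerical precision at every step.

Also provides the validation RMSE and the root:leaf-area-ratio calibration
loop used to tune the root system against layered soil-moisture observations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import hydraulics as hyd
from .hydraulics import GenotypeParams, build_continuum, canopy_temperature, \
    stomatal_demand
from .soilphys import SoilHydraulicParams, fc_pwp, theta_to_psi

__all__ = [
    "LAISchedule",
    "SimConfig",
    "SimulationOutput",
    "step_halfhour",
    "run_simulation",
    "rmse",
    "calibrate_root_ratio",
    "read_forcing",
    "write_forcing",
    "MM_PER_MMOL_STEP",
]

STEP_SECONDS = 1800.0
#: mm of water removed per (mmol m-2 ground s-1) sustained over one half-hour
MM_PER_MMOL_STEP = STEP_SECONDS * 18.015e-6

FORCING_COLUMNS = ["timestamp", "doy", "hour", "par", "t_air", "vpd", "wind",
                   "water_input"]


@dataclass(frozen=True)
class LAISchedule:
    """Staged leaf area index: piecewise-constant in 1-5 stages.

    ``breakpoints`` is a list of (doy, lai); the LAI on a day is the value of
    the last breakpoint at or before it.  A single entry gives constant LAI.
    """

    breakpoints: tuple

    def __post_init__(self) -> None:
        bps = tuple((int(d), float(l)) for d, l in self.breakpoints)
        if not (1 <= len(bps) <= 5):
            raise ValueError("LAI schedule needs 1-5 stages")
        lais = [l for _, l in bps]
        if any(l <= 0 or l > 8 for l in lais):
            raise ValueError("LAI values must be in (0, 8]")
        if any(b > a for a, b in zip(lais[1:], lais)):
            raise ValueError("staged LAI must be nondecreasing")
        object.__setattr__(self, "breakpoints", bps)

    @classmethod
    def constant(cls, lai: float) -> "LAISchedule":
        return cls(((0, lai),))

    def lai(self, doy: int) -> float:
        val = self.breakpoints[0][1]
        for d, l in self.breakpoints:
            if doy >= d:
                val = l
        return val


@dataclass
class SimConfig:
    """Everything needed to run one simulation besides the forcing."""

    genotype: GenotypeParams
    soil: SoilHydraulicParams | Sequence[SoilHydraulicParams]
    lai_schedule: LAISchedule
    root_profile: tuple = (0.35, 0.25, 0.20, 0.12, 0.08)
    n_layers: int = 5
    layer_thickness_m: float = 0.3
    theta_init: str | Sequence[float] = "fc"   # "fc" or explicit per-layer
    drainage_rate_per_day: float = 0.5
    cap_fraction: float = 0.9
    resistance_split: float = 0.5
    rhiz_geometry_factor: float = 50.0
    patm: float = 101.3
    seed: int = 0

    def soil_layers(self) -> list[SoilHydraulicParams]:
        if isinstance(self.soil, SoilHydraulicParams):
            return [self.soil] * self.n_layers
        soils = list(self.soil)
        if len(soils) != self.n_layers:
            raise ValueError("per-layer soil list length mismatch")
        return soils


@dataclass
class SimulationOutput:
    """Per-step trajectories plus the run configuration."""

    steps: pd.DataFrame
    config: SimConfig
    kmax: float

    @property
    def n_layers(self) -> int:
        return self.config.n_layers

    def theta_columns(self) -> list[str]:
        return [f"theta_{i+1}" for i in range(self.n_layers)]


@dataclass
class _State:
    theta: np.ndarray  # per-layer volumetric water content


def _infiltrate(theta: np.ndarray, water_mm: float, theta_fc: np.ndarray,
                thickness_mm: float) -> tuple[np.ndarray, float]:
    """Fill layers to field capacity top-down; excess past the bottom layer
    leaves as deep drainage.  Returns (theta', drained_mm)."""
    remaining = water_mm
    theta = theta.copy()
    for i in range(len(theta)):
        if remaining <= 0:
            break
        capacity = max(0.0, (theta_fc[i] - theta[i]) * thickness_mm)
        added = min(remaining, capacity)
        theta[i] += added / thickness_mm
        remaining -= added
    return theta, remaining


def step_halfhour(state: _State, meteo: dict, config: SimConfig,
                  soils: list[SoilHydraulicParams], theta_fc: np.ndarray,
                  theta_pwp: np.ndarray, lai: float) -> tuple[_State, dict]:
    """Advance one half-hour.  Returns the new state and the output record."""
    thickness_mm = config.layer_thickness_m * 1000.0
    theta = state.theta
    storage0 = float(theta.sum()) * thickness_mm

    # (1) infiltration
    theta, deep = _infiltrate(theta, meteo["water_input"], theta_fc, thickness_mm)

    # (2) demand (ground basis)
    if meteo["par"] <= 0.0 or meteo["vpd"] <= 0.0:
        demand_ground = 0.0
    else:
        demand_ground = stomatal_demand(config.genotype, meteo["vpd"], lai,
                                        par=meteo["par"], patm=config.patm)

    # (3) supply-demand solve (leaf basis)
    net = build_continuum(
        config.genotype, list(zip(soils, theta)), lai, config.root_profile,
        resistance_split=config.resistance_split,
        cap_fraction=config.cap_fraction,
        rhiz_geometry_factor=config.rhiz_geometry_factor)
    cstate = net.solve(demand_ground / lai)

    # (4) remove uptake per layer
    e_ground = cstate.e_c * lai
    uptake_mm = e_ground * MM_PER_MMOL_STEP
    layer_mm = uptake_mm * cstate.layer_uptake
    theta = theta - layer_mm / thickness_mm
    # guard: never draw below residual (the network should prevent this)
    if np.any(theta < np.array([s.theta_r for s in soils]) - 1e-12):
        raise RuntimeError("layer water content fell below residual")

    # (5) drainage of layers above field capacity
    drain_frac = config.drainage_rate_per_day / 48.0
    over = np.clip(theta - theta_fc, 0.0, None)
    drained_layers = over * drain_frac * thickness_mm
    theta = theta - drained_layers / thickness_mm
    drainage = deep + float(drained_layers.sum())

    storage1 = float(theta.sum()) * thickness_mm
    residual = storage1 - storage0 - meteo["water_input"] + uptake_mm + drainage
    if abs(residual) > 1e-6:
        raise RuntimeError(f"water balance violated by {residual:.3e} mm")

    if np.any(theta > np.array([s.theta_s for s in soils]) + 1e-9):
        raise RuntimeError("theta exceeded saturation")

    g_s = 0.0
    if meteo["vpd"] > 0 and cstate.e_c > 0:
        g_s = cstate.e_c / (meteo["vpd"] / config.patm) * 1e-3  # mol m-2 s-1

    t_can = canopy_temperature(meteo["t_air"], meteo["par"], meteo["wind"],
                               e_ground, lai)

    record = {
        "psi_leaf": cstate.psi_leaf,
        "e_c": cstate.e_c,
        "e_crit": cstate.e_crit,
        "e_demand": demand_ground / lai,
        "g_s": g_s,
        "k_plant": cstate.k_plant,
        "t_canopy": t_can,
        "psi_soil_eff": cstate.psi_soil_eff,
        "lai": lai,
        "water_input": meteo["water_input"],
        "transpiration_mm": uptake_mm,
        "drainage_mm": drainage,
        "supply_capped": cstate.flagged,
    }
    for i in range(len(theta)):
        record[f"theta_{i+1}"] = theta[i]
        record[f"uptake_{i+1}"] = cstate.layer_uptake[i]
    return _State(theta=theta), record


def run_simulation(config: SimConfig, forcing: pd.DataFrame,
                   start_doy: int = 160, end_doy: int = 240) -> SimulationOutput:
    """Run the half-hourly loop over [start_doy, end_doy).

    ``forcing`` must cover the window completely at half-hourly resolution
    (48 steps per day); gaps raise with the missing steps listed.  The run is
    deterministic given the config and forcing.
    """
    fz = forcing[(forcing["doy"] >= start_doy) & (forcing["doy"] < end_doy)]
    fz = fz.sort_values(["doy", "hour"]).reset_index(drop=True)
    expected = (end_doy - start_doy) * 48
    if len(fz) != expected:
        have = set(zip(fz["doy"], np.round(fz["hour"] * 2).astype(int)))
        missing = [(d, h / 2) for d in range(start_doy, end_doy)
                   for h in range(48) if (d, h) not in have]
        raise ValueError(f"forcing gaps: {len(missing)} missing steps, "
                         f"first few {missing[:5]}")

    soils = config.soil_layers()
    fcs = np.array([fc_pwp(s)[0] for s in soils])
    pwps = np.array([fc_pwp(s)[1] for s in soils])
    if isinstance(config.theta_init, str):
        if config.theta_init != "fc":
            raise ValueError("theta_init must be 'fc' or explicit values")
        theta0 = fcs.copy()
    else:
        theta0 = np.asarray(config.theta_init, dtype=float)

    state = _State(theta=theta0)
    records = []
    for row in fz.itertuples(index=False):
        meteo = {"par": row.par, "t_air": row.t_air, "vpd": row.vpd,
                 "wind": row.wind, "water_input": row.water_input}
        lai = config.lai_schedule.lai(int(row.doy))
        state, rec = step_halfhour(state, meteo, config, soils, fcs, pwps, lai)
        rec["doy"] = int(row.doy)
        rec["hour"] = float(row.hour)
        records.append(rec)

    steps = pd.DataFrame(records)
    return SimulationOutput(steps=steps, config=config,
                            kmax=hyd.kmax_saturated(config.genotype))


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def rmse(simulated, observed) -> float:
    """Root mean square error, sqrt(mean((Y_f - Y_o)^2))."""
    y_f = np.asarray(simulated, dtype=float)
    y_o = np.asarray(observed, dtype=float)
    if y_f.shape != y_o.shape:
        raise ValueError("simulated/observed length mismatch")
    if y_f.size == 0:
        raise ValueError("need at least one pair")
    return float(np.sqrt(np.mean((y_f - y_o) ** 2)))


def _match_observations(output: SimulationOutput, obs: pd.DataFrame):
    """Nearest-step join of layered theta observations onto the simulation
    (columns: doy, hour, layer, theta); 1-hour tolerance."""
    steps = output.steps
    sim_time = steps["doy"].to_numpy() * 24.0 + steps["hour"].to_numpy()
    pairs = []
    for row in obs.itertuples(index=False):
        t = row.doy * 24.0 + row.hour
        idx = int(np.argmin(np.abs(sim_time - t)))
        if abs(sim_time[idx] - t) > 1.0:
            continue
        pairs.append((steps.iloc[idx][f"theta_{int(row.layer)}"], row.theta,
                      int(row.layer)))
    return pairs


def validation_rmse_by_layer(output: SimulationOutput,
                             obs: pd.DataFrame) -> dict[int, float]:
    pairs = _match_observations(output, obs)
    if not pairs:
        raise ValueError("no matched observation pairs")
    by_layer: dict[int, list] = {}
    for sim_v, obs_v, layer in pairs:
        by_layer.setdefault(layer, []).append((sim_v, obs_v))
    return {layer: rmse([p[0] for p in v], [p[1] for p in v])
            for layer, v in sorted(by_layer.items())}


def calibrate_root_ratio(config: SimConfig, forcing: pd.DataFrame,
                         observed: pd.DataFrame,
                         candidate_ratios: Sequence[float],
                         start_doy: int = 160, end_doy: int = 240):
    """Grid calibration of the root-to-leaf-area ratio against layered soil
    moisture observations.

    Runs the simulation once per candidate ratio and picks the one minimizing
    the mean across-layer RMSE.  Returns ``(best_ratio, profile)`` where
    ``profile`` is a DataFrame (ratio, mean_rmse) for audit.
    """
    ratios = list(candidate_ratios)
    if len(ratios) < 2:
        raise ValueError("need at least two candidate ratios")
    if observed.empty or observed["layer"].nunique() < 2:
        raise ValueError("observations must span at least two layers")
    rows = []
    for r in ratios:
        geno = replace(config.genotype, root_to_leaf_area=float(r))
        cfg = replace(config, genotype=geno)
        out = run_simulation(cfg, forcing, start_doy=start_doy, end_doy=end_doy)
        by_layer = validation_rmse_by_layer(out, observed)
        rows.append({"ratio": r, "mean_rmse": float(np.mean(list(by_layer.values())))})
    profile = pd.DataFrame(rows)
    best = float(profile.loc[profile["mean_rmse"].idxmin(), "ratio"])
    return best, profile


# ---------------------------------------------------------------------------
# forcing I/O
# ---------------------------------------------------------------------------

def read_forcing(path, sep="\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    missing = set(FORCING_COLUMNS[1:]) - set(df.columns)
    if missing:
        raise ValueError(f"forcing file missing columns: {sorted(missing)}")
    return df


def write_forcing(forcing: pd.DataFrame, path, sep="\t") -> None:
    cols = [c for c in FORCING_COLUMNS if c in forcing.columns]
    forcing.to_csv(path, sep=sep, index=False, columns=cols)
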