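"""Synthetic input generators.

No raw data from the original field campaigns are deposited, so every input
class the pipeline consumes is emulated here with the statistical structure
the analysis assumes: noisy Weibull-distributed vulnerability-curve points,
spatially correlated soil-texture fields, arid-summer diurnal meteorology with
irrigation pulses, and noisy layered soil-moisture observations.  Every
generator is a pure function of its arguments including the seed.

``default_params`` packages the species-level hydraulic/soil parameter sets
(stomatal reference conductance 0.63 mol m-2 s-1, saturated transpiration
11.4 mmol m-2 s-1, predawn/midday potentials -0.8/-2.4 MPa, shoot Weibull
(1.55, 0.75), root Weibull (0.29, 0.59), root:leaf area 2.5, the low-clay and
high-clay texture sets) plus four per-genotype stem-VC presets.  Genotype
(b, c) pairs were never published; the presets are synthetic stand-ins
anchored to the published genotype P50 values (-1.52 MPa for the PD3-like
curve, -0.49 MPa for the Tipo-Chaco-like landrace curve) with the species
shape c = 0.75.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hydraulics import GenotypeParams
from .simulate import LAISchedule, SimulationOutput
from .soilphys import SoilTexture
from .vcurves import VulnerabilityCurve

__all__ = [
    "SyntheticConfig",
    "gen_meteo",
    "gen_vc_measurements",
    "gen_soil_field",
    "gen_observed_moisture",
    "default_params",
    "saturation_vapor_pressure",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Stated world for the synthetic forcing.

    Defaults emulate an arid-summer irrigated cotton season: near-zero rain,
    high radiation, 2-day irrigation cycles sized to roughly meet demand
    before drought initiation on DOY 188, and a post-initiation schedule sized
    so that the most severe derived scenario (25 % of base) receives ~69 mm
    over the drought period, matching the reported severe-scenario total.
    """

    seed: int = 0
    start_doy: int = 160
    n_days: int = 80
    latitude_deg: float = 33.07
    irrigation_interval_days: int = 2
    irrigation_depth_mm: float = 20.0
    drought_start_doy: int | None = 188
    drought_interval_days: int = 2
    drought_depth_mm: float = 10.6
    irrigation_hour: float = 6.0
    t_mean: float = 31.0
    t_amplitude: float = 7.0
    dewpoint: float = 18.0
    wind_mean: float = 2.0
    temp_noise_sd: float = 0.5
    wind_noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.irrigation_interval_days < 1 or self.drought_interval_days < 1:
            raise ValueError("invalid irrigation schedule")
        for s in (self.temp_noise_sd, self.wind_noise_sd):
            if s < 0:
                raise ValueError("noise sd must be >= 0")


def saturation_vapor_pressure(t_c):
    """Tetens saturation vapor pressure, kPa."""
    t = np.asarray(t_c, dtype=float)
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def _solar_elevation_sin(doy, hour, latitude_deg):
    lat = math.radians(latitude_deg)
    decl = np.radians(23.45) * np.sin(2.0 * np.pi * (284 + doy) / 365.0)
    hour_angle = np.radians(15.0 * (hour - 12.0))
    return (np.sin(lat) * np.sin(decl)
            + np.cos(lat) * np.cos(decl) * np.cos(hour_angle))


def gen_meteo(config: SyntheticConfig = SyntheticConfig()) -> pd.DataFrame:
    """Half-hourly meteorological forcing.

    PAR follows the solar-elevation sine (zero when the sun is down, peaking
    near 2000 umol m-2 s-1), air temperature a diurnal cosine lagging solar
    noon by 3 h, VPD from Tetens saturation pressure against a fixed dewpoint,
    wind positive with a diurnal component, and water input delivered as
    morning irrigation pulses on the configured schedule.
    """
    rng = np.random.default_rng(config.seed)
    doys = np.repeat(np.arange(config.start_doy, config.start_doy + config.n_days), 48)
    hours = np.tile(np.arange(48) * 0.5, config.n_days)

    sin_el = _solar_elevation_sin(doys, hours, config.latitude_deg)
    par = 2000.0 * np.clip(sin_el, 0.0, None)

    t_air = (config.t_mean
             + config.t_amplitude * np.cos(2.0 * np.pi * (hours - 15.0) / 24.0)
             + rng.normal(0.0, config.temp_noise_sd, len(doys)))
    vpd = np.clip(saturation_vapor_pressure(t_air)
                  - saturation_vapor_pressure(config.dewpoint), 0.01, None)
    wind = np.clip(config.wind_mean
                   + 0.8 * np.clip(sin_el, 0.0, None)
                   + rng.normal(0.0, config.wind_noise_sd, len(doys)), 0.3, None)

    water = np.zeros(len(doys))
    for i, (d, h) in enumerate(zip(doys, hours)):
        if h != config.irrigation_hour:
            continue
        in_drought = (config.drought_start_doy is not None
                      and d >= config.drought_start_doy)
        if in_drought:
            since = d - config.drought_start_doy
            if since % config.drought_interval_days == 0:
                water[i] = config.drought_depth_mm
        else:
            since = d - config.start_doy
            if since % config.irrigation_interval_days == 0:
                water[i] = config.irrigation_depth_mm

    return pd.DataFrame({
        "doy": doys, "hour": hours, "par": par, "t_air": t_air,
        "vpd": vpd, "wind": wind, "water_input": water,
    })


def gen_vc_measurements(truth: VulnerabilityCurve, pressures,
                        noise_sd: float = 5.0, n_segments: int = 3,
                        seed: int = 0, ksmax_cv: float = 0.15) -> pd.DataFrame:
    """Noisy vulnerability-curve measurement table.

    PLC values are the Weibull truth plus Gaussian noise (sd in PLC units),
    clipped to [0, 100]; per-segment K_smax is drawn lognormally around the
    truth curve's value so the conductivity scale is also populated.
    """
    if noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    p = np.asarray(pressures, dtype=float)
    if np.any(p > 0):
        raise ValueError("pressures must be <= 0 MPa")
    rng = np.random.default_rng(seed)
    rows = []
    ksmax_truth = truth.ksmax if truth.ksmax is not None else 1.0
    for seg in range(n_segments):
        ksmax_seg = ksmax_truth * math.exp(rng.normal(0.0, ksmax_cv)) \
            if noise_sd > 0 else ksmax_truth
        plc_true = truth.plc(p)
        plc_obs = np.clip(plc_true + rng.normal(0.0, noise_sd, len(p)), 0.0, 100.0)
        for psi, plc_v in zip(p, plc_obs):
            rows.append({
                "genotype": truth.genotype, "organ": truth.organ,
                "segment_id": f"seg{seg+1}", "pressure_mpa": psi,
                "plc": plc_v, "ks": ksmax_seg * (1.0 - plc_v / 100.0),
            })
    return pd.DataFrame(rows)


def gen_soil_field(extent=(180.0, 120.0), n_samples: int = 110,
                   clay_mean: float = 0.24, sand_mean: float = 0.58,
                   sill: float = 0.0025, range_m: float = 40.0,
                   nugget: float = 0.0003, seed: int = 0,
                   depths_cm=(0, 30, 60, 90, 120, 150)) -> pd.DataFrame:
    """Spatially correlated soil sample table.

    Clay is a Gaussian random field with exponential covariance (practical
    range ``range_m``) sampled at random locations across the field extent in
    each depth layer; sand mirrors clay (negative correlation) and silt closes
    the composition.  Fractions are clipped and renormalized so every sample
    satisfies the closure invariant.
    """
    if n_samples < 10:
        raise ValueError("need at least 10 samples")
    if extent[0] <= 0 or extent[1] <= 0:
        raise ValueError("degenerate field extent")
    rng = np.random.default_rng(seed)
    xy = rng.uniform([0, 0], list(extent), size=(n_samples, 2))
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
    cov = sill * np.exp(-3.0 * d / range_m) + nugget * np.eye(n_samples)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(n_samples))

    rows = []
    for top, bottom in zip(depths_cm[:-1], depths_cm[1:]):
        depth_shift = 0.004 * (top / 30.0)  # clay increases slightly with depth
        clay = clay_mean + depth_shift + chol @ rng.standard_normal(n_samples)
        sand = sand_mean - 0.9 * (clay - clay_mean) \
            + rng.normal(0.0, 0.01, n_samples)
        clay = np.clip(clay, 0.02, 0.60)
        sand = np.clip(sand, 0.05, 0.90)
        silt = np.clip(1.0 - clay - sand, 0.01, None)
        total = clay + sand + silt
        clay, sand, silt = clay / total, sand / total, silt / total
        for i in range(n_samples):
            rows.append({
                "x_m": xy[i, 0], "y_m": xy[i, 1],
                "depth_top_cm": top, "depth_bottom_cm": bottom,
                "clay": clay[i], "sand": sand[i], "silt": silt[i],
            })
    return pd.DataFrame(rows)


def gen_observed_moisture(output: SimulationOutput, noise_sd: float = 0.01,
                          n_timepoints: int = 19, seed: int = 0,
                          hour: float = 8.0) -> pd.DataFrame:
    """Noisy layered soil-moisture observation series.

    Subsamples ~evenly spaced days from the simulation (emulating roughly
    twice-weekly neutron-probe reads), adds Gaussian noise to each layer's
    theta and clips to physical bounds.  Columns: doy, hour, layer, theta.
    """
    steps = output.steps
    days = np.array(sorted(steps["doy"].unique()))
    if n_timepoints > len(days):
        raise ValueError("more time-points requested than simulated days")
    rng = np.random.default_rng(seed)
    pick = days[np.linspace(0, len(days) - 1, n_timepoints).round().astype(int)]
    soils = output.config.soil_layers()
    rows = []
    for d in pick:
        day = steps[(steps["doy"] == d) & (steps["hour"] == hour)].iloc[0]
        for layer in range(1, output.n_layers + 1):
            s = soils[layer - 1]
            theta = day[f"theta_{layer}"] + rng.normal(0.0, noise_sd)
            rows.append({"doy": int(d), "hour": hour, "layer": layer,
                         "theta": float(np.clip(theta, s.theta_r, s.theta_s))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# packaged parameter sets
# ---------------------------------------------------------------------------

def _species_vcs():
    return (VulnerabilityCurve(1.55, 0.75, organ="stem", genotype="species"),
            VulnerabilityCurve(0.29, 0.59, organ="root", genotype="species"))


def _genotype(name: str, stem_b: float) -> GenotypeParams:
    shoot = VulnerabilityCurve(stem_b, 0.75, organ="stem", genotype=name)
    _, root = _species_vcs()
    return GenotypeParams(gsref=0.63, e_sat=11.4, psi_pd_sat=-0.8,
                          psi_md_sat=-2.4, vc_shoot=shoot, vc_root=root,
                          root_to_leaf_area=2.5, name=name)


_LN2 = math.log(2.0)


def _b_from_p50(p50_mag: float, c: float = 0.75) -> float:
    return p50_mag / _LN2 ** (1.0 / c)


def default_params() -> dict:
    """Packaged parameter sets: the species-level genotype, four genotype
    stem-VC presets (synthetic stand-ins anchored to published P50s), the
    low/high-clay and mean-soil textures, and the default staged LAI."""
    shoot, root = _species_vcs()
    species = GenotypeParams(gsref=0.63, e_sat=11.4, psi_pd_sat=-0.8,
                             psi_md_sat=-2.4, vc_shoot=shoot, vc_root=root,
                             root_to_leaf_area=2.5, name="species")
    genotypes = {
        "species": species,
        # synthetic stand-ins: b back-computed from the published stem P50
        # (-0.49 landrace, -1.52 PD3-like), species shape c = 0.75
        "tipo_like": _genotype("tipo_like", _b_from_p50(0.49)),
        "dp_like": _genotype("dp_like", _b_from_p50(1.15)),
        "pd3_like": _genotype("pd3_like", _b_from_p50(1.52)),
        "coker_like": _genotype("coker_like", _b_from_p50(1.05)),
    }
    textures = {
        "LC": SoilTexture(clay=0.19, sand=0.636, silt=0.174,
                          bulk_density=1.59, porosity=0.401,
                          d_gmean_mm=0.1448, gsd=12.226),
        "HC": SoilTexture(clay=0.278, sand=0.540, silt=0.182,
                          bulk_density=1.56, porosity=0.4105,
                          d_gmean_mm=0.0764, gsd=12.226),
        # mean soil across all grid cells: 24-58-18 clay-sand-silt
        "mean": SoilTexture(clay=0.24, sand=0.58, silt=0.18,
                            bulk_density=1.575, porosity=0.4057,
                            d_gmean_mm=0.11, gsd=12.226),
    }
    lai_staged = LAISchedule(((160, 1.5), (172, 2.5), (184, 3.5), (200, 4.0)))
    return {
        "genotypes": genotypes,
        "textures": textures,
        "lai_staged": lai_staged,
        "lai_fixed": LAISchedule.constant(3.5),
        "root_profile": (0.35, 0.25, 0.20, 0.12, 0.08),
    }
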