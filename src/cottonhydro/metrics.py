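"""Derived stress and genotype-by-environment statistics.

Windowed daily aggregates (predawn 03:00-05:00, midday 12:00-14:00, half-open
intervals), percent loss of whole-plant conductance PLK = 100 (1 - k/k_max),
hydraulic safety margins E_crit - E_c and their seasonal relativization
rho = margin / max(margin), the normalized between-genotype transpiration
difference delta, sign-flip divergence-day detection between soils, and
construction of the E1/E2/E3 water-input scenarios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import SimulationOutput

__all__ = [
    "WINDOWS",
    "DailyMetrics",
    "ScenarioSet",
    "DivergenceReport",
    "window_stats",
    "plk",
    "relative_safety",
    "delta_series",
    "divergence_days",
    "build_scenarios",
    "daily_metrics",
]

#: aggregation windows, half-open [start, end) hours of local standard time
WINDOWS = {"predawn": (3.0, 5.0), "midday": (12.0, 14.0)}


def window_stats(output: SimulationOutput | pd.DataFrame, variable: str,
                 window: str = "midday") -> pd.Series:
    """Per-day arithmetic mean of ``variable`` over the named window.

    The midday window 12:00-14:00 covers the four half-hour steps starting at
    12:00, 12:30, 13:00 and 13:30; predawn 03:00-05:00 analogously.  Missing
    steps in a window raise, naming the day.
    """
    steps = output.steps if isinstance(output, SimulationOutput) else output
    if window not in WINDOWS:
        raise ValueError(f"unknown window {window!r}")
    lo, hi = WINDOWS[window]
    sel = steps[(steps["hour"] >= lo) & (steps["hour"] < hi)]
    counts = sel.groupby("doy")[variable].count()
    expected = int(round((hi - lo) * 2))
    bad = counts[counts != expected]
    if len(bad):
        raise ValueError(f"incomplete {window} window on day(s) "
                         f"{list(bad.index[:5])}")
    return sel.groupby("doy")[variable].mean()


def plk(k_plant, k_max: float):
    """Percent loss of whole-plant conductance, 100 (1 - k_plant/k_max).

    Values of k_plant slightly above k_max (numerical supersaturation) are
    clamped to zero loss with a warning.
    """
    if k_max <= 0:
        raise ValueError("k_max must be positive")
    k = np.asarray(k_plant, dtype=float)
    if np.any(k < 0):
        raise ValueError("k_plant must be >= 0")
    if np.any(k > k_max * (1.0 + 1e-9)):
        warnings.warn("k_plant exceeds k_max; clamping PLK to 0", stacklevel=2)
    val = 100.0 * (1.0 - np.clip(k / k_max, 0.0, 1.0))
    return float(val) if np.ndim(k_plant) == 0 else val


def relative_safety(margins) -> pd.Series | np.ndarray:
    """Relative hydraulic safety margin rho = margin / max(margin).

    The day attaining the seasonal maximum margin gets exactly 1.
    """
    m = np.asarray(margins, dtype=float)
    mx = np.nanmax(m)
    if not (mx > 0):
        raise ValueError("all margins are <= 0; rho undefined")
    rho = m / mx
    if isinstance(margins, pd.Series):
        return pd.Series(rho, index=margins.index, name="rho")
    return rho


def delta_series(e_c_role_a, e_c_role_b) -> pd.Series:
    """Normalized per-day transpiration difference between two runs,

        delta_i = (a_i - b_i) / mean(a_i, b_i).

    Positive values mean the role-a run transpired more that day.  Days with
    zero mean are flagged as NaN rather than dropped.  Antisymmetric under
    role swap; bounded in (-2, 2) where defined.
    """
    a = pd.Series(e_c_role_a, dtype=float)
    b = pd.Series(e_c_role_b, dtype=float)
    if not a.index.equals(b.index):
        raise ValueError("series must share day alignment")
    mean = 0.5 * (a + b)
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = (a - b) / mean
    delta[mean == 0] = np.nan
    delta.name = "delta"
    return delta


@dataclass
class DivergenceReport:
    """Days where the genotype ranking flips between the two soils."""

    delta_hc: pd.Series
    delta_lc: pd.Series
    flagged_days: list
    windows: list  # list of (start_day, end_day, orientation) maximal runs


def divergence_days(delta_hc: pd.Series, delta_lc: pd.Series) -> DivergenceReport:
    """Detect soil-dependent ranking flips.

    A day is flagged iff sign(delta_HC) * sign(delta_LC) < 0; a zero (or NaN)
    delta on either soil is treated as non-divergent.  Windows are maximal
    runs of >= 2 consecutive flagged days with the same orientation
    (orientation = sign of delta_HC).
    """
    if not delta_hc.index.equals(delta_lc.index):
        raise ValueError("series must share day alignment")
    s_hc = np.sign(delta_hc.to_numpy())
    s_lc = np.sign(delta_lc.to_numpy())
    with np.errstate(invalid="ignore"):
        flip = (s_hc * s_lc) < 0
    flip = np.where(np.isnan(s_hc) | np.isnan(s_lc), False, flip)
    days = list(delta_hc.index)
    flagged = [d for d, f in zip(days, flip) if f]

    windows = []
    i, n = 0, len(days)
    while i < n:
        if not flip[i]:
            i += 1
            continue
        j = i
        while (j + 1 < n and flip[j + 1] and days[j + 1] == days[j] + 1
               and s_hc[j + 1] == s_hc[i]):
            j += 1
        if j - i + 1 >= 2:
            windows.append((days[i], days[j], float(s_hc[i])))
        i = j + 1
    return DivergenceReport(delta_hc=delta_hc, delta_lc=delta_lc,
                            flagged_days=flagged, windows=windows)


@dataclass
class ScenarioSet:
    """The three water-input scenarios sharing all non-water forcing."""

    e1: pd.DataFrame
    e2: pd.DataFrame
    e3: pd.DataFrame
    drought_start_doy: int = 188
    multipliers: tuple = (1.0, 0.5, 0.25)

    def items(self):
        return [("E1", self.e1), ("E2", self.e2), ("E3", self.e3)]


def build_scenarios(base_forcing: pd.DataFrame,
                    drought_start_doy: int = 188,
                    multipliers: tuple = (1.0, 0.5, 0.25)) -> ScenarioSet:
    """Derive E1-E3 from a base forcing.

    E1 is the base bitwise; E2 and E3 have every water-input step from
    ``drought_start_doy`` onward multiplied by 0.5 and 0.25 (all other
    variables untouched), so post-start water totals are in ratio 1:0.5:0.25.
    """
    doys = base_forcing["doy"]
    if not (doys.min() <= drought_start_doy <= doys.max()):
        raise ValueError("drought start outside the forcing window")
    frames = []
    for m in multipliers:
        f = base_forcing.copy()
        mask = f["doy"] >= drought_start_doy
        f.loc[mask, "water_input"] = f.loc[mask, "water_input"] * m
        frames.append(f)
    return ScenarioSet(e1=frames[0], e2=frames[1], e3=frames[2],
                       drought_start_doy=drought_start_doy,
                       multipliers=tuple(multipliers))


def daily_metrics(output: SimulationOutput) -> pd.DataFrame:
    """Per-day stress metrics table.

    Columns: psi_pd, psi_md (predawn/midday mean leaf water potential),
    e_c_md, e_crit_md (leaf basis), margin = e_crit_md - e_c_md, rho over the
    run, plk from the midday-mean k_plant, lai.
    """
    psi_pd = window_stats(output, "psi_leaf", "predawn")
    psi_md = window_stats(output, "psi_leaf", "midday")
    e_c_md = window_stats(output, "e_c", "midday")
    e_crit_md = window_stats(output, "e_crit", "midday")
    k_md = window_stats(output, "k_plant", "midday")
    margin = e_crit_md - e_c_md
    df = pd.DataFrame({
        "psi_pd": psi_pd, "psi_md": psi_md,
        "e_c_md": e_c_md, "e_crit_md": e_crit_md,
        "margin": margin,
        "rho": relative_safety(margin),
        "plk": plk(k_md.to_numpy(), output.kmax),
        "lai": window_stats(output, "lai", "midday"),
    })
    df.index.name = "doy"
    return df
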