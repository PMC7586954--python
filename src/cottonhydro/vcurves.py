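"""Xylem vulnerability curves.

A vulnerability curve (VC) describes the loss of xylem hydraulic conductivity
with increasingly negative xylem pressure.  Here VCs are parameterized by a
two-parameter Weibull function,

    K_s(psi)  = K_smax * exp(-(-psi/b)**c)
    PLC(psi)  = 100 * (1 - exp(-(-psi/b)**c))

with ``b`` the scale parameter (stored as a positive magnitude, MPa) and ``c``
the dimensionless shape parameter.  Cotton xylem is strongly "R-shaped":
conductivity drops fast at mild tension and then declines slowly over a long
tail, which corresponds to c < 1.

The module fits curves to measured (pressure, PLC) or (pressure, K_s) points,
computes the P50 summary statistic, and compares fitted parameters across
genotypes with a one-way ANOVA plus Tukey HSD post-hoc test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "VCMeasurement",
    "VulnerabilityCurve",
    "VCFitResult",
    "NonIdentifiableError",
    "evaluate_vc",
    "fit_vc",
    "p50",
    "anova_oneway",
    "tukey_hsd",
    "compare_vc_parameters",
    "read_vc_table",
    "write_fit_report",
]


class NonIdentifiableError(ValueError):
    """Raised when the data cannot constrain the Weibull parameters."""


@dataclass(frozen=True)
class VCMeasurement:
    """One conductivity measurement on a xylem segment.

    ``pressure`` is xylem pressure in MPa (<= 0).  Either ``ks`` (specific
    conductivity, kg m-1 s-1 MPa-1) or ``plc`` (percent loss of conductivity
    relative to the flushed maximum) must be present.
    """

    pressure: float
    ks: float | None = None
    plc: float | None = None
    segment_id: str = ""
    genotype: str = ""
    organ: str = "stem"

    def __post_init__(self) -> None:
        if self.pressure > 0:
            raise ValueError(f"xylem pressure must be <= 0 MPa, got {self.pressure}")
        if self.ks is None and self.plc is None:
            raise ValueError("measurement needs either ks or plc")
        if self.ks is not None and self.ks < 0:
            raise ValueError("conductivity must be >= 0")
        if self.plc is not None and not (0.0 <= self.plc <= 100.0):
            raise ValueError("PLC must lie in [0, 100]")


@dataclass(frozen=True)
class VulnerabilityCurve:
    """Weibull vulnerability curve.

    ``b`` is stored as a positive magnitude (MPa), matching the usual tabular
    convention; the sign flip happens inside :func:`evaluate_vc`.  ``ksmax``
    (kg m-1 s-1 MPa-1) is optional and only required to evaluate the curve on
    the conductivity scale.
    """

    b: float
    c: float
    ksmax: float | None = None
    organ: str = "stem"
    genotype: str = "species"

    def __post_init__(self) -> None:
        if not (self.b > 0):
            raise ValueError(f"Weibull b must be > 0, got {self.b}")
        if not (self.c > 0):
            raise ValueError(f"Weibull c must be > 0, got {self.c}")
        if self.ksmax is not None and not (self.ksmax > 0):
            raise ValueError("ksmax must be > 0 when supplied")

    # convenience wrappers -------------------------------------------------
    def plc(self, pressure):
        return evaluate_vc(self, pressure)[1]

    def ks(self, pressure):
        return evaluate_vc(self, pressure)[0]

    @property
    def p50(self) -> float:
        return p50(self)


@dataclass(frozen=True)
class VCFitResult:
    """Diagnostics of a nonlinear least-squares Weibull fit."""

    curve: VulnerabilityCurve
    residual_sum_squares: float
    n_points: int
    standard_errors: dict = field(default_factory=dict)
    fit_scale: str = "plc"
    converged: bool = True


def _weibull_exponent(pressure, b, c):
    p = np.asarray(pressure, dtype=float)
    if np.any(p > 0):
        raise ValueError("xylem pressure must be <= 0 MPa")
    return (-p / b) ** c


def evaluate_vc(curve: VulnerabilityCurve, pressure):
    """Evaluate the curve at xylem ``pressure`` (MPa, <= 0).

    Returns ``(ks, plc)``; ``ks`` is ``None`` if the curve has no ``ksmax``.
    Accepts scalars or arrays.
    """
    surv = np.exp(-_weibull_exponent(pressure, curve.b, curve.c))
    plc_val = 100.0 * (1.0 - surv)
    ks_val = None if curve.ksmax is None else curve.ksmax * surv
    if np.isscalar(pressure) or np.ndim(pressure) == 0:
        plc_val = float(plc_val)
        ks_val = None if ks_val is None else float(ks_val)
    return ks_val, plc_val


def p50(curve: VulnerabilityCurve) -> float:
    """Xylem pressure (MPa) at 50 % loss of conductivity.

    Closed form from inverting PLC = 50: psi50 = -b * ln(2)**(1/c).
    """
    return -curve.b * math.log(2.0) ** (1.0 / curve.c)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_B_BOUNDS = (0.01, 20.0)
_C_BOUNDS = (0.05, 20.0)
_MULTISTART = [(b0, c0) for b0 in (0.2, 1.0, 3.0) for c0 in (0.5, 1.0, 2.0)]


def _as_measurement_frame(measurements) -> pd.DataFrame:
    if isinstance(measurements, pd.DataFrame):
        df = measurements.copy()
        if "pressure_mpa" in df.columns:
            df = df.rename(columns={"pressure_mpa": "pressure"})
        return df
    rows = []
    for m in measurements:
        rows.append(
            {"pressure": m.pressure, "ks": m.ks, "plc": m.plc,
             "segment_id": m.segment_id, "genotype": m.genotype, "organ": m.organ}
        )
    return pd.DataFrame(rows)


def fit_vc(
    measurements: Iterable[VCMeasurement] | pd.DataFrame,
    scale: str = "plc",
    ksmax: float | None = None,
    organ: str = "stem",
    genotype: str = "species",
) -> VCFitResult:
    """Fit a Weibull vulnerability curve by nonlinear least squares.

    ``scale='plc'`` fits PLC(psi) (two parameters); ``scale='ks'`` fits the
    conductivity form, co-estimating K_smax unless it is supplied.  Fits use
    multistart initialization with box bounds because R-shaped data make
    single-start fits fragile.
    """
    if scale not in ("plc", "ks"):
        raise ValueError("scale must be 'plc' or 'ks'")
    df = _as_measurement_frame(measurements)
    if len(df) < 3:
        raise NonIdentifiableError("need at least 3 measurements")
    pressure = df["pressure"].to_numpy(dtype=float)
    if np.any(pressure > 0):
        raise ValueError("xylem pressures must be <= 0 MPa")
    if len(np.unique(pressure)) < 2:
        raise NonIdentifiableError("all measurements at a single pressure")

    if scale == "plc":
        y = df["plc"].to_numpy(dtype=float)
        if np.ptp(y) == 0.0:
            raise NonIdentifiableError("PLC has zero variance; curve not identifiable")

        def resid(theta):
            b, c = theta
            return 100.0 * (1.0 - np.exp(-((-pressure / b) ** c))) - y

        lo = np.array([_B_BOUNDS[0], _C_BOUNDS[0]])
        hi = np.array([_B_BOUNDS[1], _C_BOUNDS[1]])
        starts = _MULTISTART
        build = lambda th: VulnerabilityCurve(th[0], th[1], ksmax=ksmax,
                                              organ=organ, genotype=genotype)
        names = ["b", "c"]
    else:
        y = df["ks"].to_numpy(dtype=float)
        if np.ptp(y) == 0.0:
            raise NonIdentifiableError("K_s has zero variance; curve not identifiable")
        if ksmax is None:
            def resid(theta):
                b, c, km = theta
                return km * np.exp(-((-pressure / b) ** c)) - y

            km0 = max(y.max(), 1e-6)
            lo = np.array([_B_BOUNDS[0], _C_BOUNDS[0], 1e-9])
            hi = np.array([_B_BOUNDS[1], _C_BOUNDS[1], 10.0 * km0 + 1.0])
            starts = [(b0, c0, km0) for b0, c0 in _MULTISTART]
            build = lambda th: VulnerabilityCurve(th[0], th[1], ksmax=th[2],
                                                  organ=organ, genotype=genotype)
            names = ["b", "c", "ksmax"]
        else:
            def resid(theta):
                b, c = theta
                return ksmax * np.exp(-((-pressure / b) ** c)) - y

            lo = np.array([_B_BOUNDS[0], _C_BOUNDS[0]])
            hi = np.array([_B_BOUNDS[1], _C_BOUNDS[1]])
            starts = _MULTISTART
            build = lambda th: VulnerabilityCurve(th[0], th[1], ksmax=ksmax,
                                                  organ=organ, genotype=genotype)
            names = ["b", "c"]

    best = None
    for x0 in starts:
        try:
            sol = optimize.least_squares(resid, np.clip(x0, lo, hi),
                                         bounds=(lo, hi), method="trf")
        except Exception:  # pragma: no cover - defensive
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise NonIdentifiableError("no fit converged from any start")

    rss = float(2.0 * best.cost)
    dof = max(len(df) - len(names), 1)
    sigma2 = rss / dof
    jtj = best.jac.T @ best.jac
    try:
        cov = sigma2 * np.linalg.inv(jtj)
        ses = dict(zip(names, np.sqrt(np.clip(np.diag(cov), 0.0, None))))
    except np.linalg.LinAlgError:
        ses = {n: float("nan") for n in names}

    return VCFitResult(
        curve=build(best.x),
        residual_sum_squares=rss,
        n_points=len(df),
        standard_errors=ses,
        fit_scale=scale,
        converged=bool(best.success),
    )


# ---------------------------------------------------------------------------
# genotype comparison
# ---------------------------------------------------------------------------

def anova_oneway(groups: Sequence[Sequence[float]]):
    """One-way fixed-effects ANOVA from the textbook sums of squares.

    Returns ``(F, p, df_between, df_within, ms_within)``.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least two replicates")
    n_total = sum(len(a) for a in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b = len(arrays) - 1
    df_w = n_total - len(arrays)
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0.0:
        f_stat = 0.0 if ss_between == 0.0 else float("inf")
    else:
        f_stat = ms_b / ms_w
    p_val = float(stats.f.sf(f_stat, df_b, df_w)) if np.isfinite(f_stat) else 0.0
    return float(f_stat), p_val, df_b, df_w, float(ms_w)


def tukey_hsd(groups: Sequence[Sequence[float]], labels=None, alpha: float = 0.05):
    """Tukey HSD pairwise comparisons using the studentized range distribution.

    Returns a DataFrame with one row per pair: mean difference, q statistic,
    adjusted p-value, and a significance flag at ``alpha``.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    _, _, _, df_w, ms_w = anova_oneway(arrays)
    rows = []
    for i, j in combinations(range(k), 2):
        a, b_arr = arrays[i], arrays[j]
        diff = a.mean() - b_arr.mean()
        se = math.sqrt(ms_w / 2.0 * (1.0 / len(a) + 1.0 / len(b_arr)))
        if se == 0.0:
            q = 0.0 if diff == 0.0 else float("inf")
            p_adj = 1.0 if diff == 0.0 else 0.0
        else:
            q = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q, k, df_w))
        rows.append({"group_a": labels[i], "group_b": labels[j],
                     "mean_diff": diff, "q": q, "p_adj": p_adj,
                     "significant": p_adj < alpha})
    return pd.DataFrame(rows)


def compare_vc_parameters(table: pd.DataFrame, parameters=("b", "c", "p50"),
                          alpha: float = 0.05) -> dict:
    """Compare fitted VC parameters across genotypes.

    ``table`` holds one row per biological replicate with a ``genotype`` column
    and one column per parameter.  For each parameter a one-way ANOVA across
    genotypes is run, followed by Tukey HSD pairwise tests at ``alpha``.
    """
    if "genotype" not in table.columns:
        raise ValueError("table needs a 'genotype' column")
    labels = sorted(table["genotype"].unique())
    if len(labels) < 2:
        raise ValueError("need at least two genotypes")
    report = {}
    for param in parameters:
        if param not in table.columns:
            continue
        groups = [table.loc[table["genotype"] == g, param].to_numpy(dtype=float)
                  for g in labels]
        f_stat, p_val, df_b, df_w, _ = anova_oneway(groups)
        pairs = tukey_hsd(groups, labels=labels, alpha=alpha)
        report[param] = {"F": f_stat, "p": p_val, "df": (df_b, df_w),
                         "tukey": pairs}
    return report


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def read_vc_table(path, sep="\t") -> pd.DataFrame:
    """Read a VC measurement table (columns: genotype, organ, segment_id,
    pressure_mpa, and ks and/or plc)."""
    df = pd.read_csv(path, sep=sep)
    required = {"genotype", "organ", "segment_id", "pressure_mpa"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"VC table missing columns: {sorted(missing)}")
    if "ks" not in df.columns and "plc" not in df.columns:
        raise ValueError("VC table needs a 'ks' or 'plc' column")
    return df


def write_fit_report(fits: Sequence[VCFitResult], path, sep="\t") -> None:
    rows = []
    for fr in fits:
        cv = fr.curve
        rows.append({
            "genotype": cv.genotype, "organ": cv.organ, "scale": fr.fit_scale,
            "b": cv.b, "c": cv.c, "ksmax": cv.ksmax, "p50": p50(cv),
            "rss": fr.residual_sum_squares, "n": fr.n_points,
            "se_b": fr.standard_errors.get("b"), "se_c": fr.standard_errors.get("c"),
            "converged": fr.converged,
        })
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
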