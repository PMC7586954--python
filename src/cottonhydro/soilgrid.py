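"""Field-scale soil texture interpolation.

Sparse soil samples are interpolated across the field by ordinary block
kriging: an empirical semivariogram is binned and fitted by weighted least
squares to an exponential or spherical model, the ordinary-kriging system
(with a Lagrange multiplier enforcing unit weight sum) is solved per target
block, and the block value is the average semivariance over a discretization
grid of points inside the block.  Plot-level predictions are then aggregated
to 10-plot grid cells and cells beyond the 90th / below the 10th clay
percentile are selected as the contrasting high/low-clay conditions.

Clay and sand are kriged independently per depth layer; silt closes the
composition (1 - clay - sand, clipped), avoiding compositional-kriging
machinery while preserving closure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "SoilSample",
    "VariogramModel",
    "GridCell",
    "empirical_variogram",
    "fit_variogram",
    "ordinary_krige_points",
    "block_krige",
    "aggregate_and_select_cells",
    "read_soil_samples",
]


@dataclass(frozen=True)
class SoilSample:
    """One texture sample at (x, y) over a half-open depth interval [top, bottom) cm."""

    x: float
    y: float
    depth_top: float
    depth_bottom: float
    clay: float
    sand: float
    silt: float

    def __post_init__(self) -> None:
        if abs(self.clay + self.sand + self.silt - 1.0) > 1e-6:
            raise ValueError("fractions must sum to 1")
        for name in ("clay", "sand", "silt"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} fraction out of [0, 1]")
        if self.depth_bottom <= self.depth_top:
            raise ValueError("depth_bottom must exceed depth_top")


@dataclass(frozen=True)
class VariogramModel:
    """Fitted semivariogram: gamma(h) = nugget + psill * f(h / range)."""

    model: str
    nugget: float
    partial_sill: float
    range_m: float

    def __post_init__(self) -> None:
        if self.model not in ("exponential", "spherical"):
            raise ValueError("model must be exponential or spherical")
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError("nugget and partial sill must be >= 0")
        if self.range_m <= 0:
            raise ValueError("range must be positive")

    def semivariance(self, h):
        h = np.asarray(h, dtype=float)
        if self.model == "exponential":
            struct = 1.0 - np.exp(-3.0 * h / self.range_m)
        else:
            r = np.clip(h / self.range_m, 0.0, 1.0)
            struct = 1.5 * r - 0.5 * r ** 3
        gamma = self.nugget + self.partial_sill * struct
        return np.where(h <= 0.0, 0.0, gamma)  # gamma(0) = 0 exactly


@dataclass(frozen=True)
class GridCell:
    cell_id: str
    member_plot_ids: tuple
    clay: float
    sand: float
    silt: float
    treatment: str = ""

    def __post_init__(self) -> None:
        if abs(self.clay + self.sand + self.silt - 1.0) > 1e-6:
            raise ValueError("cell fractions must sum to 1")


# ---------------------------------------------------------------------------
# variogram
# ---------------------------------------------------------------------------

def empirical_variogram(xy: np.ndarray, values: np.ndarray,
                        n_bins: int = 12, max_lag: float | None = None):
    """Binned empirical semivariogram.  Returns (lag centers, semivariance,
    pair counts), dropping empty bins."""
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
    iu = np.triu_indices(len(xy), k=1)
    lags = d[iu]
    sq = 0.5 * (values[:, None] - values[None, :]) ** 2
    semis = sq[iu]
    if max_lag is None:
        max_lag = 0.5 * lags.max()
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    centers, gammas, counts = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (lags > lo) & (lags <= hi)
        if mask.sum() == 0:
            continue
        centers.append(lags[mask].mean())
        gammas.append(semis[mask].mean())
        counts.append(int(mask.sum()))
    return np.array(centers), np.array(gammas), np.array(counts)


def fit_variogram(samples: pd.DataFrame | list, variable: str = "clay",
                  model: str = "exponential", n_bins: int = 12) -> VariogramModel:
    """Weighted least-squares fit of the empirical semivariogram.

    Bins are weighted by pair counts.  A zero-variance variable yields the
    degenerate model (nugget = sill = 0) with a warning.
    """
    df = _as_sample_frame(samples)
    if len(df) < 10:
        raise ValueError("need at least 10 samples to fit a variogram")
    xy = df[["x_m", "y_m"]].to_numpy(dtype=float)
    vals = df[variable].to_numpy(dtype=float)
    centers, gammas, counts = empirical_variogram(xy, vals, n_bins=n_bins)
    if len(centers) < 3:
        raise ValueError("fewer than 3 distinct lag bins; cannot fit")
    if np.ptp(vals) == 0.0:
        warnings.warn("zero-variance variable; degenerate variogram",
                      stacklevel=2)
        return VariogramModel(model=model, nugget=0.0, partial_sill=0.0,
                              range_m=max(centers.max(), 1.0))

    var0 = vals.var()
    w = np.sqrt(counts)

    def resid(theta):
        nug, psill, rng = theta
        vm = VariogramModel(model=model, nugget=nug, partial_sill=psill,
                            range_m=rng)
        return w * (vm.semivariance(centers) - gammas)

    lo = [0.0, 1e-12, 1e-6]
    hi = [var0 * 3 + 1e-9, var0 * 10 + 1e-9, centers.max() * 4]
    x0 = [0.1 * var0 + 1e-12, max(var0, 1e-9), centers.max() / 2]
    sol = least_squares(resid, x0, bounds=(lo, hi))
    nug, psill, rng = sol.x
    return VariogramModel(model=model, nugget=float(nug),
                          partial_sill=float(psill), range_m=float(rng))


# ---------------------------------------------------------------------------
# kriging
# ---------------------------------------------------------------------------

def _dedupe(xy: np.ndarray, values: np.ndarray):
    """Average duplicated sample locations (they make the OK system singular
    when the nugget is zero)."""
    key = np.round(xy, 9)
    uniq, idx, inv = np.unique(key, axis=0, return_index=True,
                               return_inverse=True)
    if len(idx) == len(xy):
        return xy, values
    agg = np.zeros(len(uniq))
    cnt = np.zeros(len(uniq))
    for i, g in enumerate(inv):
        agg[g] += values[i]
        cnt[g] += 1
    return uniq, agg / cnt


def _block_points(rect, discretization: int):
    x0, y0, x1, y1 = rect
    if discretization <= 1:
        return np.array([[(x0 + x1) / 2.0, (y0 + y1) / 2.0]])
    # cell-centered grid over the block
    xs = x0 + (np.arange(discretization) + 0.5) * (x1 - x0) / discretization
    ys = y0 + (np.arange(discretization) + 0.5) * (y1 - y0) / discretization
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def ordinary_krige_points(xy: np.ndarray, values: np.ndarray,
                          targets: np.ndarray, variogram: VariogramModel):
    """Ordinary kriging at point targets.

    Solves [[Gamma, 1], [1^T, 0]] [w; mu] = [gamma_0; 1] per target; weights
    sum to one by construction.  Returns (predictions, variances, weights).
    """
    xy = np.asarray(xy, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(xy)
    if n == 0:
        raise ValueError("no samples")
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
    a = np.empty((n + 1, n + 1))
    a[:n, :n] = variogram.semivariance(d)
    a[:n, n] = 1.0
    a[n, :n] = 1.0
    a[n, n] = 0.0
    d_t = np.linalg.norm(xy[:, None, :] - targets[None, :, :], axis=-1)
    rhs = np.empty((n + 1, targets.shape[0]))
    rhs[:n] = variogram.semivariance(d_t)
    rhs[n] = 1.0
    try:
        sol = np.linalg.solve(a, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular kriging system (duplicate locations with zero nugget?)"
        ) from exc
    w = sol[:n]
    mu = sol[n]
    preds = w.T @ values
    variances = np.einsum("it,it->t", w, rhs[:n]) + mu
    return preds, np.clip(variances, 0.0, None), w.T


def block_krige(samples, variogram: VariogramModel, target_blocks,
                variable: str = "clay", discretization: int = 4,
                extrapolation_warn_factor: float = 2.0):
    """Ordinary kriging with block support.

    ``target_blocks`` is a list of rectangles (x0, y0, x1, y1); the block
    prediction is the average of point predictions over a ``discretization`` x
    ``discretization`` grid inside the block (identical, by linearity, to
    kriging with block-averaged right-hand sides).  Returns a DataFrame with
    prediction and kriging variance per block.
    """
    df = _as_sample_frame(samples)
    xy = df[["x_m", "y_m"]].to_numpy(dtype=float)
    values = df[variable].to_numpy(dtype=float)
    xy, values = _dedupe(xy, values)

    # warn on far extrapolation
    if len(xy) > 1:
        d_samp = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
        max_spacing = d_samp.max()
        for rect in target_blocks:
            cx, cy = (rect[0] + rect[2]) / 2.0, (rect[1] + rect[3]) / 2.0
            nearest = np.min(np.hypot(xy[:, 0] - cx, xy[:, 1] - cy))
            if nearest > extrapolation_warn_factor * max_spacing:
                warnings.warn(f"block centered at ({cx:.1f}, {cy:.1f}) is far "
                              "outside the sampled area", stacklevel=2)
                break

    rows = []
    for rect in target_blocks:
        pts = _block_points(rect, discretization)
        preds, variances, w = ordinary_krige_points(xy, values, pts, variogram)
        rows.append({"prediction": float(preds.mean()),
                     "variance": float(variances.mean()),
                     "weights_sum": float(w.sum(axis=1).mean())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cell aggregation and selection
# ---------------------------------------------------------------------------

def aggregate_and_select_cells(plot_values: pd.DataFrame, layout: pd.DataFrame,
                               low_pct: float = 10.0, high_pct: float = 90.0,
                               expected_plots_per_cell: int | None = None):
    """Aggregate plot fractions to grid cells and select contrasting cells.

    ``plot_values``: columns plot_id, clay, sand, silt.  ``layout``: columns
    plot_id, cell_id (and optionally treatment).  Cell fractions are the mean
    of member plots, renormalized to closure.  Returns ``(cells, high, low)``
    where high/low are the cells at or beyond the clay percentiles (linear
    interpolation between order statistics; boundary ties included).
    """
    merged = plot_values.merge(layout, on="plot_id", how="left")
    if merged["cell_id"].isna().any():
        missing = merged.loc[merged["cell_id"].isna(), "plot_id"].tolist()
        raise ValueError(f"plots not assigned to any cell: {missing[:5]}")
    unassigned = set(layout["plot_id"]) - set(plot_values["plot_id"])
    if unassigned:
        raise ValueError(f"layout references unknown plots: {sorted(unassigned)[:5]}")

    cells = []
    for cell_id, grp in merged.groupby("cell_id"):
        if expected_plots_per_cell is not None \
                and len(grp) != expected_plots_per_cell:
            raise ValueError(f"cell {cell_id} has {len(grp)} plots, "
                             f"expected {expected_plots_per_cell}")
        clay, sand, silt = grp["clay"].mean(), grp["sand"].mean(), grp["silt"].mean()
        total = clay + sand + silt
        treatment = grp["treatment"].iloc[0] if "treatment" in grp.columns else ""
        cells.append(GridCell(cell_id=str(cell_id),
                              member_plot_ids=tuple(grp["plot_id"]),
                              clay=clay / total, sand=sand / total,
                              silt=silt / total, treatment=str(treatment)))
    clays = np.array([c.clay for c in cells])
    lo_thr = np.percentile(clays, low_pct)
    hi_thr = np.percentile(clays, high_pct)
    low = [c for c in cells if c.clay <= lo_thr]
    high = [c for c in cells if c.clay >= hi_thr]
    return cells, high, low


def representative_texture(cells) -> tuple[float, float, float]:
    """Average selected cells into one representative clay/sand/silt triple
    (the construction used to derive the high/low-clay parameter sets)."""
    clay = float(np.mean([c.clay for c in cells]))
    sand = float(np.mean([c.sand for c in cells]))
    silt = float(np.mean([c.silt for c in cells]))
    total = clay + sand + silt
    return clay / total, sand / total, silt / total


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _as_sample_frame(samples) -> pd.DataFrame:
    if isinstance(samples, pd.DataFrame):
        return samples
    rows = [{"x_m": s.x, "y_m": s.y, "depth_top_cm": s.depth_top,
             "depth_bottom_cm": s.depth_bottom, "clay": s.clay,
             "sand": s.sand, "silt": s.silt} for s in samples]
    return pd.DataFrame(rows)


def read_soil_samples(path, sep="\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    required = {"x_m", "y_m", "depth_top_cm", "depth_bottom_cm",
                "clay", "sand", "silt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"soil sample table missing columns: {sorted(missing)}")
    return df
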