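"""MAP binning, polynomial U-curve fitting and nadir (optimal-MAP) extraction.

The core of the method: each index series (PRx or P2/P1) is stratified into
1-mmHg MAP bins using each window's mean MAP; a least-squares polynomial
(default degree 2) is fitted to the per-bin summary, weighted by bin counts;
the optimal MAP is the curve's lowest point (nadir) over the observed MAP
span.  Quality gates refuse a nadir when MAP coverage is too thin (too few
bins, too narrow a span, too few windows per bin), when the minimum sits on
the boundary of the observed span (no U, only a trend) or when the quadratic
is concave.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .indices import IndexSeries

__all__ = [
    "CurveValidity",
    "MAPBinProfile",
    "CurveFit",
    "MapoptResult",
    "OptimalBandStats",
    "bin_by_map",
    "fit_curve",
    "find_nadir",
    "estimate_mapopt",
    "optimal_band_stats",
]


class CurveValidity(str, Enum):
    VALID_U_SHAPE = "valid_u_shape"
    NADIR_AT_BOUNDARY = "nadir_at_boundary"
    INSUFFICIENT_DATA = "insufficient_data"
    NON_CONVEX = "non_convex"


@dataclass
class MAPBinProfile:
    """Index values grouped into half-open 1-mmHg MAP bins [m, m+1)."""

    bin_left_edges: np.ndarray          # mmHg, integer-valued floors
    values: list[np.ndarray]            # raw window values per bin
    source_index: str
    bin_width: float = 1.0

    @property
    def bin_centers(self) -> np.ndarray:
        return self.bin_left_edges + self.bin_width / 2.0

    @property
    def counts(self) -> np.ndarray:
        return np.asarray([v.size for v in self.values])

    @property
    def means(self) -> np.ndarray:
        return np.asarray([np.mean(v) if v.size else np.nan for v in self.values])

    @property
    def medians(self) -> np.ndarray:
        return np.asarray([np.median(v) if v.size else np.nan for v in self.values])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left_mmhg": self.bin_left_edges,
                "bin_center_mmhg": self.bin_centers,
                "count": self.counts,
                "mean": self.means,
                "median": self.medians,
            }
        )


@dataclass
class CurveFit:
    coefficients: np.ndarray            # numpy polynomial (highest power first)
    degree: int
    r_squared: float
    bin_centers: np.ndarray             # bins used in the fit
    bin_targets: np.ndarray
    bin_weights: np.ndarray
    map_span: tuple[float, float]       # closed observed span of used bins

    def __call__(self, m):
        return np.polyval(self.coefficients, m)


@dataclass
class MapoptResult:
    """Outcome of the nadir search for one session and one index."""

    mapopt: float | None
    validity: CurveValidity
    fit: CurveFit | None = None
    profile: MAPBinProfile | None = None
    index_name: str = ""

    @property
    def is_valid(self) -> bool:
        return self.validity is CurveValidity.VALID_U_SHAPE


@dataclass
class OptimalBandStats:
    band: tuple[float, float]           # mmHg
    n: int
    median: float | None = None
    iqr: tuple[float, float] | None = None
    mean: float | None = None
    sd: float | None = None


def bin_by_map(series: IndexSeries, bin_width: float = 1.0) -> MAPBinProfile:
    """Assign each valid window's value to the bin [floor(MAP), floor(MAP)+1).

    Bins are contiguous over the observed span (empty bins retained), so the
    total count always equals the number of valid windows.
    """
    ok = series.valid & ~np.isnan(series.value) & ~np.isnan(series.window_mean_map)
    maps = series.window_mean_map[ok]
    vals = series.value[ok]
    if maps.size == 0:
        return MAPBinProfile(
            bin_left_edges=np.array([]), values=[], source_index=series.name,
            bin_width=bin_width,
        )
    which = np.floor(maps / bin_width).astype(int)
    lo, hi = which.min(), which.max()
    edges = np.arange(lo, hi + 1) * bin_width
    values = [vals[which == k] for k in range(lo, hi + 1)]
    return MAPBinProfile(
        bin_left_edges=edges.astype(float),
        values=values,
        source_index=series.name,
        bin_width=bin_width,
    )


def fit_curve(
    profile: MAPBinProfile,
    degree: int = 2,
    min_bins: int = 5,
    min_span_mmhg: float = 8.0,
    min_per_bin: int = 3,
    fit_target: str = "mean",
) -> CurveFit | None:
    """Count-weighted least-squares polynomial through the per-bin summary.

    ``fit_target``: "mean" (default), "median", or "raw" (every window value
    enters individually).  Bins with fewer than ``min_per_bin`` windows are
    excluded; returns None (insufficient data) when fewer than ``min_bins``
    bins survive or they span less than ``min_span_mmhg``.
    """
    counts = profile.counts
    keep = counts >= min_per_bin
    if keep.sum() < min_bins:
        return None
    centers = profile.bin_centers[keep]
    span = (float(centers.min()), float(centers.max()))
    if span[1] - span[0] < min_span_mmhg:
        return None
    if fit_target == "mean":
        targets = profile.means[keep]
        weights = counts[keep].astype(float)
    elif fit_target == "median":
        targets = profile.medians[keep]
        weights = counts[keep].astype(float)
    elif fit_target == "raw":
        centers = np.concatenate(
            [np.full(v.size, c) for c, v, k in zip(profile.bin_centers, profile.values, keep) if k]
        )
        targets = np.concatenate([v for v, k in zip(profile.values, keep) if k])
        weights = np.ones_like(targets)
    else:
        raise ValueError("fit_target must be 'mean', 'median' or 'raw'")
    if centers.size <= degree:
        return None
    try:
        # np.polyfit's w multiplies residuals, so sqrt(count) realises count weights
        coeffs = np.polyfit(centers, targets, deg=degree, w=np.sqrt(weights))
    except np.linalg.LinAlgError:
        return None
    fitted = np.polyval(coeffs, centers)
    wmean = np.average(targets, weights=weights)
    ss_res = float(np.sum(weights * (targets - fitted) ** 2))
    ss_tot = float(np.sum(weights * (targets - wmean) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return CurveFit(
        coefficients=coeffs,
        degree=degree,
        r_squared=r2,
        bin_centers=centers,
        bin_targets=targets,
        bin_weights=weights,
        map_span=span,
    )


_GRID_STEP = 0.01  # mmHg, dense-grid nadir resolution for degree > 2


def find_nadir(fit: CurveFit | None, profile: MAPBinProfile | None = None,
               index_name: str = "") -> MapoptResult:
    """Locate the fitted curve's minimum over the closed observed MAP span.

    Degree 2 uses the closed-form vertex; higher degrees a 0.01-mmHg grid.
    An interior strict minimum with positive local curvature is a valid
    U-shape; a boundary minimum or a concave quadratic withholds the nadir.
    """
    if fit is None:
        return MapoptResult(
            mapopt=None, validity=CurveValidity.INSUFFICIENT_DATA,
            profile=profile, index_name=index_name,
        )
    lo, hi = fit.map_span
    edge_tol = 1e-9
    if fit.degree == 2:
        a, b = fit.coefficients[0], fit.coefficients[1]
        if a <= 0:
            validity = CurveValidity.NON_CONVEX if a < 0 else CurveValidity.NADIR_AT_BOUNDARY
            return MapoptResult(
                mapopt=None, validity=validity, fit=fit, profile=profile,
                index_name=index_name,
            )
        vertex = -b / (2.0 * a)
        if vertex <= lo + edge_tol or vertex >= hi - edge_tol:
            return MapoptResult(
                mapopt=None, validity=CurveValidity.NADIR_AT_BOUNDARY,
                fit=fit, profile=profile, index_name=index_name,
            )
        return MapoptResult(
            mapopt=float(vertex), validity=CurveValidity.VALID_U_SHAPE,
            fit=fit, profile=profile, index_name=index_name,
        )
    grid = np.arange(lo, hi + _GRID_STEP / 2, _GRID_STEP)
    values = fit(grid)
    k = int(np.argmin(values))
    if k == 0 or k == grid.size - 1:
        return MapoptResult(
            mapopt=None, validity=CurveValidity.NADIR_AT_BOUNDARY,
            fit=fit, profile=profile, index_name=index_name,
        )
    return MapoptResult(
        mapopt=float(grid[k]), validity=CurveValidity.VALID_U_SHAPE,
        fit=fit, profile=profile, index_name=index_name,
    )


def estimate_mapopt(
    series: IndexSeries,
    bin_width: float = 1.0,
    degree: int = 2,
    min_bins: int = 5,
    min_span_mmhg: float = 8.0,
    min_per_bin: int = 3,
    fit_target: str = "mean",
) -> MapoptResult:
    """Convenience chain: bin_by_map -> fit_curve -> find_nadir."""
    profile = bin_by_map(series, bin_width=bin_width)
    fit = fit_curve(
        profile, degree=degree, min_bins=min_bins,
        min_span_mmhg=min_span_mmhg, min_per_bin=min_per_bin,
        fit_target=fit_target,
    )
    return find_nadir(fit, profile=profile, index_name=series.name)


def optimal_band_stats(
    p2p1_series: IndexSeries, mapopt: float, half_width: float = 5.0
) -> OptimalBandStats:
    """P2/P1 distribution inside the optimal band [mapopt - h, mapopt + h]."""
    band = (mapopt - half_width, mapopt + half_width)
    ok = p2p1_series.valid & ~np.isnan(p2p1_series.value)
    sel = ok & (p2p1_series.window_mean_map >= band[0]) & (
        p2p1_series.window_mean_map <= band[1]
    )
    vals = p2p1_series.value[sel]
    if vals.size == 0:
        warnings.warn("no P2/P1 windows inside the optimal band")
        return OptimalBandStats(band=band, n=0)
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return OptimalBandStats(
        band=band,
        n=int(vals.size),
        median=float(med),
        iqr=(float(q1), float(q3)),
        mean=float(np.mean(vals)),
        sd=float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
    )
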