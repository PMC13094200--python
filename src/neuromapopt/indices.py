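"""Block-averaged signals and moving-window indices on the 5-min/10-s grid.

The pressure-reactivity index (PRx) is the moving Pearson correlation between
block-averaged mean arterial pressure (MAP) and intracranial pressure (ICP):
10-second block means strip the cardiac and respiratory bands, a 5-minute
window (30 blocks) captures the slow-wave band, and the window slides in
10-second steps.  The same machinery produces a P2/P1 morphology series in
two modes: *direct* (window value = mean of the window's P2/P1 blocks, as
binned against MAP downstream) and *correlation* (Pearson correlation of
P2/P1 blocks with MAP blocks, the PRx-like surrogate).

Each window also records its mean MAP (mean of the window's MAP blocks),
which downstream binning uses, and a validity flag: a window is invalid when
fewer than ``min_valid_blocks`` paired blocks survive masking, or (for
correlation indices) when either channel's block variance falls below a
1e-6 mmHg^2 floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WindowSpec",
    "IndexSeries",
    "block_average",
    "moving_correlation",
    "window_count",
    "p2p1_window_series",
    "classify_reactivity",
]

VARIANCE_FLOOR = 1e-6  # mmHg^2


@dataclass
class WindowSpec:
    """Moving-window geometry: 5-min window, 10-s step, 10-s averaging blocks."""

    window_length: float = 300.0
    step: float = 10.0
    block_length: float = 10.0
    min_valid_blocks: int = 24

    def __post_init__(self) -> None:
        for name in ("window_length", "step", "block_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if abs(self.window_length / self.block_length - round(self.window_length / self.block_length)) > 1e-9:
            raise ValueError("window_length must be a multiple of block_length")
        if abs(self.step / self.block_length - round(self.step / self.block_length)) > 1e-9:
            raise ValueError("step must be a multiple of block_length")
        if self.min_valid_blocks > self.blocks_per_window:
            raise ValueError("min_valid_blocks exceeds blocks per window")

    @property
    def blocks_per_window(self) -> int:
        return int(round(self.window_length / self.block_length))

    @property
    def step_blocks(self) -> int:
        return int(round(self.step / self.block_length))


@dataclass
class IndexSeries:
    """Per-step values of one index with each window's mean MAP."""

    name: str                       # "PRx" | "P2P1" | "P2P1corr"
    window_center_time: np.ndarray  # s
    value: np.ndarray               # dimensionless; NaN where invalid
    window_mean_map: np.ndarray     # mmHg
    n_blocks: np.ndarray            # valid paired blocks per window
    valid: np.ndarray               # bool

    def __len__(self) -> int:
        return self.value.size

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_center_s": self.window_center_time,
                "index_name": self.name,
                "value": self.value,
                "window_mean_map_mmhg": self.window_mean_map,
                "n_blocks": self.n_blocks,
                "valid": self.valid,
            }
        )


def block_average(
    signal: np.ndarray,
    sampling_rate: float,
    block_length: float = 10.0,
    mask: np.ndarray | None = None,
    max_masked_frac: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean of unmasked samples per block; blocks with > ``max_masked_frac``
    masked samples become NaN.  Returns (block start times, block means);
    a trailing partial block is dropped."""
    signal = np.asarray(signal, dtype=float)
    spb = int(round(block_length * sampling_rate))
    n_blocks = signal.size // spb
    if n_blocks == 0:
        return np.array([]), np.array([])
    x = signal[: n_blocks * spb].reshape(n_blocks, spb)
    times = np.arange(n_blocks) * block_length
    if mask is None:
        return times, x.mean(axis=1)
    m = np.asarray(mask, dtype=bool)[: n_blocks * spb].reshape(n_blocks, spb)
    frac = m.mean(axis=1)
    with np.errstate(invalid="ignore"):
        sums = np.where(~m, x, 0.0).sum(axis=1)
        counts = (~m).sum(axis=1)
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    means[frac > max_masked_frac] = np.nan
    return times, means


def window_count(duration: float, spec: WindowSpec | None = None) -> int:
    """Number of moving windows: floor((duration - window)/step) + 1; zero
    (with a warning) when the recording is shorter than one window."""
    spec = spec or WindowSpec()
    if duration < spec.window_length:
        warnings.warn("duration shorter than one window; no windows produced")
        return 0
    return int(np.floor((duration - spec.window_length) / spec.step + 1e-9)) + 1


def _window_slices(n_blocks_total: int, spec: WindowSpec):
    nb, step = spec.blocks_per_window, spec.step_blocks
    start = 0
    while start + nb <= n_blocks_total:
        yield start, start + nb
        start += step


def moving_correlation(
    x_blocks: np.ndarray,
    y_blocks: np.ndarray,
    map_blocks: np.ndarray | None = None,
    spec: WindowSpec | None = None,
    name: str = "PRx",
) -> IndexSeries:
    """Per-step Pearson correlation of paired blocks inside each window.

    ``x_blocks``/``y_blocks`` must share one block grid (NaN = missing block).
    ``map_blocks`` supplies the MAP channel for ``window_mean_map`` (defaults
    to ``x_blocks``, the usual MAP-as-input convention).
    """
    spec = spec or WindowSpec()
    x = np.asarray(x_blocks, dtype=float)
    y = np.asarray(y_blocks, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y block grids differ in length")
    m = x if map_blocks is None else np.asarray(map_blocks, dtype=float)
    if m.shape != x.shape:
        raise ValueError("map block grid differs in length")

    centers, vals, maps, counts, valid = [], [], [], [], []
    for lo, hi in _window_slices(x.size, spec):
        xs, ys, ms = x[lo:hi], y[lo:hi], m[lo:hi]
        pair_ok = ~(np.isnan(xs) | np.isnan(ys))
        n_ok = int(pair_ok.sum())
        centers.append((lo * spec.block_length + spec.window_length / 2.0))
        counts.append(n_ok)
        map_ok = ms[~np.isnan(ms)]
        maps.append(float(np.mean(map_ok)) if map_ok.size else np.nan)
        if n_ok < spec.min_valid_blocks:
            vals.append(np.nan)
            valid.append(False)
            continue
        xv, yv = xs[pair_ok], ys[pair_ok]
        vx, vy = np.var(xv), np.var(yv)
        if vx < VARIANCE_FLOOR or vy < VARIANCE_FLOOR:
            vals.append(np.nan)
            valid.append(False)
            continue
        r = float(np.mean((xv - xv.mean()) * (yv - yv.mean())) / np.sqrt(vx * vy))
        vals.append(min(max(r, -1.0), 1.0))
        valid.append(True)
    return IndexSeries(
        name=name,
        window_center_time=np.asarray(centers),
        value=np.asarray(vals),
        window_mean_map=np.asarray(maps),
        n_blocks=np.asarray(counts, dtype=int),
        valid=np.asarray(valid, dtype=bool),
    )


def p2p1_window_series(
    p2p1_blocks: np.ndarray,
    map_blocks: np.ndarray,
    spec: WindowSpec | None = None,
) -> IndexSeries:
    """Direct-mode morphology series: window value = mean of its P2/P1 blocks.

    Validity requires ``min_valid_blocks`` paired (P2/P1, MAP) blocks; the
    correlation variance floor does not apply.
    """
    spec = spec or WindowSpec()
    p = np.asarray(p2p1_blocks, dtype=float)
    m = np.asarray(map_blocks, dtype=float)
    if p.shape != m.shape:
        raise ValueError("p2p1 and map block grids differ in length")
    centers, vals, maps, counts, valid = [], [], [], [], []
    for lo, hi in _window_slices(p.size, spec):
        ps, ms = p[lo:hi], m[lo:hi]
        pair_ok = ~(np.isnan(ps) | np.isnan(ms))
        n_ok = int(pair_ok.sum())
        centers.append(lo * spec.block_length + spec.window_length / 2.0)
        counts.append(n_ok)
        map_ok = ms[~np.isnan(ms)]
        maps.append(float(np.mean(map_ok)) if map_ok.size else np.nan)
        if n_ok < spec.min_valid_blocks:
            vals.append(np.nan)
            valid.append(False)
        else:
            vals.append(float(np.mean(ps[pair_ok])))
            valid.append(True)
    return IndexSeries(
        name="P2P1",
        window_center_time=np.asarray(centers),
        value=np.asarray(vals),
        window_mean_map=np.asarray(maps),
        n_blocks=np.asarray(counts, dtype=int),
        valid=np.asarray(valid, dtype=bool),
    )


def classify_reactivity(prx_value: float, threshold: float = 0.25) -> str:
    """Clinical dichotomy: cerebrovascular reactivity is ``"impaired"`` iff
    PRx strictly exceeds the cutoff (0.25 default, 0.3 also in clinical use),
    else ``"intact"``."""
    if not -1.0 <= prx_value <= 1.0:
        raise ValueError("PRx must lie in [-1, 1]")
    return "impaired" if prx_value > threshold else "intact"
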