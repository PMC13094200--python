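"""Figure helpers: U-curve pair, inter-method scatter, Bland-Altman, band histogram."""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .agreement import BlandAltmanResult, SessionPair
from .mapopt import MapoptResult

__all__ = [
    "plot_u_curves",
    "plot_method_scatter",
    "plot_bland_altman",
    "plot_band_distribution",
]


def _u_panel(ax, result: MapoptResult, ylabel: str) -> None:
    prof = result.profile
    if prof is not None and prof.counts.size:
        keep = prof.counts > 0
        ax.boxplot(
            [v for v, k in zip(prof.values, keep) if k],
            positions=prof.bin_centers[keep],
            widths=0.7,
            manage_ticks=False,
            flierprops={"markersize": 2},
        )
    if result.fit is not None:
        lo, hi = result.fit.map_span
        grid = np.linspace(lo, hi, 200)
        ax.plot(grid, result.fit(grid), color="crimson", lw=2)
    if result.mapopt is not None:
        ax.axvline(result.mapopt, color="crimson", ls="--", lw=1)
        ax.set_title(f"optimal MAP = {result.mapopt:.2f} mmHg ({result.validity.value})")
    else:
        ax.set_title(result.validity.value)
    ax.set_xlabel("MAP (mmHg)")
    ax.set_ylabel(ylabel)


def plot_u_curves(prx_result: MapoptResult, p2p1_result: MapoptResult, path) -> None:
    """Two stacked panels: PRx and P2/P1 versus 1-mmHg MAP bins with the
    fitted polynomial and its nadir."""
    fig, axes = plt.subplots(2, 1, figsize=(7, 7), sharex=True)
    _u_panel(axes[0], prx_result, "PRx")
    _u_panel(axes[1], p2p1_result, "P2/P1 ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_method_scatter(
    pairs: list[SessionPair], slope: float | None, intercept: float | None, path
) -> None:
    """Session-level scatter of the two optimal-MAP estimates with the OLS line."""
    x = np.asarray([p.mapopt_prx for p in pairs if p.both_valid])
    y = np.asarray([p.mapopt_p2p1 for p in pairs if p.both_valid])
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(x, y, s=18, alpha=0.7)
    if slope is not None and x.size:
        grid = np.linspace(x.min(), x.max(), 2)
        ax.plot(grid, slope * grid + intercept, color="crimson",
                label=f"y = {slope:.3f}x + {intercept:.3f}")
        ax.legend()
    lims = ax.get_xlim()
    ax.plot(lims, lims, color="grey", ls=":", lw=1)
    ax.set_xlabel("optimal MAP from PRx (mmHg)")
    ax.set_ylabel("optimal MAP from P2/P1 (mmHg)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_bland_altman(ba: BlandAltmanResult, path) -> None:
    """Difference (PRx-method minus P2/P1-method) versus pair mean, with bias
    and 95% limits of agreement."""
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.scatter(ba.means, ba.diffs, s=18, alpha=0.7)
    ax.axhline(ba.bias, color="crimson", label=f"bias = {ba.bias:+.2f} mmHg")
    for v in (ba.loa_low, ba.loa_high):
        ax.axhline(v, color="grey", ls="--")
    ax.set_xlabel("mean of methods (mmHg)")
    ax.set_ylabel("difference PRx − P2/P1 (mmHg)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_band_distribution(values: np.ndarray, path, band_label: str = "") -> None:
    """Histogram of P2/P1 window values inside the optimal MAP band."""
    values = np.asarray(values, dtype=float)
    fig, ax = plt.subplots(figsize=(6, 4))
    if values.size:
        ax.hist(values, bins=30, color="steelblue", alpha=0.8)
        ax.axvline(np.median(values), color="crimson",
                   label=f"median = {np.median(values):.3f}")
        ax.legend()
    ax.set_xlabel(f"P2/P1 ratio {band_label}")
    ax.set_ylabel("windows")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
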