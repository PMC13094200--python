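"""Beat segmentation and ICP pulse-morphology (P1/P2/P3) landmark detection.

The intracranial pulse carries three sub-peaks: P1 (percussion), P2 (tidal)
and P3 (dicrotic).  The P2/P1 amplitude ratio — second peak over first, both
measured above the beat's own pulse foot — rises as intracranial compliance
falls, and is the noninvasive index this package evaluates.  Bedside devices
compute the ratio internally; this module is a documented stand-in detector
validated against simulated morphology:

1. pulse feet are found on the ABP channel by a steepest-upstroke-then-
   local-minimum rule (ICP fallback when ABP is absent/flat);
2. each ICP beat is lightly smoothed (zero-phase low-pass, default 15 Hz)
   and its local maxima become landmark candidates; when fewer than two
   maxima exist, shoulder candidates are recovered from sign changes of the
   curvature (second derivative);
3. P1 is the earliest candidate inside its latency window (default first
   40% of the beat), P2 the next inside 20-70%; amplitudes are read off the
   *raw* waveform above the foot value, so smoothing never biases the ratio.

Beats are quality-flagged (``ok`` / ``merged_peaks`` / ``low_amplitude`` /
``rejected``); block means use ``ok`` beats only by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import signal as sps

from .signal_io import WaveformRecording

__all__ = [
    "BeatQuality",
    "BeatLandmarks",
    "BeatSeries",
    "LandmarkConfig",
    "detect_beats",
    "locate_landmarks",
    "extract_beats",
    "p2p1_block_means",
]

#: physiological inter-beat interval bounds (s) for ok beats
IBI_BOUNDS = (0.3, 2.0)


class BeatQuality(str, Enum):
    OK = "ok"
    MERGED_PEAKS = "merged_peaks"
    LOW_AMPLITUDE = "low_amplitude"
    REJECTED = "rejected"


@dataclass
class BeatLandmarks:
    """Landmarks of one ICP beat; amplitudes in mmHg above the foot value."""

    foot_time: float
    foot_value: float
    p1_time: float | None = None
    p2_time: float | None = None
    p3_time: float | None = None
    p1_amp: float | None = None
    p2_amp: float | None = None
    p3_amp: float | None = None
    p2p1_ratio: float | None = None
    quality_flag: BeatQuality = BeatQuality.REJECTED


@dataclass
class BeatSeries:
    """Ordered beats with each beat's mean MAP (from the ABP channel)."""

    beats: list[BeatLandmarks]
    beat_map: np.ndarray          # mmHg, one per beat
    source: str = "icp"

    def __len__(self) -> int:
        return len(self.beats)

    def ratios(self, ok_only: bool = True) -> np.ndarray:
        vals = [
            b.p2p1_ratio
            for b in self.beats
            if b.p2p1_ratio is not None
            and (not ok_only or b.quality_flag is BeatQuality.OK)
        ]
        return np.asarray(vals, dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, b in enumerate(self.beats):
            rows.append(
                {
                    "beat": i,
                    "foot_time_s": b.foot_time,
                    "foot_mmhg": b.foot_value,
                    "p1_time_s": b.p1_time,
                    "p2_time_s": b.p2_time,
                    "p3_time_s": b.p3_time,
                    "p1_amp_mmhg": b.p1_amp,
                    "p2_amp_mmhg": b.p2_amp,
                    "p3_amp_mmhg": b.p3_amp,
                    "p2p1_ratio": b.p2p1_ratio,
                    "quality": b.quality_flag.value,
                    "beat_map_mmhg": self.beat_map[i],
                }
            )
        return pd.DataFrame(rows)


@dataclass
class LandmarkConfig:
    """Tunables of the landmark detector; windows are fractions of beat length."""

    smooth_cutoff_hz: float = 15.0
    p1_window: tuple[float, float] = (0.0, 0.40)
    p2_window: tuple[float, float] = (0.20, 0.70)
    min_p1_amp: float = 0.5          # mmHg; below → low_amplitude
    min_p1_frac: float = 0.3         # P1 must carry this share of the beat's
                                     # excursion, else it is a misdetection
    min_prominence_frac: float = 0.10  # of the beat's excursion; rejects noise ripples
    max_masked_frac: float = 0.2     # beat rejected beyond this
    include_merged: bool = False     # admit merged_peaks beats into block means


def _lowpass(x: np.ndarray, fs: float, cutoff_hz: float) -> np.ndarray:
    """Zero-phase low-pass; removes sample noise without shifting peak latency."""
    nyq = fs / 2.0
    if cutoff_hz >= nyq:
        return x.copy()
    sos = sps.butter(4, cutoff_hz / nyq, output="sos")
    return sps.sosfiltfilt(sos, x)


def detect_beats(
    recording: WaveformRecording,
    min_ibi: float = IBI_BOUNDS[0],
    smooth_cutoff_hz: float = 15.0,
    min_upstroke_mmhg_s: float = 20.0,
) -> np.ndarray:
    """Locate pulse feet (seconds) on the ABP channel.

    Steepest-upstroke-then-local-minimum rule: upstrokes are peaks of the
    smoothed derivative separated by at least ``min_ibi``; each foot is the
    signal minimum in the 0.25 s preceding its upstroke.  Feet inside masked
    regions are suppressed.  No detectable pulsatility returns an empty array
    with a warning.
    """
    fs = recording.sampling_rate
    x = recording.abp
    if x.size < int(5 * fs):
        warnings.warn("need >= 5 s of signal for beat detection")
        return np.array([])
    xs = _lowpass(x, fs, smooth_cutoff_hz)
    d = np.gradient(xs) * fs  # mmHg/s
    scale = np.percentile(d, 99)
    if scale < min_upstroke_mmhg_s:
        warnings.warn("no detectable pulsatility in ABP channel")
        return np.array([])
    peaks, _ = sps.find_peaks(d, height=0.35 * scale, distance=max(int(min_ibi * fs), 1))
    look_back = int(round(0.25 * fs))
    feet_idx = []
    for u in peaks:
        lo = max(u - look_back, 0)
        seg = xs[lo : u + 1]
        base = seg.min()
        # last sample still near the minimum: robust to a flat diastole,
        # where the absolute minimum lands on noise far from the upstroke
        near = np.flatnonzero(seg <= base + 0.05 * (seg[-1] - base))
        feet_idx.append(lo + int(near[-1]) if near.size else lo + int(np.argmin(seg)))
    feet_idx = np.unique(feet_idx)
    if feet_idx.size:
        keep = np.r_[True, np.diff(feet_idx) >= int(min_ibi * fs)]
        feet_idx = feet_idx[keep]
    if recording.artifact_mask is not None and feet_idx.size:
        feet_idx = feet_idx[~recording.artifact_mask[feet_idx]]
    return feet_idx / fs


def _local_maxima(x: np.ndarray, min_prominence: float = 0.0) -> np.ndarray:
    if x.size < 3:
        return np.array([], dtype=int)
    if min_prominence > 0:
        peaks, _ = sps.find_peaks(x, prominence=min_prominence)
        return peaks
    interior = (x[1:-1] > x[:-2]) & (x[1:-1] >= x[2:])
    return np.flatnonzero(interior) + 1


def _curvature_candidates(x: np.ndarray) -> np.ndarray:
    """Shoulder recovery: indices where the second derivative changes sign."""
    if x.size < 4:
        return np.array([], dtype=int)
    d2 = np.diff(x, 2)
    sign = np.sign(d2)
    flips = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    return flips + 1


def locate_landmarks(
    segment: np.ndarray,
    foot_time: float,
    foot_value: float,
    fs: float,
    config: LandmarkConfig | None = None,
    smoothed: np.ndarray | None = None,
    masked_frac: float = 0.0,
) -> BeatLandmarks:
    """Identify P1/P2(/P3) on one beat segment starting at the pulse foot.

    ``segment`` is the raw ICP slice spanning the beat; ``smoothed`` the
    corresponding slice of the low-passed channel (computed here if absent).
    """
    config = config or LandmarkConfig()
    out = BeatLandmarks(foot_time=foot_time, foot_value=foot_value)
    n = segment.size
    if n < 4 or masked_frac > config.max_masked_frac:
        return out
    if smoothed is None:
        smoothed = _lowpass(segment, fs, config.smooth_cutoff_hz)

    excursion = float(np.ptp(smoothed))
    cands = _local_maxima(smoothed, config.min_prominence_frac * excursion)
    merged = False
    if cands.size < 2:
        cands = np.unique(np.r_[cands, _curvature_candidates(smoothed)])
        merged = True
    if cands.size == 0:
        return out

    beat_len = n / fs
    frac = cands / n

    def pick(window: tuple[float, float], after_idx: int = -1) -> int | None:
        sel = cands[(frac >= window[0]) & (frac <= window[1]) & (cands > after_idx)]
        return int(sel[0]) if sel.size else None

    i1 = pick(config.p1_window, after_idx=0)
    if i1 is None:
        return out
    i2 = pick(config.p2_window, after_idx=i1)
    if i2 is None:
        return out
    i3_cands = cands[(cands > i2) & (frac <= 0.95)]
    i3 = int(i3_cands[0]) if i3_cands.size else None

    # amplitudes are measured above the beat's foot-to-foot baseline so that
    # slow pressure drift within the beat cannot tilt the P2/P1 ratio
    base_start = float(smoothed[0])
    base_slope = (float(smoothed[-1]) - base_start) / max(n - 1, 1)

    def amp_at(i: int) -> tuple[float, float]:
        lo, hi = max(i - 2, 0), min(i + 3, n)
        j = lo + int(np.argmax(segment[lo:hi]))
        baseline = base_start + base_slope * j
        return segment[j] - baseline, foot_time + j / fs

    out.p1_amp, out.p1_time = amp_at(i1)
    out.p2_amp, out.p2_time = amp_at(i2)
    if out.p2_time <= out.p1_time:
        out.p2_time = foot_time + i2 / fs  # keep ordering under flat plateaus
    if i3 is not None:
        out.p3_amp, out.p3_time = amp_at(i3)
        if out.p3_time <= out.p2_time:
            out.p3_amp, out.p3_time = None, None
    max_excursion = float(np.max(segment)) - foot_value
    if (
        out.p1_amp <= 0
        or out.p1_amp < config.min_p1_amp
        or out.p1_amp < config.min_p1_frac * max_excursion
    ):
        out.quality_flag = BeatQuality.LOW_AMPLITUDE
        if out.p1_amp > 0:
            out.p2p1_ratio = out.p2_amp / out.p1_amp
        return out
    out.p2p1_ratio = out.p2_amp / out.p1_amp
    out.quality_flag = BeatQuality.MERGED_PEAKS if merged else BeatQuality.OK
    return out


def extract_beats(
    recording: WaveformRecording,
    config: LandmarkConfig | None = None,
    feet: np.ndarray | None = None,
) -> BeatSeries:
    """Full per-beat pipeline: feet -> landmarks -> per-beat mean MAP.

    When the recording carries a device-provided ``p2p1`` channel, landmark
    detection is bypassed: each beat's ratio is the channel's mean over the
    beat and the beat is flagged ``ok``.
    """
    config = config or LandmarkConfig()
    fs = recording.sampling_rate
    if feet is None:
        feet = detect_beats(recording)
    beats: list[BeatLandmarks] = []
    beat_map: list[float] = []
    if feet.size < 2:
        return BeatSeries(beats=[], beat_map=np.array([]))
    idx = np.round(np.asarray(feet) * fs).astype(int)
    smoothed = _lowpass(recording.icp, fs, config.smooth_cutoff_hz)
    mask = recording.artifact_mask
    device = recording.p2p1
    for k in range(idx.size - 1):
        i, j = idx[k], idx[k + 1]
        ibi = (j - i) / fs
        seg = recording.icp[i:j]
        masked_frac = float(np.mean(mask[i:j])) if mask is not None else 0.0
        foot_time = feet[k]
        if device is not None:
            b = BeatLandmarks(foot_time=foot_time, foot_value=recording.icp[i])
            if masked_frac <= config.max_masked_frac:
                b.p2p1_ratio = float(np.mean(device[i:j]))
                b.quality_flag = BeatQuality.OK
            beats.append(b)
        else:
            b = locate_landmarks(
                seg,
                foot_time,
                recording.icp[i],
                fs,
                config=config,
                smoothed=smoothed[i:j],
                masked_frac=masked_frac,
            )
            beats.append(b)
        if b.quality_flag is BeatQuality.OK and not (IBI_BOUNDS[0] <= ibi <= IBI_BOUNDS[1]):
            b.quality_flag = BeatQuality.REJECTED
        abp_seg = recording.abp[i:j]
        if mask is not None and masked_frac < 1.0:
            abp_seg = abp_seg[~mask[i:j]]
        beat_map.append(float(np.mean(abp_seg)) if abp_seg.size else np.nan)
    return BeatSeries(beats=beats, beat_map=np.asarray(beat_map))


def p2p1_block_means(
    beats: BeatSeries,
    block_length: float = 10.0,
    duration: float | None = None,
    min_beats: int = 3,
    include_merged: bool = False,
) -> pd.DataFrame:
    """Mean P2/P1 per contiguous block on the global [k*L, (k+1)*L) grid.

    Returns columns ``block_time`` (block start, s), ``mean_ratio`` (NaN when
    fewer than ``min_beats`` usable beats) and ``n_beats``.
    """
    admit = {BeatQuality.OK}
    if include_merged:
        admit.add(BeatQuality.MERGED_PEAKS)
    times, ratios = [], []
    for b in beats.beats:
        if b.quality_flag in admit and b.p2p1_ratio is not None:
            times.append(b.foot_time)
            ratios.append(b.p2p1_ratio)
    times = np.asarray(times)
    ratios = np.asarray(ratios)
    if duration is None:
        duration = (
            max((b.foot_time for b in beats.beats), default=0.0) + block_length
        )
    n_blocks = int(np.ceil(duration / block_length))
    out_t = np.arange(n_blocks) * block_length
    means = np.full(n_blocks, np.nan)
    counts = np.zeros(n_blocks, dtype=int)
    if times.size:
        which = np.floor(times / block_length).astype(int)
        ok = (which >= 0) & (which < n_blocks)
        for blk in np.unique(which[ok]):
            sel = ratios[which == blk]
            counts[blk] = sel.size
            if sel.size >= min_beats:
                means[blk] = float(np.mean(sel))
    return pd.DataFrame({"block_time": out_t, "mean_ratio": means, "n_beats": counts})
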