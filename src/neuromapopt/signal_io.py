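"""Waveform containers, the delimited-text dialect, artifact masking and session filters.

Recordings hold two uniformly sampled channels — arterial blood pressure (ABP)
and intracranial pressure (ICP), both in mmHg — plus a per-sample boolean
artifact mask (``True`` = excluded from analysis).  Bedside studies remove
artifacts by visual inspection; here an automated, fully configurable rule set
(physiological range, flatline, spike-on-first-difference) stands in, so that
the same mask is reproducible from the raw file alone.

File dialect: CSV with header ``time_s,abp_mmhg,icp_mmhg`` (optional fourth
column ``p2p1`` carrying a device-provided morphology ratio), preceded by
``# key=value`` comment lines, of which ``# fs_hz=<rate>`` declares the
sampling rate.  Timestamps are seconds from 0 with half-open sample
intervals; spacing must be uniform to 1e-6 s.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "WaveformRecording",
    "ArtifactRuleSet",
    "WaveformFormatError",
    "read_waveform",
    "write_waveform",
    "detect_artifacts",
    "include_session",
    "compute_cpp",
    "write_mask_intervals",
    "read_mask_intervals",
]

_TIME_TOL_S = 1e-6


class WaveformFormatError(ValueError):
    """Raised when a waveform file violates the dialect."""


@dataclass
class WaveformRecording:
    """Uniformly sampled two-channel (ABP, ICP) pressure recording.

    Parameters
    ----------
    sampling_rate : float
        Samples per second (Hz), > 0.
    abp, icp : ndarray
        Pressures in mmHg, equal length.
    artifact_mask : ndarray of bool, optional
        ``True`` marks samples excluded from analysis.  Defaults to all clear.
    p2p1 : ndarray, optional
        Device-provided per-sample P2/P1 channel (bypasses landmark detection).
    """

    sampling_rate: float
    abp: np.ndarray
    icp: np.ndarray
    artifact_mask: np.ndarray | None = None
    p2p1: np.ndarray | None = None
    start_time: float = 0.0
    patient_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        self.abp = np.asarray(self.abp, dtype=float)
        self.icp = np.asarray(self.icp, dtype=float)
        if self.abp.shape != self.icp.shape or self.abp.ndim != 1:
            raise ValueError("abp and icp must be equal-length 1-D arrays")
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(self.abp.size, dtype=bool)
        else:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
            if self.artifact_mask.shape != self.abp.shape:
                raise ValueError("artifact_mask length mismatch")
        if self.p2p1 is not None:
            self.p2p1 = np.asarray(self.p2p1, dtype=float)
            if self.p2p1.shape != self.abp.shape:
                raise ValueError("p2p1 length mismatch")

    @property
    def n_samples(self) -> int:
        return self.abp.size

    @property
    def duration(self) -> float:
        """Total recorded duration in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def unmasked_duration(self) -> float:
        """Seconds of data not flagged as artifact."""
        return float(np.count_nonzero(~self.artifact_mask)) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    def with_mask(self, mask: np.ndarray) -> "WaveformRecording":
        return replace(self, artifact_mask=np.asarray(mask, dtype=bool))


@dataclass
class ArtifactRuleSet:
    """Automated artifact rules replacing manual visual inspection.

    A sample is flagged iff it (a) falls outside the physiological range for
    its channel, (b) lies inside a zero-variance (flatline) window, or (c) has
    a first-difference exceeding ``spike_z`` robust standard deviations.  The
    resulting mask is then dilated by ``mask_dilation`` seconds on both sides.
    All defaults are invented, configurable surrogates.
    """

    abp_range: tuple[float, float] = (20.0, 250.0)
    icp_range: tuple[float, float] = (-10.0, 100.0)
    flatline_window: float = 2.0      # s
    flatline_tol: float = 1e-9        # mmHg; |diff| below this counts as flat
    spike_z: float = 6.0
    mask_dilation: float = 1.0        # s

    def __post_init__(self) -> None:
        for lo, hi in (self.abp_range, self.icp_range):
            if lo >= hi:
                raise ValueError("range lower bound must be < upper bound")
        if self.flatline_window <= 0 or self.spike_z <= 0:
            raise ValueError("thresholds must be > 0")


def _flatline_mask(x: np.ndarray, fs: float, window_s: float, tol: float) -> np.ndarray:
    """Flag samples belonging to constant runs of at least ``window_s`` seconds."""
    n = x.size
    out = np.zeros(n, dtype=bool)
    if n < 2:
        return out
    flat = np.abs(np.diff(x)) <= tol
    min_run = max(int(round(window_s * fs)) - 1, 1)  # diffs in a run of k samples: k-1
    # run-length encode the boolean diff sequence
    edges = np.flatnonzero(np.diff(flat.astype(np.int8)))
    starts = np.r_[0, edges + 1]
    ends = np.r_[edges, flat.size - 1]
    for s, e in zip(starts, ends):
        if flat[s] and (e - s + 1) >= min_run:
            out[s : e + 2] = True  # diffs [s..e] span samples [s..e+1]
    return out


def _spike_mask(x: np.ndarray, z: float) -> np.ndarray:
    n = x.size
    out = np.zeros(n, dtype=bool)
    if n < 3:
        return out
    d = np.diff(x)
    med = np.median(d)
    # plain SD: cardiac upstrokes are part of the legitimate diff distribution,
    # so only gross excursions far beyond pulse slopes are flagged
    scale = np.std(d)
    if scale <= 0:
        return out
    bad = np.abs(d - med) > z * scale
    out[:-1] |= bad
    out[1:] |= bad
    return out


def detect_artifacts(
    recording: WaveformRecording, rules: ArtifactRuleSet | None = None
) -> np.ndarray:
    """Return a per-sample boolean artifact mask (True = excluded)."""
    rules = rules or ArtifactRuleSet()
    fs = recording.sampling_rate
    abp, icp = recording.abp, recording.icp
    mask = (
        (abp < rules.abp_range[0])
        | (abp > rules.abp_range[1])
        | (icp < rules.icp_range[0])
        | (icp > rules.icp_range[1])
    )
    mask |= _flatline_mask(abp, fs, rules.flatline_window, rules.flatline_tol)
    mask |= _flatline_mask(icp, fs, rules.flatline_window, rules.flatline_tol)
    mask |= _spike_mask(abp, rules.spike_z)
    mask |= _spike_mask(icp, rules.spike_z)
    dil = int(round(rules.mask_dilation * fs))
    if dil > 0 and mask.any():
        mask = ndimage.binary_dilation(mask, structure=np.ones(2 * dil + 1, dtype=bool))
    return mask


def include_session(recording: WaveformRecording, min_duration: float = 900.0) -> bool:
    """Session-inclusion filter: keep only sessions with >= ``min_duration``
    seconds of *unmasked* data (default 15 minutes)."""
    return recording.unmasked_duration >= min_duration


def compute_cpp(map_value, icp_value):
    """Cerebral perfusion pressure: CPP = MAP - ICP (mmHg); elementwise on arrays."""
    return np.asarray(map_value, dtype=float) - np.asarray(icp_value, dtype=float)


# ---------------------------------------------------------------------------
# File I/O


def write_waveform(recording: WaveformRecording, path, precision: int = 6) -> None:
    """Write a recording in the waveform CSV dialect."""
    cols = {
        "time_s": recording.times,
        "abp_mmhg": recording.abp,
        "icp_mmhg": recording.icp,
    }
    if recording.p2p1 is not None:
        cols["p2p1"] = recording.p2p1
    df = pd.DataFrame(cols)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# fs_hz={recording.sampling_rate:g}\n")
        if recording.patient_id:
            fh.write(f"# patient_id={recording.patient_id}\n")
        if recording.session_id:
            fh.write(f"# session_id={recording.session_id}\n")
        df.to_csv(fh, index=False, float_format=f"%.{precision}f")


def read_waveform(path) -> WaveformRecording:
    """Read a waveform CSV, reconstructing the uniform time base.

    Raises :class:`WaveformFormatError` on missing columns, non-numeric cells
    (naming the first offending line) or non-uniform/non-monotonic timestamps
    beyond 1e-6 s.
    """
    meta: dict[str, str] = {}
    body = io.StringIO()
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                item = line[1:].strip()
                if "=" in item:
                    k, v = item.split("=", 1)
                    meta[k.strip()] = v.strip()
            else:
                body.write(line)
    body.seek(0)
    try:
        df = pd.read_csv(body)
    except pd.errors.ParserError as exc:
        raise WaveformFormatError(f"{path}: malformed CSV ({exc})") from exc
    required = ["time_s", "abp_mmhg", "icp_mmhg"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise WaveformFormatError(f"{path}: missing columns {missing}")
    for col in required + (["p2p1"] if "p2p1" in df.columns else []):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if df[col].isna().any() or bad.any():
            row = int((df[col].isna() | bad).idxmax())
            # +2: one header line, 1-based counting (comment lines not counted)
            raise WaveformFormatError(
                f"{path}: non-numeric or empty value in column {col!r}, data line {row + 2}"
            )
        df[col] = numeric
    t = df["time_s"].to_numpy()
    if t.size == 0:
        raise WaveformFormatError(f"{path}: empty recording")
    if "fs_hz" in meta:
        fs = float(meta["fs_hz"])
    elif t.size >= 2:
        fs = 1.0 / np.median(np.diff(t))
    else:
        raise WaveformFormatError(f"{path}: cannot infer sampling rate from one sample")
    if t.size >= 2:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise WaveformFormatError(f"{path}: timestamps not strictly increasing")
        if np.max(np.abs(dt - 1.0 / fs)) > _TIME_TOL_S:
            raise WaveformFormatError(
                f"{path}: non-uniform sampling (expected dt={1.0 / fs:g} s)"
            )
    return WaveformRecording(
        sampling_rate=fs,
        abp=df["abp_mmhg"].to_numpy(),
        icp=df["icp_mmhg"].to_numpy(),
        p2p1=df["p2p1"].to_numpy() if "p2p1" in df.columns else None,
        start_time=float(t[0]),
        patient_id=meta.get("patient_id", ""),
        session_id=meta.get("session_id", ""),
    )


def write_mask_intervals(mask: np.ndarray, sampling_rate: float, path) -> None:
    """Persist an artifact mask as run-length [start_s, end_s) intervals."""
    mask = np.asarray(mask, dtype=bool)
    edges = np.flatnonzero(np.diff(np.r_[False, mask, False].astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    df = pd.DataFrame(
        {"start_s": starts / sampling_rate, "end_s": ends / sampling_rate}
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_mask_intervals(path, n_samples: int, sampling_rate: float) -> np.ndarray:
    df = pd.read_csv(path)
    mask = np.zeros(n_samples, dtype=bool)
    for _, row in df.iterrows():
        i = int(round(row["start_s"] * sampling_rate))
        j = int(round(row["end_s"] * sampling_rate))
        mask[max(i, 0) : min(j, n_samples)] = True
    return mask
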