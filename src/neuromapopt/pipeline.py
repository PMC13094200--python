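"""End-to-end session and cohort orchestration.

``analyze_session`` runs the full chain on one recording — artifact masking,
session-inclusion filter (>= 15 min of usable data), beat segmentation and
landmark detection, block averaging, PRx and P2/P1 index series, MAP binning,
U-curve fit and nadir extraction for both indices — and returns every
intermediate product.  ``run_cohort`` maps it over a cohort, assembles
session pairs from the doubly valid sessions and runs the agreement layer.
Everything is deterministic for a fixed input and configuration; outputs
carry a configuration hash so identical runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from . import agreement as agr
from .indices import IndexSeries, WindowSpec, block_average, moving_correlation, p2p1_window_series
from .mapopt import MapoptResult, estimate_mapopt, optimal_band_stats, OptimalBandStats
from .pulse import BeatQuality, BeatSeries, LandmarkConfig, extract_beats, p2p1_block_means
from .signal_io import ArtifactRuleSet, WaveformRecording, detect_artifacts, include_session
from .simulate import SimulatedSession

__all__ = [
    "AnalysisConfig",
    "SessionAnalysis",
    "SessionSkip",
    "CohortResult",
    "analyze_session",
    "run_cohort",
    "config_hash",
]


@dataclass
class AnalysisConfig:
    """Every knob of the per-session analysis, with study defaults."""

    window: WindowSpec = field(default_factory=WindowSpec)
    landmarks: LandmarkConfig = field(default_factory=LandmarkConfig)
    artifact_rules: ArtifactRuleSet = field(default_factory=ArtifactRuleSet)
    auto_mask: bool = True
    min_duration: float = 900.0         # s of unmasked data (15-min rule)
    p2p1_mode: str = "direct"           # "direct" | "correlation"
    bin_width: float = 1.0              # mmHg
    degree: int = 2
    min_bins: int = 5
    min_span_mmhg: float = 8.0
    min_per_bin: int = 3
    fit_target: str = "mean"
    band_half_width: float = 5.0        # mmHg, optimal-band statistics
    min_block_beats: int = 3
    prx_threshold: float = 0.25

    def __post_init__(self) -> None:
        if self.p2p1_mode not in ("direct", "correlation"):
            raise ValueError("p2p1_mode must be 'direct' or 'correlation'")


def config_hash(config: AnalysisConfig) -> str:
    """Stable short hash of the full configuration (for output provenance)."""
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class SessionSkip:
    """Structured record of an excluded session (never an exception)."""

    patient_id: str
    session_id: str
    reason: str


@dataclass
class SessionAnalysis:
    patient_id: str
    session_id: str
    prx_result: MapoptResult
    p2p1_result: MapoptResult
    prx_series: IndexSeries
    p2p1_series: IndexSeries
    beats: BeatSeries
    band_stats: OptimalBandStats | None
    diagnostics: dict
    config_hash: str


def analyze_session(
    recording: WaveformRecording, config: AnalysisConfig | None = None
) -> SessionAnalysis | SessionSkip:
    """Run the full per-session chain; returns a skip record when the
    recording fails the usable-duration filter."""
    config = config or AnalysisConfig()
    if config.auto_mask and not recording.artifact_mask.any():
        recording = recording.with_mask(detect_artifacts(recording, config.artifact_rules))
    if not include_session(recording, config.min_duration):
        return SessionSkip(
            patient_id=recording.patient_id,
            session_id=recording.session_id,
            reason=(
                f"unmasked duration {recording.unmasked_duration:.0f} s "
                f"< {config.min_duration:.0f} s minimum"
            ),
        )
    spec = config.window
    beats = extract_beats(recording, config.landmarks)
    _, map_blocks = block_average(
        recording.abp, recording.sampling_rate, spec.block_length, recording.artifact_mask
    )
    _, icp_blocks = block_average(
        recording.icp, recording.sampling_rate, spec.block_length, recording.artifact_mask
    )
    prx_series = moving_correlation(map_blocks, icp_blocks, spec=spec, name="PRx")
    blocks = p2p1_block_means(
        beats,
        block_length=spec.block_length,
        duration=map_blocks.size * spec.block_length,
        min_beats=config.min_block_beats,
        include_merged=config.landmarks.include_merged,
    )
    p2p1_blocks = blocks["mean_ratio"].to_numpy()
    if config.p2p1_mode == "direct":
        p2p1_series = p2p1_window_series(p2p1_blocks, map_blocks, spec=spec)
    else:
        p2p1_series = moving_correlation(
            map_blocks, p2p1_blocks, spec=spec, name="P2P1corr"
        )
    kwargs = dict(
        bin_width=config.bin_width,
        degree=config.degree,
        min_bins=config.min_bins,
        min_span_mmhg=config.min_span_mmhg,
        min_per_bin=config.min_per_bin,
        fit_target=config.fit_target,
    )
    prx_result = estimate_mapopt(prx_series, **kwargs)
    p2p1_result = estimate_mapopt(p2p1_series, **kwargs)
    band = None
    if p2p1_result.is_valid and config.p2p1_mode == "direct":
        band = optimal_band_stats(
            p2p1_series, p2p1_result.mapopt, config.band_half_width
        )
    quality_counts = {q.value: 0 for q in BeatQuality}
    for b in beats.beats:
        quality_counts[b.quality_flag.value] += 1
    diagnostics = {
        "n_beats": len(beats),
        "beat_quality": quality_counts,
        "n_windows": int(len(prx_series)),
        "n_valid_prx_windows": int(prx_series.valid.sum()),
        "n_valid_p2p1_windows": int(p2p1_series.valid.sum()),
        "masked_fraction": float(np.mean(recording.artifact_mask)),
        "prx_validity": prx_result.validity.value,
        "p2p1_validity": p2p1_result.validity.value,
    }
    return SessionAnalysis(
        patient_id=recording.patient_id,
        session_id=recording.session_id,
        prx_result=prx_result,
        p2p1_result=p2p1_result,
        prx_series=prx_series,
        p2p1_series=p2p1_series,
        beats=beats,
        band_stats=band,
        diagnostics=diagnostics,
        config_hash=config_hash(config),
    )


@dataclass
class CohortResult:
    analyses: list[SessionAnalysis]
    skips: list[SessionSkip]
    pairs: list[agr.SessionPair]
    report: agr.AgreementReport | None
    config_hash: str


def run_cohort(
    sessions: list[WaveformRecording | SimulatedSession],
    config: AnalysisConfig | None = None,
    threshold: float = 6.0,
) -> CohortResult:
    """Analyze every session, pair the doubly valid estimates, run agreement.

    Accepts raw recordings or simulated sessions (their recordings are used;
    ground truth is ignored here — recovery checks live in the test-suite).
    The agreement report is withheld (None) when no valid pair exists.
    """
    config = config or AnalysisConfig()
    analyses: list[SessionAnalysis] = []
    skips: list[SessionSkip] = []
    for s in sessions:
        rec = s.recording if isinstance(s, SimulatedSession) else s
        out = analyze_session(rec, config)
        if isinstance(out, SessionSkip):
            skips.append(out)
        else:
            analyses.append(out)
    pairs = [
        agr.SessionPair(
            patient_id=a.patient_id,
            session_id=a.session_id,
            mapopt_prx=a.prx_result.mapopt,
            mapopt_p2p1=a.p2p1_result.mapopt,
        )
        for a in analyses
        if a.prx_result.is_valid and a.p2p1_result.is_valid
    ]
    report = agr.build_report(pairs, threshold=threshold) if pairs else None
    return CohortResult(
        analyses=analyses,
        skips=skips,
        pairs=pairs,
        report=report,
        config_hash=config_hash(config),
    )
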