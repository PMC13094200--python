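"""Ground-truthed ABP/ICP session simulator.

The generator plants the two statistical structures the optimal-MAP method
exploits, without attempting biophysical (Windkessel / Monro-Kellie)
mechanism:

* a *reactivity* curve: the local transmission coefficient from mean arterial
  pressure (MAP) to the slow component of intracranial pressure (ICP) is
  U-shaped in MAP, ``tau(m) = reactivity_floor + reactivity_curvature *
  (m - mapopt_prx)**2`` — negative (counter-regulation) at the nadir,
  positive (passive transmission) away from it, so the windowed ICP-MAP
  correlation (PRx) traces a U against MAP;
* a *compliance* curve: the per-beat P2/P1 pulse-morphology ratio is a
  parabola in the beat's MAP, ``p2p1_floor + p2p1_curvature *
  (m - mapopt_p2p1)**2``, clipped positive.

MAP itself is a slow-wave sinusoid (default period 60 s, within the band
correlation indices exploit) riding on a session-scale trend — a linear ramp
from -trend_amplitude to +trend_amplitude (random direction), emulating the
slow hemodynamic drift that carries MAP across the 1-mmHg bins; a ramp is
used because the 5-minute window mean of a linear trend equals the trend at
the window centre, so binning by window-mean MAP stays undistorted — plus an
AR(1) drift, all bounded to [40, 160] mmHg.
Both channels carry a cardiac pulse train built from three Gaussian bumps
(P1/P2/P3 sub-peaks) whose ICP amplitudes encode the planted ratio.  The two
nadirs are offset by ``nadir_offset = mapopt_prx - mapopt_p2p1`` (mmHg),
oriented so a positive offset yields a positive PRx-minus-P2/P1 bias
downstream.

Everything is reproducible: one root seed; per-session seeds derived by the
counter scheme ``SeedSequence([root_seed, patient_index, session_index])``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .signal_io import WaveformRecording, write_waveform

__all__ = [
    "SimulationConfig",
    "CohortDistributions",
    "GroundTruth",
    "SimulatedSession",
    "pulse_template",
    "simulate_session",
    "simulate_cohort",
    "write_session",
]

MAP_BOUNDS = (40.0, 160.0)
P2P1_CLIP_MIN = 0.05


@dataclass
class SimulationConfig:
    """Parameters of one simulated monitoring session.

    Pressures in mmHg, times in seconds, rates in Hz unless noted.
    ``mapopt_p2p1`` defaults to ``mapopt_prx - nadir_offset``.
    """

    sampling_rate: float = 250.0
    duration: float = 1200.0              # 20-min session
    heart_rate: float = 75.0              # beats/min
    map_baseline: float = 90.0
    slow_wave_amplitude: float = 12.0
    slow_wave_period: float = 60.0
    trend_amplitude: float = 10.0         # half-span of the session-long MAP ramp
    map_drift_sd: float = 2.0             # stationary SD of AR(1) MAP drift
    map_drift_tau: float = 120.0          # AR(1) time constant, s
    icp_baseline: float = 12.0
    icp_drift_sd: float = 1.0
    icp_drift_tau: float = 60.0
    mapopt_prx: float = 90.0              # planted nadir of the reactivity curve
    nadir_offset: float = 2.0             # mapopt_prx - mapopt_p2p1
    mapopt_p2p1: float | None = None
    reactivity_floor: float = -0.2        # transmission coefficient at the nadir
    reactivity_curvature: float = 0.001   # per mmHg^2; trough half-width
                                          # sqrt(-floor/curvature) ~ 14 mmHg
    reactivity_ceiling: float = 0.8       # cap on passive transmission
    p2p1_floor: float = 0.9               # minimum P2/P1 at its nadir
    p2p1_curvature: float = 0.002         # per mmHg^2
    pulse_landmark_latencies: tuple[float, float, float] = (0.09, 0.21, 0.33)
    pulse_landmark_widths: tuple[float, float, float] = (0.030, 0.035, 0.035)
    icp_pulse_p1_amp: float = 4.0         # mmHg above pulse foot
    icp_pulse_p3_frac: float = 0.5        # P3 amplitude as a fraction of P1
    abp_pulse_amps: tuple[float, float, float] = (35.0, 15.0, 5.0)
    beat_jitter_frac: float = 0.0         # +-fractional jitter on beat length
    noise_sd_abp: float = 1.0
    noise_sd_icp: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise ValueError("sampling_rate and duration must be > 0")
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be > 0")
        if self.slow_wave_period <= 0:
            raise ValueError("slow_wave_period must be > 0")
        if self.p2p1_floor <= 0:
            raise ValueError("p2p1_floor must be > 0")
        if self.reactivity_curvature < 0 or self.p2p1_curvature < 0:
            raise ValueError("curvatures must be >= 0")
        if any(w <= 0 for w in self.pulse_landmark_widths):
            raise ValueError("pulse landmark widths must be > 0")
        lats = self.pulse_landmark_latencies
        if not (0 < lats[0] < lats[1] < lats[2]):
            raise ValueError("landmark latencies must be increasing and > 0")
        if self.mapopt_p2p1 is None:
            self.mapopt_p2p1 = self.mapopt_prx - self.nadir_offset

    @property
    def beat_length(self) -> float:
        return 60.0 / self.heart_rate


@dataclass
class GroundTruth:
    """Planted quantities of one session, for recovery testing."""

    mapopt_prx: float
    mapopt_p2p1: float
    beat_foot_times: np.ndarray           # s
    beat_p2p1: np.ndarray                 # true per-beat ratio
    beat_map: np.ndarray                  # MAP at each beat foot, mmHg
    map_trajectory: np.ndarray            # per-sample true MAP, mmHg
    degenerate_distribution: bool = False

    @property
    def nadir_offset(self) -> float:
        return self.mapopt_prx - self.mapopt_p2p1


@dataclass
class SimulatedSession:
    recording: WaveformRecording
    ground_truth: GroundTruth
    config: SimulationConfig


def pulse_template(phase_in_beat, landmark_amplitudes, config: SimulationConfig):
    """Pulse excursion above the foot at ``phase_in_beat`` seconds into a beat.

    Sum of three Gaussian bumps centred at the configured P1/P2/P3 latencies.
    With widths much narrower than the inter-landmark spacing the local maxima
    equal the landmark amplitudes.
    """
    phase = np.asarray(phase_in_beat, dtype=float)
    amps = np.asarray(landmark_amplitudes, dtype=float)
    out = np.zeros_like(phase)
    for amp, lat, width in zip(
        amps, config.pulse_landmark_latencies, config.pulse_landmark_widths
    ):
        out = out + amp * np.exp(-0.5 * ((phase - lat) / width) ** 2)
    return out if out.ndim else float(out)


def _ar1(n: int, sd: float, tau_s: float, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) drift with standard deviation ``sd`` and time constant ``tau_s``."""
    if sd <= 0 or n == 0:
        return np.zeros(n)
    phi = np.exp(-1.0 / (fs * tau_s))
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    eps = rng.standard_normal(n) * innov_sd
    eps[0] = rng.standard_normal() * sd  # stationary start
    return lfilter([1.0], [1.0, -phi], eps)


def _ramp_trend(
    t: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Linear MAP ramp from -A to +A across the session (random direction).

    A linear trend's 5-minute window mean equals its value at the window
    centre, so MAP binning by window mean stays undistorted while the
    session still covers the whole +-A range.
    """
    if config.trend_amplitude <= 0 or t.size == 0:
        return np.zeros_like(t)
    direction = 1.0 if rng.random() < 0.5 else -1.0
    return direction * config.trend_amplitude * (2.0 * t / config.duration - 1.0)


def _beat_grid(config: SimulationConfig, rng: np.random.Generator):
    """Foot times covering the session; optional +-jitter on beat length."""
    nominal = config.beat_length
    n_beats = int(np.ceil(config.duration / (nominal * (1 - config.beat_jitter_frac)))) + 2
    if config.beat_jitter_frac > 0:
        lengths = nominal * (1 + config.beat_jitter_frac * rng.uniform(-1, 1, n_beats))
    else:
        lengths = np.full(n_beats, nominal)
    feet = np.concatenate([[0.0], np.cumsum(lengths)])
    return feet[feet <= config.duration + nominal], lengths


def simulate_session(config: SimulationConfig) -> SimulatedSession:
    """Generate one session; identical (config, seed) gives bit-identical output."""
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    rng = np.random.default_rng(config.seed)
    t = np.arange(n) / fs

    # --- slow MAP trajectory -------------------------------------------------
    slow = config.slow_wave_amplitude * np.sin(2 * np.pi * t / config.slow_wave_period)
    trend = _ramp_trend(t, config, rng)
    drift = _ar1(n, config.map_drift_sd, config.map_drift_tau, fs, rng)
    map_t = np.clip(config.map_baseline + slow + trend + drift, *MAP_BOUNDS)

    # --- ICP slow component: U-shaped transmission of MAP deviations ---------
    tau = np.minimum(
        config.reactivity_floor
        + config.reactivity_curvature * (map_t - config.mapopt_prx) ** 2,
        config.reactivity_ceiling,
    )
    icp_slow = (
        config.icp_baseline
        + tau * (map_t - config.map_baseline)
        + _ar1(n, config.icp_drift_sd, config.icp_drift_tau, fs, rng)
    )

    # --- cardiac pulse train --------------------------------------------------
    feet, lengths = _beat_grid(config, rng)
    beat_idx = np.searchsorted(feet, t, side="right") - 1
    phase = t - feet[beat_idx]
    foot_samples = np.minimum(np.round(feet * fs).astype(int), n - 1)
    beat_map = map_t[foot_samples]
    true_ratio = np.clip(
        config.p2p1_floor
        + config.p2p1_curvature * (beat_map - config.mapopt_p2p1) ** 2,
        P2P1_CLIP_MIN,
        None,
    )

    lats = np.asarray(config.pulse_landmark_latencies)
    widths = np.asarray(config.pulse_landmark_widths)

    def pulse_train(amp_per_beat: np.ndarray) -> np.ndarray:
        """amp_per_beat: (n_beats, 3) landmark amplitudes; returns zero-mean-per-beat train."""
        out = np.zeros(n)
        beat_len = lengths[np.minimum(beat_idx, lengths.size - 1)]
        for k in range(3):
            amp_k = amp_per_beat[beat_idx, k]
            out += amp_k * np.exp(-0.5 * ((phase - lats[k]) / widths[k]) ** 2)
            # subtract each bump's beat-mean so block averages track the slow component
            out -= amp_k * widths[k] * np.sqrt(2 * np.pi) / beat_len
        return out

    nb = feet.size
    p1 = np.full(nb, config.icp_pulse_p1_amp)
    icp_amps = np.column_stack([p1, true_ratio * p1, config.icp_pulse_p3_frac * p1])
    abp_amps = np.tile(np.asarray(config.abp_pulse_amps), (nb, 1))

    abp = map_t + pulse_train(abp_amps)
    icp = icp_slow + pulse_train(icp_amps)
    if config.noise_sd_abp > 0:
        abp = abp + config.noise_sd_abp * rng.standard_normal(n)
    if config.noise_sd_icp > 0:
        icp = icp + config.noise_sd_icp * rng.standard_normal(n)

    recording = WaveformRecording(sampling_rate=fs, abp=abp, icp=icp)
    # beats entirely after the last sample carry no evaluable pulse
    in_range = feet < config.duration
    truth = GroundTruth(
        mapopt_prx=config.mapopt_prx,
        mapopt_p2p1=float(config.mapopt_p2p1),
        beat_foot_times=feet[in_range],
        beat_p2p1=true_ratio[in_range],
        beat_map=beat_map[in_range],
        map_trajectory=map_t,
    )
    return SimulatedSession(recording=recording, ground_truth=truth, config=config)


@dataclass
class CohortDistributions:
    """Across-patient and across-session distributions of planted parameters.

    Per patient the PRx nadir is drawn uniformly from ``mapopt_prx_range``;
    each session then jitters it by a normal with SD ``session_sd`` (the
    autoregulatory set point drifts between monitoring days).  The session's
    MAP baseline is pinned to its planted PRx nadir so the MAP excursion
    always covers it.  ``nadir_offset`` (PRx-nadir minus P2/P1-nadir) is fixed
    across the cohort.
    """

    mapopt_prx_range: tuple[float, float] = (75.0, 105.0)
    session_sd: float = 5.0
    nadir_offset: float = 2.0

    @property
    def degenerate(self) -> bool:
        lo, hi = self.mapopt_prx_range
        return (hi <= lo) and self.session_sd == 0


def _session_seed(root_seed: int, patient_index: int, session_index: int) -> int:
    """Documented counter scheme: SeedSequence([root, patient, session])."""
    ss = np.random.SeedSequence([int(root_seed), patient_index, session_index])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_cohort(
    n_patients: int,
    sessions_per_patient: int = 2,
    distributions: CohortDistributions | None = None,
    seed: int = 0,
    base_config: SimulationConfig | None = None,
) -> list[SimulatedSession]:
    """Simulate a cohort with per-patient planted nadirs; reproducible under seed."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    dist = distributions or CohortDistributions()
    base = base_config or SimulationConfig()
    rng = np.random.default_rng(seed)
    sessions: list[SimulatedSession] = []
    lo, hi = dist.mapopt_prx_range
    for p in range(n_patients):
        patient_nadir = rng.uniform(lo, hi) if hi > lo else float(lo)
        pid = f"P{p + 1:03d}"
        for s in range(sessions_per_patient):
            session_nadir = patient_nadir
            if dist.session_sd > 0:
                session_nadir = session_nadir + rng.normal(0.0, dist.session_sd)
            cfg = replace(
                base,
                mapopt_prx=float(session_nadir),
                map_baseline=float(session_nadir),
                nadir_offset=dist.nadir_offset,
                mapopt_p2p1=None,
                seed=_session_seed(seed, p, s),
            )
            sess = simulate_session(cfg)
            sess.recording.patient_id = pid
            sess.recording.session_id = f"{pid}S{s + 1}"
            sess.ground_truth.degenerate_distribution = dist.degenerate
            sessions.append(sess)
    return sessions


def write_session(session: SimulatedSession, directory, precision: int = 4) -> Path:
    """Write the waveform CSV plus a ground-truth JSON sidecar; returns the CSV path.

    Sidecar keys: planted nadirs (mmHg), offset, beat foot times (s), per-beat
    true P2/P1 and MAP, the seed and the session/patient ids.  The per-sample
    MAP trajectory is not persisted (regenerate via the seed if needed).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = session.recording.session_id or "session"
    csv_path = directory / f"{name}.csv"
    write_waveform(session.recording, csv_path, precision=precision)
    truth = session.ground_truth
    sidecar = {
        "patient_id": session.recording.patient_id,
        "session_id": session.recording.session_id,
        "seed": session.config.seed,
        "mapopt_prx_mmhg": truth.mapopt_prx,
        "mapopt_p2p1_mmhg": truth.mapopt_p2p1,
        "nadir_offset_mmhg": truth.nadir_offset,
        "degenerate_distribution": truth.degenerate_distribution,
        "beat_foot_times_s": np.round(truth.beat_foot_times, 6).tolist(),
        "beat_p2p1": np.round(truth.beat_p2p1, 6).tolist(),
        "beat_map_mmhg": np.round(truth.beat_map, 4).tolist(),
    }
    with open(directory / f"{name}.truth.json", "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=1)
    return csv_path
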