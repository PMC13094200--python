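"""Beat detection and P1/P2 landmark recovery on known morphology."""

import numpy as np
import pandas as pd
import pytest

import neuromapopt as nm
from neuromapopt.pulse import (
    BeatLandmarks,
    BeatQuality,
    BeatSeries,
    detect_beats,
    extract_beats,
    locate_landmarks,
    p2p1_block_means,
)
from neuromapopt.signal_io import WaveformRecording

from conftest import synthetic_beat


class TestDetectBeats:
    def test_beat_count_at_60_bpm(self):
        cfg = nm.SimulationConfig(duration=60.0, heart_rate=60.0, seed=2)
        s = nm.simulate_session(cfg)
        feet = detect_beats(s.recording)
        assert 59 <= feet.size <= 61

    def test_flatline_yields_empty_with_warning(self):
        rec = WaveformRecording(250.0, np.full(5000, 80.0), np.full(5000, 10.0))
        with pytest.warns(UserWarning, match="pulsatility"):
            feet = detect_beats(rec)
        assert feet.size == 0

    def test_jittered_intervals_match_planted_within_two_samples(self):
        cfg = nm.SimulationConfig(
            duration=120.0, seed=7, beat_jitter_frac=0.03,
            noise_sd_abp=0.0, noise_sd_icp=0.0, map_drift_sd=0.0, icp_drift_sd=0.0,
        )
        s = nm.simulate_session(cfg)
        det = detect_beats(s.recording)
        truth = s.ground_truth.beat_foot_times
        # match each detected foot to its nearest planted foot, compare IBIs
        j = np.argmin(np.abs(truth[None, :] - det[:, None]), axis=1)
        assert np.all(np.diff(j) == 1)  # one detection per beat, in order
        ibi_err = np.diff(det) - np.diff(truth[j])
        assert np.max(np.abs(ibi_err)) <= 2.0 / cfg.sampling_rate + 1e-9


class TestLocateLandmarks:
    def test_two_bump_beat_matches_dense_template_oracle(self):
        beat, fs = synthetic_beat(amps=(8.0, 6.0, 0.0), foot=10.0)
        # oracle: local maxima of the same template on a 1 ms grid
        cfg = nm.SimulationConfig()
        grid = np.arange(0.0, 0.8, 0.001)
        y = nm.pulse_template(grid, (8.0, 6.0, 0.0), cfg)
        pk = np.flatnonzero((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])) + 1
        expected = y[pk[1]] / y[pk[0]]
        lm = locate_landmarks(beat, 0.0, beat[0], fs)
        assert lm.quality_flag is BeatQuality.OK
        assert lm.p2p1_ratio == pytest.approx(expected, abs=0.02)
        assert lm.p2p1_ratio == pytest.approx(0.75, abs=0.02)

    def test_equal_amplitudes_give_ratio_one(self):
        # fully symmetric beat: equal bumps, mirror-symmetric about the
        # segment centre and exactly on the sample grid
        beat, fs = synthetic_beat(
            amps=(6.0, 6.0, 0.0), beat_len=0.5, foot=12.0,
            latencies=(0.148, 0.348, 0.49), widths=(0.03, 0.03, 0.01),
        )
        lm = locate_landmarks(beat, 0.0, beat[0], fs)
        # equality holds up to the zero-phase filter's edge asymmetry (~1e-4)
        assert lm.p2p1_ratio == pytest.approx(1.0, abs=1e-3)

    def test_single_peak_without_shoulder_not_ok(self):
        beat, fs = synthetic_beat(amps=(8.0, 0.0, 0.0))
        lm = locate_landmarks(beat, 0.0, beat[0], fs)
        assert lm.quality_flag is not BeatQuality.OK

    @pytest.mark.parametrize("c", [0.5, 2.0, 7.3])
    def test_scale_invariance_of_ratio(self, c):
        beat, fs = synthetic_beat(amps=(8.0, 6.0, 3.0), foot=10.0)
        ref = locate_landmarks(beat, 0.0, beat[0], fs)
        scaled = beat[0] + c * (beat - beat[0])
        lm = locate_landmarks(scaled, 0.0, scaled[0], fs)
        assert lm.p2p1_ratio == pytest.approx(ref.p2p1_ratio, abs=1e-12)

    def test_shift_invariance_of_amplitudes(self):
        beat, fs = synthetic_beat(amps=(8.0, 6.0, 3.0), foot=10.0)
        ref = locate_landmarks(beat, 0.0, beat[0], fs)
        shifted = beat + 25.0
        lm = locate_landmarks(shifted, 0.0, shifted[0], fs)
        assert lm.p1_amp == pytest.approx(ref.p1_amp, abs=1e-9)
        assert lm.p2_amp == pytest.approx(ref.p2_amp, abs=1e-9)

    def test_landmark_times_strictly_increase(self, default_session):
        beats = extract_beats(default_session.recording)
        ok = [b for b in beats.beats if b.quality_flag is BeatQuality.OK]
        assert len(ok) > 1000
        for b in ok:
            assert b.foot_time < b.p1_time < b.p2_time
            if b.p3_time is not None:
                assert b.p2_time < b.p3_time


def _beat(t, ratio, quality=BeatQuality.OK):
    return BeatLandmarks(
        foot_time=t, foot_value=10.0, p1_time=t + 0.1, p2_time=t + 0.2,
        p1_amp=4.0, p2_amp=4.0 * ratio, p2p1_ratio=ratio, quality_flag=quality,
    )


class TestBlockMeans:
    def test_arithmetic_mean_per_block(self):
        beats = BeatSeries(
            beats=[_beat(1.0, 0.8), _beat(4.0, 1.0), _beat(7.0, 1.2)],
            beat_map=np.array([90.0, 90.0, 90.0]),
        )
        df = p2p1_block_means(beats, block_length=10.0, duration=10.0)
        assert df["mean_ratio"].iloc[0] == pytest.approx(1.0)
        assert df["n_beats"].iloc[0] == 3

    def test_block_below_min_beats_is_missing(self):
        beats = BeatSeries(
            beats=[_beat(1.0, 0.8), _beat(4.0, 1.2)],
            beat_map=np.array([90.0, 90.0]),
        )
        df = p2p1_block_means(beats, block_length=10.0, duration=10.0)
        assert np.isnan(df["mean_ratio"].iloc[0])
        assert df["n_beats"].iloc[0] == 2

    def test_rejected_beats_excluded(self):
        beats = BeatSeries(
            beats=[_beat(1.0, 0.8), _beat(3.0, 1.0), _beat(5.0, 1.2),
                   _beat(7.0, 5.0, BeatQuality.REJECTED)],
            beat_map=np.full(4, 90.0),
        )
        df = p2p1_block_means(beats, block_length=10.0, duration=10.0)
        assert df["mean_ratio"].iloc[0] == pytest.approx(1.0)

    def test_block_means_track_planted_curve(self, default_session):
        beats = extract_beats(default_session.recording)
        df = p2p1_block_means(beats, block_length=10.0,
                              duration=default_session.config.duration)
        gt = default_session.ground_truth
        truth_block = pd.Series(gt.beat_p2p1).groupby(
            np.floor(gt.beat_foot_times / 10.0).astype(int)
        ).mean()
        est = df["mean_ratio"]
        err = [
            est.iloc[k] - truth_block.loc[k]
            for k in truth_block.index
            if k < len(est) and not np.isnan(est.iloc[k])
        ]
        assert len(err) > 100
        assert np.mean(np.abs(err)) <= 0.05
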