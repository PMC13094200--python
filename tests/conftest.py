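import numpy as np
import pytest

import neuromapopt as nm


@pytest.fixture(scope="session")
def default_session():
    """One 20-min session at study defaults (noise on, planted nadirs 90/88)."""
    return nm.simulate_session(nm.SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def default_analysis(default_session):
    return nm.analyze_session(default_session.recording)


@pytest.fixture(scope="session")
def quiet_session():
    """Noise-free session: slow waves and ramp on, stochastic terms off."""
    cfg = nm.SimulationConfig(
        seed=11, noise_sd_abp=0.0, noise_sd_icp=0.0,
        map_drift_sd=0.0, icp_drift_sd=0.0,
    )
    return nm.simulate_session(cfg)


@pytest.fixture()
def short_session():
    """2-min noisy session for I/O and artifact tests."""
    return nm.simulate_session(nm.SimulationConfig(duration=120.0, seed=5))


def synthetic_beat(amps=(8.0, 6.0, 0.0), beat_len=0.8, fs=250.0, foot=10.0,
                   latencies=(0.09, 0.21, 0.33), widths=(0.03, 0.035, 0.035)):
    """A single sampled ICP beat built from the pulse template."""
    cfg = nm.SimulationConfig(
        pulse_landmark_latencies=latencies, pulse_landmark_widths=widths
    )
    t = np.arange(int(round(beat_len * fs))) / fs
    return foot + nm.pulse_template(t, amps, cfg), fs
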