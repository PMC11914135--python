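import numpy as np
import pytest

from eegparity import (
    CHANNELS_1020,
    FilterSpec,
    SynthesisParams,
    TrialDataset,
    build_calibration_schedule,
    online_pipeline,
    synthesize_session,
)
from eegparity.synthetic import RawSession


def quiet_params(seed=0, **erp_overrides):
    """Synthesis params with every stochastic component silenced."""
    p = SynthesisParams(seed=seed)
    p.noise.background_sd_uV = 0.0
    p.noise.alpha_amp_uV = 0.0
    p.artifacts.line_amp_uV = 0.0
    p.artifacts.blink_rate_per_s = 0.0
    p.erp.latency_jitter_sd_s = 0.0
    for key, val in erp_overrides.items():
        setattr(p.erp, key, val)
    return p


def make_separable_dataset(n_targets=30, n_nontargets=120, n_ch=4, n_s=40,
                           amp=1.0, noise_sd=1e-4, seed=0):
    """Trial tensor where targets carry a bump template and non-targets
    do not; the tiny default noise floor keeps covariances full rank
    while the classes stay separated by >1000 standard deviations."""
    rng = np.random.default_rng(seed)
    template = np.zeros((n_ch, n_s))
    t = np.arange(n_s)
    for c in range(n_ch):
        template[c] = amp * (c + 1) / n_ch * np.exp(-0.5 * ((t - 22) / 5.0) ** 2)
    n = n_targets + n_nontargets
    labels = np.zeros(n, dtype=int)
    labels[:n_targets] = 1
    rng.shuffle(labels)
    trials = rng.normal(0.0, noise_sd, size=(n, n_ch, n_s))
    trials[labels == 1] += template
    return TrialDataset(trials, labels, n_s / 150.0, 150.0, "CF", (1.0, 20.0),
                        [f"ch{i}" for i in range(n_ch)])


def sinusoid_session(n_inquiries=15, freq=10.0, amp=10.0, fs=300.0, seed=2):
    """Stationary sinusoid on every channel, with a real stimulus schedule."""
    sched = build_calibration_schedule(n_inquiries, seed=seed)
    n = int(np.ceil((sched.duration + 2.5) * fs))
    t = np.arange(n) / fs
    data = np.tile(amp * np.sin(2 * np.pi * freq * t), (len(CHANNELS_1020), 1))
    return RawSession(data, fs, list(CHANNELS_1020), sched, seed)


@pytest.fixture(scope="session")
def default_schedule():
    """The calibration task at its published size."""
    return build_calibration_schedule(110, 10, 0.10, 5.0, 1.0, 0.5, 2.0,
                                      seed=7)


@pytest.fixture(scope="session")
def noisy_of_dataset():
    """A realistic small OF dataset shared by model tests."""
    sched = build_calibration_schedule(40, seed=11)
    p = SynthesisParams(seed=11)
    p.noise.background_sd_uV = 2.0
    raw = synthesize_session(sched, p)
    return online_pipeline(raw, FilterSpec())
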