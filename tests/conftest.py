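import numpy as np
import pytest

from nervestretch.synthetic import RecordingConfig, SpecimenTruth


@pytest.fixture
def ref_specimen():
    """Cohort-average specimen with noiseless recordings."""
    return SpecimenTruth(
        id="S01", sex="female", side="left",
        L0=28.8, d0=1.42,
        alpha_true=0.183, beta_true=1.88,
        lambda50_true=1.108, width_true=0.02,
        cap_amp0=1.0, noise_sd=0.0, seed=1,
    )


@pytest.fixture
def fast_rec():
    """Reduced recording (20 kHz, 10 s -> 4 sweeps) for quick trace tests;
    still satisfies the band edge and sweep-count invariants."""
    return RecordingConfig(fs=20_000.0, record_duration=10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
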