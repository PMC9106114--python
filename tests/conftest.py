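import numpy as np
import pytest

from vcgkit import CohortConfig, MultichannelRecord, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ecg8(rng):
    """Random 8-lead ECG record, 2 s at 500 Hz."""
    return MultichannelRecord(
        samples=rng.normal(0, 0.5, size=(1000, 8)),
        lead_labels=("I", "II", "V1", "V2", "V3", "V4", "V5", "V6"),
        fs=500.0,
        record_id="ecg8",
    )


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Five noiseless, drift-free record pairs (exact IDT recovery holds)."""
    cfg = CohortConfig(n_records=5, duration_s=10.0, noise_sd=0.0,
                       drift_amp=0.0, seed=7)
    pairs, manifest = generate_cohort(cfg)
    return cfg, pairs, manifest


@pytest.fixture(scope="session")
def default_cohort():
    """The default noisy study cohort: 30 records, 10 s, seeded."""
    cfg = CohortConfig(seed=1)
    pairs, manifest = generate_cohort(cfg)
    return cfg, pairs, manifest
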