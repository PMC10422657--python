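import numpy as np
import pytest

from mwppg.signal_synth import SynthConfig, generate_clean_record


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def clean_record_60s():
    """60 s clean record at a fixed 90 BPM (shared, treat as read-only)."""
    cfg = SynthConfig(duration=60.0, heart_rate_mean=90.0, heart_rate_sd=0.0, seed=7)
    return generate_clean_record(cfg)


@pytest.fixture(scope="session")
def short_record():
    """10 s record with default vitals."""
    return generate_clean_record(SynthConfig(duration=10.0, seed=3))
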