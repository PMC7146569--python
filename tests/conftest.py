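import numpy as np
import pytest

from tdhr.conditioning import condition_signal
from tdhr.synth import SynthConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_recording():
    """Factory: noiseless synthetic recording at a given constant rate."""

    def make(hr=75.0, duration_s=60.0, seed=0, **kw):
        return generate(
            SynthConfig(duration_s=duration_s, hr=hr, noise_sd=0.0,
                        drift_sd=0.0, seed=seed, **kw)
        )

    return make


@pytest.fixture
def conditioned_window(clean_recording):
    """Factory: one conditioned 1024-sample window of clean PPG."""

    def make(hr=75.0, seed=0, n=1024, start=640):
        rec = clean_recording(hr=hr, duration_s=(start + n) / 32.0 + 10.0, seed=seed)
        y = condition_signal(rec.ppg.astype(float))
        return y[start:start + n], rec

    return make
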