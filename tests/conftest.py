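import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_epochs():
    """Two epochs, three sine channels at 128 Hz (4-s epochs)."""
    from vnseeg.io import EpochSet

    fs = 128.0
    t = np.arange(int(4 * fs)) / fs
    gen = np.random.default_rng(0)
    data = np.stack(
        [
            np.stack(
                [
                    10 * np.sin(2 * np.pi * 10 * t + e),
                    5 * np.cos(2 * np.pi * 6 * t + e),
                    gen.normal(0, 3, t.size),
                ]
            )
            for e in range(2)
        ]
    )
    return EpochSet(
        data=data,
        fs=fs,
        channel_labels=("C3", "C4", "Pz"),
        subject_id="S01",
        session="pre",
    )
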