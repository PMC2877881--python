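import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from scrlti.io_signal import EpochMatrix

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_epochs(data, fs=10.0, subjects=None, excluded=None):
    """EpochMatrix from a raw array with minimal metadata."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n = data.shape[0]
    meta = pd.DataFrame(
        {
            "subject": subjects if subjects is not None else [""] * n,
            "condition": [""] * n,
            "onset": np.arange(n, dtype=float),
            "excluded": excluded if excluded is not None else [False] * n,
        }
    )
    return EpochMatrix(data, fs=fs, epoch_len=data.shape[1] / fs, meta=meta)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
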