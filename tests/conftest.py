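import numpy as np
import pytest

from phasepower import EpochSet


@pytest.fixture(scope="session")
def fs():
    return 1000.0


@pytest.fixture(scope="session")
def times(fs):
    return np.arange(-2200.0, 1000.0 + 0.5, 1000.0 / fs)


@pytest.fixture()
def make_epochset(times, fs):
    """Factory wrapping a (time x trial) matrix into an EpochSet."""

    def _make(data):
        data = np.asarray(data, dtype=float)
        if data.ndim == 1:
            data = data[:, None]
        return EpochSet(data, times[: data.shape[0]], fs)

    return _make
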