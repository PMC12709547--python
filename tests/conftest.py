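import numpy as np
import pytest

from tfcausal.containers import ParcelEpochs
from tfcausal.synthetic import default_epoch_times


@pytest.fixture(scope="session")
def sfreq():
    return 200.0


@pytest.fixture(scope="session")
def epoch_times(sfreq):
    return default_epoch_times(sfreq)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_parcel(data, sfreq=200.0, times=None, parcel="P", condition=""):
    if times is None:
        times = default_epoch_times(sfreq)
    return ParcelEpochs(data, sfreq, times, parcel=parcel, condition=condition)


@pytest.fixture(scope="session")
def white_pair(sfreq, epoch_times):
    """Two independent white-noise parcels, 40 trials, 1 vertex each."""
    r = np.random.default_rng(999)
    x = make_parcel(r.standard_normal((40, 1, epoch_times.size)), sfreq, epoch_times, "X")
    y = make_parcel(r.standard_normal((40, 1, epoch_times.size)), sfreq, epoch_times, "Y")
    return x, y
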