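import numpy as np
import pytest

import plvnet as pv


@pytest.fixture(scope="session")
def montage():
    return pv.load_montage()


@pytest.fixture(scope="session")
def positions(montage):
    return pv.positions_for(pv.CHANNELS_16, montage)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_epochs(data, sfreq=250.0, labels=None, positions_=None,
                channel_names=None):
    """EpochSet from a raw array, defaulting to the packaged montage."""
    data = np.asarray(data)
    n_ch = data.shape[1]
    if channel_names is None:
        channel_names = pv.CHANNELS_16[:n_ch]
    if positions_ is None:
        positions_ = pv.positions_for(channel_names)
    return pv.EpochSet(data=data, channel_names=channel_names,
                       positions=positions_, sfreq=sfreq, labels=labels)


@pytest.fixture(scope="session")
def random_epochs():
    rng = np.random.default_rng(7)
    data = rng.standard_normal((4, 16, 2000))
    return make_epochs(data)
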