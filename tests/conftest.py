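import numpy as np
import pytest

from alphalat.timefreq import build_wavelet_family


#: Reduced montage for pipeline tests: the six analysis electrodes plus a
#: handful of fillers, enough for average referencing and bad-channel stats.
SMALL_MONTAGE = ("Fz", "Cz", "Pz", "Oz", "C3", "C4",
                 "P7", "P3", "P4", "P8", "CP5", "CP6")


@pytest.fixture(scope="session")
def family200():
    """The standard 50-wavelet family at the 200 Hz analysis rate."""
    return build_wavelet_family(200.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
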