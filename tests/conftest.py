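import numpy as np
import pytest

from ngtdmpet import QuantizedPatch


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


def random_patch(rng, size_lo=3, size_hi=7, max_bins=16, random_validity=True):
    """A random quantized patch with at least one valid cell."""
    h = int(rng.integers(size_lo, size_hi + 1))
    w = int(rng.integers(size_lo, size_hi + 1))
    nbins = int(rng.integers(1, max_bins + 1))
    values = rng.integers(1, nbins + 1, size=(h, w))
    if random_validity:
        valid = rng.random((h, w)) > 0.2
        if not valid.any():
            valid[h // 2, w // 2] = True
    else:
        valid = np.ones((h, w), dtype=bool)
    return QuantizedPatch(values, valid)
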