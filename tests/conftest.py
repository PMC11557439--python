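import numpy as np
import pytest

from hemocascade import PhantomSpec, generate_phantom_series


@pytest.fixture(scope="session")
def phantom_small():
    """60 phantom slices at 64 px with exact masks and labels."""
    spec = PhantomSpec(image_side=64, n_slices=60, fraction_empty_slices=0.3, seed=11)
    series, masks, labels = generate_phantom_series(spec)
    return series, masks, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_blob_mask(rng, side=64, blob_side=12):
    """Square blob at a random position; used for geometry round-trips."""
    m = np.zeros((side, side), dtype=np.uint8)
    r = int(rng.integers(0, side - blob_side))
    c = int(rng.integers(0, side - blob_side))
    m[r : r + blob_side, c : c + blob_side] = 1
    return m
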