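import numpy as np
import pytest

from hevcells import SyntheticSpec, generate_tissue_image
from hevcells.segmentation import VCellMap


@pytest.fixture(scope="session")
def tissue_fixture():
    """Default 512x512 synthetic core with gold standard and nucleus truth."""
    spec = SyntheticSpec(rng_seed=3)
    rgb, gold, centres = generate_tissue_image(spec)
    return spec, rgb, gold, centres


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_flat_vcells(n, areas=None):
    """A degenerate 1-row VCellMap whose v-cell i+1 covers ``areas[i]`` pixels.

    Lets consensus/evaluation code that only needs per-v-cell areas run
    without a real watershed segmentation.
    """
    if areas is None:
        areas = np.ones(n, dtype=int)
    labels = np.repeat(np.arange(1, n + 1), areas)[None, :]
    return VCellMap(labels=labels.astype(np.int32), nuclei=labels.astype(np.int32))


@pytest.fixture
def flat_vcells():
    return make_flat_vcells
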