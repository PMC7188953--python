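import numpy as np
import pytest

from radiotexnet import features, synthetic
from radiotexnet.preprocess import QuantizedVolume


def make_qvol(levels, mask=None, ng=None):
    """Build a QuantizedVolume directly from an integer level grid."""
    levels = np.asarray(levels, dtype=np.int32)
    if mask is None:
        mask = levels > 0
    mask = np.asarray(mask, bool)
    arr = np.where(mask, levels, 0).astype(np.int32)
    ng = ng or int(levels[mask].max())
    centroids = np.arange(1, ng + 1, dtype=float)
    return QuantizedVolume(levels=arr, mask=mask, ng=ng,
                           boundaries=0.5 + np.arange(1, ng, dtype=float),
                           centroids=centroids)


def random_qvol(rng, max_side=5, max_ng=4):
    """Random tiny quantized ROI: random shape, random mask, levels 1..ng."""
    shape = tuple(rng.integers(2, max_side + 1, size=3))
    ng = int(rng.integers(2, max_ng + 1))
    levels = rng.integers(1, ng + 1, size=shape)
    mask = rng.random(shape) < 0.8
    if not mask.any():
        mask[0, 0, 0] = True
    return make_qvol(levels, mask, ng)


@pytest.fixture(scope="session")
def small_cohort():
    """20-subject two-class synthetic cohort with the default class specs."""
    return synthetic.generate_cohort(10, 10, seed=42)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    """Feature table of the small cohort at a reduced Ng list (fast)."""
    return features.assemble_feature_table(small_cohort, ng_list=(16, 32))
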