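import numpy as np
import pytest

from tissueseg.synthetic import (
    TissueSimConfig,
    generate_voronoi_labels,
    labels_to_boundary_target,
)


@pytest.fixture
def two_half_volumes():
    """16³ volume split into two labels by the plane z=8."""
    labels = np.ones((16, 16, 16), dtype=np.int32)
    labels[8:] = 2
    return labels


@pytest.fixture
def voronoi_10():
    """Clean 10-cell Voronoi volume (32³) with its binary boundary target."""
    cfg = TissueSimConfig(shape=(32, 32, 32), n_cells=10, rng_seed=11)
    labels = generate_voronoi_labels(cfg)
    boundary = labels_to_boundary_target(labels, sigma=1.0)
    return labels, boundary


def random_label_pair(rng, shape=(8, 8, 8), k_seg=4, k_gt=4, p_zero=0.1):
    """A random (seg, gt) labelling pair; gt may contain ignore-label 0."""
    seg = rng.integers(1, k_seg + 1, size=shape)
    gt = rng.integers(1, k_gt + 1, size=shape)
    gt[rng.random(shape) < p_zero] = 0
    return seg, gt
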