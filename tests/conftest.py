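import numpy as np
import pytest

from tractmvpa.cohort import EffectSpec, NoiseSpec, simulate_dti_cohort
from tractmvpa.skeletons import TractSkeleton, make_skeleton


@pytest.fixture(scope="session")
def chain_skeleton():
    """Straight 4-voxel chain; adjacency is a path graph."""
    coords = np.array([[i, 0, 0] for i in range(4)])
    edges = np.array([[0, 1], [1, 2], [2, 3]])
    labels = np.array(["frontal", "mid", "mid", "temporal"], dtype=object)
    return TractSkeleton(coords, edges, labels, np.linspace(0, 1, 4))


@pytest.fixture(scope="session")
def small_skeleton():
    return make_skeleton(n_voxels=60, seed=11)


@pytest.fixture(scope="session")
def medium_skeleton():
    return make_skeleton(n_voxels=300, seed=5)


@pytest.fixture(scope="session")
def small_cohort(small_skeleton):
    """12 vs 12 cohort with a strong implanted MD effect."""
    noise = NoiseSpec()
    effect = EffectSpec(metric="MD", amplitude=4 * noise.total_voxel_sd)
    return simulate_dti_cohort(small_skeleton, n_pos=12, n_neg=12,
                               effect=effect, noise=noise, behaviour=False,
                               seed=21)


@pytest.fixture(scope="session")
def null_cohort(small_skeleton):
    return simulate_dti_cohort(small_skeleton, n_pos=10, n_neg=10,
                               effect=EffectSpec(amplitude=0.0),
                               noise=NoiseSpec(), behaviour=False, seed=33)
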