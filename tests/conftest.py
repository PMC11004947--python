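import numpy as np
import pytest

from sbmpet import CohortConfig, RunConfig, analyze_cohort, make_cohort
from sbmpet.matrix import SubjectMatrix
from sbmpet.volumes import VoxelMask


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def matrix_from_array(data: np.ndarray, demeaned: bool = False) -> SubjectMatrix:
    """Wrap a plain N x V array as a SubjectMatrix on a trivial full mask."""
    data = np.asarray(data, dtype=np.float64)
    n, v = data.shape
    mask = VoxelMask(included=np.ones((1, 1, v), dtype=bool))
    return SubjectMatrix(
        data=data,
        row_means=np.zeros(n),
        subject_ids=[f"sub-{i:03d}" for i in range(n)],
        mask=mask,
        demeaned=demeaned,
    )


def small_cohort_config(**overrides) -> CohortConfig:
    """A reduced three-source cohort for fast structural tests."""
    defaults = dict(
        grid_shape=(24, 24, 24),
        k_true=3,
        geometries=("mixed_sign", "bilateral_blobs", "focal_blobs"),
        group_shifts=((1.0, 0.5, 0.0), (0.0, 0.0, 0.0), (0.0, 0.0, 0.0)),
        n_per_group=(8, 6, 10),
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def demo_cohort():
    cfg = CohortConfig(
        grid_shape=(24, 24, 24),
        k_true=3,
        geometries=("mixed_sign", "bilateral_blobs", "focal_blobs"),
        group_shifts=((1.0, 0.5, 0.0), (0.0, 0.0, 0.0), (0.0, 0.0, 0.0)),
        n_per_group=(8, 6, 10),
    )
    return make_cohort(cfg, seed=11)


@pytest.fixture(scope="session")
def demo_result(demo_cohort):
    volumes, meta, truth = demo_cohort
    config = RunConfig(n_components=5, seed=11, min_cluster_voxels=10)
    return analyze_cohort(volumes, meta, config, mask=truth.brain_mask)
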