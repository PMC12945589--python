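import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from strainmap.grid import VoxelGrid
from strainmap.synthetic import default_ground_truth, make_normative_field

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def truth_default():
    """Default study conditions on the full desk-scale grid."""
    return default_ground_truth(seed=1)


@pytest.fixture(scope="session")
def truth_tiny():
    """One planted blob on a small grid; cheap enough for per-test cohorts."""
    grid = VoxelGrid(shape=(20, 22, 20), voxel_size=(2.0, 2.0, 2.0), affine=None)
    return make_normative_field(
        grid, [((10.0, 11.0, 10.0), 6.0, 2.0)], seed=7
    )


@pytest.fixture(scope="session")
def mre_cohort_tiny(truth_tiny):
    from strainmap.synthetic import simulate_mre_cohort

    return simulate_mre_cohort(truth_tiny, 6, seed=2)


@pytest.fixture(scope="session")
def single_shell_table():
    from strainmap.dwi import make_gradient_table

    return make_gradient_table(64, 1000.0, 1)


@pytest.fixture(scope="session")
def calibrated_response(single_shell_table):
    """Response estimated from 60 noiseless single-fiber voxels."""
    from strainmap.csd import estimate_response
    from strainmap.dwi import fit_tensor, simulate_dwi

    bvals, bvecs = single_shell_table
    rng = np.random.default_rng(11)
    dirs = rng.standard_normal((60, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    dwi = simulate_dwi([[(d, 1.0)] for d in dirs], bvals=bvals, bvecs=bvecs)
    return estimate_response(dwi, fit_tensor(dwi))
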