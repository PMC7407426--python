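import numpy as np
import pytest

from lungstrain import PhantomSpec, StrainProfile, generate_subject
from lungstrain.phantom import make_lung_mask, make_separable_warp


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A 48^3 phantom small enough for per-test meshing."""
    return PhantomSpec(grid_shape=(48, 48, 48), lung_axes=(1.8, 1.5, 1.6))


@pytest.fixture(scope="session")
def sb_subject(small_spec):
    return generate_subject("SB", "T1", small_spec, seed=11, subject_id="sb01")


@pytest.fixture(scope="session")
def graded_warp_spec() -> PhantomSpec:
    """DV-graded separable stretch with closed-form Jacobian."""
    return PhantomSpec(
        grid_shape=(48, 48, 48),
        lung_axes=(1.8, 1.5, 1.6),
        strain_profile=StrainProfile(a_ab=1.05, a_dv=1.05, a_lr=1.10, dv_gradient=0.2),
    )


@pytest.fixture(scope="session")
def graded_ground_truth(graded_warp_spec):
    mask = make_lung_mask(graded_warp_spec)
    gt = make_separable_warp(graded_warp_spec)
    return graded_warp_spec, mask, gt


def lung_points(mask, rng, n=1000):
    """Random points (mm) inside a mask, at voxel centres jittered by 1/4 voxel."""
    idx = np.argwhere(mask.data)
    pick = idx[rng.integers(0, len(idx), n)]
    jitter = rng.uniform(-0.25, 0.25, size=(n, 3))
    return (pick + jitter) * mask.spacing
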