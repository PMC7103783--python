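import numpy as np
import pytest

from fetalrecon.acquisition import SliceGeometry, make_psf
from fetalrecon.geometry import ImageGrid3D, RigidTransform, Slice2D, Stack, Volume3D
from fetalrecon.simulate import (ArtifactSpec, MotionSpec, PhantomSpec,
                                 make_phantom, simulate_acquisition)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """48^3 phantom at 2 mm spacing: fast enough for unit-level pipelines."""
    return make_phantom(PhantomSpec((48, 48, 48), 2.0, seed=7))


@pytest.fixture(scope="session")
def static_stacks(small_phantom):
    """Three orthogonal stacks, no motion, no artifacts, no noise."""
    phantom, mask = small_phantom
    stacks, gt = simulate_acquisition(
        phantom, mask, slice_shape=(36, 36), in_plane_spacing=2.0,
        thickness=4.0,
        motion=MotionSpec(max_rotation=0, max_translation=0,
                          walk_step_rotation=0, walk_step_translation=0,
                          jump_rotation=0, jump_translation=0),
        artifacts=ArtifactSpec(outlier_fraction=0.0),
        noise_sd=0.0, intensity_scales=[(1, 0)] * 3, seed=3)
    return stacks, gt


def random_rigid(rng, max_rot=20.0, max_trans=10.0) -> RigidTransform:
    return RigidTransform.from_params(
        np.concatenate([rng.uniform(-max_rot, max_rot, 3),
                        rng.uniform(-max_trans, max_trans, 3)]))


@pytest.fixture
def random_geometry(rng):
    """A random slice geometry overlapping a small random grid."""
    def make(seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        grid = ImageGrid3D((10, 11, 12), tuple(r.uniform(0.8, 1.5, 3)),
                           tuple(r.uniform(-2, 2, 3)))
        T = RigidTransform.from_params(
            np.concatenate([r.uniform(-25, 25, 3), r.uniform(-2, 2, 3)]),
            center=grid.index_to_world((4.5, 5, 5.5)))
        geom = SliceGeometry((6, 7), 1.4, 2.8, T)
        return grid, geom
    return make


def dense_forward_matrix(geom, psf, grid):
    """Independent brute-force dense A: per pixel, evaluate the oriented
    Gaussian at every voxel center in world space, truncate at the
    Mahalanobis radius (including the box-voxel moment), renormalize."""
    R = geom.transform.rotation
    # effective covariance: PSF rotated to world + voxel box second moment
    M = grid.direction @ np.diag(grid.spacing)
    cov = R @ psf.covariance @ R.T + M @ (np.eye(3) / 12.0) @ M.T
    prec = np.linalg.inv(cov)
    vox = grid.world_centers()
    pix = geom.pixel_world_coords()
    A = np.zeros((len(pix), len(vox)))
    for p, c in enumerate(pix):
        d = vox - c
        maha = np.einsum("ni,ij,nj->n", d, prec, d)
        w = np.where(maha <= psf.truncation_radius**2 + 1e-12,
                     np.exp(-0.5 * maha), 0.0)
        if w.sum() > 0:
            A[p] = w / w.sum()
    return A
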