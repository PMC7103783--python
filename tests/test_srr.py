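import numpy as np
import pytest

from fetalrecon.acquisition import SliceGeometry, make_psf
from fetalrecon.errors import NoInliersError, UndefinedSimilarityError
from fetalrecon.geometry import (ImageGrid3D, MaskVolume, RigidTransform,
                                 Slice2D, Volume3D)
from fetalrecon.srr import (SRRConfig, adjoint_gradient, gradient, ncc,
                            select_inliers, slice_similarity, solve_srr)

from conftest import dense_forward_matrix


def _slice(pixels, transform, mask=None, spacing=1.0, thickness=2.0,
           index=0, sid="s"):
    return Slice2D(np.asarray(pixels, float), spacing, thickness, transform,
                   mask, slice_index=index, stack_id=sid)


def _orthogonal_slices(vol, psf, spacing=1.0, thickness=2.0, shape=(10, 10)):
    """Noise-free consistent observations: slices = A x for three orthogonal
    pass-throughs of a small volume."""
    from fetalrecon.acquisition import forward_project
    from fetalrecon.simulate import default_orientations
    n = np.asarray(vol.grid.shape)
    center = vol.grid.index_to_world((n - 1) / 2.0)
    slices = []
    for j, base in enumerate(default_orientations()):
        extent = max(n) * max(vol.grid.spacing)
        n_slices = int(np.ceil(extent / thickness)) + 1
        for k in range(n_slices):
            off = np.array([-(shape[0] - 1) / 2.0 * spacing,
                            -(shape[1] - 1) / 2.0 * spacing,
                            (k - (n_slices - 1) / 2.0) * thickness])
            T = RigidTransform(base.rotation, base.rotation @ off + center)
            geom = SliceGeometry(shape, spacing, thickness, T)
            try:
                y = forward_project(vol, geom, psf)
            except Exception:
                continue
            slices.append(_slice(y, T, spacing=spacing, thickness=thickness,
                                 index=k, sid=f"st{j}"))
    return slices


class TestSliceSimilarity:
    def test_self_similarity_is_one(self, rng):
        px = rng.random((6, 6))
        s = _slice(px, RigidTransform.identity())
        assert slice_similarity(s, px) == pytest.approx(1.0)

    def test_anticorrelation_is_minus_one(self, rng):
        px = rng.random((6, 6))
        s = _slice(px, RigidTransform.identity())
        assert slice_similarity(s, -px + 3.0) == pytest.approx(-1.0)

    def test_hand_evaluated_value(self):
        # masked pixels y=(1,2,3), y_sim=(2,2,5): direct covariance oracle
        y = np.array([[1.0, 2.0, 3.0]])
        ysim = np.array([[2.0, 2.0, 5.0]])
        a = y.ravel() - y.mean()
        b = ysim.ravel() - ysim.mean()
        expected = float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
        s = _slice(y, RigidTransform.identity())
        assert slice_similarity(s, ysim) == pytest.approx(expected, abs=1e-12)

    def test_constant_region_raises(self):
        s = _slice(np.ones((4, 4)), RigidTransform.identity())
        with pytest.raises(UndefinedSimilarityError):
            slice_similarity(s, np.ones((4, 4)) * 2)

    def test_tiny_mask_raises(self, rng):
        s = _slice(rng.random((4, 4)), RigidTransform.identity())
        m = np.zeros((4, 4), bool)
        m[0, 0] = True
        with pytest.raises(UndefinedSimilarityError):
            slice_similarity(s, rng.random((4, 4)), m)


class TestSelectInliers:
    @pytest.fixture
    def scene(self, rng):
        grid = ImageGrid3D((12, 12, 12), (1.0, 1.0, 1.0))
        from scipy.ndimage import gaussian_filter
        x = Volume3D(gaussian_filter(rng.random(grid.shape), 1.5), grid)
        mask = MaskVolume(np.ones(grid.shape), grid)
        psf = make_psf(1.0, 2.0)
        slices = _orthogonal_slices(x, psf, shape=(8, 8))[:12]
        return x, mask, psf, slices

    def test_consistent_slices_all_accepted_and_outlier_rejected(self, scene, rng):
        x, mask, psf, slices = scene
        bad = _slice(rng.random(slices[0].pixels.shape),
                     slices[1].transform, index=99, sid="bad")
        res = select_inliers(slices + [bad], x, mask, psf, beta=0.8)
        evaluable = [s for s in slices
                     if not np.isnan(res.similarities[s.key])]
        assert len(evaluable) >= 6
        for s in evaluable:
            assert res.is_inlier(s.key)
        assert not res.is_inlier(bad.key)

    def test_floor_threshold_accepts_all_evaluable(self, scene):
        x, mask, psf, slices = scene
        res = select_inliers(slices, x, mask, psf, beta=-0.999)
        evaluable = [s for s in slices
                     if not np.isnan(res.similarities[s.key])]
        assert len(evaluable) >= 6
        assert all(res.is_inlier(s.key) for s in evaluable)

    def test_threshold_definition(self, scene):
        x, mask, psf, slices = scene
        res = select_inliers(slices, x, mask, psf, beta=0.8)
        for s in slices:
            sim = res.similarities[s.key]
            assert res.is_inlier(s.key) == (sim >= 0.8)


class TestGradient:
    def test_constant_has_zero_gradient(self):
        grid = ImageGrid3D((6, 6, 6), (1.0, 2.0, 0.5))
        g = gradient(Volume3D(np.full(grid.shape, 3.0), grid))
        assert np.all(g == 0)

    def test_linear_ramp_exact(self):
        grid = ImageGrid3D((6, 6, 6), (1.0, 1.0, 1.0))
        vals = np.arange(6)[:, None, None] * np.ones((6, 6, 6)) * 2.5
        g = gradient(Volume3D(vals, grid))
        assert np.abs(g[0][:-1] - 2.5).max() < 1e-12
        assert np.all(g[0][-1] == 0)

    def test_adjoint_identity(self, rng):
        grid = ImageGrid3D((7, 8, 9), (1.1, 0.7, 1.3))
        x = Volume3D(rng.random(grid.shape), grid)
        g = rng.random((3,) + grid.shape)
        lhs = float((gradient(x) * g).sum())
        rhs = float((x.values * adjoint_gradient(g, grid).values).sum())
        assert abs(lhs - rhs) < 1e-10


class TestSolveSrr:
    def test_zero_slices_give_zero_volume(self):
        grid = ImageGrid3D((8, 8, 8), (1.0, 1.0, 1.0))
        psf = make_psf(1.0, 2.0)
        slices = [_slice(np.zeros((6, 6)),
                         RigidTransform(np.eye(3), np.array([1.0, 1.0, 2.0 + k])),
                         index=k) for k in range(4)]
        x = solve_srr(slices, grid, psf, alpha=0.01)
        assert np.abs(x.values).max() < 1e-8

    def test_empty_inliers_raise(self):
        grid = ImageGrid3D((8, 8, 8), (1.0, 1.0, 1.0))
        with pytest.raises(NoInliersError):
            solve_srr([], grid, make_psf(1.0, 2.0))

    def test_consistent_system_recovers_truth(self, rng):
        from scipy.ndimage import gaussian_filter
        grid = ImageGrid3D((12, 12, 12), (1.0, 1.0, 1.0))
        x_true = gaussian_filter(rng.random(grid.shape), 1.0)
        psf = make_psf(1.0, 2.0)
        slices = _orthogonal_slices(Volume3D(x_true, grid), psf, shape=(14, 14))
        x = solve_srr(slices, grid, psf, alpha=0.0, lsq_max_iter=400,
                      lsq_tol=1e-10, clip_negative=False)
        rel = np.linalg.norm(x.values - x_true) / np.linalg.norm(x_true)
        assert rel < 1e-3

    def test_matches_dense_normal_equations(self, rng):
        """Matrix-free LSMR vs explicit dense least squares on a small
        instance (alpha=0, overdetermined by three orthogonal stacks)."""
        from scipy.ndimage import gaussian_filter
        grid = ImageGrid3D((8, 8, 8), (1.0, 1.0, 1.0))
        x_true = gaussian_filter(rng.random(grid.shape), 1.0)
        psf = make_psf(1.0, 2.0)
        slices = _orthogonal_slices(Volume3D(x_true, grid), psf, shape=(10, 10))
        rows = []
        b = []
        for s in slices:
            geom = SliceGeometry(s.pixels.shape, s.in_plane_spacing,
                                 s.thickness, s.transform)
            rows.append(dense_forward_matrix(geom, psf, grid))
            b.append(s.pixels.ravel())
        A = np.vstack(rows)
        b = np.concatenate(b)
        dense = np.linalg.lstsq(A, b, rcond=None)[0]
        ours = solve_srr(slices, grid, psf, alpha=0.0, lsq_max_iter=5000,
                         lsq_tol=1e-14, clip_negative=False)
        rel = (np.linalg.norm(ours.values.ravel() - dense)
               / np.linalg.norm(dense))
        assert rel < 1e-6

    def test_regularization_path_monotone(self, rng):
        from scipy.ndimage import gaussian_filter
        grid = ImageGrid3D((10, 10, 10), (1.0, 1.0, 1.0))
        x_true = gaussian_filter(rng.random(grid.shape), 1.0)
        psf = make_psf(1.0, 2.0)
        slices = _orthogonal_slices(Volume3D(x_true, grid), psf, shape=(12, 12))
        noisy = [
            _slice(s.pixels + rng.normal(0, 0.05, s.pixels.shape), s.transform,
                   spacing=s.in_plane_spacing, thickness=s.thickness,
                   index=s.slice_index, sid=s.stack_id) for s in slices]
        norms = []
        for alpha in (0.01, 0.1, 1.0, 10.0):
            x = solve_srr(noisy, grid, psf, alpha=alpha, lsq_max_iter=300,
                          lsq_tol=1e-10, clip_negative=False)
            norms.append(float(np.linalg.norm(gradient(x))))
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_output_nonnegative(self, rng):
        grid = ImageGrid3D((8, 8, 8), (1.0, 1.0, 1.0))
        psf = make_psf(1.0, 2.0)
        slices = [_slice(rng.normal(0, 1, (8, 8)),
                         RigidTransform(np.eye(3), np.array([0.0, 0.0, 1.0 + k * 2])),
                         index=k) for k in range(4)]
        x = solve_srr(slices, grid, psf, alpha=0.01)
        assert x.values.min() >= 0

    def test_complete_rejection_is_bit_identical(self, rng):
        """Adding a slice whose similarity falls below beta must leave the
        reconstruction bit-identical: rejected slices never enter the solve."""
        from scipy.ndimage import gaussian_filter
        grid = ImageGrid3D((10, 10, 10), (1.0, 1.0, 1.0))
        x_prev = Volume3D(gaussian_filter(rng.random(grid.shape), 1.5), grid)
        mask = MaskVolume(np.ones(grid.shape), grid)
        psf = make_psf(1.0, 2.0)
        slices = _orthogonal_slices(x_prev, psf, shape=(10, 10))[:10]

        def run(all_slices):
            sel = select_inliers(all_slices, x_prev, mask, psf, beta=0.8)
            inl = [s for s in all_slices if sel.is_inlier(s.key)]
            return solve_srr(inl, grid, psf, alpha=0.01, lsq_max_iter=60)

        bad = _slice(rng.random(slices[0].pixels.shape), slices[0].transform,
                     index=77, sid="junk")
        a = run(slices)
        b = run(slices + [bad])
        assert np.array_equal(a.values, b.values)


def test_config_validation():
    with pytest.raises(ValueError):
        SRRConfig(alpha=-1)
    with pytest.raises(ValueError):
        SRRConfig(beta_schedule=(0.5, 1.5))
    cfg = SRRConfig()
    assert cfg.n_cycles == len(cfg.beta_schedule) == 3
    assert cfg.beta_schedule == (0.5, 0.65, 0.8)


def test_ncc_clips_to_unit_interval(rng):
    a = rng.random(50)
    assert ncc(a, 2 * a + 3) == pytest.approx(1.0)
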