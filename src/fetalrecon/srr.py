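"""Outlier-robust super-resolution reconstruction.

The high-resolution volume is the maximum a-posteriori estimate

    x = argmin_{x >= 0}  sum_{k in K_beta}  1/2 ||y_k - A_k x||^2
                         + alpha/2 ||grad x||^2

where K_beta is the set of *inlier* slices: slices whose masked normalized
cross-correlation with their simulated counterpart (projected from the
previous iterate) reaches the threshold beta. Outliers are rejected
completely. For fixed K_beta the problem is linear least squares, solved
matrix-free with LSMR; positivity is enforced by clipping negative values
once after convergence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.linalg import LinearOperator, lsmr

from .acquisition import PSFSpec, SliceGeometry, forward_project, slice_weights, \
    _project_with
from .errors import EmptyProjectionError, NoInliersError, UndefinedSimilarityError
from .geometry import ImageGrid3D, MaskVolume, Slice2D, Volume3D

__all__ = ["SRRConfig", "InlierSet", "slice_similarity", "select_inliers",
           "solve_srr", "gradient", "adjoint_gradient", "ncc"]


@dataclass(frozen=True)
class SRRConfig:
    """Scalar hyperparameters of the robust reconstruction.

    alpha: Tikhonov first-order regularization weight (default 0.01).
    beta_schedule: per-cycle inlier thresholds (default 0.5, 0.65, 0.8).
    recon_spacing: isotropic reconstruction resolution in mm (default 0.8,
        the template-space resolution).
    sda_sigma: SDA smoothing standard deviation in target-grid voxels.
    """

    alpha: float = 0.01
    beta_schedule: tuple[float, ...] = (0.5, 0.65, 0.8)
    similarity: str = "NCC"
    recon_spacing: float = 0.8
    sda_sigma: float = 1.0
    lsq_max_iter: int = 100
    lsq_tol: float = 1e-6
    mask_threshold: float = 0.5
    grid_margin_mm: float = 10.0
    psf_in_plane_fwhm_factor: float = 1.2
    psf_truncation_radius: float = 3.0

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.similarity != "NCC":
            raise ValueError("only NCC similarity is implemented")
        if any(not (-1 < b <= 1) for b in self.beta_schedule):
            raise ValueError("NCC thresholds must lie in (-1, 1]")
        if self.recon_spacing <= 0:
            raise ValueError("recon_spacing must be positive")

    @property
    def n_cycles(self) -> int:
        return len(self.beta_schedule)


@dataclass
class InlierSet:
    """Slices accepted at a given threshold, with their similarities."""

    members: set[tuple[str, int]]
    similarities: dict[tuple[str, int], float]
    beta: float

    def is_inlier(self, key) -> bool:
        return key in self.members


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-mean normalized cross-correlation of two flat samples."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise UndefinedSimilarityError("constant input: NCC undefined")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def slice_similarity(y: Slice2D, y_sim: np.ndarray,
                     mask: np.ndarray | None = None) -> float:
    """NCC between an acquired slice and its simulated counterpart over a mask."""
    y_sim = np.asarray(y_sim, dtype=float)
    if y_sim.shape != y.pixels.shape:
        raise ValueError("shape mismatch between slice and simulation")
    m = y.mask if mask is None else np.asarray(mask).astype(bool)
    if m.shape != y.pixels.shape:
        raise ValueError("mask shape mismatch")
    if m.sum() < 2:
        raise UndefinedSimilarityError("fewer than 2 masked pixels")
    return ncc(y.pixels[m], y_sim[m])


def _slice_geometry(s: Slice2D) -> SliceGeometry:
    return SliceGeometry(s.pixels.shape, s.in_plane_spacing, s.thickness, s.transform)


def project_mask_to_slice(mask_hr: MaskVolume, s: Slice2D,
                          threshold: float = 0.5) -> np.ndarray:
    """High-resolution mask resampled onto the slice plane, thresholded."""
    geom = _slice_geometry(s)
    pts = mask_hr.grid.world_to_index(geom.pixel_world_coords())
    from scipy import ndimage
    vals = ndimage.map_coordinates(mask_hr.values, pts.T, order=1,
                                   mode="constant", cval=0.0)
    return (vals.reshape(s.pixels.shape) >= threshold)


def select_inliers(slices: list[Slice2D], x_prev: Volume3D,
                   mask_hr: MaskVolume, psf: PSFSpec, beta: float) -> InlierSet:
    """Inlier-set definition: keep slices with Sim(y_k, A_k x_prev) >= beta.

    The similarity is evaluated only on the slice-projected high-resolution
    mask voxels. Degenerate slices (no evaluable pixels, constant region,
    no overlap) become outliers.
    """
    members: set[tuple[str, int]] = set()
    sims: dict[tuple[str, int], float] = {}
    for s in slices:
        try:
            y_sim = forward_project(x_prev, _slice_geometry(s), psf)
            # similarity over the slice-projected high-resolution mask
            # voxels only: the region that, at the current pose, should
            # contain brain — a corrupted slice cannot escape evaluation
            # there by its own mask
            m = project_mask_to_slice(mask_hr, s)
            sim = slice_similarity(s, y_sim, m)
        except (UndefinedSimilarityError, EmptyProjectionError):
            sims[s.key] = float("nan")
            continue
        sims[s.key] = sim
        if sim >= beta:
            members.add(s.key)
    return InlierSet(members, sims, beta)


# ---------------------------------------------------------------------------
# differential operator
# ---------------------------------------------------------------------------


def gradient(x: Volume3D) -> np.ndarray:
    """Spacing-scaled forward differences (mm^-1), zero at the far boundary.

    Returns an array of shape (3, *vol.shape).
    """
    v = x.values
    g = np.zeros((3,) + v.shape)
    for ax in range(3):
        sl_hi = [slice(None)] * 3
        sl_lo = [slice(None)] * 3
        sl_hi[ax] = slice(1, None)
        sl_lo[ax] = slice(0, -1)
        g[ax][tuple(sl_lo)] = (v[tuple(sl_hi)] - v[tuple(sl_lo)]) / x.grid.spacing[ax]
    return g


def adjoint_gradient(g: np.ndarray, grid: ImageGrid3D) -> Volume3D:
    """Exact adjoint of :func:`gradient` (a negative divergence)."""
    g = np.asarray(g, dtype=float)
    out = np.zeros(grid.shape)
    for ax in range(3):
        sl_hi = [slice(None)] * 3
        sl_lo = [slice(None)] * 3
        sl_hi[ax] = slice(1, None)
        sl_lo[ax] = slice(0, -1)
        h = grid.spacing[ax]
        out[tuple(sl_lo)] -= g[ax][tuple(sl_lo)] / h
        out[tuple(sl_hi)] += g[ax][tuple(sl_lo)] / h
    return Volume3D(out, grid)


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------


def _build_system(inliers, target, psf):
    """Per-slice masked-row weight caches for the stacked operator."""
    rows = []
    for s in inliers:
        geom = _slice_geometry(s)
        w = slice_weights(geom, psf, target)
        keep = s.mask.ravel()
        rows.append((s, geom, w, keep))
    return rows


def solve_srr(inliers: list[Slice2D], target: ImageGrid3D, psf: PSFSpec,
              alpha: float = 0.01, lsq_max_iter: int = 100,
              lsq_tol: float = 1e-6, x0: Volume3D | None = None,
              clip_negative: bool = True) -> Volume3D:
    """Tikhonov-regularized least-squares reconstruction from inlier slices.

    Minimizes ``sum_k 1/2 ||y_k - A_k x||^2 + alpha/2 ||grad x||^2`` over the
    masked pixels of the inlier slices with a matrix-free LSMR solve of the
    stacked system ``[A_k; sqrt(alpha) grad]``, then clips negatives to zero.
    """
    if not inliers:
        raise NoInliersError("empty inlier set; retry with beta reduced by 0.15")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    rows = _build_system(inliers, target, psf)
    n = int(np.prod(target.shape))
    m_data = sum(int(keep.sum()) for _, _, _, keep in rows)
    m = m_data + 3 * n
    sqa = np.sqrt(alpha)
    dummy = Volume3D(np.zeros(target.shape), target)

    def matvec(xf):
        vol = xf.reshape(target.shape)
        parts = []
        for s, geom, w, keep in rows:
            parts.append(_project_with(w, geom.shape, xf).ravel()[keep])
        gv = gradient(Volume3D(vol, target)) if sqa > 0 else np.zeros((3,) + target.shape)
        parts.append(sqa * gv.ravel())
        return np.concatenate(parts)

    def rmatvec(yf):
        out = np.zeros(n)
        pos = 0
        for s, geom, w, keep in rows:
            nk = int(keep.sum())
            yfull = np.zeros(int(np.prod(geom.shape)))
            yfull[keep] = yf[pos:pos + nk]
            pos += nk
            flat, ww, row_ptr = w
            counts = np.diff(row_ptr)
            out += np.bincount(flat, weights=ww * np.repeat(yfull, counts),
                               minlength=n)
        if sqa > 0:
            g = yf[pos:].reshape((3,) + target.shape)
            out += sqa * adjoint_gradient(g, target).values.ravel()
        return out

    A = LinearOperator((m, n), matvec=matvec, rmatvec=rmatvec, dtype=float)
    b = np.concatenate(
        [s.pixels.ravel()[keep] for s, _, _, keep in rows] + [np.zeros(3 * n)])
    x0f = None if x0 is None else x0.values.ravel()
    if x0f is not None:
        res = lsmr(A, b - A.matvec(x0f), atol=lsq_tol, btol=lsq_tol,
                   maxiter=lsq_max_iter)
        sol = x0f + res[0]
    else:
        res = lsmr(A, b, atol=lsq_tol, btol=lsq_tol, maxiter=lsq_max_iter)
        sol = res[0]
    vol = sol.reshape(target.shape)
    if clip_negative:
        vol = np.maximum(vol, 0.0)
    return Volume3D(vol, target)
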