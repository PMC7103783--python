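"""Slice acquisition model: oriented-Gaussian PSF forward operator and adjoint.

Each acquired pixel is modelled as a normalized, oriented-Gaussian-weighted
average of high-resolution volume voxels (``y_k = A_k x + e_k``): the rigid
slice pose rotates a slice-aligned anisotropic Gaussian point spread function
into the volume frame, the kernel is evaluated at voxel centers inside a
Mahalanobis truncation radius, and the weights are renormalized to sum to one
over the in-extent support so constants are preserved away from boundaries.
The operator is matrix-free: weights are generated on the fly per slice and
never assembled into a global system matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyProjectionError, InvalidGeometryError
from .geometry import ImageGrid3D, RigidTransform, Volume3D

__all__ = ["PSFSpec", "SliceGeometry", "make_psf", "forward_project",
           "adjoint_project", "slice_weights"]

#: FWHM -> standard deviation for a Gaussian.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: In-plane FWHM as a multiple of the in-plane pixel spacing (SSFSE slice
#: profile approximation); the through-plane FWHM equals the slice thickness.
IN_PLANE_FWHM_FACTOR = 1.2


@dataclass(frozen=True)
class PSFSpec:
    """Slice-frame PSF covariance (mm^2) and Mahalanobis truncation radius."""

    covariance: np.ndarray
    truncation_radius: float = 3.0

    def __post_init__(self):
        C = np.asarray(self.covariance, dtype=float)
        object.__setattr__(self, "covariance", C)
        if C.shape != (3, 3) or not np.allclose(C, C.T, atol=1e-12):
            raise InvalidGeometryError("PSF covariance must be symmetric 3x3")
        if np.any(np.linalg.eigvalsh(C) <= 0):
            raise InvalidGeometryError("PSF covariance must be positive definite")
        if self.truncation_radius <= 0:
            raise InvalidGeometryError("truncation radius must be positive")


@dataclass(frozen=True)
class SliceGeometry:
    """Pixel lattice + pose of one slice; ``transform`` maps slice frame -> world."""

    shape: tuple[int, int]
    in_plane_spacing: float
    thickness: float
    transform: RigidTransform = field(default_factory=RigidTransform.identity)

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        if self.in_plane_spacing <= 0 or self.thickness <= 0:
            raise InvalidGeometryError("spacing and thickness must be positive")

    def pixel_world_coords(self) -> np.ndarray:
        ii, jj = np.indices(self.shape)
        pts = np.stack(
            [ii.ravel() * self.in_plane_spacing, jj.ravel() * self.in_plane_spacing,
             np.zeros(ii.size)], axis=1)
        return self.transform.apply(pts)


def make_psf(in_plane_spacing: float, thickness: float,
             truncation_radius: float = 3.0,
             in_plane_fwhm_factor: float = IN_PLANE_FWHM_FACTOR) -> PSFSpec:
    """Slice-aligned Gaussian PSF from the acquisition resolution.

    In-plane FWHM = ``in_plane_fwhm_factor * in_plane_spacing`` on both
    in-plane axes; through-plane FWHM = ``thickness``.
    """
    if in_plane_spacing <= 0 or thickness <= 0:
        raise InvalidGeometryError("spacing and thickness must be positive")
    s_in = in_plane_fwhm_factor * in_plane_spacing * FWHM_TO_SIGMA
    s_th = thickness * FWHM_TO_SIGMA
    return PSFSpec(np.diag([s_in**2, s_in**2, s_th**2]), truncation_radius)


def _index_frame_covariance(psf: PSFSpec, geom: SliceGeometry,
                            grid: ImageGrid3D) -> np.ndarray:
    """PSF covariance expressed in (continuous) volume index coordinates.

    The high-resolution voxels are treated as box basis functions: the
    voxel's own second moment (1/12 per index axis) is added to the rotated
    PSF covariance, which both reflects the finite voxel extent and keeps
    narrow kernels well resolved on the grid."""
    R = geom.transform.rotation
    cov_world = R @ psf.covariance @ R.T
    M = np.diag([1.0 / s for s in grid.spacing]) @ grid.direction.T  # world -> index
    return M @ cov_world @ M.T + np.eye(3) / 12.0


def slice_weights(geom: SliceGeometry, psf: PSFSpec, grid: ImageGrid3D,
                  pixel_indices: np.ndarray | None = None):
    """Sparse row structure of A_k for one slice on ``grid``.

    Returns ``(flat_voxel_indices, weights, row_ptr)`` in CSR-like layout:
    pixel ``p`` (C-order over ``geom.shape``, or the subset
    ``pixel_indices``) owns entries ``row_ptr[p]:row_ptr[p+1]``. Per-pixel
    weights sum to 1 over the truncated, in-extent support; pixels with no
    support get empty rows.
    """
    cov_idx = _index_frame_covariance(psf, geom, grid)
    prec = np.linalg.inv(cov_idx)
    L = np.linalg.cholesky(prec)  # maha(d) = ||d @ L||^2
    r = psf.truncation_radius
    half = np.ceil(r * np.sqrt(np.diag(cov_idx)) + 1e-9).astype(int)
    offs = np.stack(np.meshgrid(*[np.arange(-h, h + 1) for h in half], indexing="ij"),
                    axis=-1).reshape(-1, 3)

    centers = grid.world_to_index(geom.pixel_world_coords())  # (P, 3)
    if pixel_indices is not None:
        centers = centers[pixel_indices]
    base = np.round(centers).astype(int)
    # d[p, o] = f[p] + offs[o]; expand the quadratic form through a GEMM
    f = base - centers
    fL = f @ L
    oL = offs @ L
    maha = ((fL * fL).sum(1)[:, None] + 2.0 * (fL @ oL.T)
            + (oL * oL).sum(1)[None, :])
    w = np.exp(-0.5 * maha)
    valid = maha <= r * r + 1e-12
    for ax, n in enumerate(grid.shape):
        v = base[:, ax, None] + offs[None, :, ax]
        valid &= (v >= 0) & (v < n)
    w *= valid
    tot = w.sum(axis=1)
    has = tot > 0
    w[has] /= tot[has, None]

    counts = valid.sum(axis=1)
    row_ptr = np.concatenate([[0], np.cumsum(counts)])
    strides = np.array([grid.shape[1] * grid.shape[2], grid.shape[2], 1])
    flat = (base @ strides)[:, None] + (offs @ strides)[None, :]
    sel = valid.ravel()
    return flat.ravel()[sel], w.ravel()[sel], row_ptr


def _project_with(weights, shape, x_flat):
    flat, w, row_ptr = weights
    acc = np.add.reduceat(
        np.concatenate([w * x_flat[flat], [0.0]]),
        np.minimum(row_ptr[:-1], len(w)))
    # reduceat with repeated indices (empty rows) copies the element at the
    # index; zero those rows explicitly.
    empty = row_ptr[1:] == row_ptr[:-1]
    acc = acc[: np.prod(shape)]
    acc[empty] = 0.0
    return acc.reshape(shape)


def project_pixels(x: Volume3D, geom: SliceGeometry, psf: PSFSpec,
                   pixel_indices: np.ndarray) -> np.ndarray:
    """``(A_k x)`` restricted to a flat C-order subset of slice pixels.

    Fast path for registration metrics that only need masked pixels."""
    flat, w, row_ptr = slice_weights(geom, psf, x.grid, pixel_indices)
    acc = np.add.reduceat(
        np.concatenate([w * x.values.ravel()[flat], [0.0]]),
        np.minimum(row_ptr[:-1], len(w)))
    acc = acc[: len(pixel_indices)]
    acc[row_ptr[1:] == row_ptr[:-1]] = 0.0
    return acc


def forward_project(x: Volume3D, geom: SliceGeometry, psf: PSFSpec,
                    weights=None) -> np.ndarray:
    """Simulate the acquisition of one slice from the volume: ``A_k x``."""
    if weights is None:
        weights = slice_weights(geom, psf, x.grid)
    if len(weights[1]) == 0:
        raise EmptyProjectionError("slice geometry does not overlap the volume")
    return _project_with(weights, geom.shape, x.values.ravel())


def adjoint_project(y: np.ndarray, geom: SliceGeometry, psf: PSFSpec,
                    target: ImageGrid3D, weights=None) -> Volume3D:
    """Exact adjoint ``A_k^T y`` on ``target`` (Euclidean inner products)."""
    y = np.asarray(y, dtype=float)
    if y.shape != geom.shape:
        raise InvalidGeometryError("observation shape must match slice geometry")
    if weights is None:
        weights = slice_weights(geom, psf, target)
    flat, w, row_ptr = weights
    if len(w) == 0:
        raise EmptyProjectionError("slice geometry does not overlap the volume")
    counts = np.diff(row_ptr)
    yrep = np.repeat(y.ravel(), counts)
    n = int(np.prod(target.shape))
    out = np.bincount(flat, weights=w * yrep, minlength=n)
    return Volume3D(out.reshape(target.shape), target)
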