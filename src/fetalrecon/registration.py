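"""Self-contained rigid registration: multi-resolution Powell search on
masked normalized cross-correlation, plus an NMI estimator for candidate
selection.

The same engine serves volume-to-volume alignment, slice-to-volume motion
correction and the rigid refinement of template-alignment candidates. It is
a derivative-free local search over the 6 rigid parameters (intrinsic Z-Y-X
Euler angles in degrees, translations in mm) with a Gaussian-smoothed,
stride-subsampled resolution pyramid.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, optimize

from .acquisition import PSFSpec, project_pixels
from .errors import RegistrationFailureError, UndefinedSimilarityError
from .geometry import (MaskVolume, RigidTransform, Slice2D, Volume3D,
                       compose)
from .srr import _slice_geometry, ncc, project_mask_to_slice

__all__ = ["register_volumes", "register_slice_to_volume", "nmi"]


def nmi(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    """Normalized mutual information (H(A)+H(B))/H(A,B), joint 32-bin histogram."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedSimilarityError("constant input: NMI undefined")
    h, _, _ = np.histogram2d(a, b, bins=bins)
    p = h / h.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)

    def ent(q):
        q = q[q > 0]
        return -(q * np.log(q)).sum()

    hab = ent(p.ravel())
    if hab == 0:
        raise UndefinedSimilarityError("degenerate joint histogram")
    return float((ent(px) + ent(py)) / hab)


def _sample(vol: Volume3D, pts_world: np.ndarray, order: int = 1) -> np.ndarray:
    idx = vol.grid.world_to_index(pts_world)
    return ndimage.map_coordinates(vol.values, idx.T, order=order,
                                   mode="constant", cval=0.0)


def register_volumes(moving: Volume3D, fixed: Volume3D,
                     moving_mask: MaskVolume | None = None,
                     fixed_mask: MaskVolume | None = None,
                     init: RigidTransform | None = None,
                     levels: tuple[tuple[float, int], ...] = ((2.0, 4), (1.0, 2), (0.0, 1)),
                     maxfev: int = 160,
                     xtol: float = 1e-3,
                     capture_range: tuple[float, float] = (30.0, 30.0),
                     robust: bool = False) -> RigidTransform:
    """Rigid transform maximizing masked NCC between ``resample(moving, T)``
    and ``fixed``; ``T`` maps fixed-space world points into moving space
    (resampling convention).

    ``levels`` is a coarse-to-fine schedule of (smoothing sigma in voxels,
    sampling stride) applied to the fixed grid. With ``robust`` the metric
    is a trimmed blockwise NCC (blocks along the fixed slice axis; the worst
    quarter of blocks is discarded), which keeps artifact-corrupted slices
    from dominating the alignment.
    """
    if np.ptp(fixed.values) == 0 or np.ptp(moving.values) == 0:
        raise RegistrationFailureError("constant volume: NCC undefined")
    fmask = None if fixed_mask is None else fixed_mask.as_bool()
    init = RigidTransform.identity() if init is None else init
    # rotations act about the fixed masked centroid (lever-arm-free search)
    if fmask is not None and fmask.any():
        center = fixed.grid.index_to_world(np.argwhere(fmask).mean(axis=0))
    else:
        center = fixed.grid.index_to_world((np.asarray(fixed.grid.shape) - 1) / 2.0)
    params = np.zeros(6)
    for sigma, stride in levels:
        fvals_full = (ndimage.gaussian_filter(fixed.values, sigma) if sigma > 0
                      else fixed.values)
        mvals = (ndimage.gaussian_filter(moving.values, sigma) if sigma > 0
                 else moving.values)
        mov = Volume3D(mvals, moving.grid)
        sub = tuple(slice(None, None, stride) for _ in range(3))
        fsel = fvals_full[sub].ravel()
        sub_idx = np.stack(np.meshgrid(*[np.arange(0, n, stride)
                                         for n in fixed.grid.shape],
                                       indexing="ij"), axis=-1).reshape(-1, 3)
        pts = fixed.grid.index_to_world(sub_idx)
        block_id = sub_idx[:, 2]  # slab blocks along the fixed slice axis
        if fmask is not None:
            keep = fmask[sub].ravel()
            if keep.sum() < 8:
                keep = np.ones(fsel.size, dtype=bool)
            fsel = fsel[keep]
            pts = pts[keep]
            block_id = block_id[keep]
        if np.ptp(fsel) == 0:
            raise RegistrationFailureError("constant masked region")
        blocks = None
        if robust:
            uniq = [np.flatnonzero(block_id == b) for b in np.unique(block_id)]
            blocks = [u for u in uniq if u.size >= 8 and np.ptp(fsel[u]) > 0]
            if len(blocks) < 6:
                blocks = None

        def cost(p):
            T = compose(init, RigidTransform.from_params(p, center=center))
            wv = _sample(mov, T.apply(pts))
            try:
                if blocks is None:
                    return -ncc(fsel, wv)
                vals = []
                for u in blocks:
                    try:
                        vals.append(ncc(fsel[u], wv[u]))
                    except UndefinedSimilarityError:
                        vals.append(-1.0)
                vals = np.sort(vals)
                n_keep = max(int(np.ceil(0.75 * len(vals))), 1)
                return -float(np.mean(vals[-n_keep:]))
            except UndefinedSimilarityError:
                return 1.0

        bounds = optimize.Bounds(
            np.array([-capture_range[0]] * 3 + [-capture_range[1]] * 3),
            np.array([capture_range[0]] * 3 + [capture_range[1]] * 3))
        res = optimize.minimize(cost, params, method="Powell", bounds=bounds,
                                options={"maxfev": maxfev, "xtol": xtol,
                                         "ftol": 1e-6})
        params = res.x
    return compose(init, RigidTransform.from_params(params, center=center))


def register_slice_to_volume(s: Slice2D, x: Volume3D,
                             mask_hr: MaskVolume, psf: PSFSpec,
                             init: RigidTransform | None = None,
                             maxfev: int = 250,
                             xtol: float = 5e-3,
                             capture_range: tuple[float, float] = (12.0, 8.0),
                             translation_only: bool = False) -> RigidTransform:
    """Rigid slice pose maximizing NCC between the acquired slice and its
    forward projection from ``x``, over pixels inside both the slice mask and
    the slice-projected high-resolution mask.

    The returned transform maps the slice frame into the volume's world
    space. The pose is parameterized as a perturbation of ``init`` (the
    previous cycle's estimate). Raises ``RegistrationFailureError`` on
    degenerate slices; the caller keeps the previous transform.
    """
    init = s.transform if init is None else init
    m0 = s.mask & project_mask_to_slice(mask_hr, s.with_transform(init))
    if m0.sum() < 8:
        m0 = s.mask
    if m0.sum() < 2 or np.ptp(s.pixels[m0]) == 0:
        raise RegistrationFailureError("degenerate slice: NCC undefined")
    yref = s.pixels[m0]
    pix_idx = np.flatnonzero(m0.ravel())
    # perturbation rotations act about the slice's masked center in world space
    ij = np.argwhere(m0).mean(axis=0) * s.in_plane_spacing
    center = init.apply(np.array([ij[0], ij[1], 0.0]))

    def cost(p):
        T = compose(RigidTransform.from_params(p, center=center), init)
        try:
            y_sim = project_pixels(x, _slice_geometry(s.with_transform(T)),
                                   psf, pix_idx)
            return -ncc(yref, y_sim)
        except Exception:
            return 1.0

    # stage 1: translation only — the NCC valley is much sharper in
    # translation than rotation, so fixing translation first keeps the
    # subsequent rotation line searches inside the correct basin
    p = np.zeros(6)

    def cost_t(t):
        q = p.copy()
        q[3:] = t
        return cost(q)

    rt = optimize.minimize(
        cost_t, p[3:], method="Powell",
        bounds=optimize.Bounds(np.full(3, -capture_range[1]),
                               np.full(3, capture_range[1])),
        options={"maxfev": 60, "xtol": 1e-2})
    p[3:] = rt.x
    if translation_only:
        # against a blurry reference (first cycle) rotations are not
        # identifiable; keep the initialization's rotation
        return compose(RigidTransform.from_params(p, center=center), init)

    # stage 2: full 6-DOF refinement, translation directions searched first
    bounds = optimize.Bounds(
        np.array([-capture_range[0]] * 3 + [-capture_range[1]] * 3),
        np.array([capture_range[0]] * 3 + [capture_range[1]] * 3))
    res = optimize.minimize(cost, p, method="Powell", bounds=bounds,
                            options={"maxfev": maxfev, "xtol": xtol,
                                     "ftol": 1e-6,
                                     "direc": np.eye(6)[[3, 4, 5, 0, 1, 2]]})
    if not np.all(np.isfinite(res.x)):
        raise RegistrationFailureError("optimizer diverged")
    # coordinate-wise parabolic polish: the NCC valley is extremely shallow
    # in rotation, where Powell's line searches stop early; a local
    # quadratic fit per parameter recovers the sub-step optimum
    p = res.x
    f0 = cost(p)
    steps = (0.5, 0.5, 0.5, 0.25, 0.25, 0.25)
    for _ in range(2):
        for ax in range(6):
            h = steps[ax]
            pm, pp = p.copy(), p.copy()
            pm[ax] -= h
            pp[ax] += h
            fm, fp = cost(pm), cost(pp)
            curv = fm - 2 * f0 + fp
            if curv > 1e-12:
                cand = p.copy()
                cand[ax] += np.clip(0.5 * h * (fm - fp) / curv, -h, h)
                fc = cost(cand)
                if fc < f0:
                    p, f0 = cand, fc
            elif min(fm, fp) < f0:
                p, f0 = (pm, fm) if fm < fp else (pp, fp)
    return compose(RigidTransform.from_params(p, center=center), init)
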