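"""Two-step iterative motion correction / robust reconstruction pipeline.

Pipeline order (fixed): target-stack selection -> volume-to-volume alignment
of all stacks to the target -> linear intensity correction -> SDA
initialization of volume and mask -> n_cycles of {per-slice rigid SVR;
inlier selection at beta_i; robust SRR solve; mask SDA from inlier slice
masks}, producing the subject-space reconstruction.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .acquisition import PSFSpec, make_psf
from .errors import NoBrainFoundError, NoOverlapWarning, RegistrationFailureError
from .geometry import (ImageGrid3D, MaskVolume, RigidTransform, Slice2D, Stack,
                       Volume3D, compose, resample)
from .errors import EmptyProjectionError, UndefinedSimilarityError
from .registration import register_slice_to_volume, register_volumes
from .sda import sda_loo_reconstructions, sda_mask, sda_reconstruct
from .srr import (InlierSet, SRRConfig, _slice_geometry,
                  project_mask_to_slice, select_inliers, slice_similarity,
                  solve_srr)

__all__ = ["ReconstructionResult", "select_target_stack", "volume_to_volume_register",
           "intensity_correct", "slice_to_volume_register", "reconstruct_subject_space",
           "stack_to_volume"]

log = logging.getLogger(__name__)


@dataclass
class ReconstructionResult:
    volume: Volume3D
    mask: MaskVolume
    slice_transforms: dict[tuple[str, int], RigidTransform]
    inlier_history: list[InlierSet]
    target_stack_id: str
    slices: list[Slice2D]
    config: SRRConfig
    psf: PSFSpec

    def final_inliers(self) -> list[Slice2D]:
        if not self.inlier_history:
            return list(self.slices)
        last = self.inlier_history[-1]
        return [s for s in self.slices if last.is_inlier(s.key)]


def select_target_stack(stacks: list[Stack]) -> str:
    """Stack whose estimated brain volume is closest to 70% of the median.

    Ties break toward the lower stack index.
    """
    vols = np.array([st.mask_volume_mm3() for st in stacks])
    if np.all(vols == 0):
        raise NoBrainFoundError("all stack masks are empty")
    ref = 0.7 * np.median(vols)
    return stacks[int(np.argmin(np.abs(vols - ref)))].stack_id


def stack_to_volume(stack: Stack) -> tuple[Volume3D, MaskVolume]:
    """Stack the slices on their nominal grid (slice axis last, mm spacing)."""
    s0 = stack.slices[0]
    data = np.stack([s.pixels for s in stack.slices], axis=2)
    mask = np.stack([s.mask for s in stack.slices], axis=2)
    normal = np.cross(s0.transform.rotation[:, 0], s0.transform.rotation[:, 1])
    D = np.column_stack([s0.transform.rotation[:, 0],
                         s0.transform.rotation[:, 1], normal])
    grid = ImageGrid3D(data.shape,
                       (s0.in_plane_spacing, s0.in_plane_spacing, stack.thickness),
                       tuple(s0.transform.translation), D)
    return Volume3D(data, grid), MaskVolume(mask.astype(float), grid)


def volume_to_volume_register(moving: Volume3D, fixed: Volume3D,
                              moving_mask: MaskVolume | None = None,
                              fixed_mask: MaskVolume | None = None,
                              **kw) -> RigidTransform:
    """Rigid transform (fixed world -> moving world) maximizing masked NCC.

    ``robust=True`` switches to a trimmed blockwise metric (slabs along the
    fixed slice axis)."""
    return register_volumes(moving, fixed, moving_mask, fixed_mask, **kw)


def intensity_correct(stack: Stack, target: Stack,
                      v2v: RigidTransform | None = None) -> Stack:
    """Linear intensity correction a*I + b of ``stack`` against ``target``.

    Masked target voxels are paired with trilinearly interpolated moving-stack
    values after volume-to-volume alignment (``v2v``: target world -> stack
    world); (a, b) is the simple least-squares regression mapping stack
    intensities to the target reference values.
    """
    tvol, tmask = stack_to_volume(target)
    svol, _ = stack_to_volume(stack)
    v2v = RigidTransform.identity() if v2v is None else v2v
    warped = resample(svol, tvol.grid, v2v, "linear")
    m = tmask.as_bool()
    # restrict to voxels actually covered by the moving stack
    cover = resample(Volume3D(np.ones(svol.grid.shape), svol.grid),
                     tvol.grid, v2v, "linear").values > 0.5
    m = m & cover
    if m.sum() < 2 or np.ptp(warped.values[m]) == 0:
        warnings.warn("insufficient masked overlap; stack left unchanged",
                      NoOverlapWarning)
        return stack
    X = warped.values[m]
    Y = tvol.values[m]
    a, b = np.polyfit(X, Y, 1)
    new_slices = [dataclasses.replace(s, pixels=a * s.pixels + b)
                  for s in stack.slices]
    return Stack(new_slices, stack.interleave, stack.source_path)


def slice_to_volume_register(s: Slice2D, x: Volume3D, mask_hr: MaskVolume,
                             psf: PSFSpec,
                             init: RigidTransform | None = None,
                             **kw) -> RigidTransform:
    """Rigid slice pose (slice frame -> world) maximizing masked NCC with the
    forward projection from ``x``; initialized at ``init``."""
    return register_slice_to_volume(s, x, mask_hr, psf, init=init, **kw)


def _select_inliers_loo_sda(slices: list[Slice2D], grid: ImageGrid3D,
                            sigma: float, mask_hr: MaskVolume, psf: PSFSpec,
                            beta: float) -> InlierSet:
    """First-cycle inlier selection against leave-one-out SDA references.

    The cycle-1 reference is the SDA gridding of the slices themselves, so
    a corrupted slice scored against the full SDA partly correlates with
    its own contribution and can bootstrap itself into the reconstruction.
    Scoring each slice against the SDA of all *other* slices (a jackknife)
    removes that self-vote; later cycles score against solved volumes that
    no longer contain rejected slices and need no correction.
    """
    from .acquisition import forward_project
    members: set[tuple[str, int]] = set()
    sims: dict[tuple[str, int], float] = {}
    bykey = {s.key: s for s in slices}
    for key, x_loo in sda_loo_reconstructions(slices, grid, sigma=sigma):
        s = bykey[key]
        try:
            y_sim = forward_project(x_loo, _slice_geometry(s), psf)
            m = project_mask_to_slice(mask_hr, s)
            sim = slice_similarity(s, y_sim, m)
        except (UndefinedSimilarityError, EmptyProjectionError):
            sims[key] = float("nan")
            continue
        sims[key] = sim
        if sim >= beta:
            members.add(key)
    return InlierSet(members, sims, beta)


def _reconstruction_grid(stacks_aligned: list[Stack], target_stack: Stack,
                         config: SRRConfig) -> ImageGrid3D:
    """Isotropic grid oriented by the target stack, covering the union of the
    aligned stack masks extended by the configured margin (10 mm default)."""
    s0 = target_stack.slices[0]
    normal = np.cross(s0.transform.rotation[:, 0], s0.transform.rotation[:, 1])
    D = np.column_stack([s0.transform.rotation[:, 0],
                         s0.transform.rotation[:, 1], normal])
    pts = []
    for st in stacks_aligned:
        for s in st.slices:
            if s.mask.any():
                w = s.pixel_world_coords()[s.mask.ravel()]
                pts.append(w)
    if not pts:
        raise NoBrainFoundError("no masked pixels to define the grid")
    P = np.concatenate(pts) @ D  # coordinates in the target-stack frame
    lo = P.min(axis=0) - config.grid_margin_mm
    hi = P.max(axis=0) + config.grid_margin_mm
    sp = config.recon_spacing
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / sp)) + 1 for i in range(3))
    origin = D @ lo
    return ImageGrid3D(shape, (sp, sp, sp), tuple(origin), D)


def reconstruct_subject_space(stacks: list[Stack], config: SRRConfig,
                              psf_factory=make_psf,
                              grid: ImageGrid3D | None = None,
                              n4_hook=None) -> ReconstructionResult:
    """Run the full two-step iterative SVR / outlier-robust SRR pipeline.

    ``psf_factory(in_plane_spacing, thickness)`` builds the PSF; ``n4_hook``
    is an optional callable applied to each stack before processing (external
    bias-field correction interface; no-op by default).
    """
    if not stacks:
        raise ValueError("need at least one stack")
    if n4_hook is not None:
        stacks = [n4_hook(st) for st in stacks]

    target_id = select_target_stack(stacks)
    target_stack = next(st for st in stacks if st.stack_id == target_id)

    # volume-to-volume alignment of all other stacks to the target
    tvol, tmask = stack_to_volume(target_stack)
    aligned: list[Stack] = []
    for st in stacks:
        if st.stack_id == target_id:
            aligned.append(st)
            continue
        svol, smask = stack_to_volume(st)
        try:
            T = volume_to_volume_register(svol, tvol, smask, tmask)
        except RegistrationFailureError:
            log.warning("v2v registration failed for stack %s; keeping pose",
                        st.stack_id)
            aligned.append(st)
            continue
        Tinv = T.inverse()  # stack world -> target world
        moved = [s.with_transform(compose(Tinv, s.transform)) for s in st.slices]
        aligned.append(Stack(moved, st.interleave, st.source_path))

    # intensity correction against the target stack
    corrected = []
    for st in aligned:
        if st.stack_id == target_id:
            corrected.append(st)
        else:
            corrected.append(intensity_correct(st, target_stack))
    stacks = corrected

    if psf_factory is make_psf:
        psf = make_psf(stacks[0].in_plane_spacing, stacks[0].thickness,
                       truncation_radius=config.psf_truncation_radius,
                       in_plane_fwhm_factor=config.psf_in_plane_fwhm_factor)
    else:
        psf = psf_factory(stacks[0].in_plane_spacing, stacks[0].thickness)

    if grid is None:
        grid = _reconstruction_grid(stacks, target_stack, config)

    all_slices: list[Slice2D] = [s for st in stacks for s in st.slices]
    x = sda_reconstruct(all_slices, grid, sigma=config.sda_sigma)
    mask_hr = sda_mask(all_slices, grid, sigma=config.sda_sigma,
                       threshold=config.mask_threshold)

    transforms = {s.key: s.transform for s in all_slices}
    history: list[InlierSet] = []
    for cycle, beta in enumerate(config.beta_schedule):
        # SVR: re-estimate every slice pose against the current iterate.
        # Cycle 1 registers translation only: against the blurry SDA
        # initialization the rotational NCC valley is too shallow to be
        # trusted; rotations are refined against the sharper SRR iterates.
        updated = []
        for s in all_slices:
            try:
                T = slice_to_volume_register(s, x, mask_hr, psf,
                                             init=transforms[s.key],
                                             translation_only=(cycle == 0))
            except RegistrationFailureError:
                T = transforms[s.key]
                log.info("SVR failed for slice %s; keeping previous pose", s.key)
            transforms[s.key] = T
            updated.append(s.with_transform(T))
        all_slices = updated

        if cycle == 0:
            inliers_set = _select_inliers_loo_sda(
                all_slices, grid, config.sda_sigma, mask_hr, psf, beta)
        else:
            inliers_set = select_inliers(all_slices, x, mask_hr, psf, beta)
        history.append(inliers_set)
        inliers = [s for s in all_slices if inliers_set.is_inlier(s.key)]
        x = solve_srr(inliers, grid, psf, alpha=config.alpha,
                      lsq_max_iter=config.lsq_max_iter, lsq_tol=config.lsq_tol)
        mask_hr = sda_mask(inliers, grid, sigma=config.sda_sigma,
                           threshold=config.mask_threshold)
        log.info("cycle %d (beta=%.2f): %d/%d inliers", cycle + 1, beta,
                 len(inliers), len(all_slices))

    for s in all_slices:
        s.inlier = (not history) or history[-1].is_inlier(s.key)
    return ReconstructionResult(x, mask_hr, transforms, history, target_id,
                                all_slices, config, psf)
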