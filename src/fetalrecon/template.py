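"""Template-space alignment: brain-volume-matched template selection,
principal-brain-axes (PBA) initialization over the four right-handed
eigenvector sign permutations, NMI-based candidate selection after rigid
refinement, and a final SRR on the template grid.

Directly registering a pathological subject reconstruction to a normal-brain
template easily falls into local minima; aligning the principal axes of the
binary brain masks first, and trying all four right-handed sign choices of
the two leading eigenvectors, makes the rigid refinement robust to large
pose and morphology differences.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (AlignmentFailureError, AmbiguousAxesWarning,
                     NoTemplateError, RegistrationFailureError,
                     UndefinedSimilarityError)
from .geometry import (ImageGrid3D, MaskVolume, RigidTransform, Volume3D,
                       compose, resample, load_volume, save_volume)
from .motion import ReconstructionResult
from .registration import nmi, register_volumes
from .srr import SRRConfig, solve_srr

__all__ = ["TemplateEntry", "select_template", "pba_candidates",
           "align_to_template", "reconstruct_template_space",
           "load_atlas", "save_atlas"]


@dataclass
class TemplateEntry:
    volume: Volume3D
    mask: MaskVolume
    brain_volume: float
    label: str

    def __post_init__(self):
        bv = self.mask.brain_volume_mm3()
        if bv > 0 and abs(bv - self.brain_volume) > 1e-6 * max(bv, 1.0):
            raise ValueError(
                f"declared brain volume {self.brain_volume} inconsistent with "
                f"mask volume {bv}")


def select_template(subject_mask: MaskVolume,
                    atlas: list[TemplateEntry]) -> TemplateEntry:
    """Atlas entry with brain volume nearest the subject's; ties break toward
    the lower label."""
    if not atlas:
        raise NoTemplateError("empty template atlas")
    sv = subject_mask.brain_volume_mm3()
    order = sorted(atlas, key=lambda e: (abs(e.brain_volume - sv), e.label))
    return order[0]


def _mask_pca(mask: MaskVolume):
    """Centroid (world mm) and principal axes (columns, descending variance)
    of the binary mask voxel point cloud."""
    pts = np.argwhere(mask.as_bool())
    if len(pts) < 4:
        raise ValueError("mask needs >= 4 positive voxels")
    w = mask.grid.index_to_world(pts)
    c = w.mean(axis=0)
    cov = np.cov((w - c).T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return c, evecs[:, order], evals[order]


def pba_candidates(subject_mask: MaskVolume,
                   template_mask: MaskVolume) -> list[RigidTransform]:
    """Four rigid transforms (template world -> subject world) aligning the
    principal brain axes of the two masks.

    The four candidates are the sign combinations of the first two subject
    eigenvectors that keep the basis right-handed (the third axis is the
    cross product). A near-isotropic eigenvalue spectrum triggers an
    ``AmbiguousAxesWarning``; candidates are still returned.
    """
    cs, Vs, es = _mask_pca(subject_mask)
    ct, Vt, et = _mask_pca(template_mask)
    for ev in (es, et):
        r = np.sqrt(np.maximum(ev, 1e-30))
        if r[0] / r[1] < 1.05 or r[1] / r[2] < 1.05:
            warnings.warn("principal axes nearly isotropic; PBA initialization "
                          "is ill-determined", AmbiguousAxesWarning)
            break
    cands = []
    for s1, s2 in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        a1, a2 = s1 * Vs[:, 0], s2 * Vs[:, 1]
        Bs = np.column_stack([a1, a2, np.cross(a1, a2)])
        b1, b2 = Vt[:, 0], Vt[:, 1]
        Bt = np.column_stack([b1, b2, np.cross(b1, b2)])
        R = Bs @ Bt.T  # template frame -> subject frame
        cands.append(RigidTransform(R, cs - R @ ct))
    return cands


def align_to_template(srr: Volume3D, mask: MaskVolume, template: TemplateEntry,
                      return_diagnostics: bool = False, **reg_kw):
    """Refine all four PBA candidates by masked rigid registration and return
    the one with maximal NMI between the warped reconstruction and the
    template. The transform maps template world points into subject world
    (resampling convention: ``resample(srr, template.grid, T)`` overlays the
    template)."""
    best = None
    diags = []
    for i, cand in enumerate(pba_candidates(mask, template.mask)):
        try:
            T = register_volumes(srr, template.volume,
                                 moving_mask=mask, fixed_mask=template.mask,
                                 init=cand, **reg_kw)
            warped = resample(srr, template.volume.grid, T, "linear")
            tm = template.mask.as_bool()
            score = nmi(template.volume.values[tm], warped.values[tm])
        except (RegistrationFailureError, UndefinedSimilarityError):
            diags.append((i, None, None))
            continue
        diags.append((i, T, score))
        if best is None or score > best[1]:
            best = (T, score)
    if best is None:
        raise AlignmentFailureError(
            "all PBA-initialized refinements failed; manual initialization "
            "is the documented recovery")
    if return_diagnostics:
        return best[0], diags
    return best[0]


def reconstruct_template_space(result: ReconstructionResult,
                               transform: RigidTransform,
                               template_grid: ImageGrid3D,
                               config: SRRConfig | None = None) -> Volume3D:
    """Final SRR on the template grid from the motion-corrected inlier slices.

    ``transform`` maps template world -> subject world (the output of
    :func:`align_to_template`). Slice poses are composed with its inverse so
    the slices live in template space, and one robust least-squares solve is
    run on the template grid — the subject-space volume itself is never
    resampled, avoiding interpolation losses.
    """
    config = result.config if config is None else config
    Tinv = transform.inverse()  # subject world -> template world
    inliers = [s.with_transform(compose(Tinv, s.transform))
               for s in result.final_inliers()]
    return solve_srr(inliers, template_grid, result.psf, alpha=config.alpha,
                     lsq_max_iter=config.lsq_max_iter, lsq_tol=config.lsq_tol)


# ---------------------------------------------------------------------------
# atlas directory layout: <dir>/<label>.nii.gz + <label>_mask.nii.gz + manifest
# ---------------------------------------------------------------------------


def save_atlas(entries: list[TemplateEntry], directory: str) -> None:
    os.makedirs(directory, exist_ok=True)
    manifest = []
    for e in entries:
        save_volume(e.volume, os.path.join(directory, f"{e.label}.nii.gz"))
        save_volume(e.mask, os.path.join(directory, f"{e.label}_mask.nii.gz"))
        manifest.append({"label": e.label, "brain_volume": e.brain_volume})
    with open(os.path.join(directory, "manifest.json"), "w") as f:
        json.dump(manifest, f, indent=2)


def load_atlas(directory: str) -> list[TemplateEntry]:
    with open(os.path.join(directory, "manifest.json")) as f:
        manifest = json.load(f)
    entries = []
    for rec in manifest:
        vol = load_volume(os.path.join(directory, f"{rec['label']}.nii.gz"))
        mvol = load_volume(os.path.join(directory, f"{rec['label']}_mask.nii.gz"))
        mask = MaskVolume((mvol.values > 0.5).astype(float), mvol.grid)
        entries.append(TemplateEntry(vol, mask, rec["brain_volume"], rec["label"]))
    return entries
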