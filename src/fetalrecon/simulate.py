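"""Synthetic ground-truth generator.

Emulates the statistical structure of interleaved multi-orientation fetal
MRI at desk scale: a smooth asymmetric nested-ellipsoid phantom with an
elongated "brain" mask, interleaved slice acquisition in several
orientations, per-slice rigid motion that is a smooth random walk within
each temporally contiguous sub-stack with independent jumps between
sub-stacks, artifact-corrupted outlier slices (intensity banding, in-plane
blur, signal dropout), additive Gaussian observation noise, and a per-stack
linear intensity distortion a*I + b.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .acquisition import PSFSpec, SliceGeometry, forward_project, make_psf
from .geometry import (ImageGrid3D, MaskVolume, RigidTransform, Slice2D,
                       Stack, Volume3D, compose, save_volume)

__all__ = ["PhantomSpec", "MotionSpec", "ArtifactSpec", "make_phantom",
           "simulate_acquisition", "default_orientations", "GroundTruth",
           "write_simulation"]


@dataclass(frozen=True)
class PhantomSpec:
    """Structured 3D phantom: nested smooth ellipsoids inside an elongated
    brain-shaped mask with distinct principal axes."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: float = 1.5
    seed: int = 0
    feature_scales: tuple[float, ...] = (6.0, 12.0)  # mm radii of internal texture

    # half-axes of the brain ellipsoid as fractions of the half field of view;
    # pairwise distinct so principal-axis estimation is well posed
    mask_semiaxes: tuple[float, float, float] = (0.62, 0.48, 0.36)


@dataclass(frozen=True)
class MotionSpec:
    """Per-slice rigid motion: within-sub-stack random walk + inter-sub-stack
    jumps (interleaved acquisition)."""

    interleave: int = 2
    max_rotation: float = 5.0       # degrees, bound on any slice's rotation params
    max_translation: float = 3.0    # mm
    walk_step_rotation: float = 0.5  # degrees per slice within a sub-stack
    walk_step_translation: float = 0.3  # mm per slice
    jump_rotation: float = 3.0      # degrees between consecutive sub-stacks
    jump_translation: float = 2.0   # mm between consecutive sub-stacks
    seed: int = 0

    def __post_init__(self):
        if min(self.max_rotation, self.max_translation,
               self.walk_step_rotation, self.walk_step_translation,
               self.jump_rotation, self.jump_translation) < 0:
            raise ValueError("motion bounds must be >= 0")
        if self.interleave < 1:
            raise ValueError("interleave must be >= 1")


@dataclass(frozen=True)
class ArtifactSpec:
    """Outlier-slice corruption model (magnitudes calibrated so corrupted
    slices fall well below an NCC of 0.8 against their clean counterparts)."""

    outlier_fraction: float = 0.1
    kinds: tuple[str, ...] = ("intensity_band", "blur", "dropout")
    band_amplitude: tuple[float, float] = (1.2, 2.0)   # rel. to intensity range
    #: motion-smear (ghosting) length in pixels for the "blur" artifact
    blur_smear_px: tuple[float, float] = (12.0, 18.0)
    dropout_fraction: tuple[float, float] = (0.6, 0.9)
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.outlier_fraction <= 1:
            raise ValueError("outlier_fraction must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Per-slice truth of a simulated acquisition."""

    transforms: dict[tuple[str, int], RigidTransform]
    outliers: set[tuple[str, int]]
    intensity_scales: dict[str, tuple[float, float]]
    clean_pixels: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)


def make_phantom(spec: PhantomSpec = PhantomSpec()) -> tuple[Volume3D, MaskVolume]:
    """Smooth, asymmetric nested-ellipsoid phantom with intensities in [0, 1]
    and an elongated single-component brain mask."""
    rng = np.random.default_rng(spec.seed)
    n = np.asarray(spec.shape)
    grid = ImageGrid3D(tuple(spec.shape), (spec.spacing,) * 3)
    c = (n - 1) / 2.0
    idx = np.indices(spec.shape).astype(float)
    half_mm = (n - 1) / 2.0 * spec.spacing
    ax = np.asarray(spec.mask_semiaxes) * half_mm
    u = [(idx[i] - c[i]) * spec.spacing / ax[i] for i in range(3)]
    r2 = u[0] ** 2 + u[1] ** 2 + u[2] ** 2
    mask = r2 <= 1.0

    # asymmetric smooth base: bright cortex-like shell + interior gradient
    vol = np.zeros(spec.shape)
    vol[mask] = 0.35 + 0.45 * (1.0 - r2[mask])
    shell = (r2 <= 1.0) & (r2 >= 0.72)
    vol[shell] += 0.25
    # off-center nested ellipsoids ("ventricle"-like dark and bright blobs)
    for k, scale in enumerate(spec.feature_scales):
        off = rng.uniform(-0.25, 0.25, size=3)
        amp = (-0.3) ** (k + 1) * (1.0 + 0.5 * rng.random())
        d2 = sum(((idx[i] - c[i]) * spec.spacing / scale - off[i] * 4) ** 2
                 for i in range(3))
        vol += amp * np.exp(-0.5 * d2) * mask
    vol = ndimage.gaussian_filter(vol, 1.0)
    # band-limited texture (correlation length ~ 1.5 voxels) so the phantom,
    # like real anatomy, constrains through-plane slice alignment
    tex = ndimage.gaussian_filter(rng.standard_normal(spec.shape), 1.5)
    tex /= max(np.abs(tex).max(), 1e-12)
    vol += 0.25 * tex * mask
    vol *= mask
    vol = np.clip(vol, 0.0, None)
    vol /= max(vol.max(), 1e-12)
    return Volume3D(vol, grid), MaskVolume(mask.astype(float), grid)


def default_orientations() -> list[RigidTransform]:
    """Three orthogonal acquisition orientations (axial/coronal/sagittal-like)
    as rotations about the volume axes."""
    Rz = RigidTransform.from_params([0, 0, 0, 0, 0, 0])
    Rx = RigidTransform(np.array([[1.0, 0, 0], [0, 0, -1.0], [0, 1.0, 0]]),
                        np.zeros(3))
    Ry = RigidTransform(np.array([[0, 0, 1.0], [0, 1.0, 0], [-1.0, 0, 0]]),
                        np.zeros(3))
    return [Rz, Rx, Ry]


def _substack_motion(n_slices: int, motion: MotionSpec, rng) -> list[np.ndarray]:
    """Per-slice 6-parameter motion trajectories honouring the declared
    bounds exactly.

    The first sub-stack starts at a uniform draw within the global bounds;
    each subsequent sub-stack starts at the previous sub-stack's start plus
    an independent jump within the jump bounds (motion within a sub-stack is
    smooth, between sub-stacks discontinuous). All states are clipped to the
    global bounds."""
    params = [None] * n_slices
    groups = [list(range(g, n_slices, motion.interleave))
              for g in range(motion.interleave)]
    bound = np.array([motion.max_rotation] * 3 + [motion.max_translation] * 3)
    step = np.array([motion.walk_step_rotation] * 3
                    + [motion.walk_step_translation] * 3)
    jump = np.array([motion.jump_rotation] * 3 + [motion.jump_translation] * 3)
    start = rng.uniform(-bound, bound)
    for g, grp in enumerate(groups):
        if g > 0:
            start = np.clip(start + rng.uniform(-jump, jump), -bound, bound)
        cur = start.copy()
        for k in grp:
            params[k] = cur.copy()
            cur = np.clip(cur + rng.uniform(-step, step), -bound, bound)
    return params


def _corrupt(pixels: np.ndarray, mask: np.ndarray, kind: str,
             art: ArtifactSpec, rng) -> np.ndarray:
    """Corrupt a slice; band/dropout artifacts are centred on the masked
    rows so the corruption hits the anatomy, not just background."""
    rngv = np.ptp(pixels) or 1.0
    rows = np.flatnonzero(mask.any(axis=1))
    r_lo, r_hi = (rows[0], rows[-1]) if rows.size else (0, pixels.shape[0] - 1)
    if kind == "intensity_band":
        amp = rng.uniform(*art.band_amplitude) * rngv
        width = max((r_hi - r_lo + 1) * 2 // 3, 1)
        i0 = rng.integers(r_lo, max(r_hi - width + 1, r_lo + 1))
        out = pixels.copy()
        out[i0:i0 + width] += amp * np.sin(
            np.linspace(0, 3 * np.pi, out[i0:i0 + width].shape[0]))[:, None]
        return out
    if kind == "blur":
        # directional motion smear plus a displaced ghost copy
        L = int(round(rng.uniform(*art.blur_smear_px)))
        axis = int(rng.integers(2))
        shifts = np.linspace(-L, L, 7).round().astype(int)
        smear = np.mean([np.roll(pixels, sh, axis=axis) for sh in shifts], axis=0)
        ghost = np.roll(pixels, 2 * L, axis=axis)
        return 0.5 * smear + 0.5 * ghost
    if kind == "dropout":
        frac = rng.uniform(*art.dropout_fraction)
        width = max(int((r_hi - r_lo + 1) * frac), 1)
        i0 = rng.integers(r_lo, max(r_hi - width + 1, r_lo + 1))
        out = pixels.copy()
        out[i0:i0 + width] *= rng.uniform(0.0, 0.15)
        return out
    raise ValueError(f"unknown artifact kind {kind!r}")


def simulate_acquisition(
    phantom: Volume3D,
    mask: MaskVolume,
    orientations: list[RigidTransform] | None = None,
    slice_shape: tuple[int, int] = (44, 44),
    in_plane_spacing: float = 1.5,
    thickness: float = 3.0,
    n_slices: int | None = None,
    motion: MotionSpec = MotionSpec(),
    artifacts: ArtifactSpec = ArtifactSpec(),
    noise_sd: float = 0.01,
    intensity_scales: list[tuple[float, float]] | None = None,
    psf: PSFSpec | None = None,
    seed: int = 0,
) -> tuple[list[Stack], GroundTruth]:
    """Acquire interleaved low-resolution stacks from the phantom.

    Every slice is the oriented-Gaussian forward projection of the phantom
    under its true (motion-perturbed) pose plus Gaussian noise; outlier
    slices are additionally corrupted and labelled; slice masks are the
    projected phantom mask; each stack is finally distorted by its linear
    intensity scaling (a, b). ``noise_sd`` is relative to the phantom
    intensity range.
    """
    orientations = default_orientations() if orientations is None else orientations
    if not orientations:
        raise ValueError("need at least one orientation")
    rng = np.random.default_rng(seed)
    psf = make_psf(in_plane_spacing, thickness) if psf is None else psf

    # center the slice lattice on the phantom center
    center = phantom.grid.index_to_world((np.asarray(phantom.grid.shape) - 1) / 2.0)
    if n_slices is None:
        # cover the masked anatomy plus a 10 mm margin in any orientation
        idxm = np.argwhere(mask.as_bool())
        ext = (idxm.max(axis=0) - idxm.min(axis=0) + 1) * np.asarray(mask.grid.spacing)
        n_slices = int(np.ceil((ext.max() + 10.0)
                               / thickness)) | 1

    stacks = []
    gt = GroundTruth({}, set(), {})
    amp = np.ptp(phantom.values)
    for j, base in enumerate(orientations):
        sid = f"stack{j}"
        mot = _substack_motion(n_slices, motion, rng)
        a, b = (intensity_scales[j] if intensity_scales is not None
                else (rng.uniform(0.8, 1.2), rng.uniform(-0.05, 0.05) * amp))
        gt.intensity_scales[sid] = (float(a), float(b))
        n_out = 0
        slices = []
        for k in range(n_slices):
            # nominal slice pose: slice plane k stacked along the base normal
            offset = np.array([
                -(slice_shape[0] - 1) / 2.0 * in_plane_spacing,
                -(slice_shape[1] - 1) / 2.0 * in_plane_spacing,
                (k - (n_slices - 1) / 2.0) * thickness,
            ])
            nominal = RigidTransform(base.rotation,
                                     base.rotation @ offset + center)
            # motion rotations act about the anatomy center, so the declared
            # parameter bounds are honoured without lever-arm amplification
            true = compose(RigidTransform.from_params(mot[k], center=center),
                           nominal) \
                if motion.max_rotation or motion.max_translation else nominal
            geom = SliceGeometry(slice_shape, in_plane_spacing, thickness, true)
            clean = forward_project(phantom, geom, psf)
            mvals = forward_project(Volume3D(mask.values, mask.grid), geom, psf)
            smask = mvals >= 0.5
            pix = clean.copy()
            is_out = rng.random() < artifacts.outlier_fraction
            if is_out:
                kind = artifacts.kinds[rng.integers(len(artifacts.kinds))]
                pix = _corrupt(pix, smask, kind, artifacts, rng)
                gt.outliers.add((sid, k))
                n_out += 1
            if noise_sd > 0:
                pix = pix + rng.normal(0.0, noise_sd * amp, size=pix.shape)
            pix = a * pix + b
            gt.clean_pixels[(sid, k)] = clean
            gt.transforms[(sid, k)] = true
            slices.append(Slice2D(pix, in_plane_spacing, thickness, nominal,
                                  smask, slice_index=k, stack_id=sid))
        stacks.append(Stack(slices, interleave=motion.interleave))
    return stacks, gt


def write_simulation(stacks: list[Stack], gt: GroundTruth, directory: str) -> None:
    """Write simulated stacks, masks and the ground-truth record to disk."""
    os.makedirs(directory, exist_ok=True)
    from .motion import stack_to_volume
    for st in stacks:
        vol, m = stack_to_volume(st)
        save_volume(vol, os.path.join(directory, f"{st.stack_id}.nii.gz"))
        save_volume(m, os.path.join(directory, f"{st.stack_id}_mask.nii.gz"))
    rec = {
        "outliers": sorted([list(k) for k in gt.outliers]),
        "intensity_scales": {k: list(v) for k, v in gt.intensity_scales.items()},
        "transforms": {f"{k[0]}:{k[1]}": v.to_params().tolist()
                       for k, v in gt.transforms.items()},
    }
    with open(os.path.join(directory, "ground_truth.json"), "w") as f:
        json.dump(rec, f, indent=2)
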