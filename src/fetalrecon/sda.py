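"""Scattered data approximation by discrete Nadaraya-Watson kernel regression.

Irregularly posed slice pixels are gridded onto a regular 3D target by a
nearest-neighbor splat of intensity*weight and of the weights themselves,
followed by Gaussian blurring of both accumulators; the ratio is the kernel
regression estimate. This builds the initial high-resolution volume and the
high-resolution brain-mask volumes from (motion-corrected) slices.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import EmptyInputError
from .geometry import ImageGrid3D, MaskVolume, Slice2D, Volume3D

__all__ = ["sda_reconstruct", "sda_mask", "sda_loo_reconstructions"]

#: relative denominator floor: voxels whose blurred weight is below
#: ``DENOM_FLOOR * max_weight`` are set to 0 (no coverage).
DENOM_FLOOR = 1e-8


def _splat(slices, target: ImageGrid3D, values_from, masked: bool):
    num = np.zeros(target.shape)
    den = np.zeros(target.shape)
    any_in = False
    for s in slices:
        vals = values_from(s).ravel()
        keep = s.mask.ravel() if masked else np.ones(vals.size, dtype=bool)
        idx = target.world_to_index(s.pixel_world_coords())
        # nearest-neighbor splat; .5 ties round toward the lower index
        nn = np.ceil(idx - 0.5).astype(int)
        inb = keep.copy()
        for ax, n in enumerate(target.shape):
            inb &= (nn[:, ax] >= 0) & (nn[:, ax] < n)
        if not inb.any():
            continue
        any_in = True
        flat = np.ravel_multi_index(tuple(nn[inb].T), target.shape)
        np.add.at(num.ravel(), flat, vals[inb])
        np.add.at(den.ravel(), flat, 1.0)
    if not any_in:
        raise EmptyInputError("no slice pixel falls inside the target grid")
    return num, den


def sda_reconstruct(slices: list[Slice2D], target: ImageGrid3D,
                    sigma: float = 1.0, sigma_in_mm: bool = False,
                    masked: bool = True) -> Volume3D:
    """Nadaraya-Watson gridding of slice intensities onto ``target``.

    ``sigma`` is the Gaussian smoothing standard deviation, by default in
    target-grid voxels (set ``sigma_in_mm`` to interpret it in mm). With
    ``masked`` (default) only pixels where the slice mask is 1 contribute.
    """
    if not slices:
        raise EmptyInputError("empty slice list")
    num, den = _splat(slices, target, lambda s: s.pixels, masked)
    sig = (np.asarray([sigma / sp for sp in target.spacing])
           if sigma_in_mm else np.full(3, float(sigma)))
    num = ndimage.gaussian_filter(num, sig, mode="constant")
    den = ndimage.gaussian_filter(den, sig, mode="constant")
    out = np.zeros(target.shape)
    ok = den > DENOM_FLOOR * den.max()
    out[ok] = num[ok] / den[ok]
    return Volume3D(out, target)


def sda_loo_reconstructions(slices: list[Slice2D], target: ImageGrid3D,
                            sigma: float = 1.0, masked: bool = True):
    """Leave-one-out SDA volumes: for each slice, the Nadaraya-Watson
    gridding of all *other* slices.

    Yields ``(key, Volume3D)`` pairs. Exploits linearity of the splat and
    the Gaussian blur: the per-slice contribution is subtracted from the
    global accumulators before blurring. Used to score a slice against an
    initialization that does not contain its own vote.
    """
    if not slices:
        raise EmptyInputError("empty slice list")
    sig = np.full(3, float(sigma))
    num_tot = np.zeros(target.shape)
    den_tot = np.zeros(target.shape)
    per_slice = []
    any_in = False
    for s in slices:
        try:
            num_k, den_k = _splat([s], target, lambda q: q.pixels, masked)
            any_in = True
        except EmptyInputError:
            num_k = np.zeros(target.shape)
            den_k = np.zeros(target.shape)
        num_tot += num_k
        den_tot += den_k
        per_slice.append((s.key, num_k, den_k))
    if not any_in:
        raise EmptyInputError("no slice pixel falls inside the target grid")
    for key, num_k, den_k in per_slice:
        num = ndimage.gaussian_filter(num_tot - num_k, sig, mode="constant")
        den = ndimage.gaussian_filter(den_tot - den_k, sig, mode="constant")
        out = np.zeros(target.shape)
        mx = den.max()
        if mx > 0:
            ok = den > DENOM_FLOOR * mx
            out[ok] = num[ok] / den[ok]
        yield key, Volume3D(out, target)


def sda_mask(slice_masks: list[Slice2D], target: ImageGrid3D,
             sigma: float = 1.0, threshold: float = 0.5,
             sigma_in_mm: bool = False) -> MaskVolume:
    """SDA on binary slice-mask values, thresholded to a hard mask volume."""
    if not slice_masks:
        raise EmptyInputError("empty slice list")
    num, den = _splat(slice_masks, target,
                      lambda s: s.mask.astype(float), masked=False)
    sig = (np.asarray([sigma / sp for sp in target.spacing])
           if sigma_in_mm else np.full(3, float(sigma)))
    num = ndimage.gaussian_filter(num, sig, mode="constant")
    den = ndimage.gaussian_filter(den, sig, mode="constant")
    soft = np.zeros(target.shape)
    ok = den > DENOM_FLOOR * den.max()
    soft[ok] = num[ok] / den[ok]
    return MaskVolume((np.clip(soft, 0, 1) >= threshold).astype(float), target,
                      binary=True)
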