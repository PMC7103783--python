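"""Evaluation metrics: bounding-box IoU and centroid distance, Dice and
Hausdorff on masks, and the masked slice-similarity suite (NCC, NMI, SSIM,
PSNR, RMSE, MAE)."""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree
from skimage.metrics import structural_similarity

from .errors import UndefinedMetricError, UndefinedSimilarityError
from .geometry import MaskVolume, Slice2D, Volume3D
from .registration import nmi as _nmi
from .srr import ncc as _ncc

__all__ = ["iou_3d", "centroid_distance", "dice_score", "hausdorff",
           "similarity_suite", "masked_psnr", "gauge_align", "motion_errors"]

#: PSNR is reported as this documented maximum when the error vanishes.
PSNR_CAP_DB = 160.0


def iou_3d(a, b) -> float:
    """Intersection-over-union of two axis-aligned world-space boxes."""
    lo = np.maximum(a.lower_mm, b.lower_mm)
    hi = np.minimum(a.upper_mm, b.upper_mm)
    inter = float(np.prod(np.maximum(hi - lo, 0.0)))
    union = a.volume_mm3() + b.volume_mm3() - inter
    return inter / union if union > 0 else 0.0


def centroid_distance(a, b) -> float:
    """Distance between box centers in mm."""
    return float(np.linalg.norm(a.center_mm - b.center_mm))


def dice_score(a: MaskVolume, b: MaskVolume) -> float:
    """Hard-mask overlap 2|A n B| / (|A| + |B|)."""
    if a.grid.shape != b.grid.shape:
        raise ValueError("masks must share a grid")
    am, bm = a.as_bool(), b.as_bool()
    s = am.sum() + bm.sum()
    if s == 0:
        raise UndefinedMetricError("both masks empty")
    return float(2.0 * (am & bm).sum() / s)


def hausdorff(a: MaskVolume, b: MaskVolume) -> float:
    """Symmetric Hausdorff distance between mask voxel point sets, in mm."""
    if a.grid.shape != b.grid.shape:
        raise ValueError("masks must share a grid")
    pa = a.grid.index_to_world(np.argwhere(a.as_bool()))
    pb = b.grid.index_to_world(np.argwhere(b.as_bool()))
    if len(pa) == 0 or len(pb) == 0:
        raise UndefinedMetricError("empty mask")
    d_ab = cKDTree(pb).query(pa)[0].max()
    d_ba = cKDTree(pa).query(pb)[0].max()
    return float(max(d_ab, d_ba))


def _psnr(err: np.ndarray, dynamic_range: float) -> float:
    rmse = float(np.sqrt(np.mean(err**2)))
    if dynamic_range <= 0:
        raise UndefinedMetricError("zero dynamic range")
    if rmse == 0:
        return PSNR_CAP_DB
    return float(min(20.0 * np.log10(dynamic_range / rmse), PSNR_CAP_DB))


def masked_psnr(x: Volume3D, ref: Volume3D, mask: MaskVolume) -> float:
    """PSNR of ``x`` against ``ref`` over the mask, using the masked
    reference dynamic range."""
    m = mask.as_bool()
    if not m.any():
        raise UndefinedMetricError("empty mask")
    return _psnr(x.values[m] - ref.values[m], float(np.ptp(ref.values[m])))


def gauge_align(est: dict, true: dict, slices) -> "RigidTransform":
    """Best global rigid transform mapping estimated slice poses onto true
    poses (Kabsch on per-slice anchor points).

    The subject-space frame of a reconstruction is arbitrary (it inherits
    the target stack's average motion), so recovered slice poses are only
    comparable to simulated ground truth modulo one global rigid transform;
    this estimates that gauge.
    """
    from .geometry import RigidTransform
    P, Q = [], []
    anchors = (np.zeros(3), np.array([20.0, 0, 0]), np.array([0, 20.0, 0]),
               np.array([0, 0, 20.0]))
    for s in slices:
        if s.key not in est or s.key not in true:
            continue
        c = np.array([(s.pixels.shape[0] - 1) / 2 * s.in_plane_spacing,
                      (s.pixels.shape[1] - 1) / 2 * s.in_plane_spacing, 0.0])
        for d in anchors:
            P.append(est[s.key].apply(c + d))
            Q.append(true[s.key].apply(c + d))
    P, Q = np.asarray(P), np.asarray(Q)
    if len(P) < 3:
        raise UndefinedMetricError("need at least one slice to estimate gauge")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, cq - R @ cp)


def motion_errors(est: dict, true: dict, slices) -> dict[str, np.ndarray]:
    """Per-slice pose recovery errors after global gauge alignment.

    Returns arrays of the geodesic rotation error (degrees), the absolute
    per-parameter rotation errors (degrees; Z-Y-X Euler convention, the
    convention slice motion is usually reported in), and the displacement of
    the slice center (mm).
    """
    from scipy.spatial.transform import Rotation
    from .geometry import compose
    G = gauge_align(est, true, slices)
    geo, par, tr = [], [], []
    for s in slices:
        T = compose(G, est[s.key])
        D = compose(T, true[s.key].inverse())
        geo.append(D.rotation_angle_deg())
        par.extend(np.abs(Rotation.from_matrix(D.rotation)
                          .as_euler("ZYX", degrees=True)))
        c = np.array([(s.pixels.shape[0] - 1) / 2 * s.in_plane_spacing,
                      (s.pixels.shape[1] - 1) / 2 * s.in_plane_spacing, 0.0])
        tr.append(np.linalg.norm(T.apply(c) - true[s.key].apply(c)))
    return {"rotation_geodesic_deg": np.asarray(geo),
            "rotation_param_deg": np.asarray(par),
            "translation_mm": np.asarray(tr),
            "gauge": G}


def similarity_suite(y: Slice2D, y_sim: np.ndarray,
                     mask: np.ndarray | None = None) -> dict[str, float]:
    """All six slice-similarity measures over masked pixels.

    Degenerate inputs yield NaN entries for the undefined measures (NCC, NMI
    and SSIM need nonconstant intensities) rather than raising.
    """
    y_sim = np.asarray(y_sim, dtype=float)
    m = y.mask if mask is None else np.asarray(mask).astype(bool)
    ya = y.pixels[m]
    yb = y_sim[m]
    if ya.size == 0:
        raise UndefinedMetricError("empty mask")
    err = ya - yb
    out = {
        "RMSE": float(np.sqrt(np.mean(err**2))),
        "MAE": float(np.mean(np.abs(err))),
    }
    rng = float(np.ptp(ya))
    out["PSNR"] = _psnr(err, rng) if rng > 0 else float("nan")
    for name, fn in (("NCC", _ncc), ("NMI", _nmi)):
        try:
            out[name] = fn(ya, yb)
        except UndefinedSimilarityError:
            out[name] = float("nan")
    # SSIM on the bounding crop of the mask, standard constants, 7x7 window
    ii, jj = np.nonzero(m)
    crop = (slice(ii.min(), ii.max() + 1), slice(jj.min(), jj.max() + 1))
    ca, cb = y.pixels[crop], y_sim[crop]
    dr = float(max(np.ptp(ca), np.ptp(cb)))
    if dr == 0 or min(ca.shape) < 7:
        out["SSIM"] = float("nan") if dr == 0 else float(
            structural_similarity(ca, cb, data_range=dr,
                                  win_size=min(ca.shape) // 2 * 2 + 1))
    else:
        out["SSIM"] = float(structural_similarity(ca, cb, data_range=dr,
                                                  win_size=7))
    return out
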