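"""Image-grid geometry, rigid transforms, and the slice/stack/volume model.

Conventions
-----------
* World coordinates are millimetres; the NIfTI affine is used as-is.
* Voxel indexing is 0-based with voxel centers at integer indices, so the
  voxel-to-world map is ``world = origin + direction @ (spacing * index)``.
* Rotations are parameterized for optimizers as three intrinsic Z-Y-X Euler
  angles in degrees followed by three translations in mm.
* ``resample`` follows the resampling-transform convention: the transform
  maps points of the *target* grid (fixed space) into the *source* volume
  (moving space), i.e. ``out(i) = vol(T(world_target(i)))``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .errors import InvalidGeometryError

__all__ = [
    "ImageGrid3D",
    "RigidTransform",
    "Slice2D",
    "Stack",
    "Volume3D",
    "MaskVolume",
    "compose",
    "resample",
    "load_volume",
    "save_volume",
    "load_stack",
]


# ---------------------------------------------------------------------------
# grids and transforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageGrid3D:
    """A regular 3D sampling grid: shape, spacing (mm), origin (mm), direction."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))
        D = np.asarray(self.direction, dtype=float)
        object.__setattr__(self, "direction", D)
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise InvalidGeometryError(f"invalid shape {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise InvalidGeometryError(f"spacing must be positive, got {self.spacing}")
        if D.shape != (3, 3) or not np.allclose(D @ D.T, np.eye(3), atol=1e-6):
            raise InvalidGeometryError("direction must be 3x3 orthonormal")
        if np.linalg.det(D) < 0:
            raise InvalidGeometryError("direction must be right-handed (det +1)")

    # affine maps ---------------------------------------------------------

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world affine."""
        A = np.eye(4)
        A[:3, :3] = self.direction @ np.diag(self.spacing)
        A[:3, 3] = self.origin
        return A

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return idx @ (self.direction @ np.diag(self.spacing)).T + np.asarray(self.origin)

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float) - np.asarray(self.origin)
        M = np.diag([1.0 / s for s in self.spacing]) @ self.direction.T
        return pts @ M.T

    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def world_centers(self) -> np.ndarray:
        """(N, 3) world coordinates of all voxel centers, C-order raveled."""
        idx = np.indices(self.shape).reshape(3, -1).T
        return self.index_to_world(idx)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``p -> rotation @ p + translation`` (mm)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6) or np.linalg.det(R) < 0:
            raise InvalidGeometryError("rotation must be orthonormal with det +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_params(cls, params, center=None) -> "RigidTransform":
        """(rx, ry, rz, tx, ty, tz): intrinsic Z-Y-X Euler angles in degrees + mm.

        With ``center`` the rotation acts about that world point instead of
        the origin (``p -> R (p - c) + c + t``), the natural parameterization
        for anatomy far from the world origin.
        """
        p = np.asarray(params, dtype=float).reshape(6)
        R = Rotation.from_euler("ZYX", p[:3], degrees=True).as_matrix()
        t = p[3:]
        if center is not None:
            c = np.asarray(center, dtype=float)
            t = t + c - R @ c
        return cls(R, t)

    def to_params(self) -> np.ndarray:
        ang = Rotation.from_matrix(self.rotation).as_euler("ZYX", degrees=True)
        return np.concatenate([ang, self.translation])

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    @property
    def matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def rotation_angle_deg(self) -> float:
        """Geodesic rotation magnitude in degrees."""
        return float(np.degrees(Rotation.from_matrix(self.rotation).magnitude()))


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Transform applying ``b`` then ``a``: ``compose(a, b)(p) = a(b(p))``."""
    return RigidTransform(a.rotation @ b.rotation, a.rotation @ b.translation + a.translation)


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------


@dataclass
class Volume3D:
    """A 3D scalar image with grid geometry."""

    values: np.ndarray
    grid: ImageGrid3D

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise InvalidGeometryError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise InvalidGeometryError("volume values must be finite")

    def copy(self) -> "Volume3D":
        return Volume3D(self.values.copy(), self.grid)


@dataclass
class MaskVolume:
    """A [0, 1]-valued 3D mask; ``binary`` marks a thresholded hard mask."""

    values: np.ndarray
    grid: ImageGrid3D
    binary: bool = True

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise InvalidGeometryError("mask shape mismatch with grid")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise InvalidGeometryError("mask values must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)

    def brain_volume_mm3(self) -> float:
        return float(self.values.sum() * self.grid.voxel_volume())

    def as_bool(self, threshold: float = 0.5) -> np.ndarray:
        return self.values >= threshold


@dataclass
class Slice2D:
    """A single acquired 2D slice with its rigid pose in world space.

    ``transform`` maps slice-frame points (mm; pixel (i, j) sits at
    ``(i * in_plane_spacing, j * in_plane_spacing, 0)``) into world space.
    Observation noise lives implicitly in ``pixels``.
    """

    pixels: np.ndarray
    in_plane_spacing: float
    thickness: float
    transform: RigidTransform
    mask: np.ndarray | None = None
    slice_index: int = 0
    stack_id: str = ""
    inlier: bool = True

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise InvalidGeometryError("slice pixels must be 2D")
        if self.in_plane_spacing <= 0 or self.thickness <= 0:
            raise InvalidGeometryError("spacing and thickness must be positive")
        if self.mask is None:
            self.mask = np.ones_like(self.pixels, dtype=bool)
        else:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != self.pixels.shape:
                raise InvalidGeometryError("slice mask shape must match pixels")

    @property
    def key(self) -> tuple[str, int]:
        return (self.stack_id, self.slice_index)

    def pixel_world_coords(self) -> np.ndarray:
        """(N, 3) world coordinates of all pixel centers, C-order raveled."""
        ii, jj = np.indices(self.pixels.shape)
        pts = np.stack(
            [ii.ravel() * self.in_plane_spacing, jj.ravel() * self.in_plane_spacing,
             np.zeros(ii.size)], axis=1)
        return self.transform.apply(pts)

    def with_transform(self, transform: RigidTransform) -> "Slice2D":
        return dataclasses.replace(self, transform=transform)


@dataclass
class Stack:
    """An ordered, possibly interleaved, collection of slices from one scan."""

    slices: list[Slice2D]
    interleave: int = 1
    source_path: str | None = None

    def __post_init__(self):
        if not self.slices:
            raise InvalidGeometryError("a stack needs at least one slice")
        if self.interleave < 1:
            raise InvalidGeometryError("interleave must be >= 1")
        idx = sorted(s.slice_index for s in self.slices)
        if idx != list(range(len(self.slices))):
            raise InvalidGeometryError("slice_index values must be 0..K-1 without gaps")
        sp = {(s.in_plane_spacing, s.thickness) for s in self.slices}
        if len(sp) != 1:
            raise InvalidGeometryError("all slices must share spacing and thickness")
        sid = {s.stack_id for s in self.slices}
        if len(sid) != 1:
            raise InvalidGeometryError("all slices must share stack_id")

    @property
    def stack_id(self) -> str:
        return self.slices[0].stack_id

    @property
    def in_plane_spacing(self) -> float:
        return self.slices[0].in_plane_spacing

    @property
    def thickness(self) -> float:
        return self.slices[0].thickness

    def mask_volume_mm3(self) -> float:
        """Estimated brain volume from the per-slice masks (mm^3)."""
        px = self.in_plane_spacing
        n = sum(int(s.mask.sum()) for s in self.slices)
        return float(n * px * px * self.thickness)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

_ORDER = {"nearest": 0, "linear": 1, "bspline": 3}


def resample(
    volume: Volume3D,
    target: ImageGrid3D,
    transform: RigidTransform | None = None,
    interpolation: str = "linear",
) -> Volume3D:
    """Resample ``volume`` onto ``target``; ``transform`` maps target world
    points into the source volume's world space. Out-of-extent voxels get 0.
    """
    if interpolation not in _ORDER:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if transform is None:
        transform = RigidTransform.identity()
    # identical grid + identity transform: bit-stable shortcut
    if (target.shape == volume.grid.shape
            and target.spacing == volume.grid.spacing
            and target.origin == volume.grid.origin
            and np.array_equal(target.direction, volume.grid.direction)
            and np.array_equal(transform.matrix, np.eye(4))):
        return Volume3D(volume.values.copy(), target)
    pts = target.world_centers()
    src_idx = volume.grid.world_to_index(transform.apply(pts))
    out = ndimage.map_coordinates(
        volume.values, src_idx.T, order=_ORDER[interpolation], mode="constant", cval=0.0
    )
    return Volume3D(out.reshape(target.shape), target)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def _grid_from_affine(affine: np.ndarray, shape) -> ImageGrid3D:
    A = np.asarray(affine, dtype=float)
    M = A[:3, :3]
    spacing = np.linalg.norm(M, axis=0)
    if np.any(spacing <= 0):
        raise InvalidGeometryError("degenerate NIfTI affine")
    D = M / spacing
    if np.linalg.det(D) < 0:
        # flip the first axis direction to keep a right-handed frame; the
        # spacing-signed column convention is preserved on write via affine.
        raise InvalidGeometryError(
            "left-handed NIfTI affine not supported; reorient the image first"
        )
    return ImageGrid3D(tuple(shape[:3]), tuple(spacing), tuple(A[:3, 3]), D)


def load_volume(path: str) -> Volume3D:
    img = nib.load(path)
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 3:
        data = data.reshape(data.shape[:3])
    return Volume3D(data, _grid_from_affine(img.affine, data.shape))


def save_volume(vol: Volume3D | MaskVolume, path: str) -> None:
    nib.save(nib.Nifti1Image(np.asarray(vol.values, dtype=np.float32), vol.grid.affine), path)


def load_stack(path: str, mask_path: str | None = None, interleave: int = 1,
               stack_id: str | None = None) -> Stack:
    """Read a stack from a NIfTI volume.

    The slice-select axis is taken to be the axis with the largest spacing
    (headers are often ambiguous); each slice inherits the pose implied by
    the file's affine.
    """
    img = nib.load(path)
    data = np.asarray(img.get_fdata(), dtype=float)
    grid = _grid_from_affine(img.affine, data.shape)
    mask = None
    if mask_path is not None:
        mask = np.asarray(nib.load(mask_path).get_fdata()) > 0.5
        if mask.shape != data.shape:
            raise InvalidGeometryError("stack mask shape mismatch")
    axis = int(np.argmax(grid.spacing))
    data = np.moveaxis(data, axis, 2)
    if mask is not None:
        mask = np.moveaxis(mask, axis, 2)
    in_plane = [grid.spacing[i] for i in range(3) if i != axis]
    if abs(in_plane[0] - in_plane[1]) > 1e-6:
        raise InvalidGeometryError("anisotropic in-plane spacing not supported")
    cols = [grid.direction[:, i] for i in range(3) if i != axis]
    normal = grid.direction[:, axis]
    sid = stack_id if stack_id is not None else path
    slices = []
    for k in range(data.shape[2]):
        origin = np.asarray(grid.origin) + normal * grid.spacing[axis] * k
        R = np.column_stack(cols + [normal])
        if np.linalg.det(R) < 0:
            R = np.column_stack([cols[0], cols[1], -normal])
        slices.append(
            Slice2D(
                data[:, :, k], in_plane[0], grid.spacing[axis],
                RigidTransform(R, origin),
                mask[:, :, k] if mask is not None else None,
                slice_index=k, stack_id=sid,
            )
        )
    return Stack(slices, interleave=interleave, source_path=path)
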