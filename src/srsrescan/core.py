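"""Core image and rigid-geometry types shared by every analysis stage.

Coordinate conventions
----------------------
All world coordinates are DICOM LPS patient coordinates in millimetres:
+x = patient left, +y = posterior, +z = superior.  Voxel indices are
0-based and ``(i, j, k)`` maps to ``(x, y, z)``; world positions refer to
voxel *centers*, so voxel ``(i, j, k)`` sits at
``origin + (i*dx, j*dy, k*dz)``.  Only axis-aligned grids are supported;
oblique direction cosines are rejected at the I/O layer rather than
silently reoriented.

Rotations are parameterised as roll / pitch / yaw in degrees:

* roll  — rotation about the superior-inferior axis (z),
* pitch — rotation about the left-right axis (x),
* yaw   — rotation about the anterior-posterior axis (y),

composed about fixed (extrinsic) axes as ``R = R_yaw @ R_pitch @ R_roll``
and applied about an explicit rotation center.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

__all__ = [
    "VolumeImage",
    "GridSpec",
    "RigidTransform",
    "Target",
    "compose",
    "invert",
    "recenter",
    "resample_volume",
    "transform_volume",
    "max_voxel_path",
]

# Euler sequence realising R = R_y(yaw) @ R_x(pitch) @ R_z(roll) with
# extrinsic (fixed-axis) composition: roll applied first, then pitch, then yaw.
_EULER_SEQ = "zxy"


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned sampling grid: shape, spacing (mm) and origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 2 for n in self.shape):
            raise ValueError(f"grid must be 3D with every dim >= 2, got {self.shape}")
        if any(not (s > 0) for s in self.spacing):
            raise ValueError(f"grid spacing must be strictly positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape ``(*shape, 3)``."""
        axes = [
            self.origin[d] + self.spacing[d] * np.arange(self.shape[d])
            for d in range(3)
        ]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)

    @property
    def center(self) -> np.ndarray:
        """World position of the geometric grid center (mm)."""
        return np.asarray(self.origin) + (np.asarray(self.shape) - 1) / 2.0 * np.asarray(self.spacing)


@dataclass
class VolumeImage:
    """Axis-aligned 3D scalar grid (HU, MR intensity or Gy).

    Parameters
    ----------
    voxels
        3D array indexed ``(i, j, k)`` along ``(x, y, z)``.
    spacing
        Voxel spacing ``(dx, dy, dz)`` in mm, strictly positive.
    origin
        World coordinates (mm) of the *center* of voxel ``(0, 0, 0)``.
    modality
        One of ``"CT"``, ``"MR"``, ``"DOSE"``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "CT"

    _MODALITIES = ("CT", "MR", "DOSE")

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3 or any(n < 2 for n in self.voxels.shape):
            raise ValueError(
                f"voxels must be a 3D array with every dim >= 2, got shape {self.voxels.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(not (s > 0) for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        if self.modality not in self._MODALITIES:
            raise ValueError(f"modality must be one of {self._MODALITIES}, got {self.modality!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.shape, self.spacing, self.origin)

    @property
    def center(self) -> np.ndarray:
        return self.grid.center

    def index_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (fractional) voxel indices, shape (..., 3), to world mm."""
        ijk = np.asarray(ijk, dtype=np.float64)
        return np.asarray(self.origin) + ijk * np.asarray(self.spacing)

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Map world mm positions, shape (..., 3), to fractional indices."""
        xyz = np.asarray(xyz, dtype=np.float64)
        return (xyz - np.asarray(self.origin)) / np.asarray(self.spacing)

    def sample(self, xyz: np.ndarray, order: int = 1, fill: float = 0.0) -> np.ndarray:
        """Interpolate the volume at world positions ``xyz`` (shape (..., 3))."""
        idx = self.world_to_index(xyz)
        lead_shape = idx.shape[:-1]
        coords = idx.reshape(-1, 3).T
        out = ndimage.map_coordinates(
            self.voxels, coords, order=order, mode="constant", cval=fill
        )
        return out.reshape(lead_shape) if lead_shape else out[0]

    def copy(self) -> "VolumeImage":
        return VolumeImage(self.voxels.copy(), self.spacing, self.origin, self.modality)

    def default_fill(self) -> float:
        """Out-of-field fill value: -1000 HU for CT (air), 0 for MR/dose."""
        return -1000.0 if self.modality == "CT" else 0.0


def _rotation(roll: float, pitch: float, yaw: float) -> Rotation:
    return Rotation.from_euler(_EULER_SEQ, [roll, pitch, yaw], degrees=True)


@dataclass(frozen=True)
class RigidTransform:
    """6-DOF rigid body motion: translations (mm) plus roll/pitch/yaw (deg).

    A point ``p`` maps to ``R @ (p - center) + center + t`` where
    ``R = R_yaw @ R_pitch @ R_roll`` (fixed-axis composition) and
    ``t = (tx, ty, tz)``.  ``center`` is the world point the rotation
    pivots about; reported translation components depend on it, so it is
    always carried explicitly.
    """

    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    roll: float = 0.0
    pitch: float = 0.0
    yaw: float = 0.0
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    # -- constructors ------------------------------------------------------
    @classmethod
    def identity(cls, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(center=center)

    @classmethod
    def translation(cls, tx: float, ty: float, tz: float, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(tx=tx, ty=ty, tz=tz, center=center)

    @classmethod
    def from_params(cls, params, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Build from a 6-vector ``(tx, ty, tz, roll, pitch, yaw)``."""
        tx, ty, tz, roll, pitch, yaw = (float(v) for v in params)
        return cls(tx, ty, tz, roll, pitch, yaw, center=center)

    # -- views -------------------------------------------------------------
    @property
    def params(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz, self.roll, self.pitch, self.yaw])

    @property
    def translation_vector(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz])

    @property
    def translation_magnitude(self) -> float:
        return float(np.linalg.norm(self.translation_vector))

    def rotation_matrix(self) -> np.ndarray:
        return _rotation(self.roll, self.pitch, self.yaw).as_matrix()

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous world-to-world matrix."""
        R = self.rotation_matrix()
        c = np.asarray(self.center)
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = c + self.translation_vector - R @ c
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map world points, shape (..., 3), through the transform."""
        p = np.asarray(points, dtype=np.float64)
        R = self.rotation_matrix()
        c = np.asarray(self.center)
        return (p - c) @ R.T + c + self.translation_vector

    def is_identity(self, atol: float = 1e-12) -> bool:
        return bool(np.all(np.abs(self.params) <= atol))

    def __str__(self) -> str:
        return (
            f"t=({self.tx:+.3f}, {self.ty:+.3f}, {self.tz:+.3f}) mm, "
            f"rpy=({self.roll:+.3f}, {self.pitch:+.3f}, {self.yaw:+.3f}) deg, "
            f"center={tuple(round(c, 3) for c in self.center)}"
        )


def _decompose(R: Rotation, t: np.ndarray, center) -> RigidTransform:
    roll, pitch, yaw = R.as_euler(_EULER_SEQ, degrees=True)
    return RigidTransform(t[0], t[1], t[2], roll, pitch, yaw, center=tuple(center))


def compose(A: RigidTransform, B: RigidTransform) -> RigidTransform:
    """Transform mapping any point ``p`` to ``A(B(p))``.

    Both transforms must share the same rotation center; re-center one with
    :func:`recenter` first if they do not.
    """
    if not np.allclose(A.center, B.center, atol=1e-9):
        raise ValueError(
            f"rotation centers differ ({A.center} vs {B.center}); recenter() one first"
        )
    Ra = _rotation(A.roll, A.pitch, A.yaw)
    Rb = _rotation(B.roll, B.pitch, B.yaw)
    Rc = Ra * Rb
    # A(B(p)) = Ra Rb (p - c) + c + Ra tb + ta
    tc = Ra.as_matrix() @ B.translation_vector + A.translation_vector
    return _decompose(Rc, tc, A.center)


def invert(T: RigidTransform) -> RigidTransform:
    """Inverse transform: ``invert(T)(T(p)) == p`` for all p."""
    R = _rotation(T.roll, T.pitch, T.yaw)
    Rinv = R.inv()
    tinv = -(Rinv.as_matrix() @ T.translation_vector)
    return _decompose(Rinv, tinv, T.center)


def recenter(T: RigidTransform, new_center) -> RigidTransform:
    """Re-express the same point mapping about a different rotation center."""
    new_center = np.asarray(new_center, dtype=np.float64)
    R = T.rotation_matrix()
    c = np.asarray(T.center)
    # R(p-c)+c+t == R(p-c') + [R(c'-c) + c - c' + t]
    t_new = R @ (new_center - c) + c - new_center + T.translation_vector
    return RigidTransform(
        t_new[0], t_new[1], t_new[2], T.roll, T.pitch, T.yaw, center=tuple(new_center)
    )


_INTERP_ORDER = {"trilinear": 1, "nearest": 0}


def resample_volume(
    img: VolumeImage,
    transform: RigidTransform | None,
    target_grid: GridSpec | None = None,
    interpolation: str = "trilinear",
    fill: float | None = None,
    return_mask: bool = False,
):
    """Sample ``img`` onto ``target_grid`` through a rigid transform.

    ``transform`` maps *target-grid world points to source-image world
    points* (a pull-back/sampling map): the output voxel at world position
    ``x`` holds ``img(transform(x))``.  To move an image *by* ``T`` use
    :func:`transform_volume`, which passes ``invert(T)`` here.

    Out-of-field positions are filled with ``fill`` (default: -1000 for CT,
    0 for MR/dose).  With ``return_mask=True`` also returns the boolean
    in-field mask (True where the sampled position lay inside the source
    grid), which downstream overlap statistics rely on.
    """
    if interpolation not in _INTERP_ORDER:
        raise ValueError(f"interpolation must be one of {sorted(_INTERP_ORDER)}")
    if target_grid is None:
        target_grid = img.grid
    if fill is None:
        fill = img.default_fill()
    if transform is None:
        transform = RigidTransform.identity()

    identity_map = transform.is_identity(atol=1e-12)
    same_grid = (
        target_grid.shape == img.shape
        and np.allclose(target_grid.spacing, img.spacing, atol=1e-12)
        and np.allclose(target_grid.origin, img.origin, atol=1e-12)
    )
    if identity_map and same_grid:
        out = VolumeImage(img.voxels.copy(), img.spacing, img.origin, img.modality)
        if return_mask:
            return out, np.ones(img.shape, dtype=bool)
        return out

    pts = target_grid.voxel_centers()
    src_world = transform.apply(pts.reshape(-1, 3))
    src_idx = img.world_to_index(src_world)
    coords = src_idx.T
    values = ndimage.map_coordinates(
        img.voxels, coords, order=_INTERP_ORDER[interpolation], mode="constant", cval=fill
    ).reshape(target_grid.shape)
    out = VolumeImage(values, target_grid.spacing, target_grid.origin, img.modality)
    if return_mask:
        dims = np.asarray(img.shape)
        infield = np.all((src_idx >= 0) & (src_idx <= dims - 1), axis=1)
        return out, infield.reshape(target_grid.shape)
    return out


def transform_volume(
    img: VolumeImage,
    T: RigidTransform,
    target_grid: GridSpec | None = None,
    interpolation: str = "trilinear",
    fill: float | None = None,
    return_mask: bool = False,
):
    """Rigidly move ``img`` by ``T`` and resample onto ``target_grid``.

    The anatomy at source position ``p`` appears at ``T(p)`` in the output.
    """
    return resample_volume(
        img, invert(T), target_grid, interpolation=interpolation, fill=fill,
        return_mask=return_mask,
    )


def max_voxel_path(spacing) -> float:
    """Longest straight path across one voxel: the space diagonal (mm).

    For the 0.78 x 0.78 x 1.0 mm grids typical of SRS planning CTs this is
    1.49 mm, the natural yardstick for sub-voxel skull-distance agreement.
    """
    dx, dy, dz = (float(s) for s in spacing)
    if not (dx > 0 and dy > 0 and dz > 0):
        raise ValueError(f"spacing components must be strictly positive, got {spacing}")
    return math.sqrt(dx * dx + dy * dy + dz * dz)


@dataclass(frozen=True)
class Target:
    """Spherical SRS target: GTV sphere plus a PTV safety margin.

    The PTV radius is the GTV radius plus ``margin`` (1 mm by default,
    matching single-fraction SRS practice of expanding the MR-defined GTV
    by 1 mm).
    """

    centroid: tuple[float, float, float]
    gtv_radius: float
    margin: float = 1.0
    target_id: str = "t0"

    def __post_init__(self) -> None:
        object.__setattr__(self, "centroid", tuple(float(c) for c in self.centroid))
        if not self.gtv_radius > 0:
            raise ValueError(f"gtv_radius must be > 0, got {self.gtv_radius}")
        if self.margin < 0:
            raise ValueError(f"margin must be >= 0, got {self.margin}")

    @property
    def ptv_radius(self) -> float:
        return self.gtv_radius + self.margin

    def moved_by(self, T: RigidTransform) -> "Target":
        new_c = T.apply(np.asarray(self.centroid))
        return replace(self, centroid=tuple(new_c))
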