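"""Core image data model and world-coordinate geometry.

All analyses in this package share a small set of spatial primitives:

* :class:`ImageVolume` — a 3-D scalar grid with physical geometry (spacing,
  origin, orientation) in the DICOM patient coordinate system (LPS), all
  distances in millimetres.  The scanner isocentre is taken as the world
  origin unless an explicit offset is configured.
* :class:`Point3` — a world-coordinate point in mm.
* :class:`RigidTransform` — a six-degrees-of-freedom rigid motion expressed
  as three translations (RL, AP, SI, mm) and three rotations (pitch, roll,
  yaw, degrees).

Axis and rotation convention (fixed and used consistently everywhere):

* RL = x, AP = y, SI = z.
* pitch = rotation about the RL axis, yaw = rotation about the AP axis,
  roll = rotation about the SI axis.
* Rotations compose extrinsically in the order pitch -> roll -> yaw, i.e.
  ``R = R_yaw(y) @ R_roll(z) @ R_pitch(x)`` (scipy extrinsic sequence
  ``"xzy"`` with angles ``(pitch, roll, yaw)``).

This convention is not universal in the QA literature, so every report that
prints angles also states it (see :data:`ROTATION_CONVENTION`).

Voxel indices are 0-based and may be fractional; ``voxel_to_world`` maps the
voxel *centre*: ``world = origin + direction @ (spacing * index)``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Modality",
    "Point3",
    "ImageVolume",
    "RigidTransform",
    "MarkerSet",
    "QAError",
    "ROTATION_CONVENTION",
    "EULER_SEQ",
]

#: Human-readable statement of the angle convention, embedded in reports.
ROTATION_CONVENTION = (
    "RL=x, AP=y, SI=z; pitch about RL, roll about SI, yaw about AP; "
    "extrinsic rotation order pitch->roll->yaw; angles in degrees, "
    "translations in mm (LPS patient frame, isocentre at origin)"
)

#: scipy extrinsic Euler sequence realising pitch->roll->yaw about x, z, y.
EULER_SEQ = "xzy"


class QAError(Exception):
    """Base class for all analysis failures raised by this package."""


class Modality(str, enum.Enum):
    MR = "MR"
    PET = "PET"


@dataclass(frozen=True)
class Point3:
    """A point in world (LPS) coordinates, mm."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.x, self.y, self.z])):
            raise ValueError(f"non-finite point: {self}")

    def to_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @staticmethod
    def from_array(a: Iterable[float]) -> "Point3":
        x, y, z = np.asarray(a, dtype=float)
        return Point3(float(x), float(y), float(z))

    def distance_to(self, other: "Point3") -> float:
        return float(np.linalg.norm(self.to_array() - other.to_array()))


@dataclass
class ImageVolume:
    """A 3-D scalar image with physical geometry.

    ``voxels`` is indexed ``[i, j, k]`` along the (column, row, slice)
    directions whose world-space unit vectors are the columns of
    ``direction``.  For an identity direction matrix this means
    ``voxels[i, j, k]`` sits at ``origin + spacing * (i, j, k)`` — i.e. the
    first index runs along +x (RL), the second along +y (AP), the third
    along +z (SI).

    MR voxel values are in arbitrary units; PET values are activity
    concentration in Bq/ml (``meta["units"] == "BQML"``).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))
    modality: Modality = Modality.MR
    acquisition_time: datetime | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("voxel grid must be a non-empty 3-D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.direction = np.asarray(self.direction, dtype=float)
        if self.direction.shape != (3, 3):
            raise ValueError("direction must be 3x3")
        if abs(abs(np.linalg.det(self.direction)) - 1.0) > 1e-6 or not np.allclose(
            self.direction.T @ self.direction, np.eye(3), atol=1e-6
        ):
            raise ValueError("direction matrix must be orthonormal (|det| = 1)")
        self.modality = Modality(self.modality)
        if self.modality is Modality.PET and "units" not in self.meta:
            raise ValueError("PET volumes must carry units metadata (e.g. 'BQML')")

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def voxel_to_world(self, index: Iterable[float]) -> Point3:
        """Map a (possibly fractional) 0-based voxel index to a world point."""
        idx = np.asarray(index, dtype=float)
        world = np.asarray(self.origin) + self.direction @ (np.asarray(self.spacing) * idx)
        return Point3.from_array(world)

    def world_to_voxel(self, point: Point3 | Iterable[float]) -> np.ndarray:
        """Inverse of :meth:`voxel_to_world`; returns a fractional index."""
        p = point.to_array() if isinstance(point, Point3) else np.asarray(point, dtype=float)
        rel = self.direction.T @ (p - np.asarray(self.origin))
        return rel / np.asarray(self.spacing)

    def world_to_voxel_many(self, points: np.ndarray) -> np.ndarray:
        """Vectorised ``world_to_voxel`` for an (n, 3) array of points."""
        rel = (np.asarray(points, dtype=float) - np.asarray(self.origin)) @ self.direction
        return rel / np.asarray(self.spacing)

    def voxel_to_world_many(self, indices: np.ndarray) -> np.ndarray:
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + (idx * np.asarray(self.spacing)) @ self.direction.T

    def index_grid_world(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of every voxel centre, as three broadcastable axes.

        Only valid for identity-direction volumes (the common case for the
        synthetic phantoms); raises otherwise.
        """
        if not np.allclose(self.direction, np.eye(3)):
            raise QAError("index_grid_world requires an axis-aligned volume")
        nx, ny, nz = self.shape
        sx, sy, sz = self.spacing
        ox, oy, oz = self.origin
        xs = ox + sx * np.arange(nx)[:, None, None]
        ys = oy + sy * np.arange(ny)[None, :, None]
        zs = oz + sz * np.arange(nz)[None, None, :]
        return xs, ys, zs


@dataclass
class MarkerSet:
    """Identified point landmarks with integer IDs, in world coordinates (mm).

    ``positions`` maps marker id -> length-3 array.  ``out_of_field`` lists
    ids whose true position fell outside the imaged volume (ground-truth
    sets only); ``spurious`` counts detections that matched no id.
    """

    positions: dict[int, np.ndarray] = field(default_factory=dict)
    out_of_field: set[int] = field(default_factory=set)
    missing: set[int] = field(default_factory=set)
    spurious: int = 0

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def ids(self) -> list[int]:
        return sorted(self.positions)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (ids, (n, 3) positions) sorted by id."""
        ids = self.ids
        pts = np.array([self.positions[i] for i in ids], dtype=float).reshape(-1, 3)
        return np.asarray(ids, dtype=int), pts


def _wrap_angle(a: float) -> float:
    """Wrap an angle in degrees into (-180, 180]."""
    a = float((a + 180.0) % 360.0 - 180.0)
    return 180.0 if a == -180.0 else a


@dataclass(frozen=True)
class RigidTransform:
    """Six-DOF rigid motion: ``p' = R @ p + t``.

    Translations in mm along RL/AP/SI; angles in degrees per the package
    convention (:data:`ROTATION_CONVENTION`).
    """

    t_rl: float = 0.0
    t_ap: float = 0.0
    t_si: float = 0.0
    pitch: float = 0.0
    roll: float = 0.0
    yaw: float = 0.0

    def __post_init__(self) -> None:
        for name in ("pitch", "roll", "yaw"):
            a = getattr(self, name)
            if not -180.0 < a <= 180.0:
                object.__setattr__(self, name, _wrap_angle(a))
        if not np.all(np.isfinite(self.as_params())):
            raise ValueError("non-finite rigid transform parameters")

    # -- conversions ------------------------------------------------------

    def as_params(self) -> np.ndarray:
        return np.array(
            [self.t_rl, self.t_ap, self.t_si, self.pitch, self.roll, self.yaw], dtype=float
        )

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.t_rl, self.t_ap, self.t_si], dtype=float)

    @property
    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler(
            EULER_SEQ, [self.pitch, self.roll, self.yaw], degrees=True
        ).as_matrix()

    @staticmethod
    def from_matrix(rotation: np.ndarray, translation: Iterable[float]) -> "RigidTransform":
        pitch, roll, yaw = Rotation.from_matrix(np.asarray(rotation)).as_euler(
            EULER_SEQ, degrees=True
        )
        t = np.asarray(translation, dtype=float)
        return RigidTransform(
            t_rl=float(t[0]),
            t_ap=float(t[1]),
            t_si=float(t[2]),
            pitch=float(pitch),
            roll=float(roll),
            yaw=float(yaw),
        )

    # -- application ------------------------------------------------------

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (n, 3) array (or single 3-vector) of world points."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        out = p @ self.rotation_matrix.T + self.translation
        return out[0] if np.asarray(points).ndim == 1 else out

    def apply_point(self, point: Point3) -> Point3:
        return Point3.from_array(self.apply(point.to_array()))

    def inverse(self) -> "RigidTransform":
        r = self.rotation_matrix
        return RigidTransform.from_matrix(r.T, -r.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        r = self.rotation_matrix @ other.rotation_matrix
        t = self.rotation_matrix @ other.translation + self.translation
        return RigidTransform.from_matrix(r, t)

    def to_dict(self) -> dict:
        return {
            "t_rl_mm": self.t_rl,
            "t_ap_mm": self.t_ap,
            "t_si_mm": self.t_si,
            "pitch_deg": self.pitch,
            "roll_deg": self.roll,
            "yaw_deg": self.yaw,
            "convention": ROTATION_CONVENTION,
        }
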