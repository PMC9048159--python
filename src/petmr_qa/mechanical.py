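"""Laser/couch mechanical accuracy from a cross-plane phantom and from
operator-entered ruler readings.

The cross-plane phantom contains three orthogonal 10 cm signal planes.
After laser alignment and a shift to isocentre, an image centred on the
isocentre is acquired; the cross centre and the points +/-5 cm along each
axis are marked (manually in a planning system, or automatically here) and
the transverse and rotational offsets of the phantom from the image centre
are computed.

Rotations use the two-point secant angle of each +/- axis pair — what
manual +/-5 cm marking supports — with the cyclic assignment matching the
package convention: pitch (about RL) from the SI-deviation of the AP pair,
yaw (about AP) from the RL-deviation of the SI pair, roll (about SI) from
the AP-deviation of the RL pair.

Ruler-based procedures (laser movements, couch movements, internal/external
laser differences) are physical measurements; this module only stores the
operator-entered readings, differences them against the commanded values,
and extracts hysteresis from the return-to-zero reading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import ImageVolume, QAError
from .qastats import Measurement

__all__ = [
    "CrossMarkSet",
    "MechanicalResult",
    "ManualEntry",
    "MANUAL_TESTS",
    "nominal_cross_points",
    "compute_offsets",
    "auto_locate_cross",
    "evaluate_manual",
]

AXES = ("x", "y", "z")  # RL, AP, SI
ARM_MM = 50.0

MANUAL_TESTS = (
    "lateral_coincidence",
    "laser_movement",
    "el_il_difference",
    "il_si_offset",
    "couch_movement",
)
_MOVEMENT_TESTS = ("laser_movement", "couch_movement")


def nominal_cross_points(arm_mm: float = ARM_MM) -> dict[str, np.ndarray]:
    """The 7 nominal mark positions: centre plus +/-arm on each axis."""
    pts = {"centre": np.zeros(3)}
    for a, ax in enumerate(AXES):
        for sign, tag in ((1.0, "+"), (-1.0, "-")):
            v = np.zeros(3)
            v[a] = sign * arm_mm
            pts[f"{ax}{tag}"] = v
    return pts


@dataclass
class CrossMarkSet:
    """Centre plus +/-5 cm marks on each cross-plane axis (world mm)."""

    centre: np.ndarray
    axis_points: dict[str, np.ndarray]  # keys "x+", "x-", "y+", "y-", "z+", "z-"
    source: str = "manual"  # manual | auto

    def __post_init__(self) -> None:
        self.centre = np.asarray(self.centre, dtype=float)
        self.axis_points = {k: np.asarray(v, dtype=float) for k, v in self.axis_points.items()}
        expected = {f"{ax}{s}" for ax in AXES for s in "+-"}
        if set(self.axis_points) != expected:
            raise QAError(f"need marks {sorted(expected)}, got {sorted(self.axis_points)}")
        for ax in AXES:
            p, m = self.axis_points[f"{ax}+"], self.axis_points[f"{ax}-"]
            seg = p - m
            norm = np.linalg.norm(seg)
            if norm < 1e-9:
                raise QAError(f"{ax} marks coincide")
            sagitta = np.linalg.norm(np.cross(self.centre - m, seg)) / norm
            if sagitta > 5.0:
                raise QAError(f"centre is {sagitta:.1f} mm off the {ax} mark pair line (> 5 mm)")


@dataclass
class MechanicalResult:
    rl_offset: float
    ap_offset: float
    pitch: float
    roll: float
    yaw: float
    source: str = "manual"

    def to_measurements(self, session: str = "") -> list[Measurement]:
        rows = [
            ("EL Right-Left Offset", self.rl_offset, "mm"),
            ("EL Ant-Post Offset", self.ap_offset, "mm"),
            ("EL Pitch Angle", self.pitch, "deg"),
            ("EL Roll Angle", self.roll, "deg"),
            ("EL Yaw Angle", self.yaw, "deg"),
        ]
        return [
            Measurement(test="Mechanical Accuracy", component=c, value=v, units=u, session=session)
            for c, v, u in rows
        ]


def _secant_angle_deg(dev_plus: float, dev_minus: float, sep: float) -> float:
    return math.degrees(math.atan2(dev_plus - dev_minus, sep))


def compute_offsets(marks: CrossMarkSet, image_centre=(0.0, 0.0, 0.0)) -> MechanicalResult:
    """Transverse and rotational offsets of the cross from the image centre.

    Translations are the RL and AP components of (cross centre - image
    centre); the SI offset is covered by the internal-laser ruler test.
    Each rotation is the secant angle of its +/- mark pair (see module
    docstring for the cyclic axis assignment).  Axis pairs separated by
    less than 50 mm are rejected as implausible markings.
    """
    ic = np.asarray(image_centre, dtype=float)
    d = marks.centre - ic

    pairs = {}
    for ax_i, ax in enumerate(AXES):
        p, m = marks.axis_points[f"{ax}+"], marks.axis_points[f"{ax}-"]
        sep = p[ax_i] - m[ax_i]
        if sep < 50.0:
            raise QAError(f"{ax} mark pair separation {sep:.1f} mm < 50 mm — marks implausible")
        pairs[ax] = (p, m, sep)

    # cyclic right-handed assignment: rotation about a moves b towards c
    py_p, py_m, py_sep = pairs["y"]
    pitch = _secant_angle_deg(py_p[2], py_m[2], py_sep)  # AP pair, SI deviation
    pz_p, pz_m, pz_sep = pairs["z"]
    yaw = _secant_angle_deg(pz_p[0], pz_m[0], pz_sep)  # SI pair, RL deviation
    px_p, px_m, px_sep = pairs["x"]
    roll = _secant_angle_deg(px_p[1], px_m[1], px_sep)  # RL pair, AP deviation

    return MechanicalResult(
        rl_offset=float(d[0]),
        ap_offset=float(d[1]),
        pitch=pitch,
        roll=roll,
        yaw=yaw,
        source=marks.source,
    )


def auto_locate_cross(
    volume: ImageVolume,
    arm_mm: float = ARM_MM,
    threshold_frac: float = 0.3,
    window_mm: float = 4.0,
) -> CrossMarkSet:
    """Automatically mark the cross centre and +/-5 cm axis points.

    The centre is the intensity-weighted centroid of the thresholded cross;
    each axis point comes from ridge following: stepping outward along the
    (re-estimated) axis direction, re-centring on the local transverse
    intensity-weighted centroid, out to the +/-5 cm mark.
    """
    vox = np.clip(np.asarray(volume.voxels, dtype=float), 0.0, None)
    vmax = vox.max()
    if vmax <= 0:
        raise QAError("empty volume — ridges not found; mark the cross manually")
    if (vox >= threshold_frac * vmax).sum() < 10:
        raise QAError("cross-plane signal not found; mark the cross manually")
    # centre: brightest point of the smoothed cross (the triple overlap),
    # refined by an iterated intensity-weighted centroid — the cross is
    # point-symmetric about its centre, so the fixed point is unbiased
    smooth = ndimage.gaussian_filter(vox, 1.0 / np.asarray(volume.spacing))
    com = np.asarray(np.unravel_index(int(np.argmax(smooth)), vox.shape), dtype=float)
    half = np.maximum(2, np.round(5.0 / np.asarray(volume.spacing)).astype(int))
    for _ in range(5):
        lo = np.maximum(0, np.round(com).astype(int) - half)
        hi = np.minimum(np.asarray(vox.shape), np.round(com).astype(int) + half + 1)
        sub = vox[lo[0]: hi[0], lo[1]: hi[1], lo[2]: hi[2]]
        com = lo + np.asarray(ndimage.center_of_mass(sub))
    centre = volume.voxel_to_world(com).to_array()

    axis_points: dict[str, np.ndarray] = {}
    for ax_i, ax in enumerate(AXES):
        for sign, tag in ((1.0, "+"), (-1.0, "-")):
            direction = np.zeros(3)
            direction[ax_i] = sign
            point = centre.copy()
            for d in np.arange(8.0, arm_mm + 0.5, 2.0):
                probe = centre + d * direction
                refined = _transverse_centroid(volume, vox, probe, ax_i, window_mm)
                if refined is None:
                    raise QAError(f"ridge lost on {ax}{tag} at {d:.0f} mm; mark the cross manually")
                point = refined
                direction = point - centre
                direction = direction / np.linalg.norm(direction)
            axis_points[f"{ax}{tag}"] = centre + arm_mm * direction
    return CrossMarkSet(centre=centre, axis_points=axis_points, source="auto")


def _transverse_centroid(volume: ImageVolume, vox: np.ndarray, probe: np.ndarray, ax_i: int, window_mm: float):
    """Intensity-weighted centroid of a thin slab orthogonal to axis ``ax_i``
    around the probe point; None when there is no signal there."""
    idx = volume.world_to_voxel(probe)
    spacing = np.asarray(volume.spacing)
    half = np.maximum(1, np.round(window_mm / spacing).astype(int))
    half[ax_i] = max(1, int(round(1.0 / spacing[ax_i])))
    lo = np.maximum(0, np.round(idx).astype(int) - half)
    hi = np.minimum(np.asarray(vox.shape), np.round(idx).astype(int) + half + 1)
    if np.any(hi <= lo):
        return None
    sub = vox[lo[0]: hi[0], lo[1]: hi[1], lo[2]: hi[2]]
    if sub.max() < 0.1 * vox.max() or sub.sum() <= 0:
        return None
    com = lo + np.asarray(ndimage.center_of_mass(sub))
    return volume.voxel_to_world(com).to_array()


# -- manual (ruler) entries ------------------------------------------------


@dataclass
class ManualEntry:
    """One operator-entered ruler/laser reading."""

    test: str
    commanded: float  # mm
    measured: float  # mm
    return_to_zero: float | None = None  # reading after the final shift back to zero
    session: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.test not in MANUAL_TESTS:
            raise QAError(f"unknown manual test {self.test!r}; expected one of {MANUAL_TESTS}")
        if not np.isfinite(self.measured):
            raise QAError("measured value must be finite")


def evaluate_manual(entries: list[ManualEntry], tolerance_mm: float = 2.0) -> list[dict]:
    """Difference (measured - commanded), hysteresis |return-to-zero| for
    movement tests, and a +/- tolerance verdict per entry.  Movement tests
    without a return-to-zero reading get a warning, not an error."""
    report = []
    for e in entries:
        diff = e.measured - e.commanded
        row = {
            "test": e.test,
            "session": e.session,
            "commanded_mm": e.commanded,
            "measured_mm": e.measured,
            "difference_mm": diff,
            "verdict": "pass" if abs(diff) <= tolerance_mm else "fail",
            "warnings": [],
        }
        if e.test in _MOVEMENT_TESTS:
            if e.return_to_zero is None:
                row["warnings"].append("movement test without return-to-zero reading")
            else:
                row["hysteresis_mm"] = abs(e.return_to_zero)
        report.append(row)
    return report
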