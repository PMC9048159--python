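"""PET SUV accuracy from a uniform activity phantom.

A cylinder uniformly filled with ~30 MBq of ¹⁸F-FDG is scanned, and the
mean standard-uptake value inside a centred 18 cm diameter x 18 cm long
cylindrical ROI is compared with the reference.  With the mass/activity
normalisation used here the reference SUV of a uniform phantom is exactly
1 by construction:

    SUV(voxel) = C(voxel) [Bq/ml] * fill mass [g] / net activity [Bq]

with fill mass = fill volume x density (1.00 g/ml for water by default)
and net activity the assayed activity minus the residual left in the
syringe, both decay-corrected to scan start with the ¹⁸F half-life
(109.77 min).  The percent difference of the ROI mean SUV from 1 is the
reported result; it is equivalently the percent difference of the
measured mean concentration from the expected concentration
(net activity / fill volume).

Scanner-side reconstruction corrections (attenuation maps, resolution
recovery, filtering) are assumed already applied to the input series.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .core import ImageVolume, Modality, QAError

__all__ = ["ActivityRecord", "SUVResult", "decay_correct", "place_cylinder_roi", "suv_difference"]

F18_HALF_LIFE_MIN = 109.77


@dataclass
class ActivityRecord:
    """Dose-calibrator assay and fill bookkeeping for one phantom fill."""

    assayed_mbq: float
    assay_time: _dt.datetime
    scan_start: _dt.datetime
    fill_volume_ml: float
    residual_mbq: float = 0.0
    residual_time: _dt.datetime | None = None
    fill_density_g_ml: float = 1.0
    half_life_min: float = F18_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        if self.assayed_mbq <= 0 or self.fill_volume_ml <= 0 or self.half_life_min <= 0:
            raise QAError("activity, fill volume and half-life must be positive")
        if self.residual_mbq < 0:
            raise QAError("residual activity cannot be negative")
        if self.residual_mbq > self.assayed_mbq:
            raise QAError("residual activity exceeds assayed activity")
        if self.assay_time > self.scan_start:
            raise QAError("assay time must not be after scan start")
        if self.residual_time is None:
            self.residual_time = self.assay_time

    @staticmethod
    def from_yaml(path: str | Path) -> "ActivityRecord":
        raw = yaml.safe_load(Path(path).read_text())
        parse = lambda s: _dt.datetime.fromisoformat(str(s))  # noqa: E731
        return ActivityRecord(
            assayed_mbq=float(raw["assayed_mbq"]),
            assay_time=parse(raw["assay_time"]),
            scan_start=parse(raw["scan_start"]),
            fill_volume_ml=float(raw["fill_volume_ml"]),
            residual_mbq=float(raw.get("residual_mbq", 0.0)),
            residual_time=parse(raw["residual_time"]) if raw.get("residual_time") else None,
            fill_density_g_ml=float(raw.get("fill_density_g_ml", 1.0)),
            half_life_min=float(raw.get("half_life_min", F18_HALF_LIFE_MIN)),
        )


@dataclass
class SUVResult:
    mean_suv: float
    reference_suv: float
    percent_difference: float
    roi_voxels: int
    expected_concentration_bq_ml: float
    net_activity_bq: float


def _decay_factor(from_time: _dt.datetime, to_time: _dt.datetime, half_life_min: float) -> float:
    dt_min = (to_time - from_time).total_seconds() / 60.0
    return 2.0 ** (-dt_min / half_life_min)


def net_activity_at_scan_bq(rec: ActivityRecord) -> float:
    """Assayed minus residual activity, both decayed to scan start (Bq)."""
    assayed = rec.assayed_mbq * 1e6 * _decay_factor(rec.assay_time, rec.scan_start, rec.half_life_min)
    residual = rec.residual_mbq * 1e6 * _decay_factor(rec.residual_time, rec.scan_start, rec.half_life_min)
    net = assayed - residual
    if net <= 0:
        raise QAError("non-positive net activity at scan start")
    return net


def decay_correct(rec: ActivityRecord) -> float:
    """Expected activity concentration in the phantom at scan start, Bq/ml."""
    return net_activity_at_scan_bq(rec) / rec.fill_volume_ml


def place_cylinder_roi(
    volume: ImageVolume,
    diameter_mm: float = 180.0,
    length_mm: float = 180.0,
    support_threshold_frac: float = 0.5,
    min_inside_frac: float = 0.99,
) -> np.ndarray:
    """Centred cylindrical ROI mask (SI axis) inside the phantom support.

    The phantom centre is the centroid of the thresholded support; the ROI
    is the set of voxels whose centres fall inside the cylinder.  If more
    than 1% of ROI voxels lie outside the support the phantom is too small
    or mispositioned and the placement fails.
    """
    vox = np.asarray(volume.voxels, dtype=float)
    vmax = vox.max()
    if vmax <= 0:
        raise QAError("empty volume — no phantom support found")
    support = vox >= support_threshold_frac * vmax
    if not support.any():
        raise QAError("no phantom support above threshold")
    com = np.asarray(ndimage.center_of_mass(support))
    centre = volume.voxel_to_world(com).to_array()

    xs, ys, zs = volume.index_grid_world()
    r2 = (xs - centre[0]) ** 2 + (ys - centre[1]) ** 2
    # strict inequalities: a centre exactly on the boundary would otherwise
    # pick up a whole extra voxel plane when the grid aligns with the ROI
    mask = (r2 < (diameter_mm / 2.0) ** 2) & (np.abs(zs - centre[2]) < length_mm / 2.0)
    n_roi = int(mask.sum())
    if n_roi == 0:
        raise QAError("ROI contains no voxels")
    inside = float((mask & support).sum()) / n_roi
    if inside < min_inside_frac:
        raise QAError(
            f"only {100 * inside:.1f}% of the ROI lies inside the phantom support "
            f"(needs >= {100 * min_inside_frac:.0f}%) — phantom too small or mispositioned"
        )
    return mask


def suv_difference(volume: ImageVolume, roi: np.ndarray, rec: ActivityRecord) -> SUVResult:
    """Mean SUV in the ROI and its percent difference from the reference.

    Requires a PET volume in activity-concentration units (Bq/ml).
    """
    if volume.modality is not Modality.PET or volume.meta.get("units") != "BQML":
        raise QAError("SUV analysis needs a PET volume with units metadata 'BQML'")
    net_bq = net_activity_at_scan_bq(rec)
    mass_g = rec.fill_volume_ml * rec.fill_density_g_ml
    suv = np.asarray(volume.voxels, dtype=float) * mass_g / net_bq
    mean_suv = float(suv[roi].mean())
    reference = 1.0
    return SUVResult(
        mean_suv=mean_suv,
        reference_suv=reference,
        percent_difference=100.0 * (mean_suv - reference) / reference,
        roi_voxels=int(roi.sum()),
        expected_concentration_bq_ml=net_bq / rec.fill_volume_ml,
        net_activity_bq=net_bq,
    )
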