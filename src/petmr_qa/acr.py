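"""ACR-style MR image-quality metrics.

Analyses T1-like and T2-like axial series of a large image-quality phantom
containing two angled ramps (slice thickness), crossed 45° wedges at either
end (slice position), a uniform compartment (integral uniformity and
ghosting) and hole arrays of decreasing diameter (high-contrast
resolution).  The low-contrast spoke count is a manual observation and is
recorded verbatim, never computed.

Metric definitions:

* slice thickness = f · (L_top · L_bot) / (L_top + L_bot) with f the ramp
  slope factor (0.2 for 1:10 ramps) and L the full-width-half-maximum
  length of each ramp's signal profile.  The half-maximum level is midway
  between the profile minimum (the dark insert plateau) and maximum, with
  linear interpolation between samples for sub-pixel edge localisation.
* slice position = half the signed difference of the two wedge-bar
  lengths (45° wedges convert a longitudinal offset into an in-plane
  length difference at a factor of two).
* PIU = 100 · (1 − (high − low)/(high + low)) with high/low the means of
  the brightest/darkest ~1 cm² sub-regions inside the uniform compartment.
* ghosting = 100 · |(top + bottom) − (left + right)| / (2 · phantom mean)
  over four elliptical background ROIs and a large central ROI.
* resolution = smallest hole diameter with a fully "resolved" horizontal
  or vertical line: every inter-hole trough below a configurable fraction
  (default 0.7) of its adjacent peaks.

All region geometry lives in :class:`ACRGeometryConfig` (world mm, phantom
frame); an in-plane phantom rotation can be declared in the config and is
applied to every region, so the metrics follow the phantom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import ImageVolume, QAError
from .qastats import Measurement

__all__ = [
    "LineRegion",
    "CircleROI",
    "EllipseROI",
    "HoleArray",
    "ACRGeometryConfig",
    "ImageQualityResult",
    "measure_slice_thickness",
    "measure_slice_position",
    "measure_uniformity",
    "measure_ghosting",
    "assess_resolution",
    "record_low_contrast",
    "analyse_series",
]

# Canonical synthetic-phantom layout (mm, phantom frame).  The generator in
# :mod:`petmr_qa.phantoms` renders exactly this geometry so that the default
# config analyses it without adjustment; a real phantom needs its own config.
DISK_RADIUS = 95.0
Z_STRUCT = 0.0
Z_UNIFORM = 5.0
RAMP_BAR_HALF_HEIGHT = 3.0
RAMP_BAR_Y = (5.0, -5.0)  # top, bottom bar centres
RAMP_INSERT = (-70.0, 70.0, -12.0, 12.0)  # x0, x1, y0, y1
WEDGE_INSERT = (-30.0, 30.0, -90.0, -50.0)
WEDGE_BAR_X = (-15.0, 15.0)  # left, right bar centres
WEDGE_BAR_HALF_WIDTH = 2.0
WEDGE_BAR_BASE_Y = -85.0  # bars grow upward (+y) from here
WEDGE_BAR_BASE_LEN = 25.0
RES_BLOCK_X = (-44.0, 0.0, 44.0)
RES_BLOCK_HALF = (14.0, 12.0)
RES_BLOCK_Y = 58.0
RES_DIAMETERS = (1.1, 1.0, 0.9)
GHOST_ELLIPSES = {  # centre (x, y), semi-axes (a, b)
    "top": ((0.0, -105.0), (30.0, 8.0)),
    "bottom": ((0.0, 105.0), (30.0, 8.0)),
    "left": ((-105.0, 0.0), (8.0, 30.0)),
    "right": ((105.0, 0.0), (8.0, 30.0)),
}


@dataclass(frozen=True)
class LineRegion:
    """A rotated rectangle along which a 1-D profile is measured."""

    centre: tuple[float, float, float]  # phantom frame, mm
    half_length: float  # along the profile axis
    half_width: float  # averaged across
    axis_angle_deg: float = 0.0  # profile direction, 0 = +x, 90 = +y


@dataclass(frozen=True)
class CircleROI:
    centre: tuple[float, float, float]
    radius: float


@dataclass(frozen=True)
class EllipseROI:
    centre: tuple[float, float, float]
    semi_axes: tuple[float, float]


@dataclass(frozen=True)
class HoleArray:
    diameter: float
    centre: tuple[float, float, float]
    n: int = 4

    @property
    def pitch(self) -> float:
        return 2.0 * self.diameter


@dataclass
class ACRGeometryConfig:
    ramp_top: LineRegion
    ramp_bottom: LineRegion
    wedge_left: LineRegion
    wedge_right: LineRegion
    uniform_roi: CircleROI
    phantom_roi: CircleROI
    ghost_rois: dict[str, EllipseROI]
    hole_arrays: list[HoleArray]
    ramp_slope_factor: float = 0.2
    resolution_threshold: float = 0.7
    inplane_rotation_deg: float = 0.0

    @staticmethod
    def default() -> "ACRGeometryConfig":
        return ACRGeometryConfig(
            ramp_top=LineRegion((0.0, RAMP_BAR_Y[0], Z_STRUCT), 65.0, 2.0, 0.0),
            ramp_bottom=LineRegion((0.0, RAMP_BAR_Y[1], Z_STRUCT), 65.0, 2.0, 0.0),
            wedge_left=LineRegion((WEDGE_BAR_X[0], -70.0, Z_STRUCT), 16.0, 1.2, 90.0),
            wedge_right=LineRegion((WEDGE_BAR_X[1], -70.0, Z_STRUCT), 16.0, 1.2, 90.0),
            uniform_roi=CircleROI((0.0, 0.0, Z_UNIFORM), 60.0),
            phantom_roi=CircleROI((0.0, 0.0, Z_UNIFORM), 70.0),
            ghost_rois={
                k: EllipseROI((c[0], c[1], Z_UNIFORM), ax) for k, (c, ax) in GHOST_ELLIPSES.items()
            },
            hole_arrays=[
                HoleArray(d, (x, RES_BLOCK_Y, Z_STRUCT))
                for d, x in zip(RES_DIAMETERS, RES_BLOCK_X)
            ],
        )

    def rotated(self, angle_deg: float) -> "ACRGeometryConfig":
        return replace(self, inplane_rotation_deg=angle_deg)


@dataclass
class ImageQualityResult:
    series: str
    slice_thickness: float
    slice_position: float
    piu: float
    ghosting: float
    resolution: float
    low_contrast: int | None = None
    warnings: list[str] = field(default_factory=list)

    def to_measurements(self, session: str = "") -> list[Measurement]:
        s = self.series
        rows = [
            (f"Slice Thickness ({s})", self.slice_thickness, "mm"),
            (f"Slice Position ({s})", self.slice_position, "mm"),
            (f"Image Uniformity ({s})", self.piu, "%"),
            (f"Ghosting ({s})", self.ghosting, "%"),
            (f"Spatial Resolution ({s})", self.resolution, "mm"),
        ]
        if self.low_contrast is not None:
            rows.append((f"Low-Contrast Detection ({s})", float(self.low_contrast), "spokes"))
        return [
            Measurement(test="MR Image Quality", component=c, value=v, units=u, session=session)
            for c, v, u in rows
        ]


# -- geometry helpers ------------------------------------------------------


def _axial_slice(volume: ImageVolume, z_mm: float) -> tuple[np.ndarray, int]:
    """The slice nearest world z; requires an axis-aligned axial volume."""
    if not np.allclose(volume.direction, np.eye(3), atol=1e-6):
        raise QAError("ACR analysis expects an axis-aligned axial volume")
    oz, sz = volume.origin[2], volume.spacing[2]
    k = int(round((z_mm - oz) / sz))
    if not 0 <= k < volume.shape[2]:
        raise QAError(f"no slice at z = {z_mm} mm")
    return np.asarray(volume.voxels, dtype=float)[:, :, k], k


def _rot2(angle_deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))
    return np.array([[c, -s], [s, c]])


def _phantom_to_index(volume: ImageVolume, pts_xy: np.ndarray, rotation_deg: float) -> np.ndarray:
    """Phantom-frame (n, 2) points -> fractional voxel indices (2, n)."""
    img_xy = pts_xy @ _rot2(rotation_deg).T
    ix = (img_xy[:, 0] - volume.origin[0]) / volume.spacing[0]
    iy = (img_xy[:, 1] - volume.origin[1]) / volume.spacing[1]
    return np.vstack([ix, iy])


def _sample_at(slice2d: np.ndarray, volume: ImageVolume, pts_xy: np.ndarray, rotation_deg: float, order: int) -> np.ndarray:
    coords = _phantom_to_index(volume, np.atleast_2d(pts_xy), rotation_deg)
    return ndimage.map_coordinates(slice2d, coords, order=order, mode="nearest")


def _profile(volume: ImageVolume, region: LineRegion, rotation_deg: float, order: int = 1):
    """Mean-across-width profile along the region axis.  Returns (s, values)
    with s in mm relative to the region centre."""
    slice2d, _ = _axial_slice(volume, region.centre[2])
    px = min(volume.spacing[0], volume.spacing[1])
    u = np.array([math.cos(math.radians(region.axis_angle_deg)), math.sin(math.radians(region.axis_angle_deg))])
    v = np.array([-u[1], u[0]])
    s = np.arange(-region.half_length, region.half_length + 1e-9, px / 2.0)
    t = np.arange(-region.half_width, region.half_width + 1e-9, px)
    c = np.asarray(region.centre[:2])
    pts = c[None, None, :] + s[:, None, None] * u[None, None, :] + t[None, :, None] * v[None, None, :]
    vals = _sample_at(slice2d, volume, pts.reshape(-1, 2), rotation_deg, order).reshape(len(s), len(t))
    return s, vals.mean(axis=1)


def _fwhm(s: np.ndarray, profile: np.ndarray, what: str) -> float:
    """Full width at half maximum with linear interpolation at the crossings.

    The half level is midway between the profile minimum (local dark
    plateau) and maximum."""
    lo, hi = float(profile.min()), float(profile.max())
    if hi - lo <= 0:
        raise QAError(f"{what}: flat profile, no half-maximum crossing")
    half = 0.5 * (lo + hi)
    above = profile >= half
    if not above.any() or above.all():
        raise QAError(f"{what}: profile never crosses half-maximum")
    idx = np.flatnonzero(above)
    i0, i1 = idx[0], idx[-1]
    if i0 == 0 or i1 == len(profile) - 1:
        raise QAError(f"{what}: half-maximum crossing lies outside the measured region")

    def interp(ia: int, ib: int) -> float:
        f = (half - profile[ia]) / (profile[ib] - profile[ia])
        return float(s[ia] + f * (s[ib] - s[ia]))

    left = interp(i0 - 1, i0)
    right = interp(i1, i1 + 1)
    return right - left


# -- metrics ---------------------------------------------------------------


def measure_slice_thickness(volume: ImageVolume, cfg: ACRGeometryConfig, series: str = "") -> Measurement:
    """Slice thickness from the FWHM lengths of the two angled ramps."""
    rot = cfg.inplane_rotation_deg
    l_top = _fwhm(*_profile(volume, cfg.ramp_top, rot), what="top ramp")
    l_bot = _fwhm(*_profile(volume, cfg.ramp_bottom, rot), what="bottom ramp")
    thickness = cfg.ramp_slope_factor * (l_top * l_bot) / (l_top + l_bot)
    return Measurement(
        test="MR Image Quality",
        component=f"Slice Thickness ({series})" if series else "Slice Thickness",
        value=float(thickness),
        units="mm",
        meta={"L_top_mm": l_top, "L_bottom_mm": l_bot, "slope_factor": cfg.ramp_slope_factor},
    )


def measure_slice_position(volume: ImageVolume, cfg: ACRGeometryConfig, series: str = "") -> Measurement:
    """Half the signed wedge-bar length difference (left minus right)."""
    rot = cfg.inplane_rotation_deg
    l_left = _fwhm(*_profile(volume, cfg.wedge_left, rot), what="left wedge bar")
    l_right = _fwhm(*_profile(volume, cfg.wedge_right, rot), what="right wedge bar")
    return Measurement(
        test="MR Image Quality",
        component=f"Slice Position ({series})" if series else "Slice Position",
        value=0.5 * (l_left - l_right),
        units="mm",
        meta={"L_left_mm": l_left, "L_right_mm": l_right},
    )


def _support_mask(slice2d: np.ndarray, frac: float = 0.25) -> np.ndarray:
    return slice2d > frac * slice2d.max()


def _circle_mask(volume: ImageVolume, slice2d: np.ndarray, roi: CircleROI, rotation_deg: float) -> np.ndarray:
    nx, ny = slice2d.shape
    xs = volume.origin[0] + volume.spacing[0] * np.arange(nx)[:, None]
    ys = volume.origin[1] + volume.spacing[1] * np.arange(ny)[None, :]
    r = _rot2(rotation_deg)
    px = r[0, 0] * xs + r[1, 0] * ys  # image -> phantom frame (R^T)
    py = r[0, 1] * xs + r[1, 1] * ys
    return (px - roi.centre[0]) ** 2 + (py - roi.centre[1]) ** 2 <= roi.radius**2


def _ellipse_mask(volume: ImageVolume, slice2d: np.ndarray, roi: EllipseROI, rotation_deg: float) -> np.ndarray:
    nx, ny = slice2d.shape
    xs = volume.origin[0] + volume.spacing[0] * np.arange(nx)[:, None]
    ys = volume.origin[1] + volume.spacing[1] * np.arange(ny)[None, :]
    r = _rot2(rotation_deg)
    px = r[0, 0] * xs + r[1, 0] * ys
    py = r[0, 1] * xs + r[1, 1] * ys
    a, b = roi.semi_axes
    return ((px - roi.centre[0]) / a) ** 2 + ((py - roi.centre[1]) / b) ** 2 <= 1.0


def measure_uniformity(volume: ImageVolume, cfg: ACRGeometryConfig, series: str = "") -> Measurement:
    """Percent integral uniformity from the brightest and darkest ~1 cm²
    mean-filtered sub-regions inside the uniform compartment."""
    slice2d, _ = _axial_slice(volume, cfg.uniform_roi.centre[2])
    roi = _circle_mask(volume, slice2d, cfg.uniform_roi, cfg.inplane_rotation_deg)
    support = _support_mask(slice2d)
    if not support[roi].all():
        raise QAError("uniformity ROI extends outside the phantom support")
    size = max(3, int(round(10.0 / volume.spacing[0])) | 1)
    filtered = ndimage.uniform_filter(slice2d, size=size)
    # restrict sub-region centres so the averaging kernel stays inside the ROI
    margin = (size / 2.0) * volume.spacing[0] * math.sqrt(2.0)
    inner = _circle_mask(
        volume,
        slice2d,
        CircleROI(cfg.uniform_roi.centre, max(cfg.uniform_roi.radius - margin, 1.0)),
        cfg.inplane_rotation_deg,
    )
    high = float(filtered[inner].max())
    low = float(filtered[inner].min())
    piu = 100.0 * (1.0 - (high - low) / (high + low))
    return Measurement(
        test="MR Image Quality",
        component=f"Image Uniformity ({series})" if series else "Image Uniformity",
        value=piu,
        units="%",
        meta={"high": high, "low": low, "kernel_px": size},
    )


def measure_ghosting(volume: ImageVolume, cfg: ACRGeometryConfig, series: str = "") -> Measurement:
    """Ghosting ratio from four background ellipses and the phantom ROI."""
    slice2d, _ = _axial_slice(volume, cfg.phantom_roi.centre[2])
    support = _support_mask(slice2d)
    rot = cfg.inplane_rotation_deg
    means = {}
    for name in ("top", "bottom", "left", "right"):
        mask = _ellipse_mask(volume, slice2d, cfg.ghost_rois[name], rot)
        if not mask.any():
            raise QAError(f"{name} ghost ROI lies outside the field of view")
        if support[mask].any():
            raise QAError(f"{name} ghost ROI overlaps the phantom support")
        means[name] = float(slice2d[mask].mean())
    phantom_mask = _circle_mask(volume, slice2d, cfg.phantom_roi, rot)
    if not support[phantom_mask].all():
        raise QAError("phantom ROI extends outside the phantom support")
    mean_phantom = float(slice2d[phantom_mask].mean())
    ghost = 100.0 * abs((means["top"] + means["bottom"]) - (means["left"] + means["right"])) / (
        2.0 * mean_phantom
    )
    return Measurement(
        test="MR Image Quality",
        component=f"Ghosting ({series})" if series else "Ghosting",
        value=ghost,
        units="%",
        meta={**{f"{k}_mean": v for k, v in means.items()}, "phantom_mean": mean_phantom},
    )


def assess_resolution(volume: ImageVolume, cfg: ACRGeometryConfig, series: str = "") -> Measurement:
    """Smallest hole diameter with a resolved horizontal or vertical line.

    A line is resolved when every inter-hole trough is below
    ``resolution_threshold`` times the smaller of its two adjacent peaks
    (values sampled with cubic interpolation at the known hole/midpoint
    positions).  If no array is resolved the largest diameter is returned
    with a warning flag.
    """
    rot = cfg.inplane_rotation_deg
    thr = cfg.resolution_threshold
    resolved: dict[float, bool] = {}
    for array in sorted(cfg.hole_arrays, key=lambda a: -a.diameter):
        slice2d, _ = _axial_slice(volume, array.centre[2])
        n, pitch = array.n, array.pitch
        offs = (np.arange(n) - (n - 1) / 2.0) * pitch
        cx, cy = array.centre[0], array.centre[1]
        ok = False
        for horizontal in (True, False):
            for line in range(n):
                if horizontal:
                    peaks = np.column_stack([cx + offs, np.full(n, cy + offs[line])])
                else:
                    peaks = np.column_stack([np.full(n, cx + offs[line]), cy + offs])
                mids = 0.5 * (peaks[:-1] + peaks[1:])
                pv = _sample_at(slice2d, volume, peaks, rot, order=3)
                tv = _sample_at(slice2d, volume, mids, rot, order=3)
                if np.all(tv < thr * np.minimum(pv[:-1], pv[1:])):
                    ok = True
                    break
            if ok:
                break
        resolved[array.diameter] = ok
    resolved_d = [d for d, ok in resolved.items() if ok]
    warnings = []
    if resolved_d:
        value = min(resolved_d)
    else:
        value = max(resolved.keys())
        warnings.append("no hole array resolved; reporting the largest diameter")
    return Measurement(
        test="MR Image Quality",
        component=f"Spatial Resolution ({series})" if series else "Spatial Resolution",
        value=float(value),
        units="mm",
        meta={"resolved": {str(k): v for k, v in resolved.items()}, "warnings": warnings},
    )


def record_low_contrast(score: int, series: str, observer: str) -> Measurement:
    """Store the manual low-contrast spoke count (0-40) verbatim."""
    if not float(score).is_integer() or not 0 <= int(score) <= 40:
        raise QAError(f"low-contrast score must be an integer in [0, 40], got {score}")
    return Measurement(
        test="MR Image Quality",
        component=f"Low-Contrast Detection ({series})",
        value=float(int(score)),
        units="spokes",
        meta={"observer": observer, "manual": True},
    )


def analyse_series(volume: ImageVolume, cfg: ACRGeometryConfig, series: str, low_contrast: int | None = None, observer: str = "") -> ImageQualityResult:
    """Run every automated metric on one series; low-contrast is attached
    only if an observer score is supplied."""
    thickness = measure_slice_thickness(volume, cfg, series)
    position = measure_slice_position(volume, cfg, series)
    piu = measure_uniformity(volume, cfg, series)
    ghost = measure_ghosting(volume, cfg, series)
    res = assess_resolution(volume, cfg, series)
    lc = None
    if low_contrast is not None:
        lc = int(record_low_contrast(low_contrast, series, observer).value)
    return ImageQualityResult(
        series=series,
        slice_thickness=thickness.value,
        slice_position=position.value,
        piu=piu.value,
        ghosting=ghost.value,
        resolution=res.value,
        low_contrast=lc,
        warnings=list(res.meta.get("warnings", [])),
    )
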