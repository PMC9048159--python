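"""Synthetic phantom image generators with known ground truth.

Every QA analysis in this package has a generator here that emulates its
physical phantom at desk scale: a marker-grid distortion phantom, an
ACR-like image-quality phantom, a cross-plane laser phantom, the PET/MR
sphere alignment phantom, a three-vial diffusion phantom and a uniform
PET activity cylinder.  Generators return in-memory volumes plus the
exact ground truth; they are seed-deterministic (same spec + seed gives
bit-identical voxels) and their output can be written through the DICOM
fixture writer so analyses exercise the real ingestion path.

Markers and spheres are rendered as isotropic Gaussian blobs
(sigma = radius / 2) rather than hard spheres: centroid detection is then
sub-voxel accurate and partial-volume behaviour is controlled, which is
the property the analyses actually rely on.  No MR physics (relaxation,
EPI distortion) or PET reconstruction physics is simulated; MR magnitude
noise is Rician, PET noise is Gaussian with optionally intensity-
proportional variance (reconstructed PET noise is not Poisson).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from scipy.special import ive

from . import acr as _acr
from .core import ImageVolume, MarkerSet, Modality, QAError, RigidTransform
from .distortion import ReferenceGrid
from .mechanical import ARM_MM, CrossMarkSet, nominal_cross_points

__all__ = [
    "GridPhantomSpec",
    "VQCPhantomSpec",
    "DWVialSpec",
    "UniformPETSpec",
    "ACRSeriesSpec",
    "gen_grid_phantom",
    "gen_vqc_phantom",
    "gen_dw_vials",
    "dw_vial_masks",
    "gen_uniform_pet",
    "gen_acr_phantom",
    "gen_acr_like",
    "gen_cross_phantom",
    "gen_cross_marks",
    "add_rician_noise",
    "rician_mean",
]


# -- noise helpers ---------------------------------------------------------


def add_rician_noise(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of the signal plus complex Gaussian noise (per-channel SD
    ``sigma``) — the noise distribution of MR magnitude images."""
    if sigma <= 0:
        return np.asarray(signal, dtype=float).copy()
    s = np.asarray(signal, dtype=float)
    re = s + rng.normal(0.0, sigma, s.shape)
    im = rng.normal(0.0, sigma, s.shape)
    return np.hypot(re, im)


def rician_mean(nu: float, sigma: float) -> float:
    """Analytic mean of a Rician distribution with location ``nu`` and
    scale ``sigma`` (sigma * sqrt(pi/2) * L_{1/2}(-nu^2 / 2 sigma^2))."""
    if sigma <= 0:
        return float(nu)
    x = -(nu**2) / (2.0 * sigma**2)
    z = -x / 2.0
    laguerre_half = (1.0 - x) * ive(0, z) - x * ive(1, z)  # e^{x/2} folded into ive
    return float(sigma * math.sqrt(math.pi / 2.0) * laguerre_half)


def _add_blob(vox: np.ndarray, origin: np.ndarray, spacing: np.ndarray, centre: np.ndarray, sigma: float, amplitude: float) -> None:
    """Add an isotropic Gaussian blob (in place), evaluated within 4 sigma."""
    half = 4.0 * sigma
    lo = np.maximum(0, np.floor((centre - half - origin) / spacing).astype(int))
    hi = np.minimum(np.asarray(vox.shape), np.ceil((centre + half - origin) / spacing).astype(int) + 1)
    if np.any(hi <= lo):
        return
    ax = [origin[a] + spacing[a] * np.arange(lo[a], hi[a]) - centre[a] for a in range(3)]
    r2 = ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2 + ax[2][None, None, :] ** 2
    vox[lo[0]: hi[0], lo[1]: hi[1], lo[2]: hi[2]] += amplitude * np.exp(-r2 / (2.0 * sigma**2))


# -- marker-grid distortion phantom ---------------------------------------


@dataclass
class GridPhantomSpec:
    """Foam phantom with ~1,200 spherical markers on a regular grid.

    ``displacement_field`` maps an (n, 3) array of nominal positions to an
    (n, 3) array of displacements (mm); ``jitter_sd`` adds independent
    per-marker Gaussian jitter per axis on top of it.
    """

    grid_spacing: float = 14.0
    extent: tuple[int, int, int] = (11, 11, 10)
    marker_radius: float = 2.5
    marker_amplitude: float = 1000.0
    background: float = 0.0
    displacement_field: Callable[[np.ndarray], np.ndarray] | None = None
    jitter_sd: float = 0.0
    noise_sd: float = 0.0
    voxel_mm: float = 1.0
    margin_mm: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_mm > self.marker_radius:
            raise QAError("image spacing must not exceed the marker radius")

    def reference_grid(self) -> ReferenceGrid:
        return ReferenceGrid.regular(self.extent, self.grid_spacing)


def gen_grid_phantom(spec: GridPhantomSpec) -> tuple[ImageVolume, MarkerSet]:
    """Render the marker grid; ground truth records the exact blob centres
    (nominal + displacement + jitter) and flags markers pushed out of the
    imaged field."""
    rng = np.random.default_rng(spec.seed)
    grid = spec.reference_grid()
    ids, nominal = grid.as_arrays()

    disp = spec.displacement_field(nominal) if spec.displacement_field else np.zeros_like(nominal)
    if np.asarray(disp).shape != nominal.shape:
        raise QAError("displacement_field must return an (n, 3) array")
    jitter = rng.normal(0.0, spec.jitter_sd, nominal.shape) if spec.jitter_sd > 0 else 0.0
    true_centres = nominal + disp + jitter

    half_extent = (np.asarray(spec.extent) - 1) / 2.0 * spec.grid_spacing + spec.margin_mm
    origin = -half_extent
    shape = np.ceil(2.0 * half_extent / spec.voxel_mm).astype(int) + 1
    spacing = np.full(3, spec.voxel_mm)
    vox = np.full(tuple(shape), float(spec.background))

    sigma = spec.marker_radius / 2.0
    upper = origin + (shape - 1) * spacing
    out_of_field: set[int] = set()
    positions: dict[int, np.ndarray] = {}
    for mid, c in zip(ids.tolist(), true_centres):
        if np.any(c < origin + 2.0 * sigma) or np.any(c > upper - 2.0 * sigma):
            out_of_field.add(int(mid))
            continue
        positions[int(mid)] = c
        _add_blob(vox, origin, spacing, c, sigma, spec.marker_amplitude)
    if spec.noise_sd > 0:
        vox = add_rician_noise(vox, spec.noise_sd, rng)

    volume = ImageVolume(
        voxels=vox,
        spacing=tuple(spacing),
        origin=tuple(origin),
        modality=Modality.MR,
        meta={"series_description": "synthetic marker grid"},
    )
    truth = MarkerSet(positions=positions, out_of_field=out_of_field)
    return volume, truth


# -- PET-MR sphere alignment phantom --------------------------------------

DEFAULT_PET_SPHERES = (
    (0.0, 0.0, 0.0),
    (50.0, 50.0, 25.0),
    (-50.0, 50.0, -25.0),
    (-50.0, -50.0, 25.0),
    (50.0, -50.0, -25.0),
)


@dataclass
class VQCPhantomSpec:
    """Five PET spheres, each flanked by MR spheres at +/- an SI offset.

    ``true_misalignment`` is applied to the PET sphere positions (the PET
    frame), so the recovered MR-midpoints -> PET transform equals it.
    """

    pet_sphere_positions: Sequence[tuple[float, float, float]] = DEFAULT_PET_SPHERES
    mr_offset_si: float = 15.0
    true_misalignment: RigidTransform = field(default_factory=RigidTransform)
    centroid_noise_sd: float = 0.0
    mr_voxel_mm: float = 1.2
    pet_voxel_mm: float = 2.0
    mr_sphere_radius: float = 5.0
    pet_sphere_radius: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.pet_sphere_positions) != 5:
            raise QAError("the alignment phantom has exactly 5 PET spheres")
        if self.mr_offset_si <= 0:
            raise QAError("MR sphere SI offset must be positive")


def _render_spheres(centres: np.ndarray, radius: float, amplitude: float, voxel: float, pad: float, modality: Modality, meta: dict) -> ImageVolume:
    lo = centres.min(axis=0) - pad
    hi = centres.max(axis=0) + pad
    shape = np.ceil((hi - lo) / voxel).astype(int) + 1
    vox = np.zeros(tuple(shape))
    spacing = np.full(3, voxel)
    for c in centres:
        _add_blob(vox, lo, spacing, c, radius / 2.0, amplitude)
    return ImageVolume(voxels=vox, spacing=tuple(spacing), origin=tuple(lo), modality=modality, meta=meta)


def gen_vqc_phantom(spec: VQCPhantomSpec) -> tuple[ImageVolume, ImageVolume, RigidTransform]:
    """Render the MR (10 spheres) and PET (5 spheres) volumes; the returned
    transform is the true misalignment for recovery tests."""
    rng = np.random.default_rng(spec.seed)
    pet_nominal = np.asarray(spec.pet_sphere_positions, dtype=float)

    mr_centres = np.vstack(
        [pet_nominal + [0, 0, spec.mr_offset_si], pet_nominal - [0, 0, spec.mr_offset_si]]
    )
    pet_centres = spec.true_misalignment.apply(pet_nominal)
    if spec.centroid_noise_sd > 0:
        mr_centres = mr_centres + rng.normal(0.0, spec.centroid_noise_sd, mr_centres.shape)
        pet_centres = pet_centres + rng.normal(0.0, spec.centroid_noise_sd, pet_centres.shape)

    mr = _render_spheres(
        mr_centres, spec.mr_sphere_radius, 1000.0, spec.mr_voxel_mm, 15.0, Modality.MR,
        {"series_description": "synthetic alignment phantom MR"},
    )
    pet = _render_spheres(
        pet_centres, spec.pet_sphere_radius, 5000.0, spec.pet_voxel_mm, 15.0, Modality.PET,
        {"series_description": "synthetic alignment phantom PET", "units": "BQML"},
    )
    return mr, pet, spec.true_misalignment


# -- diffusion vial phantom ------------------------------------------------

DW_VIAL_CENTRES_X = (-40.0, 0.0, 40.0)


@dataclass
class DWVialSpec:
    """Three sealed liquid vials with mono-exponential diffusion signal."""

    vial_true_adc: tuple[float, float, float] = (0.7e-3, 1.2e-3, 1.7e-3)  # mm^2/s
    b_values: tuple[float, ...] = (50.0, 800.0)  # s/mm^2
    s0: float = 1000.0
    snr_b50: float | None = None  # Rician SNR on the lowest-b image; None = noiseless
    vial_radius: float = 15.0
    vial_length: float = 40.0
    voxel_mm: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        if np.any(b < 0) or np.any(np.diff(b) <= 0):
            raise QAError("b-values must be non-negative and strictly increasing")
        if 2.0 * self.vial_radius >= DW_VIAL_CENTRES_X[1] - DW_VIAL_CENTRES_X[0]:
            raise QAError("vials overlap at this radius")
        if len(self.vial_true_adc) != 3:
            raise QAError("three vials, three true ADCs")


def _dw_geometry(spec: DWVialSpec):
    half = np.array(
        [abs(DW_VIAL_CENTRES_X[0]) + spec.vial_radius + 10.0, spec.vial_radius + 10.0, spec.vial_length / 2.0 + 10.0]
    )
    shape = np.ceil(2.0 * half / spec.voxel_mm).astype(int) + 1
    origin = -half
    return origin, np.full(3, spec.voxel_mm), tuple(shape)


def dw_vial_masks(spec: DWVialSpec) -> list[np.ndarray]:
    """True cylinder masks (voxel centres) matching the generated grid."""
    origin, spacing, shape = _dw_geometry(spec)
    xs = origin[0] + spacing[0] * np.arange(shape[0])[:, None, None]
    ys = origin[1] + spacing[1] * np.arange(shape[1])[None, :, None]
    zs = origin[2] + spacing[2] * np.arange(shape[2])[None, None, :]
    masks = []
    for cx in DW_VIAL_CENTRES_X:
        m = ((xs - cx) ** 2 + ys**2 <= spec.vial_radius**2) & (np.abs(zs) <= spec.vial_length / 2.0)
        masks.append(np.broadcast_to(m, shape).copy())
    return masks


def gen_dw_vials(spec: DWVialSpec) -> list[ImageVolume]:
    """One volume per b-value: S(b) = s0 * exp(-b * ADC) in each vial, zero
    background, Rician noise at the configured SNR (noise SD derived from
    the mean in-vial signal of the lowest-b image)."""
    rng = np.random.default_rng(spec.seed)
    origin, spacing, shape = _dw_geometry(spec)
    masks = dw_vial_masks(spec)
    sigma = 0.0
    if spec.snr_b50 is not None and np.isfinite(spec.snr_b50):
        mean_b_low = spec.s0 * float(np.mean(np.exp(-spec.b_values[0] * np.asarray(spec.vial_true_adc))))
        sigma = mean_b_low / spec.snr_b50
    volumes = []
    for b in spec.b_values:
        vox = np.zeros(shape)
        for m, adc in zip(masks, spec.vial_true_adc):
            vox[m] = spec.s0 * math.exp(-b * adc)
        if sigma > 0:
            vox = add_rician_noise(vox, sigma, rng)
        volumes.append(
            ImageVolume(
                voxels=vox,
                spacing=tuple(spacing),
                origin=tuple(origin),
                modality=Modality.MR,
                meta={"b_value": float(b), "series_description": f"synthetic DW vials b={b:g}"},
            )
        )
    return volumes


# -- uniform PET cylinder --------------------------------------------------


@dataclass
class UniformPETSpec:
    concentration: float = 5000.0  # Bq/ml
    cylinder_radius: float = 110.0
    cylinder_length: float = 200.0
    centre: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_model: str = "gaussian"  # gaussian | scaled-poisson
    noise_scale: float = 0.0
    voxel_mm: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise QAError("concentration must be positive")
        if self.noise_model not in ("gaussian", "scaled-poisson"):
            raise QAError(f"unknown noise model {self.noise_model!r}")


def gen_uniform_pet(spec: UniformPETSpec) -> ImageVolume:
    """Uniform activity cylinder (SI axis) with seeded count-like noise:
    Gaussian of fixed SD, or Gaussian with variance proportional to the
    local mean ('scaled-poisson')."""
    rng = np.random.default_rng(spec.seed)
    c = np.asarray(spec.centre, dtype=float)
    half = np.array([spec.cylinder_radius + 15.0, spec.cylinder_radius + 15.0, spec.cylinder_length / 2.0 + 15.0])
    origin = c - half
    shape = tuple(np.ceil(2.0 * half / spec.voxel_mm).astype(int) + 1)
    spacing = np.full(3, spec.voxel_mm)
    xs = origin[0] + spacing[0] * np.arange(shape[0])[:, None, None]
    ys = origin[1] + spacing[1] * np.arange(shape[1])[None, :, None]
    zs = origin[2] + spacing[2] * np.arange(shape[2])[None, None, :]
    inside = ((xs - c[0]) ** 2 + (ys - c[1]) ** 2 <= spec.cylinder_radius**2) & (
        np.abs(zs - c[2]) <= spec.cylinder_length / 2.0
    )
    vox = np.where(inside, float(spec.concentration), 0.0)
    if spec.noise_scale > 0:
        if spec.noise_model == "gaussian":
            sd = np.full(shape, float(spec.noise_scale))
        else:
            sd = spec.noise_scale * np.sqrt(np.clip(vox, 0.0, None))
        vox = vox + rng.normal(0.0, 1.0, shape) * sd
    return ImageVolume(
        voxels=vox,
        spacing=tuple(spacing),
        origin=tuple(origin),
        modality=Modality.PET,
        meta={"units": "BQML", "series_description": "synthetic uniform PET cylinder"},
    )


# -- ACR-like image-quality phantom ---------------------------------------


@dataclass
class ACRSeriesSpec:
    """Synthetic ACR-like axial series with analytically known truth.

    The rendered layout matches :func:`petmr_qa.acr.ACRGeometryConfig.default`
    exactly.  Ramp bar lengths are derived from the true slice thickness
    (harmonic-mean formula inverted); wedge bar lengths from the true
    longitudinal slice-position offset.
    """

    pixel_mm: float = 0.5
    n_pix: int = 480
    n_slices: int = 5
    slice_spacing_mm: float = 5.0
    plateau: float = 1000.0
    insert_value: float = 100.0
    slice_thickness_mm: float = 5.0
    ramp_asymmetry_mm: float = 0.0
    slice_position_offset_mm: float = 0.0
    ghost_fraction: float = 0.0
    psf_sigma_mm: float = 0.0
    noise_sd: float = 0.0
    inplane_rotation_deg: float = 0.0
    hole_diameters: tuple[float, ...] = _acr.RES_DIAMETERS
    seed: int = 0

    def ramp_lengths(self) -> tuple[float, float]:
        t = self.slice_thickness_mm
        l_top = 10.0 * t + self.ramp_asymmetry_mm
        l_bot = t * l_top / (0.2 * l_top - t)
        return l_top, l_bot

    def truth(self) -> dict:
        return {
            "slice_thickness_mm": self.slice_thickness_mm,
            "slice_position_mm": self.slice_position_offset_mm,
            "piu_pct": 100.0 if self.noise_sd == 0 else None,
            "ghosting_pct": 100.0 * self.ghost_fraction,
        }


def _cov_interval(v: np.ndarray, lo: float, hi: float, px: float) -> np.ndarray:
    return np.clip((v - lo) / px + 0.5, 0.0, 1.0) * np.clip((hi - v) / px + 0.5, 0.0, 1.0)


def _paint(img: np.ndarray, cov: np.ndarray, value: float) -> np.ndarray:
    return img * (1.0 - cov) + value * cov


def gen_acr_phantom(spec: ACRSeriesSpec) -> tuple[ImageVolume, dict]:
    rng = np.random.default_rng(spec.seed)
    n, px = spec.n_pix, spec.pixel_mm
    coords = (np.arange(n) - (n - 1) / 2.0) * px
    x = coords[:, None]
    y = coords[None, :]
    th = math.radians(spec.inplane_rotation_deg)
    c, s = math.cos(th), math.sin(th)
    xp = c * x + s * y  # phantom-frame coordinates of each pixel
    yp = -s * x + c * y

    disk = np.clip((_acr.DISK_RADIUS - np.hypot(xp, yp)) / px + 0.5, 0.0, 1.0)

    def struct_slice() -> np.ndarray:
        img = _paint(np.zeros((n, n)), disk, spec.plateau)
        x0, x1, y0, y1 = _acr.RAMP_INSERT
        img = _paint(img, _cov_interval(xp, x0, x1, px) * _cov_interval(yp, y0, y1, px), spec.insert_value)
        l_top, l_bot = spec.ramp_lengths()
        for yc, length in zip(_acr.RAMP_BAR_Y, (l_top, l_bot)):
            cov = _cov_interval(xp, -length / 2.0, length / 2.0, px) * _cov_interval(
                yp, yc - _acr.RAMP_BAR_HALF_HEIGHT, yc + _acr.RAMP_BAR_HALF_HEIGHT, px
            )
            img = _paint(img, cov, spec.plateau)
        x0, x1, y0, y1 = _acr.WEDGE_INSERT
        img = _paint(img, _cov_interval(xp, x0, x1, px) * _cov_interval(yp, y0, y1, px), spec.insert_value)
        for xc, sign in zip(_acr.WEDGE_BAR_X, (1.0, -1.0)):
            length = _acr.WEDGE_BAR_BASE_LEN + sign * spec.slice_position_offset_mm
            cov = _cov_interval(xp, xc - _acr.WEDGE_BAR_HALF_WIDTH, xc + _acr.WEDGE_BAR_HALF_WIDTH, px) * _cov_interval(
                yp, _acr.WEDGE_BAR_BASE_Y, _acr.WEDGE_BAR_BASE_Y + length, px
            )
            img = _paint(img, cov, spec.plateau)
        hx, hy = _acr.RES_BLOCK_HALF
        for d, xc in zip(spec.hole_diameters, _acr.RES_BLOCK_X):
            cov = _cov_interval(xp, xc - hx, xc + hx, px) * _cov_interval(
                yp, _acr.RES_BLOCK_Y - hy, _acr.RES_BLOCK_Y + hy, px
            )
            img = _paint(img, cov, spec.insert_value)
            sigma0 = d / 2.355  # Gaussian dot with FWHM = hole diameter
            offs = (np.arange(4) - 1.5) * 2.0 * d
            for ox in offs:
                for oy in offs:
                    r2 = (xp - (xc + ox)) ** 2 + (yp - (_acr.RES_BLOCK_Y + oy)) ** 2
                    img = img + (spec.plateau - spec.insert_value) * np.exp(-r2 / (2.0 * sigma0**2))
        return img

    def uniform_slice() -> np.ndarray:
        return _paint(np.zeros((n, n)), disk, spec.plateau)

    z0 = -spec.slice_spacing_mm * (spec.n_slices - 1) / 2.0
    k_struct = int(round((_acr.Z_STRUCT - z0) / spec.slice_spacing_mm))
    k_uniform = int(round((_acr.Z_UNIFORM - z0) / spec.slice_spacing_mm))

    slices = []
    for k in range(spec.n_slices):
        img = struct_slice() if k == k_struct else uniform_slice()
        if spec.psf_sigma_mm > 0:
            img = ndimage.gaussian_filter(img, spec.psf_sigma_mm / px)
        if k == k_uniform and spec.ghost_fraction > 0:
            for name in ("top", "bottom"):
                (cx, cy), (a, b) = _acr.GHOST_ELLIPSES[name]
                mask = ((xp - cx) / a) ** 2 + ((yp - cy) / b) ** 2 <= 1.0
                img = img + spec.ghost_fraction * spec.plateau * mask
        if spec.noise_sd > 0:
            img = add_rician_noise(img, spec.noise_sd, rng)
        slices.append(img)

    vox = np.stack(slices, axis=2)
    volume = ImageVolume(
        voxels=vox,
        spacing=(px, px, spec.slice_spacing_mm),
        origin=(coords[0], coords[0], z0),
        modality=Modality.MR,
        meta={"series_description": "synthetic ACR-like phantom"},
    )
    return volume, spec.truth()


def gen_acr_like(t1_spec: ACRSeriesSpec | None = None, t2_spec: ACRSeriesSpec | None = None):
    """Generate a T1-like and a T2-like series (the T2 default differs only
    in overall signal level); returns ((t1_vol, t1_truth), (t2_vol, t2_truth))."""
    t1_spec = t1_spec or ACRSeriesSpec()
    if t2_spec is None:
        t2_spec = ACRSeriesSpec(plateau=700.0, insert_value=70.0, seed=t1_spec.seed + 1)
    return gen_acr_phantom(t1_spec), gen_acr_phantom(t2_spec)


# -- cross-plane laser phantom --------------------------------------------


def gen_cross_marks(
    offset: RigidTransform, noise_sd: float = 0.0, seed: int = 0, arm_mm: float = ARM_MM
) -> CrossMarkSet:
    """Mark set for a cross phantom at a true offset/rotation, with optional
    Gaussian marking noise per axis on all seven points."""
    rng = np.random.default_rng(seed)
    nominal = nominal_cross_points(arm_mm)
    marks = {k: offset.apply(v) for k, v in nominal.items()}
    if noise_sd > 0:
        marks = {k: v + rng.normal(0.0, noise_sd, 3) for k, v in marks.items()}
    centre = marks.pop("centre")
    return CrossMarkSet(centre=centre, axis_points=marks, source="manual")


def gen_cross_phantom(
    offset: RigidTransform,
    arm_mm: float = ARM_MM,
    voxel_mm: float = 1.0,
    rod_sigma_mm: float = 1.2,
    amplitude: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[ImageVolume, CrossMarkSet]:
    """Render three orthogonal 10 cm signal rods under a rigid offset; the
    truth mark set is the offset applied to the nominal 7 points."""
    rng = np.random.default_rng(seed)
    half = arm_mm + 12.0
    shape = int(math.ceil(2 * half / voxel_mm)) + 1
    origin = np.full(3, -half)
    spacing = np.full(3, voxel_mm)
    vox = np.zeros((shape, shape, shape))

    step = 0.4
    amp_per_sample = amplitude * step / (rod_sigma_mm * math.sqrt(2.0 * math.pi))
    ts = np.arange(-arm_mm, arm_mm + step / 2.0, step)
    for axis in range(3):
        e = np.zeros(3)
        e[axis] = 1.0
        pts = offset.apply(np.outer(ts, e))
        for p in pts:
            _add_blob(vox, origin, spacing, p, rod_sigma_mm, amp_per_sample)
    if noise_sd > 0:
        vox = add_rician_noise(vox, noise_sd, rng)

    volume = ImageVolume(
        voxels=vox,
        spacing=tuple(spacing),
        origin=tuple(origin),
        modality=Modality.MR,
        meta={"series_description": "synthetic cross-plane phantom"},
    )
    truth = gen_cross_marks(offset, noise_sd=0.0, arm_mm=arm_mm)
    return volume, truth
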