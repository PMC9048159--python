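"""DW-MR apparent-diffusion-coefficient accuracy.

The phantom is three sealed vials of pure alkanes (n-nonane, n-undecane,
n-tridecane) whose self-diffusion coefficients are known functions of
temperature, imaged with a diffusion-weighted sequence at two b-values
(50 and 800 s/mm² in routine use).  For a freely diffusing liquid the
signal is mono-exponential, S(b) = S0 · exp(-b · ADC), so two b-values
invert it exactly:

    ADC = ln(S_low / S_high) / (b_high - b_low)

Each vial is segmented automatically on the b=50 image (Otsu threshold,
connected components, one-voxel erosion against edge partial volume); the
vial value is the mean of the per-voxel ADC map over the eroded mask
(mean-of-ADCs rather than ADC-of-mean-signals — the two differ under
noise, and the per-voxel convention matches common analysis toolkits).
The reference ADC is linearly interpolated from a substance-specific
temperature table at the mean of the pre/post-scan phantom temperatures,
and the result is the percent difference from that reference.

A multi-b log-linear least-squares fit is also provided for validation
acquisitions with many b-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core import ImageVolume, QAError

__all__ = [
    "ReferenceADCTable",
    "ADCResult",
    "SUBSTANCES",
    "default_reference_table",
    "segment_vials",
    "compute_adc",
    "fit_adc_multib",
    "reference_adc",
    "adc_report",
]

SUBSTANCES = ("nonane", "undecane", "tridecane")


@dataclass
class ReferenceADCTable:
    """Substance -> ordered (temperature °C, ADC mm²/s) pairs."""

    entries: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        for name, (temps, adcs) in self.entries.items():
            temps = np.asarray(temps, dtype=float)
            adcs = np.asarray(adcs, dtype=float)
            if temps.size < 2:
                raise QAError(f"reference table for {name} needs >= 2 temperature points")
            if np.any(np.diff(temps) <= 0):
                raise QAError(f"reference temperatures for {name} must strictly increase")
            if np.any(adcs <= 0):
                raise QAError(f"non-positive reference ADC for {name}")
            self.entries[name] = (temps, adcs)

    @staticmethod
    def from_yaml(path: str | Path) -> "ReferenceADCTable":
        raw = yaml.safe_load(Path(path).read_text())
        return ReferenceADCTable.from_dict(raw)

    @staticmethod
    def from_dict(raw: dict) -> "ReferenceADCTable":
        entries = {}
        for name, pairs in raw.items():
            if name.startswith("_"):
                continue  # comment keys
            arr = np.asarray(pairs, dtype=float)
            entries[str(name)] = (arr[:, 0], arr[:, 1])
        return ReferenceADCTable(entries=entries)


def default_reference_table() -> ReferenceADCTable:
    """The packaged alkane ADC-vs-temperature table.

    The shipped values are approximations assembled from published alkane
    self-diffusion data; sites should replace the YAML with their own
    literature-traceable table (same format).
    """
    with resources.files("petmr_qa").joinpath("data/alkane_adc.yaml").open("r") as fh:
        return ReferenceADCTable.from_dict(yaml.safe_load(fh))


@dataclass
class ADCResult:
    per_vial: list[dict]  # substance, measured, reference, percent_difference, n_voxels
    temp_pre: float
    temp_post: float
    warnings: list[str] = field(default_factory=list)

    @property
    def temp_mean(self) -> float:
        return 0.5 * (self.temp_pre + self.temp_post)


# -- segmentation ----------------------------------------------------------


def segment_vials(b50: ImageVolume, expected: int = 3, min_frac_of_largest: float = 0.25) -> list[np.ndarray]:
    """Segment the vials on the b=50 image.

    Otsu threshold, connected components, keep the ``expected`` largest
    plausible components (>= ``min_frac_of_largest`` of the largest), erode
    each by one voxel.  Exactly ``expected`` plausible components are
    required.  Masks are returned ordered by RL (x) centroid so that they
    line up with the configured substance order.
    """
    vox = np.asarray(b50.voxels, dtype=float)
    thr = threshold_otsu(vox)
    labels, n = ndimage.label(vox > thr)
    if n == 0:
        raise QAError("no vial-like components above the Otsu threshold")
    sizes = ndimage.sum_labels(np.ones_like(vox), labels, index=np.arange(1, n + 1))
    plausible = np.flatnonzero(sizes >= min_frac_of_largest * sizes.max()) + 1
    if len(plausible) != expected:
        raise QAError(
            f"expected {expected} vials, found {len(plausible)} plausible components "
            f"(sizes {sorted(sizes.tolist(), reverse=True)[:5]})"
        )
    masks = []
    for lab in plausible:
        m = ndimage.binary_erosion(labels == lab)
        if not m.any():
            raise QAError(f"vial component {lab} vanished under erosion")
        masks.append(m)
    order = np.argsort([ndimage.center_of_mass(m)[0] for m in masks])
    return [masks[i] for i in order]


# -- ADC estimation --------------------------------------------------------


def _check_same_grid(a: ImageVolume, b: ImageVolume) -> None:
    if a.shape != b.shape or not np.allclose(a.spacing, b.spacing) or not np.allclose(a.origin, b.origin):
        raise QAError("b-value volumes do not share a grid")


def compute_adc(b_low: ImageVolume, b_high: ImageVolume, masks: list[np.ndarray]) -> list[dict]:
    """Per-vial mean of the per-voxel two-point ADC map (mm²/s).

    Voxels with a non-positive signal on either image are excluded and
    counted; a vial with no usable voxels is a failure.
    """
    _check_same_grid(b_low, b_high)
    try:
        bl, bh = float(b_low.meta["b_value"]), float(b_high.meta["b_value"])
    except KeyError as e:
        raise QAError("b-value metadata missing") from e
    if bh <= bl:
        raise QAError(f"need b_high > b_low, got {bl} and {bh}")
    s_low = np.asarray(b_low.voxels, dtype=float)
    s_high = np.asarray(b_high.voxels, dtype=float)
    out = []
    for m in masks:
        valid = m & (s_low > 0) & (s_high > 0)
        n_excl = int(m.sum() - valid.sum())
        if not valid.any():
            raise QAError("all voxels excluded in a vial (non-positive signals)")
        adc = np.log(s_low[valid] / s_high[valid]) / (bh - bl)
        out.append({"adc": float(adc.mean()), "n_voxels": int(valid.sum()), "n_excluded": n_excl})
    return out


def fit_adc_multib(volumes: list[ImageVolume], masks: list[np.ndarray]) -> list[dict]:
    """Log-linear least-squares ADC over many b-values (validation mode).

    Fits ln(mean vial signal) against b; the slope magnitude is the ADC.
    """
    if len(volumes) < 3:
        raise QAError("multi-b fit needs >= 3 b-values")
    for v in volumes[1:]:
        _check_same_grid(volumes[0], v)
    bvals = np.array([float(v.meta["b_value"]) for v in volumes])
    if np.any(np.diff(np.sort(bvals)) <= 0):
        raise QAError("duplicate b-values")
    out = []
    for m in masks:
        means = np.array([float(np.asarray(v.voxels)[m].mean()) for v in volumes])
        if np.any(means <= 0):
            raise QAError("non-positive mean vial signal")
        slope, intercept = np.polyfit(bvals, np.log(means), 1)
        out.append({"adc": float(-slope), "s0": float(np.exp(intercept)), "n_b": len(bvals)})
    return out


# -- reference interpolation and reporting ---------------------------------


def reference_adc(
    table: ReferenceADCTable, substance: str, temperature_c: float, extrapolate: bool = False
) -> float:
    """Piecewise-linear interpolation of the reference ADC at a temperature.

    Refuses to extrapolate outside the tabulated range unless
    ``extrapolate`` is set, in which case the end segments are extended
    linearly (and the caller should warn).
    """
    if substance not in table.entries:
        raise QAError(f"no reference entry for {substance!r}; have {sorted(table.entries)}")
    temps, adcs = table.entries[substance]
    if not extrapolate and not (temps[0] <= temperature_c <= temps[-1]):
        raise QAError(
            f"temperature {temperature_c:.1f} °C outside reference range "
            f"[{temps[0]:.1f}, {temps[-1]:.1f}] for {substance} (pass extrapolate=True to extend)"
        )
    if temperature_c < temps[0]:
        slope = (adcs[1] - adcs[0]) / (temps[1] - temps[0])
        return float(adcs[0] + slope * (temperature_c - temps[0]))
    if temperature_c > temps[-1]:
        slope = (adcs[-1] - adcs[-2]) / (temps[-1] - temps[-2])
        return float(adcs[-1] + slope * (temperature_c - temps[-1]))
    return float(np.interp(temperature_c, temps, adcs))


def adc_report(
    measured: list[dict],
    substances: tuple[str, ...],
    table: ReferenceADCTable,
    temp_pre_c: float,
    temp_post_c: float,
    extrapolate: bool = False,
) -> ADCResult:
    """Percent difference of each vial's measured ADC from the reference
    evaluated at the mean of the pre/post temperatures."""
    if len(measured) != len(substances):
        raise QAError(f"{len(measured)} vials but {len(substances)} substances")
    warnings = []
    if abs(temp_pre_c - temp_post_c) > 1.0:
        warnings.append(
            f"pre/post temperatures differ by {abs(temp_pre_c - temp_post_c):.1f} °C — "
            "phantom may not have been equilibrated"
        )
    t_mean = 0.5 * (temp_pre_c + temp_post_c)
    per_vial = []
    for m, sub in zip(measured, substances):
        ref = reference_adc(table, sub, t_mean, extrapolate=extrapolate)
        pct = 100.0 * (m["adc"] - ref) / ref
        per_vial.append(
            {
                "substance": sub,
                "measured_adc": m["adc"],
                "reference_adc": ref,
                "percent_difference": pct,
                "n_voxels": m.get("n_voxels", 0),
            }
        )
    return ADCResult(per_vial=per_vial, temp_pre=temp_pre_c, temp_post=temp_post_c, warnings=warnings)
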