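"""PET-MR alignment from a sphere phantom.

The alignment phantom holds five low-activity PET spheres, each flanked by
one MR-visible sphere superior and one inferior at equal offsets, so that
the midpoint of each MR pair coincides with its PET sphere by design.  The
analysis:

1. detects the sphere centroids on each modality (blob maxima with
   sub-voxel intensity-weighted centroids),
2. pairs the MR spheres along SI by mutual nearest neighbour and takes
   pair midpoints,
3. rigidly registers the five MR midpoints onto the five PET centroids
   (closed-form least squares, rotation via SVD with det +1 enforced),

and reports the six-DOF transform (MR midpoints -> PET frame) plus the
residual RMS.  Translations and Euler angles follow the package convention
(see :mod:`petmr_qa.core`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import ImageVolume, Modality, QAError, RigidTransform

__all__ = ["SphereDetections", "AlignmentResult", "kabsch", "detect_spheres", "midpoints", "register", "align_session"]


@dataclass
class SphereDetections:
    modality: Modality
    centroids: np.ndarray  # (n, 3) world mm
    intensities: np.ndarray = field(default_factory=lambda: np.zeros(0))
    radii: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __len__(self) -> int:
        return len(self.centroids)


@dataclass
class AlignmentResult:
    transform: RigidTransform  # maps MR midpoints onto PET centroids
    residual_rms: float
    n_points: int

    def to_dict(self) -> dict:
        d = self.transform.to_dict()
        d.update(residual_rms_mm=self.residual_rms, n_points=self.n_points, direction="MR-midpoints -> PET")
        return d


# -- closed-form rigid least squares --------------------------------------


def kabsch(source: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid fit mapping ``source`` onto ``target``.

    Returns ``(R, t, rms)`` minimising ``sum ||R s_i + t - t_i||^2`` with
    ``det(R) = +1`` (reflections are never returned).  Raises on fewer than
    three points or a collinear/degenerate source configuration.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 3:
        raise QAError("point sets must both be (n, 3)")
    n = src.shape[0]
    if n < 3:
        raise QAError("rigid registration needs at least 3 point pairs")
    sc, tc = src.mean(axis=0), tgt.mean(axis=0)
    s0, t0 = src - sc, tgt - tc
    # collinearity check: second singular value of the centred cloud
    sv = np.linalg.svd(s0, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise QAError("degenerate (collinear) point configuration")
    h = s0.T @ t0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = tc - r @ sc
    resid = src @ r.T + t - tgt
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return r, t, rms


# -- sphere detection ------------------------------------------------------


def _refine_centroid(volume: ImageVolume, index: np.ndarray, window_mm: float, iters: int = 3) -> tuple[np.ndarray, float]:
    """Iterated intensity-weighted centroid in a box window around ``index``
    (voxel units); returns (fractional index, peak intensity)."""
    vox = np.asarray(volume.voxels, dtype=float)
    half = np.maximum(1, np.round(window_mm / np.asarray(volume.spacing)).astype(int))
    centre = np.asarray(index, dtype=float)
    peak = 0.0
    for _ in range(iters):
        lo = np.maximum(0, np.round(centre).astype(int) - half)
        hi = np.minimum(np.asarray(vox.shape), np.round(centre).astype(int) + half + 1)
        sub = vox[lo[0]: hi[0], lo[1]: hi[1], lo[2]: hi[2]]
        w = np.clip(sub, 0.0, None)
        total = w.sum()
        if total <= 0:
            raise QAError("empty centroid window")
        grids = np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij")
        centre = np.array([float((g * w).sum() / total) for g in grids])
        peak = float(sub.max())
    return centre, peak


def detect_spheres(
    volume: ImageVolume,
    expected_count: int,
    min_separation_mm: float = 15.0,
    threshold_frac: float = 0.5,
    smooth_mm: float = 2.0,
    window_mm: float = 8.0,
) -> SphereDetections:
    """Detect exactly ``expected_count`` bright spheres, or fail.

    Local maxima of a lightly smoothed image above ``threshold_frac`` of the
    smoothed maximum, non-maximum suppressed at ``min_separation_mm``, then
    refined to sub-voxel intensity-weighted centroids.
    """
    vox = np.asarray(volume.voxels, dtype=float)
    sigma_vox = smooth_mm / np.asarray(volume.spacing)
    sm = ndimage.gaussian_filter(vox, sigma=sigma_vox)
    size = np.maximum(3, np.round(min_separation_mm / np.asarray(volume.spacing)).astype(int) | 1)
    local_max = (sm == ndimage.maximum_filter(sm, size=tuple(size))) & (sm > threshold_frac * sm.max())
    # symmetric blobs can tie across adjacent voxels: one candidate per plateau
    labels, n_lab = ndimage.label(local_max)
    cand = np.asarray(
        np.round(ndimage.center_of_mass(local_max, labels, index=np.arange(1, n_lab + 1))), dtype=int
    ).reshape(-1, 3)
    if len(cand) != expected_count:
        raise QAError(
            f"expected {expected_count} spheres but found {len(cand)} candidates "
            f"at threshold {threshold_frac:.2f}: {cand.tolist()[:12]}"
        )
    centroids, intens = [], []
    for c in cand:
        idx, peak = _refine_centroid(volume, c, window_mm)
        centroids.append(volume.voxel_to_world(idx).to_array())
        intens.append(peak)
    order = np.lexsort(np.array(centroids).T[::-1])  # stable order: by x, y, z
    return SphereDetections(
        modality=volume.modality,
        centroids=np.array(centroids)[order],
        intensities=np.array(intens)[order],
    )


# -- MR pair midpoints -----------------------------------------------------


def midpoints(mr: SphereDetections, max_pair_sep_mm: float = 40.0, max_xy_mm: float = 10.0) -> np.ndarray:
    """Midpoints of the five sup/inf MR sphere pairs.

    Pairs are mutual nearest neighbours in the transverse (xy) plane among
    detections separated along SI by at most ``max_pair_sep_mm``; ambiguous
    (non-mutual) pairings fail.
    """
    pts = np.asarray(mr.centroids, dtype=float)
    n = len(pts)
    if n % 2 != 0:
        raise QAError(f"need an even number of MR spheres to pair, got {n}")
    partner = np.full(n, -1)
    for i in range(n):
        best, best_d = -1, np.inf
        for j in range(n):
            if j == i:
                continue
            dz = abs(pts[i, 2] - pts[j, 2])
            dxy = float(np.hypot(pts[i, 0] - pts[j, 0], pts[i, 1] - pts[j, 1]))
            if dz == 0 or dz > max_pair_sep_mm or dxy > max_xy_mm:
                continue
            if dxy < best_d:
                best, best_d = j, dxy
        partner[i] = best
    mids = []
    used = set()
    for i in range(n):
        j = partner[i]
        if j < 0 or partner[j] != i:
            raise QAError(f"ambiguous SI pairing for MR sphere {i} at {pts[i]}")
        if i in used:
            continue
        used.update((i, j))
        mids.append(0.5 * (pts[i] + pts[j]))
    return np.array(mids)


# -- registration ----------------------------------------------------------


def register(mr_midpoints: np.ndarray, pet_centroids: np.ndarray) -> AlignmentResult:
    """Six-DOF rigid fit of MR pair midpoints onto PET sphere centroids.

    Correspondence is established by nearest neighbour (the phantom design
    keeps misalignments far below the sphere grid spacing).
    """
    mr = np.asarray(mr_midpoints, dtype=float)
    pet = np.asarray(pet_centroids, dtype=float)
    if len(mr) != len(pet):
        raise QAError(f"point count mismatch: {len(mr)} MR midpoints vs {len(pet)} PET centroids")
    # order-insensitive correspondence
    d2 = np.sum((mr[:, None, :] - pet[None, :, :]) ** 2, axis=2)
    corr = np.argmin(d2, axis=1)
    if len(set(corr.tolist())) != len(pet):
        raise QAError("could not establish one-to-one MR/PET sphere correspondence")
    r, t, rms = kabsch(mr, pet[corr])
    return AlignmentResult(transform=RigidTransform.from_matrix(r, t), residual_rms=rms, n_points=len(mr))


def align_session(mr_volume: ImageVolume, pet_volume: ImageVolume, n_pet: int = 5) -> AlignmentResult:
    """Full pipeline: detect spheres on both modalities, pair, register."""
    pet_det = detect_spheres(pet_volume, expected_count=n_pet)
    mr_det = detect_spheres(mr_volume, expected_count=2 * n_pet)
    mids = midpoints(mr_det)
    return register(mids, pet_det.centroids)
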