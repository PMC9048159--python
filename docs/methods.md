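# Methods

This note documents the models, conventions and numerical choices behind
the analyses and the synthetic phantom generators, and what the test suite
does and does not demonstrate about real scanner data.

## Coordinate and rotation conventions

All geometry lives in the DICOM patient frame (LPS), distances in mm, with
the scanner isocentre as world origin.  Axis naming is RL = x, AP = y,
SI = z.  Rotations: pitch about RL, roll about SI, yaw about AP, composed
extrinsically in the order pitch → roll → yaw (scipy Euler sequence
`xzy`).  No consensus convention exists for reporting phantom rotations in
QA practice, so this one is fixed once and every report that prints angles
embeds the convention string.  Voxel indices are 0-based and map to voxel
centres; world↔voxel round trips are exact to well below 1e-6 mm (tested
over random orthonormal orientations).

## DICOM ingestion and the fixture writer

`load_series` builds a volume from one directory of single-frame slices:
mixed SeriesInstanceUIDs, missing geometry tags, and slice-gap variation
above 1% are hard rejections; rescale slope/intercept are applied;
b-values, PET units and acquisition time are lifted into metadata.  The
fixture writer emits minimal valid Explicit-VR files so generated phantoms
can exercise the same ingestion path.  Integer-valued volumes round-trip
bit-exactly; other data is linearly quantised to 16 bits (relative error
≤ span/32000), which is far below every analysis tolerance here.

## Synthetic phantoms

Generators return in-memory volumes plus exact ground truth and are
seed-deterministic.  Design choices:

* **Blobs, not hard spheres.**  Markers and spheres render as isotropic
  Gaussians with σ = radius/2.  Sub-voxel centroid detection is then
  well-conditioned and partial-volume behaviour controlled; the vendor
  optics that determine real marker profiles are not modelled.
* **Noise models.**  MR magnitude noise is Rician (magnitude of complex
  Gaussian); its analytic mean (via the Laguerre-½ form with
  exponentially scaled Bessel functions) is unit-tested against sampling,
  and bias at SNR ≥ 20 is below 1%.  PET noise is Gaussian with fixed or
  intensity-proportional variance — reconstructed PET noise is not
  Poisson, so true Poisson sampling is deliberately not the default
  (selectable per spec).
* **Desk scale.**  Default grids stay near or below 160³ voxels so the
  whole suite runs in well under a minute per study: the marker grid is
  11×11×10 markers at 14 mm pitch on 1 mm isotropic voxels (1,210 markers,
  matching the physical phantom's ~1,200); the ACR-like phantom is 5
  axial slices at 0.5 mm in-plane; DW vials use 2 mm voxels; the PET
  cylinder 4 mm voxels.
* **What is not simulated:** MR relaxation and EPI distortion, PET
  sinogram/reconstruction physics, attenuation, and scanner drift.
  Passing recovery tests therefore demonstrates correctness of the
  *analysis* under controlled truth — not robustness to every real-world
  artefact.  The physical low-contrast ACR sub-test remains a manual
  observation by design.

The ACR generator and the default analysis config share one layout
(constants in `petmr_qa.acr`), with features rendered through linear-edge
anti-aliasing so that half-maximum crossings sit on exact geometric edges;
ramp bar lengths are derived by inverting the harmonic-mean thickness
formula, wedge bars by the factor-2 offset-to-length rule.

## Analysis choices

* **Marker detection** (grid phantom): difference-of-Gaussians band-pass,
  plateau-collapsed local maxima, then three iterations of
  intensity-weighted centroid over a ±2·radius window.  ID assignment runs
  an ICP-style loop (nearest-nominal match → rigid fit → re-match) so a
  coarse phantom placement error cannot scramble ids; candidates further
  than half the grid pitch from any nominal position are dropped, ties
  keep the brighter blob, and a session finding fewer than half the
  expected markers fails hard.
* **Setup-error removal**: distortion is the residual after a six-DOF fit
  of detected→nominal markers restricted to markers within 10 cm of the
  isocentre, where true distortion is smallest.  This makes the metric
  invariant to phantom placement (tested under random ≤5 mm / ≤2°
  motions); distance-to-isocentre uses the *measured* position; shell
  edges are lower-inclusive.  Sample SD (n−1 denominator) is used in every
  longitudinal statistic; with n = 3 repeats the denominator materially
  matters, so it is fixed and documented here.
* **Rigid registration**: closed-form least squares (centroid demeaning,
  SVD, det +1 enforcement).  Tests cross-check it against brute-force
  Nelder-Mead minimisation of the same cost, verify reflection-freedom on
  adversarial clouds, and confirm the s/√k translation-noise law by Monte
  Carlo.  The reported transform maps MR midpoints onto PET centroids
  (direction stated in the output).
* **Cross-plane rotations** use the two-point secant angle of each ± mark
  pair — the estimator that manual ±5 cm marking actually supports —
  with the cyclic assignment pitch ← AP-pair SI-deviation, yaw ← SI-pair
  RL-deviation, roll ← RL-pair AP-deviation, signs matching the package's
  rotation matrices.  Automatic marking follows each ridge outward with
  transverse re-centring; the centre uses an iterated local centroid at
  the triple-rod overlap (point-symmetric, hence unbiased up to window
  truncation, ~0.1–0.2 mm at 1 mm voxels).
* **ADC** is the mean of the per-voxel two-point map over each eroded
  Otsu-segmented vial (mean-of-ADCs, not ADC-of-mean-signal; the two
  differ under noise and the per-voxel convention matches common analysis
  toolkits).  Voxels with non-positive signal are excluded and counted.
  Temperature is the mean of the pre/post readings; interpolation is
  piecewise linear with extrapolation refused unless explicitly enabled.
  A multi-b log-linear fit is provided for validation acquisitions.  The
  shipped alkane reference table is an approximation assembled from
  published self-diffusion data (~2%/°C around room temperature) and is
  explicitly replaceable per site; synthetic studies compare against
  configured true ADCs, so no shipped value enters a computed result.
* **SUV** uses mass/activity normalisation so a uniform phantom has
  reference SUV exactly 1; decay correction references scan start, with
  the residual syringe activity decayed from its own assay time.  The ROI
  is a centred 18×18 cm cylinder of voxel centres with strict boundary
  inequalities (an inclusive test would capture a whole extra voxel plane
  whenever the grid aligns with a face) and must lie ≥99% inside the
  phantom support.
* **Resolution scoring** replaces visual inspection with a trough/peak
  criterion: a hole line is resolved when every inter-hole trough is below
  0.7× its adjacent peaks (cubic-interpolated samples at known hole
  positions; the threshold is configurable because the visual criterion it
  replaces has no unique numeric equivalent).
* **Trend screening** (OLS slope vs session index, flag at |slope| > 2 SE)
  is labelled a screening aid: the underlying programme judged monthly
  trends from plots, and the 2-SE rule is a heuristic whose null flag rate
  (~5% at 30 sessions) is verified by simulation.

## Repeatability studies (scripts/acceptance.py)

Each study generates three repeat sessions — one fixed truth, independent
noise — and summarises the full-pipeline outputs by sample SD:

1. **Geometric**: fixed quadratic radial distortion field (3 mm at
   117 mm) plus independent 0.2 mm/axis marker jitter; statistic: mean
   per-marker SD over the markers common to all three sessions.
2. **ADC**: true ADCs 0.7/1.2/1.7 ×10⁻³ mm²/s, b = 50 and 800 s/mm²,
   Rician SNR 50 on the b=50 image; statistic: max over vials of the SD of
   the percent difference from the configured truth.
3. **Alignment**: true misalignment (0.5, 0.3, 0.2) mm and 0.1° pitch,
   0.05 mm/axis centroid noise; statistic: max translation-component SD.
4. **Mechanical**: true yaw 0.5°, 0.1 mm/axis marking noise on all seven
   points; statistic: SD of the recovered yaw.

Session seeds are fixed small integers offset deterministically by the
`--seed` argument.  The noise levels are the study conditions, chosen to
represent careful phantom work (sub-voxel centroiding, SNR-50 diffusion
images); they are not tuned per run.

## Known limitations

* Analyses assume axis-aligned axial volumes for the ACR and region-based
  steps; oblique acquisitions are rejected rather than resampled.
* Overlapping blobs contaminate each other's centroids (no joint fitting);
  the grid pitch keeps real markers well separated, so this only affects
  pathological inputs.
* The distortion/vendor separation of setup error from distortion is this
  package's own definition (near-isocentre rigid fit); other software may
  define it differently, so absolute shell means are comparable only under
  the same convention.
* The resolution criterion's 0.7 threshold, the Otsu vial segmentation and
  the 0.5 support threshold for PET centroiding are heuristics with
  configurable parameters; defaults were chosen on the synthetic phantoms
  and should be reviewed against real series before clinical use.
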