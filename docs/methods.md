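# Methods

## Problem and scope

Navigated 3D intraoperative ultrasound (iUS) is used during brain-tumor
surgery to visualize tumor before resection and residual tumor afterwards,
with intraoperative MRI (iMRI) as the reference standard. Validating iUS
quantitatively requires (1) bringing iUS and MRI segmentations into one
coordinate frame through the rigid transforms exported by the navigation
system, (2) spatial agreement metrics on the aligned binary masks, and
(3) cohort-level statistics: diagnostic accuracy of the residual-tumor call,
correlation and agreement of volume measurements, and extent of resection.
`navseg` implements that pipeline, plus a synthetic phantom generator so every
stage is testable without patient data.

## Coordinate conventions

All spatial metadata is in millimetres in the DICOM patient-based LPS frame.
NIfTI affines (RAS) are converted to LPS on read by negating the first two
world axes, and back on write. Voxel indices are 0-based and address voxel
*centers*, matching DICOM `ImagePositionPatient` semantics. Image arrays are
indexed `(slice, row, column)`; a grid's direction matrix stores the world
unit vector of each array axis in its columns and must be orthonormal within
1e-6 (vendor metadata is rounded; tighter tolerances reject real exports).

DICOM series carry no explicit stacking direction, so the slice normal and
inter-slice spacing are derived from successive `ImagePositionPatient`
values when a series is read, and are an explicit sign parameter when an
affine is built from raw geometry attributes.

## Transforms and resampling

Rigid world-to-world mappings are 4x4 homogeneous matrices with an
orthonormal, det(+1) rotation block; registration chains are composed into a
single source-to-destination matrix before any image is touched, so each mask
is interpolated exactly once. Masks are resampled with nearest-neighbour
interpolation only — partial-volume labels would make the set-based metrics
(Dice, Hausdorff) ill-defined — and voxels pulled from outside the source
extent become background. Scalar images may use linear interpolation.

The destination grid is a choice the data does not force. The default is the
MRI grid (the registration target); the US grid is available as an option.
Nearest-neighbour round trips lose a sub-voxel shell at the mask surface:
for masks whose linear size is >= ~14 voxels the loss stays below 1% of the
foreground, which is the regime the pipeline's property tests check.

## Masks and the cyst-exclusion rule

Volumes are foreground voxel count x voxel volume, reported in cm^3.
Connected components use 26-connectivity by default (standard for 3D lesion
masks; 6 and 18 are available). Fluid-filled cysts are not solid tumor, so
before agreement metrics a segmentation drops every connected component that
is (a) majority-cystic — more than 50% of its voxels carry the cyst label,
an operational reading of "solitary cystic component" — and (b) strictly
larger than 2 cm^3. Cyst labels are inputs (ground truth in phantoms, manual
annotation otherwise); the package does not detect cysts from intensities.
The operation is idempotent and never increases volume.

## Agreement metrics

* **DSC** = 2|A∩B| / (|A|+|B|) on voxel counts; both masks must share a grid,
  and two empty masks raise an undefined-metric error rather than returning a
  sentinel (the analysis only compares pairs where both modalities segmented
  tissue).
* **Hausdorff distances**: Euclidean distances in world mm (anisotropic
  spacing honored) from every foreground voxel center in one mask to the
  nearest in the other; using all voxels rather than only boundary voxels
  follows the "every point in one volume" definition, and a surface-only
  option exists for comparison. The two directed distance sets are pooled
  into one multiset; HD_max is its maximum and HD95 its 95th percentile with
  linear interpolation between order statistics (the percentile convention
  used everywhere in the package, so results are bit-stable). Two
  implementations exist: a Euclidean distance transform on the complement
  grid (fast path) and an all-pairs brute force; both compute voxel-center
  distances and are tested to agree exactly on small masks.
* **Volume difference**: signed (a−b) and absolute, cm^3; extents may differ
  but spacings must match.
* **Interpretation flags**: DSC in [0.7, 0.9] is "good similarity" and
  HD95 < 10 mm "clinically relevant", the thresholds used in intraoperative
  imaging practice; sensitivity and specificity above 80% count as good
  diagnostic value.

## Cohort statistics

Diagnostic accuracy counts only records flagged evaluable with a known
ultrasound call; sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), each
raising an undefined-metric error only when its own denominator is empty.
Summaries are median and IQR with linear-interpolation quartiles. Volume
pairs get a Pearson r and an OLS line (reference MRI regressed on
ultrasound; the orientation is recorded in the result). Bland–Altman
differences are ultrasound minus MRI with first/third-quartile limits rather
than 1.96·SD — volume differences in these cohorts are heavy-tailed, and
quartile limits match how such plots are drawn in this literature. Extent of
resection is (preop − residual)/preop·100 with the MRI residual volume; a
residual exceeding the preop volume warns but is reported as-is.

Age SD defaults to the population form (divisor n): on the bundled
24-patient table it reproduces the conventional one-decimal summary (3.9),
while the sample form gives 4.0; the divisor is an explicit option.

The bundled example cohort (`navseg/data/example_cohort.csv`) is a
24-patient pediatric brain-tumor table with per-patient ultrasound calls
chosen to realize a 10 TP / 0 FN / 2 FP / 11 TN split on 23 evaluable
patients; which negatives carry the false positives is arbitrary and does not
affect any statistic. Residual volumes are deliberately absent — they are
exercised with synthetic data.

## Synthetic phantoms

`PhantomSpec` defaults define the study conditions: tumor volumes drawn
log-uniformly over 0.35–107 cm^3 and residual volumes over 0.90–7.95 cm^3,
residual-disease prevalence 10/23, MRI grid 1 mm isotropic, ultrasound grid
0.24 x 0.24 mm in-plane with 1 mm slices, rigid misregistration up to 5
degrees and 5 mm, cyst probability 0.2 (0.5–6 cm^3), and a false-positive
artifact probability of 2/13 for residual-negative cases.

Tumor masks are unions of 3–7 random ellipsoids chained so each center lies
inside its parent (hence connected); a global scale factor found by bisection
drives the achieved volume within 2% of target. The grid is sized to the
target volume with a 12 mm margin, capped at a 256 mm field of view.

The observed segmentation adds a smooth unit-variance Gaussian field
(correlation length 5 mm) scaled by `boundary_noise_mm` to the truth's signed
distance and rethresholds, taking exactly the top-k voxels so the volume bias
is hit exactly (ties on distance plateaus break deterministically by index).
Zero noise and zero bias return the truth unchanged. The default boundary
noise of 4 mm was calibrated once so that a default phantom cohort lands at
median DSC ≈ 0.70 — the regime reported for navigated ultrasound against MRI
— and is not adjusted per experiment. No quantitative model of real
ultrasound segmentation error underlies this choice; the generator reproduces
the regime, not the mechanism.

Injected cysts are placed with a gap of 3 mm + 2x the boundary noise from the
tumor so they remain solitary components after perturbation. Each case's
truth record stores the generative parameters and the DSC/HD95 obtained by
re-registering the observation with the true transform and applying cyst
exclusion — exactly the pipeline's measurement, so truth records and pipeline
output are consistent by construction.

Cohort generation derives per-case seeds from the master seed via
`numpy.random.SeedSequence([master, index])` (recorded in the table) and has
two modes: a volumes-only mode, where paired volumes follow a statistical
noise model (used for large-n parameter recovery, e.g. n = 200, and for
record tables), and a render mode that builds full 3D cases (used at small n;
rendering hundreds of ultrasound-resolution volumes is not a desk-scale
computation). `simulate_volume_pairs` draws MRI volumes log-uniformly and
adds a bias plus Gaussian noise whose variance is set from the sample
variance to realize a chosen Pearson correlation.

What the phantoms do **not** emulate: ultrasound physics (speckle,
attenuation, shadowing), tracked-sweep reconstruction, deformable brain
shift, observer variability in manual segmentation, and the intensity
characteristics of either modality (rendered intensities are visual QC only;
no metric reads them). Passing tests therefore demonstrate the correctness
and calibration behaviour of the *analysis*, not the clinical performance of
ultrasound.

## Numerical choices and degenerate inputs

* Percentiles/quartiles: linear interpolation, everywhere.
* Orthonormality tolerances: 1e-6 (metadata); rigidity verified to 1e-9 in
  tests.
* Empty masks: undefined-metric errors for DSC (both empty) and Hausdorff
  (either empty); the volume of an empty mask is 0.
* Cyst threshold: strict `> 2 cm^3`.
* Composition of an empty transform list: error, not identity.
* Resampling clips to the source extent; nothing wraps.

## Problem sizes

Default test and acceptance runs use phantoms of 1–25 cm^3 on 1 mm grids,
Hausdorff oracle checks on masks of <= 500 voxels, round-trip checks on 14^3
cubes, rendered phantom cohorts of ~9 cases, and statistical cohorts of
n = 200 — sizes chosen so the full suite is a coffee-break computation while
still exercising every code path at realistic anisotropies.

## Known limitations

* Rigid transforms only; brain shift between iUS and iMRI is exactly what a
  rigid model cannot capture, and the package does not estimate transforms at
  all — they are inputs.
* The Hausdorff convention (all voxel centers, pooled directions) is one of
  several in use; surface-only and per-direction variants can differ by a few
  voxel diagonals on coarse grids. Options are exposed.
* The majority-vote reading of "solitary cystic component" is a convention;
  other operationalizations (e.g. topological separation from an enhancing
  rim) would need cyst labels of a different kind.
* Extent of resection uses MRI volumes; if ultrasound residual volumes are
  preferred, compute it from those fields explicitly.
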