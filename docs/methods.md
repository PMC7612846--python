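# Methods

`wmatlas` implements the construction and validation of a probabilistic
white matter tract atlas from per-subject streamline bundles, together with
the statistical machinery used to compare atlases and groups. This note
documents the models, numerical choices and their rationale, what the
synthetic cohort generator does and does not emulate, and known
limitations.

## Atlas model

A tract is delineated in each subject by *virtual dissection*: streamlines
from a whole-brain tractogram belong to the tract iff they pass through all
of its inclusion regions and none of its exclusion regions. Queries are
boolean expressions over named ROI masks (ALL / ANY / NOT), which covers
both the standard two-waypoint protocols and the fornix protocol (body AND
(left limb OR right limb)). After transforming the dissected streamlines to
a common template space, every voxel visited by at least one streamline is
marked, giving a binary tract mask per subject; the voxelwise mean of these
masks across the atlas cohort is the probability map. By construction every
probability is k/n for integer k.

Group intensity templates are voxelwise means (aDWI, FA). Diffusion tensors
are averaged componentwise ("scalar averaging" of the six independent
elements) after reorientation by the rotational part of each subject's
affine (polar decomposition of the linear part; shears and scales do not
reorient). The group FA image follows from the averaged tensor's
eigenvalues, FA = sqrt(3/2)·‖λ − mean λ‖ / ‖λ‖, with negative eigenvalues
(possible after averaging noisy tensors) clamped to zero and the output
clipped to [0, 1].

## Geometry conventions and exact voxel traversal

World space is RAS millimetres; voxel indices are 0-based; a world point
belongs to the voxel whose index is round(inv(affine)·p) (voxel-centre
convention). Points mapping outside a grid are dropped, not errors, since
whole-brain tractograms legitimately exceed ROI grids.

Streamline–voxel membership (for both ROI queries and voxelisation) is
computed by *exact traversal*: each polyline segment's crossings of the
half-integer voxel-boundary planes are solved analytically in continuous
voxel coordinates, and the voxel between consecutive crossings is the
rounded midpoint. An earlier draft resampled segments at half the minimum
voxel edge; that is provably insufficient — a segment can clip a voxel
corner for an interval shorter than any fixed step — whereas the analytic
traversal is step-free, resolution-independent and identical to resampling
at an arbitrarily fine step. Voxels grazed exactly on a boundary plane
(a measure-zero event) resolve by the rounding rule.

## Validation measurements

* **Dice curves.** For thresholds θ (default 0.05…1.00 in steps of 0.05;
  the sweep granularity is configurable) the Dice score
  2|A∩B|/(|A|+|B|) is computed between {P ≥ θ} and the subject-specific
  mask; an empty thresholded atlas against a non-empty subject mask scores
  0. The peak over θ summarises each tract/subject.
* **Probability-weighted FA.** FA = Σᵢ FAᵢPᵢ / ΣᵢPᵢ over the full,
  unthresholded map. Subject-specific ("gold standard") FA is the plain
  mean over the mask; the two coincide when P is binary.
* **Slice profiles.** Mean FA per slice perpendicular to the tract's major
  axis — coronal (y) for tracts projecting anterior/posterior, axial (z)
  for dorsal/ventral ones. The axis is part of each tract definition; the
  default assignment puts only the CST on the axial axis and, because a
  Y-shaped body-plus-limbs tract is predominantly vertical, the fornix as
  well. Atlas slice values apply the weighted-FA formula restricted to the
  slice; no threshold is applied for FA sampling.

## Statistics

* **QC score.** Each movement/distortion metric is z-scored across
  participants (sample SD; zero-variance columns contribute 0), the score
  is the RMS of the z-scores, and a participant is rejected iff their score
  exceeds the cohort mean by more than one SD. "Normalised" is interpreted
  as z-scoring; any numeric metric table is accepted.
* **Repeated-measures correlation.** ANCOVA with per-unit intercepts and a
  common slope; equivalently, x and y are centred within unit and
  r = Σxᶜyᶜ/√(Σxᶜ²·Σyᶜ²) with df = N − k − 1 for N records and k units and
  a two-sided p from the t distribution. The sign convention follows the
  common slope (the ANOVA ratio is unsigned). The reported best-fit line
  (m, c) is the pooled OLS fit to all records, as conventionally plotted.
  Units are subjects; records are tracts (whole-tract analysis) or slices
  (slice-wise analysis).
* **Atlas comparison.** Differences of Fisher-z-transformed correlations,
  Δz = atanh r₁ − atanh r₂, with percentile-bootstrap 95% CIs. For the
  whole-tract analysis the resampling unit is the subject (records within a
  subject move together, respecting their dependence). For slice series a
  moving-block bootstrap resamples overlapping blocks of consecutive slices
  within each subject (default block length ⌈√L⌉), concatenated and
  truncated to the series length, with the same block draw applied to the
  gold standard and both atlas series to preserve pairing. Defaults:
  n_boot = 2000, α = 0.05, all configurable. Replicates with degenerate
  data are dropped; more than 10% dropped is an error.
* **Peak-Dice comparison.** Two-tailed paired t per tract.
* **Group comparison.** Two-sided Mann-Whitney U per tract on whole-tract
  FA; the exact null distribution for tie-free groups with min(n₁,n₂) ≤ 8,
  the tie-corrected normal approximation otherwise (FA values rarely tie,
  but synthetic fixtures may). Bonferroni m defaults to the number of tract
  tests actually run; significance is corrected p < 0.05.

### Bootstrap calibration and its limits

The null coverage of the percentile CI was verified by simulation with the
noise level set so each "atlas" correlates with the gold standard at
r ≈ 0.7 (the whole-tract level this pipeline targets) and 100 subjects —
a regime where cluster-bootstrap theory predicts near-nominal coverage, so
the check isolates the implementation. There the bootstrap SD matches the
true sampling SD to within 1% and coverage is 93–96%. At realistic
validation cohort sizes (8–15 subjects) the percentile bootstrap *itself*
undercovers by roughly 2–3 percentage points (true coverage ≈ 92% at 15
units); this is a documented property of cluster bootstraps with few
units, not an implementation artefact, and CIs from small cohorts should
be read with that in mind. Under AR(1) slice noise (ρ = 0.8) the
moving-block bootstrap's coverage clearly dominates naive single-slice
resampling (≈ 85% vs ≈ 60% at 8 subjects × 40 slices), which is the reason
the block scheme is used for the spatially dependent slice-wise analysis.

## Synthetic cohorts

The generator produces cohorts with analytic ground truth; tubes of 3 mm
radius around parametric curves (lines, quadratic arcs, and a Y-shaped
body-plus-limbs tract exercising the ANY query) stand in for anatomy on a
44×40×40 grid of 2 mm voxels. No attempt is made at realistic brains: the
point is that every downstream quantity has a known true value.

* **Bundles.** Each tract carries a deterministic canonical bundle: 19
  streamlines per leg at fixed ring offsets (radii 0, 0.5 r, 0.9 r) carried
  along the centreline in a reference-vector frame. Determinism is what
  makes atlas recovery exact in the noiseless case.
* **Layout.** Tracts are placed so that every tract carrying a case effect
  keeps ≥ 14 mm centreline clearance from every non-designated tract.
  The margin is deliberate: painted FA regions (tube radius + half the
  voxel diagonal) and atlas supports must stay disjoint under affine
  jitter, residual registration error and interpolation smoothing,
  otherwise a designated tract's FA offset bleeds into a neighbour's
  measurement and contaminates the group comparison (this failure mode was
  observed with a 10.8 mm clearance and motivated the layout).
* **Subjects.** A random similarity jitter (rotation SD 3°, translation SD
  2 mm, isotropic scale SD 3% about the volume centre) maps the template to
  each subject; its exact inverse is stored as the subject→template
  transform. A second, smaller uncompensated affine (0.5°, 0.4 mm, 0.5%)
  emulates registration error — it is what makes Dice < 1 and atlas FA
  imperfect, as in real data; it is sized to keep the transform round-trip
  error below half a voxel RMS. With jitter and noise disabled a subject is
  an exact copy of the template with an identity transform.
* **FA and tensors.** FA = 0.15 background plus per-tract means
  (0.36–0.58) painted on each tract's padded tube support, plus a
  per-(subject, tract) offset ~ N(0, 0.012) (between-subject biological
  variation) and voxelwise N(0, 0.05) noise, truncated to keep FA in
  [0, 0.99]. Tensors are axially symmetric, oriented along the local
  centreline tangent, with the eigenvalue ratio solved in closed form so
  the per-voxel FA of the tensor equals the painted FA exactly — the FA
  and tensor channels are mutually consistent by construction.
* **Cohort design.** Defaults mirror the emulated study: 28 atlas + 8
  validation controls (together the 36-strong control group) and 33 cases,
  with a −0.03 FA case effect on four designated tracts (CG, CH, SLF,
  fornix). An effect of 0.03 against a 0.012 between-subject SD is the
  regime where tract-level FA differences are realistically detectable at
  these group sizes.
* **Fast FA tables.** `sample_fa_table` draws whole-tract FA directly from
  the generative model the imaging pipeline measures (tract mean +
  between-subject offset + voxel-noise mean over the support), which is
  how the power and family-wise-error properties are simulated at 100+
  repetitions without re-running image segmentation each time. One full
  imaging-pipeline run verifies separately that the pipeline's significant
  set equals the designated set.

What passing tests on these cohorts shows: the geometry, averaging,
measurement and statistical code chains are correct, calibrated and
recover known truth. What they do not show: robustness to real anatomy
(crossing fibres, partial voluming, nonlinear deformation), scanner noise
models, or tractography failure modes — streamline generation, DWI signal
simulation and registration estimation are all outside the package's
scope (transforms are inputs; only their application is implemented).

## Numerical and design choices

* Problem sizes in the test-suite simulations (e.g. 20 noiseless subjects
  for exact recovery, 200 simulated datasets × 500 bootstrap replicates
  for calibration, 100 repetitions for the power property) are chosen to
  make each check statistically decisive at desk scale.
* Probability maps are exact rationals k/n by integer counting before a
  single division.
* The comparison ("adult-stand-in") atlas in the pipeline is the
  age-specific probability map translated by one voxel in x and y: same
  topology, systematically displaced support — the qualitative failure
  mode an atlas built from a mismatched population exhibits.
* Scalar resampling through affines uses trilinear interpolation
  (`scipy.ndimage.affine_transform`), clipped back to [0, 1] for FA.
* TCK is the canonical streamline format (world mm, read/write); TRK is
  accepted read-only. NIfTI volumes round-trip data at float32 and the
  affine exactly. Tensor NIfTIs store the six components in
  lower-triangular order (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz).
* Group FA templates are emitted unmasked (no brain mask is applied).
* Pipeline outputs are deterministic given the seed and configuration;
  `summary.json` records the package version, seed and a configuration
  hash so reruns are byte-identical.

## Known limitations

* Tensor reorientation is implemented for affine transforms only (rotation
  by the polar factor); nonlinear reorientation is out of scope, matching
  the affine atlas-construction path.
* Percentile CIs from cohorts of 8–15 subjects undercover slightly (see
  calibration section); the moving-block bootstrap shares the same
  small-sample behaviour.
* The exact Mann-Whitney path requires tie-free data; ties fall back to
  the tie-corrected normal approximation regardless of group size.
* The synthetic generator's affine jitter cannot represent the nonlinear
  component of inter-subject anatomical variability; validation metrics on
  synthetic cohorts are therefore optimistic relative to real data.
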