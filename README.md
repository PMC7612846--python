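# wmatlas

Tools for building and validating **probabilistic white matter tract
atlases** from per-subject streamline bundles, aimed at diffusion-MRI
studies of cohorts — in particular paediatric cohorts, where registering to
an adult atlas misrepresents developing anatomy and an age-specific atlas
is needed.

The package implements the full analysis chain around such an atlas:

1. **Virtual dissection** — select the streamlines of a named tract from a
   whole-brain tractogram with boolean ROI queries: a streamline belongs to
   the tract iff it passes through *all* inclusion ROIs and *no* exclusion
   ROIs. Queries are ALL/ANY/NOT expression trees, which also covers
   protocols like the fornix (body AND (left limb OR right limb)).
2. **Atlas construction** — transform dissected streamlines to a template
   grid, mark every voxel containing a streamline (binary mask per
   subject), and average masks across subjects into per-voxel tract
   probabilities P ∈ {0, 1/n, …, 1}. Group aDWI/FA templates come from
   voxelwise averaging; group tensors from componentwise ("scalar")
   averaging after rotating each subject's tensors by the rigid part of
   their affine, with group FA from the averaged tensor's eigenvalues:
   FA = √(3/2) · ‖λ − λ̄‖ / ‖λ‖.
3. **Validation against subject-specific tracts** — Dice overlap
   2|A∩B|/(|A|+|B|) of the thresholded atlas {P ≥ θ} over a threshold
   sweep (with paired t-tests on peak Dice); probability-weighted FA

       FA = Σᵢ FAᵢ · Pᵢ / Σᵢ Pᵢ

   compared with the mask-mean FA of the subject's own tract, both
   whole-tract and slice-by-slice along each tract's major axis; agreement
   quantified by the **repeated-measures correlation** (ANCOVA with
   per-subject intercepts; r between within-subject residuals,
   df = N − k − 1); and atlas-vs-atlas comparison via differences of
   Fisher-z-transformed correlations, Δz = atanh r₁ − atanh r₂, with
   percentile-bootstrap CIs (subjects resampled as units) and a
   moving-block bootstrap for spatially dependent slice series.
4. **QC and group comparison** — the movement/distortion rejection rule
   (z-score metrics, RMS per subject, reject above mean + 1 SD) and
   tract-wise case/control comparison of whole-tract FA by two-sided
   Mann-Whitney U with Bonferroni correction.
5. **Synthetic cohorts** — a generator producing cohorts of subjects, each
   carrying 12 named tract bundles (tubes around parametric curves,
   including a Y-shaped fornix-like tract) with known per-tract FA,
   mutually consistent FA/tensor volumes, affine jitter with stored
   inverse transforms, and a designated case/control FA offset — so every
   stage above is testable against analytic ground truth without any
   imaging data. See `docs/methods.md` for what the generator does and
   does not emulate.

## Worked example

Simulate a small cohort (8 atlas, 8 validation, 16 case subjects), run the
whole pipeline, and read the results:

```python
import json
from wmatlas.synthetic_cohort import CohortSpec, make_cohort
from wmatlas.cli_io import PipelineConfig, run_pipeline

spec = CohortSpec(n_atlas=8, n_validation=8, n_cases=16, seed=42)
make_cohort(spec, "demo_cohort")
cfg = PipelineConfig(cohort_dir="demo_cohort", out_dir="demo_results",
                     n_boot=500, seed=42)
results = run_pipeline(cfg)
print(json.dumps(results, indent=2, default=str))
```

which prints (after a QC log line rejecting 6 high-movement subjects):

```
{
  "n_atlas": 7,
  "n_validation": 6,
  "mean_peak_dice_age": 0.8772480233568241,
  "mean_peak_dice_alt": 0.6800402842331139,
  "rm_r_age": 0.9800009932633695,
  "rm_r_alt": 0.9278125050416526,
  "zdiff": 0.6551478125201111,
  "zdiff_ci": [
    0.08973402151012065,
    1.539148752741557
  ],
  "slice_zdiff_mean": 0.5556070005499385,
  "significant_tracts": [
    "CG",
    "CH",
    "SLF"
  ]
}
```

Reading these numbers: the atlas built from the cohort overlaps
subject-specific tracts at a mean peak Dice of 0.88, versus 0.68 for a
deliberately misregistered comparison atlas (the probability maps shifted
by one voxel, standing in for a mismatched-population atlas). Whole-tract
FA sampled through the atlas correlates with gold-standard subject FA at
r = 0.98 vs 0.93 for the comparison atlas; the z-transformed difference
+0.66 has a bootstrap 95% CI [0.09, 1.54] excluding zero, so the cohort's
own atlas is measurably better. The case/control comparison flags CG, CH
and SLF — three of the four tracts carrying the simulated −0.03 FA
deficit (the fornix misses the Bonferroni threshold at these small group
sizes; at the default 33-vs-36 design all four are flagged).

Per-tract tables (`dice_curves.tsv`, `whole_tract_fa.tsv`, `slice_fa.tsv`,
`group_comparison.tsv`, …) and a `summary.json` with the seed and a
configuration hash are written to the output directory. The same run is
available from the shell:

    wmatlas simulate demo_cohort --seed 42 --n-atlas 8 --n-validation 8 --n-cases 16
    wmatlas run-all demo_cohort demo_results --seed 42

Subcommands `qc`, `segment`, `build-atlas`, `validate` and
`compare-groups` expose the individual stages.

## File formats

* Streamlines: TCK (read/write, world mm); TRK read-only.
* Volumes: NIfTI-1, any affine; tensors as 4-D NIfTI with six components
  in lower-triangular order (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz).
* Affines: 4×4 whitespace-separated text, mapping subject world mm to
  template world mm. Voxel coordinates in result tables are 0-based.
* Tract definitions: JSON per tract —
  `{"name", "major_axis", "laterality", "query": {"all": [...], "any": [...], "not": ...}}`
  with leaf strings naming ROI mask files.

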