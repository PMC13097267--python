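# Methods

## Model and procedure

The pipeline quantifies extraocular-muscle (EOM) heterogeneity from paired
water and fat signal-intensity volumes by a four-way intensity partition
("habitats") and evaluates longitudinal volumetric change as a marker of
glucocorticoid treatment response.

**Thresholding.** The analysis assumes one global intensity threshold per
channel is meaningful across the cohort, i.e. that scanner and protocol
are fixed so signal intensities are comparable between subjects. All
in-mask voxels of all subjects are pooled into a 256-bin equal-width
histogram per channel spanning the pooled [min, max]; the Otsu criterion
picks the cut maximizing between-class variance. Conventions, fixed for
determinism:

- the threshold is reported as a **bin edge** (upper edge of the last
  "low" bin), making binarization independent of within-bin interpolation;
- a voxel is high iff intensity **strictly exceeds** the threshold;
- variance ties resolve to the **smallest** threshold. Ties are compared
  with a relative tolerance of 1e-12 because cuts inside a run of empty
  bins are mathematically tied yet accumulate different floating-point
  rounding. A corollary worth knowing: when the two intensity classes are
  perfectly separated (empty gap in the histogram), the criterion is
  constant across the gap and the reported threshold sits at the gap's low
  edge, not its middle. The induced classification is identical either way.

By default the voxel pool spans **both time points** of every subject, so
pre and post maps are comparable under one ThresholdPair; per-timepoint
pooling is available via configuration (`pooling="per_timepoint"`).

**Partition and features.** Water binary × fat binary → LL/HL/LH/HH; the
four habitats partition the mask exhaustively, so habitat volumes sum to
the whole-muscle volume exactly in voxel counts, and VPs sum to 100.
Volumes are voxel count × voxel volume (mm³→mL). Δ = post − pre;
Δ% = (post−pre)/pre × 100, recorded as missing (NaN) when pre = 0 and
excluded pairwise downstream. Δ% of a VP is computed on the VP values
themselves, not re-derived from volumes. Masks merge both orbits; features
are bilateral totals, matching one-value-per-patient reporting.

**Geometry.** The fat channel is resampled onto the water grid (linear)
and masks nearest-neighbor when grids differ; water is the delineation
reference. Grid agreement is tested with a 1e-4 mm tolerance on spacing
and origin because NIfTI headers store float32.

## Statistics

- Group comparisons are gated by Shapiro–Wilk at α = 0.05 in **every**
  group: Student's t (equal variances, mean ± SD summaries) when all pass,
  Mann–Whitney U (median/IQR summaries) otherwise. Constant-valued groups
  route to the nonparametric branch rather than erroring.
- χ² is Pearson's, no continuity correction.
- ICC is the two-way random-effects, absolute-agreement, single-measure
  form (ICC(2,1)) with the McGraw & Wong F-based 95% CI, implemented
  directly so degenerate inputs behave by contract: duplicated ratings give
  exactly 1 with CI (1,1); zero between-subject variance is an error.
- Correlations are Pearson/Spearman under the same normality gate; |r|
  bands step at 0.40 / 0.60 / 0.80.
- The marker combination is an unpenalized maximum-likelihood logistic
  model; its fitted probability is the combined score. Singular designs or
  perfect separation fall back to a gradient fit and are flagged
  non-converged. The combined model reports no cutoff, since a probability
  cutoff is not in feature units.
- ROC: AUC as the concordance fraction with half credit for ties (equal to
  the trapezoidal empirical area); 95% CI by DeLong; orientation
  auto-chosen so AUC ≥ 0.5 and reported as a direction operator ('>' when
  larger scores indicate response, '≤' otherwise); the cutoff is the
  observed score maximizing the Youden index, ties resolved toward higher
  specificity. Evaluation is in-sample; no cross-validation and no
  multiple-testing correction anywhere, by design.

## Synthetic phantoms

The generator emulates what the pipeline needs to be validated — not MRI
physics. An ellipsoidal "muscle" on a 48×48×15 grid at (0.625, 0.625, 3.6)
mm (15 thick slices echo a coronal orbital acquisition; the default mask is
~4.5 mL, the scale of bilateral EOM volumes) is split into contiguous
class compartments by largest-remainder rounding of prescribed fractions;
sub-voxel fractions may round to zero voxels, as a real muscle can lack a
habitat. Channel intensities are class means — defaults LL (30,30),
HL (80,30), LH (30,80), HH (80,80) arbitrary units — plus seeded Gaussian
noise (SD 5, i.e. 10 SDs of class separation), clipped at zero. A "mixed"
layout assigns classes voxelwise for threshold stress-tests.

Remodeling archetypes set pre/post fractions and a whole-volume factor.
The defaults are normalized group-median VPs of the clinical pattern the
package targets: responders 0.50/0.38/0.07/0.05 → 0.68/0.12/0.16/0.04
(LL/HL/LH/HH) with volume factor 0.90; non-responders
0.74/0.155/0.09/0.015 → 0.86/0.055/0.08/0.005 with factor 1.14. Cohort
variation: Dirichlet jitter of fractions (concentration 2/jitter², default
jitter 0.15), lognormal jitter of the volume factor (σ = jitter/3) and of
baseline size (σ = 2·jitter).

What the phantoms do **not** model: partial-volume averaging, bias fields,
chemical-shift artifacts, registration error, anatomically realistic
muscle shapes, or intensity non-comparability across subjects. Passing
recovery tests therefore demonstrates correctness of the partition,
feature, and statistical machinery under the stated intensity model — not
clinical segmentation accuracy on real orbits.

## Numerical and design choices

- 256 histogram bins: classical Otsu practice; phantom recovery is
  insensitive at the default separation.
- Bin-edge thresholds + strict '>' make `binarize` reproduce the histogram
  split exactly and deterministically.
- No morphological cleanup of habitat maps.
- Per-patient failures during cohort runs are collected and reported
  together with patient ids; any failure aborts the run.
- Every run artifact carries a configuration hash; stages refuse to
  consume artifacts produced under a different configuration.
- Determinism: all randomness flows through numpy Generators seeded from
  explicit integers; identical seed + configuration reproduces
  byte-identical feature tables and file hashes.
- Problem sizes in the validation suite (20+20 end-to-end cohorts, 100
  phantoms for recovery, 100 patients per archetype for directionality,
  1,000 histogram / ROC oracle instances) were chosen to make sampling
  statements stable at desk scale.

## Known limitations

- Cohorts too small for the logistic combination (fewer than 10
  observations per feature) fall back to single-marker ROC reporting with
  an explanatory note.
- The Otsu criterion cannot separate fibrosis from treated-but-quiescent
  muscle: both are low-water/low-fat, and the LL habitat conflates them.
- DeLong CIs and Wald p-values are asymptotic; they are reported even at
  small n where exact methods would differ.
- With per-timepoint threshold pooling, longitudinal Δs mix two threshold
  definitions; the default cohort pooling avoids this.
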