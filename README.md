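# eomhabitat

Water–fat **habitat imaging** of the extraocular muscles (EOMs) in thyroid
eye disease (TED), as a tested, reusable Python pipeline.

In active moderate-to-severe TED the EOMs remodel heterogeneously —
inflammatory edema, fatty infiltration (myosteatosis), and fibrosis coexist
within one muscle — and that heterogeneity tracks the response to
intravenous glucocorticoid (IVGC) therapy. Water–fat separation MRI (e.g.
IDEAL) yields co-registered water and fat signal-intensity images, so each
muscle voxel can be classified by where it sits in the (water, fat)
intensity plane:

| habitat | water SI | fat SI | reading                      |
|---------|----------|--------|------------------------------|
| LL      | low      | low    | inactive / fibrosis-like     |
| HL      | high     | low    | edema                        |
| LH      | low      | high   | myosteatosis                 |
| HH      | high     | high   | water–fat interface          |

## Method

1. **Cohort thresholds.** All in-mask muscle voxels from every subject (and
   both time points) are pooled into one 256-bin histogram per channel. A
   single Otsu threshold *t* is derived per channel — the cut maximizing the
   between-class variance σ²_B(t) = ω₀ω₁(μ₀−μ₁)², equivalently minimizing
   the within-class variance. A voxel is "high" iff its intensity is
   strictly greater than *t*; ties in the variance scan resolve to the
   smallest threshold.
2. **Partition.** Binarizing water and fat at their thresholds and crossing
   the two binary maps partitions every muscle voxel into exactly one of
   LL/HL/LH/HH.
3. **Features.** Per patient and time point: whole-muscle volume (mL), each
   habitat's volume, and its volume percentage VP = volume/whole × 100.
   Longitudinal change per feature: Δ = post − pre and
   Δ% = (post − pre)/pre × 100 (missing when pre = 0).
4. **Statistics.** Shapiro–Wilk-gated group comparisons (Student's t vs
   Mann–Whitney U), Pearson χ² for categorical tables, ICC(2,1) with an
   F-based 95% CI for repeatability, normality-gated Pearson/Spearman
   correlations with |r| bands (poor < 0.40 ≤ moderate < 0.60 ≤ good <
   0.80 ≤ excellent), unpenalized logistic combination of markers, and ROC
   analysis: concordance AUC with DeLong 95% CI and the observed-score
   cutoff maximizing the Youden index (sensitivity + specificity − 1).

Because no patient images ship with the analysis, a **synthetic phantom
module** generates water/fat volume pairs, masks and longitudinal cohorts
with planted habitat composition and remodeling archetypes (responders:
edema shrinks, myosteatosis grows, whole muscle shrinks; non-responders:
whole muscle and the LL compartment grow), so every stage is validated
against known ground truth.

## Worked example

```bash
python examples/02_longitudinal_remodeling.py
```

```
whole volume: pre 4.47 mL -> post 3.95 mL
  delta = -0.51 mL (-11.5%)
                 edema VP:  38.00% ->  11.98%   (delta -26.02 points)
          myosteatosis VP:   6.99% ->  16.00%   (delta +9.01 points)
inactive/fibrosis-like VP:  50.00% ->  67.99%   (delta +17.99 points)
```

One simulated treatment responder: the whole muscle shrinks by 11.5%, the
edema habitat loses 26 VP points while the myosteatosis habitat gains 9 —
the volumetric signature of edema resolving into fatty remodeling. The
measured values match the planted archetype to within voxelization, since
the class means sit 10 noise-SDs apart.

The other examples cover single-phantom habitat recovery
(`01_phantom_and_habitats.py`), full-cohort marker evaluation with ROC
(`03_cohort_response_markers.py`), and ICC repeatability
(`04_reproducibility_icc.py`).

A thin CLI mirrors the stages:

```bash
eomhabitat simulate --n-responsive 10 --n-unresponsive 10 --seed 1 --out-dir cohort/
eomhabitat run-all --manifest cohort/manifest.csv --out-dir run/
```

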