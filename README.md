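# histogate

Attention-gated quantification of histopathological features from panoptic
segmentation of H&E whole-slide images (WSIs), with a classifier bank,
model-agnostic importance aggregation, progressive feature selection and
survival stratification.

## The problem

In high-grade serous ovarian carcinoma (HGSC) treated with neoadjuvant
chemotherapy, the progression-free interval (PFI) after platinum therapy
separates resistant (PFI < 180 days, "short") from sensitive
(PFI > 365 days, "long") disease. Attention-based multiple-instance-learning
(MIL) models predict this response from WSIs and point, through their
attention heatmaps, at small informative tissue regions — but attention
alone does not say *which* histologic features carry the signal. This
package implements the interpretable downstream half of such a pipeline for
computational-pathology researchers: it takes panoptic segmentation output
(typed nuclei and tissue regions), a patch-level attention map and clinical
outcomes, and turns them into a ranked, survival-validated set of
human-readable features.

## Method

1. **Gating.** Patches with attention score in [0.2, 1.0] form the attended
   mask; cells are gated by centroid membership, regions by geometric
   clipping.
2. **Quantification.** 69 spatially aware features per slide (attended
   region and/or whole slide): nuclear morphometry from analytic polygon
   moments — eccentricity e = √(1 − (b/a)²), major axis 2a of the ellipse
   of equal second moments — box-counting fractal dimension of nuclear
   outlines, stromal areas with a tumor–stroma-interface partition (band
   within d = 100 px of tumor vs distal stroma), and graph-based
   neighborhood statistics (radius graph at 112 px bandwidth; per-type
   counts, fractions, Simpson diversity 1 − Σ p²).
3. **Classification.** A bank of standard classifiers under patient-grouped,
   label-stratified 3-fold CV (random state 42); models with AUC > 0.8 and
   per-class F1 > 0.8 are retained.
4. **Importance aggregation.** Per retained model × fold: native
   importances, Monte-Carlo Shapley attributions and local linear-surrogate
   attributions; rankings pooled by robust rank aggregation
   (Beta order-statistic scores, exactly null-calibrated), features then
   added progressively until the cross-validated AUC stops improving (elbow
   rule, ε = 0.005).
5. **Survival.** Kaplan–Meier / log-rank for predicted classes vs overall
   survival and per-feature median splits vs PFI.

Because clinical WSI cohorts with linked outcomes are rarely shareable, the
package ships a synthetic-cohort generator that emulates all three inputs
and plants known class effects in seven headline features (tumor-cell
eccentricity, major axis, fractal dimension; stromal cell count and
proportion; total and distal stromal area) — by default only inside the
attended region, so the attended-vs-whole-slide contrast is testable.
See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
from histogate import CohortConfig, PipelineConfig, run_pipeline

config = PipelineConfig(synthetic=CohortConfig(seed=7), seed=42)
report = run_pipeline(config)

print(f"slides: {len(report.attended_fractions)}")
print(f"mean attended fraction: "
      f"{100 * sum(report.attended_fractions.values()) / len(report.attended_fractions):.1f}%")
print("retained models:", report.retained_models)
print("attended AUC (retained mean): "
      f"{report.provenance_deltas['retained_mean_attended']:.3f}")
print("whole-slide AUC (retained mean): "
      f"{report.provenance_deltas['retained_mean_whole_slide']:.3f}")
print("selected k:", report.elbow_k)
print("selected features:", report.selected_features)
```

prints

```
slides: 100
mean attended fraction: 10.0%
retained models: ['logistic_regression', 'random_forest', 'xgboost']
attended AUC (retained mean): 0.976
whole-slide AUC (retained mean): 0.657
selected k: 4
selected features: ['mean_fractal_dimension_neoplastic', 'proportion_connective_cells',
 'max_eccentricity_neoplastic', 'distal_stromal_area']
```

Read: the attention gate keeps ~10% of patches; classifiers trained on
attended-region features clearly beat the same classifiers on whole-slide
features (the planted signal sits in the attended region and is diluted
elsewhere); the selected set is drawn from the planted tumor-morphology and
stromal-architecture effects — on this cohort realization four of them
already saturate the cross-validated AUC, so the elbow stops there.

The same pipeline runs from the shell:

```bash
histogate simulate --seed 7 --out cohort/          # write a synthetic cohort
histogate run-all --synthetic-seed 7 --out run/    # or run end-to-end
histogate run-all --segmentation-dir seg/ --attention-dir att/ \
    --clinical-table clinical.csv --out run/       # on real inputs
```

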