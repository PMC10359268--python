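# haemorasis

Automated detection, morphometric characterization and
disease-association analysis of blood cells in digitized peripheral
blood slides (PBS).

Peripheral blood smears carry diagnostic signal for myelodysplastic
syndromes (MDS) and anemias — abnormal granulocyte lobulation, altered
red-cell size and shape — but manual assessment of individual cells is
slow and poorly reproducible. This package implements a complete
computational pipeline for slide-scale cytomorphology:

1. **Tile quality control** — keep only sharp, monolayer-like 512×512
   tiles (engineered blob-count / foreground / sharpness features +
   logistic classifier, behind a pluggable backend contract).
2. **White-cell segmentation** — a pixel-probability model with
   dihedral test-time augmentation and rule-based post-processing;
   nuclei segmented by 2-cluster intensity k-means (darker cluster =
   nucleus).
3. **Red-cell detection** — Canny-based candidate generation with
   hole-filling for central pallor, then a gradient-boosted morphometric
   filter that removes clumps and artifacts.
4. **Morphometry** — a fixed schema of 42 cellular features (12 shape,
   18 color, 12 co-occurrence texture) per cell and 11 nuclear features
   per white cell (53 total), including the centroid distance function
   (CDF) statistics.
5. **Moments model** — per-slide feature means/variances (+ blood
   counts) classified with cross-validated elastic-net logistic
   regression, with a variance decomposition attributing prediction to
   feature groups.
6. **Morphotype analysis** — the core model: K soft cell prototypes
   ("computational morphotypes", CMs) per cell type learned jointly with
   per-task linear heads over slide-level CM proportions,

       a_ik = softmax_k(−τ · ‖x_i − m_k‖²),   p_slide = mean_i a_i,
       logit_t = w_t · [p_wbc ; p_rbc ; blood counts] + c_t,

   trained by Adam on a masked multi-task cross-entropy across four
   diagnostic contrasts (disease detection, disease classification, MDS
   SF3B1 subtyping, anemia classification), with cross-fold **stability
   selection**: morphotypes recurring in every CV fold (optimal cosine
   matching ≥ 0.8) are kept for validated prediction.
7. **Association statistics** — expert-annotation enrichment ratios with
   chi-squared tests, condition proportion-ratio heatmaps, embedding
   density ratios, and external-validation AUC ± 1/√n.

A first-class synthetic-data module renders smear tiles (pale-centered
red cells, dark-nucleus white cells, platelets, clumps, blur) with
ground-truth masks, and simulates per-cell feature bags from planted
morphotype mixtures, so the entire pipeline is testable end to end
without slide data.

## Worked example

```python
import numpy as np
from haemorasis import synthetic, mil

# simulate a 60-slide cohort with 4 planted morphotypes per cell type
design = synthetic.default_bag_design(
    d=10, k_true=4, n_slides_per_condition=12,
    cells_per_slide=(200, 200), seed=11,
)
bags, _ = synthetic.simulate_bags(design)

# 5-fold cross-validated morphotype analysis, K=10, all four tasks
cv = mil.crossvalidate(bags, k=10, objectives=list(mil.TASKS), folds=5, seed=1)
report = mil.stability_select(cv.fold_models, threshold=0.8,
                              reference_fold=cv.best_fold)
print({t: round(a, 3) for t, a in cv.auc.items()})
print("stable morphotypes:", report.n_stable(), "of", 2 * 10)
```

Output:

```
{'disease_detection': 1.0, 'disease_classification': 1.0,
 'mds_subtyping': 1.0, 'anemia_classification': 1.0}
stable morphotypes: 16 of 20
```

All four diagnostic contrasts are recovered perfectly on this planted
cohort (centroid separation 6× the within-morphotype scatter), and 16 of
the 20 prototypes are stable across folds — the stable ones match the 8
planted centroids at cosine ≥ 0.9.

A command-line interface wraps the same functionality for shell use:

```bash
haemorasis simulate tiles --n-tiles 10 --seed 0 --out tiles/
haemorasis simulate bags  --seed 0 --out bags/
haemorasis detect-rbc --tiles tiles/ --out cells.geojson
haemorasis enrich --assignments a.csv --annotations ann.csv --out enrichment.csv
```

Detections export as QuPath-compatible GeoJSON; feature tables as
CSV/Parquet.

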