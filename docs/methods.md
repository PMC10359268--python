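# Methods

`haemorasis` implements an end-to-end computational cytomorphology
pipeline for digitized peripheral blood slides (PBS): tile quality
control, white- and red-cell detection, fixed morphometric feature
extraction, slide-level classification from morphometric moments, and a
prototype-based multiple-instance-learning model ("morphotype analysis")
that discovers diagnostically informative cell classes jointly with
slide-level classifiers. This note records the models, the defaults and
the design decisions taken where the design was genuinely open.

## Study conditions and tasks

Five leaf clinical conditions are modeled throughout: healthy control,
iron-deficiency anemia (IDA), megaloblastic anemia (MA), SF3B1-mutant
MDS and SF3B1-wildtype MDS. Four binary tasks are defined on subsets of
slides:

| task | contrast | eligible slides |
|---|---|---|
| disease_detection | control vs any disease | all |
| disease_classification | anemia vs MDS | diseased only |
| mds_subtyping | SF3B1-wildtype vs SF3B1-mutant | MDS only |
| anemia_classification | IDA vs MA | anemia only |

A slide's eligibility is encoded by its label being 0/1 versus absent;
ineligible slides are masked out of the corresponding loss terms.

## Synthetic data

Two generators supply ground truth for every stage; both are
bit-reproducible under a fixed seed.

**Tile renderer.** Red cells are ellipses (default semi-axes ~14 px,
i.e. ~7 µm at 0.25 µm/px, 40×) with a paler central region emulating
biconcave pallor — deliberately so, because the pallor fragments naive
edge detection and exercises the hole-filling step. White cells are
larger discs (default radius 28 px) with a strictly darker multi-lobed
nucleus; platelets are small dark dots. Gaussian blur and additive
Gaussian sensor noise (σ = 2 gray levels) are applied last. The renderer
does **not** model staining variation, out-of-plane cells, scanner color
profiles or compression artifacts; passing tests therefore demonstrate
the correctness of the pipeline's logic on well-posed inputs, not
robustness to real scanner variation.

**Bag simulator.** Per cell type, `K_true` planted morphotype centroids
are placed as scaled orthonormal vectors so every pairwise distance is
exactly `separation × within_scatter` (defaults: 6 × 1 — "well
separated"); each condition has a slide-level mixing vector over
morphotypes (one dominant morphotype per condition; the SF3B1-wildtype
profile splits its weight so all four tasks carry signal). Cells are
drawn Gaussian around their centroid; default feature dimension is 10
(the model is dimension-agnostic; a 42/53-dimensional preset simply uses
the real schema length). Blood counts (WBCC, Hb, Plt) are Gaussian
around condition-typical means (e.g. anemias at Hb ≈ 9–9.5 g/dL, MDS
with leukopenia/thrombocytopenia). Cohorts default to 12 slides per
condition with 150–250 cells per slide per cell type; the benchmark runs
fix 200 cells so results depend only on the seed.

## Tile quality control

Engineered features per 512×512 tile: cell-scale blob count (maxima of
the inverse Laplacian-of-Gaussian response at σ = 8 px), foreground
fraction (Otsu threshold on luma, guarded for constant tiles), variance
of the Laplacian (sharpness), plus luma mean and SD; a standardized
logistic regression produces the good/poor score with default threshold
0.5. The backend is a pluggable contract, so a convolutional classifier
can replace the engineered one without changing callers. Held-out
accuracy is reported from an internal stratified 25% split.

## White-cell segmentation

The segmenter contract is "RGB tile in, per-pixel WBC probability map
out". The default backend is a logistic pixel classifier over RGB, luma,
Gaussian-smoothed luma and local luma SD at σ ∈ {2, 4}. Training uses
per-tile stochastic gradient steps (learning rate 0.5, class-balanced
samples of 2000 px/tile) under random augmentations — rotations, flips,
additive intensity jitter (±10 levels), blur up to σ = 1 — and records
the cross-entropy on a fixed unaugmented reference sample each epoch.
Zero epochs leaves the zero-initialized model (probability 0.5
everywhere), making the initialization contract testable.

Test-time augmentation averages predictions over the 8-element dihedral
group, inverse-transforming each map. Averaging over a closed group is
idempotent, which the tests exploit.

Post-processing: threshold at 0.5 → 8-connected components → hole fill →
area gate [300, 15000] px² (leukocyte diameters ~10–70 µm at 40×) →
optional distance-transform watershed split of touching cells (off by
default; undersegmentation is rare and splitting can bisect lobated
cells).

Nuclei are segmented inside each cell mask with k-means (k = 2, 10
restarts, fixed seed) on grayscale intensity; the darker cluster is the
nucleus, and connected components smaller than 15% of the largest are
discarded so multi-lobed nuclei survive while speckle does not. On
inverted-contrast (pale-nucleus) cells this rule selects the wrong
region by construction — a documented failure mode in low-contrast
material. Constant-intensity cells raise a degeneracy error and the
caller marks nuclear features missing.

## Red-cell detection and filtering

Candidates: luma → Canny (σ = 2; hysteresis high threshold = Otsu point
of the Sobel gradient magnitude, floored at 8 gray levels/px so pure
sensor noise yields no edges) → morphological closing (disk r = 2) →
hole fill (central pallor) → connected components → drop components
overlapping a white-cell mask by > 50% → area gate [150, 3000] px²
(5–9 µm erythrocytes with margin).

The filter is a gradient-boosted tree ensemble (200 trees, depth 4,
learning rate 0.2, single-threaded for determinism) over the 42 cellular
features, with decision threshold 0.5. Its held-out false-positive rate
is reported at training time; residual contamination after filtering is
the product of the candidate false-positive proportion and the filter
FPR (0.173 × 0.11 ≈ 1.9%).

## Morphometric features

42 cellular features per cell — 12 shape, 18 color, 12 texture — plus 11
nuclear features per white cell (53 total). The exact list lives in
`morphometry.SCHEMA` (versioned and pluggable). Numerical choices:

* perimeter by the Crofton approximation (less raster bias than border
  counting); circularity 4πA/P²; convexity = convex-hull perimeter /
  perimeter.
* centroid distance function (CDF) sampled at 128 equal-arc-length
  boundary points; its SD is the red-cell irregularity statistic,
  max/min the elongation statistic. 128 samples keep the SD stable for
  cells ≥ 150 px².
* color statistics (mean, SD, skewness, quantiles 0.05/0.5/0.95 per RGB
  channel) use in-mask pixels only; skewness is defined as 0 for
  constant channels.
* texture from symmetric normalized gray-level co-occurrence matrices on
  32 levels at distances {1, 3}, angle-averaged over 0°/45°/90°/135°;
  out-of-mask pixels in the bounding box are filled with the in-mask
  mean so boundary-crossing pixel pairs import no background structure.

Nuclear features repeat the core shape statistics for the nucleus and
add the nucleus:cell area ratio and the nucleus:cytoplasm mean-intensity
ratio (defined as 1 when the nucleus fills the cell).

## Moments model

Each slide is summarized by the mean and unbiased (n−1) variance of
every feature per cell type; blood counts can be appended. Per task, an
elastic-net logistic regression (mixing parameter 0.5; regularization
strength chosen by inner 3-fold deviance over a small C grid) is
evaluated by stratified 5-fold cross-validation. Standardization and
median imputation use training-fold statistics only — a sentinel test
asserts no leakage.

Feature-group attribution decomposes the variance of the linear
predictor: with η = Σ_g η_g, group g receives
(Var η_g + Σ_{h≠g} Cov(η_g, η_h)) / Var η — covariance cross-terms split
equally between the two groups involved, so shares sum to 1, are
order-invariant, and may be negative for suppressor groups.

## Morphotype analysis

Per cell type, K prototypes **M** (K ∈ {10, 25, 50}) live in
standardized feature space with a learnable temperature τ (parametrized
as log τ, initialized at 0). Cell i gets the soft assignment
a_ik = softmax_k(−τ‖x_i − m_k‖²); slide proportions are mean assignment
rows; the per-task linear heads act on [p_wbc ; p_rbc] (plus
standardized blood counts when enabled). The classification loss is the
sum over tasks of the mean binary cross-entropy over task-eligible
slides, so at zero initialization it equals (number of tasks)·ln 2.

Training is full-batch Adam with analytic gradients (verified against
finite differences in the tests). Three deliberate optimization choices:

* **Separate learning rates.** Heads train at 1e-2; prototypes and τ at
  1e-3. K-means initialization already places prototypes at cell-density
  optima; equal step sizes let the slide-level objective drag them to
  fold-specific decision-optimal positions, destroying cross-fold
  reproducibility.
* **Density attachment.** A soft k-means distortion term (weight 0.1,
  EM-style gradient with assignments treated as constants) pulls each
  prototype toward its softly assigned cell mean. Without it, surplus
  prototypes fragment each density mode along directions chosen by
  sampling noise — a rotational degeneracy that makes morphotypes
  irreproducible across folds even on perfectly separated synthetic
  mixtures. The reported loss trajectory remains the pure classification
  term, and slides ineligible for every selected objective are dropped
  before training, so masked slides affect neither loss nor gradients.
* **Early stopping** on a 50-epoch plateau of the classification loss
  (minimum improvement 1e-5), capped at 500 epochs.

Cross-validation stratifies 5 folds on the first objective; slides
unlabeled for it are spread round-robin. The best fold maximizes mean
held-out AUC over objectives. The cross-validated AUC per task averages
naturally over pooled out-of-fold predictions for signal detection; the
permutation-null protocol in the tests evaluates 20 label permutations
of the balanced disease-classification contrast, since small-sample
pooled CV AUC is noticeably noisy (and slightly negatively biased) on
the 12-vs-48 detection contrast.

**Stability selection.** Prototypes of the best (reference) fold are
matched one-to-one to each other fold's prototypes by solving the
assignment problem that maximizes total cosine similarity in
standardized space; a morphotype is *stable* iff its match similarity is
≥ 0.8 in every fold. Prediction restricted to stable morphotypes
renormalizes the surviving proportions within each cell-type block (so
the full stable set reproduces the unrestricted forward pass exactly)
and restricts head weights correspondingly.

## Association statistics

* **Enrichment**: enrichment(c, t) = [count(c,t)/count(c)] / [count(t)/N]
  over hard (argmax, low-index tie-break) morphotype labels, with a
  continuity-corrected chi-squared test on each 2×2 table and
  Benjamini–Hochberg control at 0.05 across the morphotype × type grid.
  The identity Σ_c P(c)·enrichment(c, t) = 1 holds exactly.
* **Proportion ratios**: ratio of median slide proportions between two
  conditions; top-k (default 5) morphotypes selected by absolute
  difference of medians — the most direct reading of "median effect
  size" — with a standardized (MAD-scaled) variant exposed as an option.
  A zero denominator is reported as an infinity flag, not an exception.
* **Density ratios**: per-point ratio of the predominant class's kernel
  density (Gaussian, absolute bandwidth, class-size weighted) to the
  summed class densities in a supplied 2-D embedding; a single class
  degenerates to 1 everywhere. The embedding itself (e.g. UMAP) is an
  input, not computed here.
* **External validation**: rank-statistic AUC with standard error
  1/√n and the interval [max(AUC−se, 0), min(AUC+se, 1)].

## Problem sizes used in the shipped benchmarks

The reproducibility script and the test suite run entirely on synthetic
data at deliberately modest sizes chosen to exercise every code path
with comfortable statistical margins: 60 slides × 200 cells × d = 10 for
morphotype recovery (K = 10, 5-fold CV), 200 tiles for QC, 40 clump
scenes (~1400 candidates) for the red-cell filter, 50 tiles of 128² px
for segmenter training, and 20 label permutations for the null. These
sizes are the package's own benchmark definition; the algorithms scale
to cohort-sized inputs without modification.

## Known limitations

* The renderer's simplified appearance model means detection thresholds
  (edge floor, area gates) are validated on synthetic contrast levels;
  real slides need the exposed configuration parameters re-checked.
* Nucleus segmentation assumes the nucleus is the darker region;
  low-contrast or inverted staining defeats it by construction.
* The engineered segmentation backend is linear per pixel; heavily
  textured backgrounds would need the pluggable encoder–decoder backend.
* Morphotype identity is only defined up to the stability matching;
  interpreting individual morphotypes requires the enrichment and
  proportion-ratio statistics, not prototype coordinates alone.
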