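# Methods

## Scope and data model

`cardiogrid` operates on tables conforming to a declarative `FeatureSchema`:
an ordered list of predictors, each numeric (closed interval) or nominal
(finite integer code set), plus a binary target with class 1 = disease
present. The bundled heart schema has 13 predictors — 5 numeric (`age`,
`trestbps`, `chol`, `thalach`, `oldpeak`) and 8 nominal (`sex`, `cp`, `fbs`,
`restecg`, `exang`, `slope`, `ca`, `thal`). `thal = 0` is accepted as a
valid code but counted by the validator as a missingness indicator, since
the coding tables label it NULL. Columns are matched by header name, never
by position, so reordered CSV exports load identically.

## Preprocessing

*Normalization* is min-max to [0, 1] with extremes taken column-wise from
the fitting data; the fitted minimum maps to 0, the maximum to 1, values are
affine in between, out-of-range unseen values are clipped, and degenerate
(constant) features map to 0. All 13 features — nominal codes included —
are scaled uniformly because every cell becomes a pixel intensity in the
imaging step; this uniform treatment is an interpretation choice and is
applied consistently in fitting and prediction.

*Imputation* is the simplest deterministic rule: numeric median, nominal
mode (ties to the lowest code), fitted on training data, with per-feature
imputation counts logged. It is idempotent by construction.

*Outlier flagging* uses the Tukey fence: a numeric cell is flagged iff it
falls outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR], with quartiles computed by
linear interpolation between order statistics. Nominal cells are never
flagged. The mask is report-only; no rows are dropped.

By default every parameter above is fitted on training rows only and applied
frozen elsewhere. A `paper_mode` flag fits them on the full dataset instead,
reproducing the common (leakier) one-pass procedure on demand.

## Tabular-to-image conversion

The feature order is the dendrogram leaf order of agglomerative clustering
on `D = 1 − R`, where `R` is the Pearson correlation matrix of the scaled
training data. Design choices, all configurable:

- **Signed distance** `1 − r` rather than `1 − |r|`: the most literal
  reading of "distance from correlation"; anticorrelated features are far
  apart.
- **Average linkage**: the common default for correlation-derived distances;
  single and complete linkage are available.
- **Determinism**: the distance matrix is rounded to 10 decimals before
  linkage so summation-order float noise cannot flip ties; ties then break
  by the clustering's stable index order. The resulting order is invariant
  to row permutation of the fitting data.
- Constant features get correlation 0 to everything (distance 1) with a
  warning.

Each scaled record is reordered and written row-major into an s×s grid with
s = ceil(√d) (4 for d = 13); the trailing s² − d cells — the last three
cells of the fourth row for the heart schema — are zero padding, tracked by
an explicit mask so the embedding is exactly invertible. Upscaling to the
target side (default 224 px) is nearest-neighbor block replication: when s
divides S each cell becomes a constant (S/s)² block, the set of pixel values
equals the set of cell values (bilinear interpolation would violate this),
and the grayscale plane is replicated onto 3 identical channels. Images are
carried as floats in [0, 1]; any backend-specific intensity convention lives
inside the backbone adapter.

## Frozen backbones

A backbone is a pure function of (frozen weights, image). The `vgg16`
adapter wraps the pretrained ImageNet network, applies that ecosystem's
input preprocessing internally, and emits 512 features under global average
pooling of the final convolutional layer (a flatten mode yielding 25,088 is
available; pooling is the default because it keeps the fused matrix
desk-scale). The adapter raises an explicit capability error when its
optional deep-learning dependency is absent.

The default `toy` backbone is a seeded random frozen stack: grayscale
channel mean, binned average pooling to at most 28×28, one bank of 16
bias-free 3×3 convolutions, ReLU, global spatial average pooling, and a
seeded linear projection to the output dimension (default 32). It is
bit-reproducible, has no training path at all, and maps the zero image to
the zero vector (no biases anywhere). It is a genuine, if small, convolution
feature extractor — distinct images give distinct, non-degenerate features —
and is the backend used throughout the test suite.

## Classifier tuning

The fused matrix is `[tabular block | deep block]`, column-wise, rows
aligned. Grid search is exhaustive over declared grids, scored by accuracy
under seeded stratified k-fold CV (default 5 folds), ties broken by declared
candidate order, and the winner refit on all training rows. The shipped
default grids are supersets containing each published best configuration
(random forest: `n_estimators {50,100,200} × max_depth {None,5,10}`;
logistic regression: `C {0.1,1,10} × solver {liblinear}`; decision tree:
`max_depth {None,5,10} × min_samples_split {2,5}`; KNN:
`n_neighbors {3,5,7} × weights {uniform,distance}`; gradient boosting:
`learning_rate {0.05,0.1,0.2} × n_estimators {50,100}`; SVM:
`C {0.1,1,10} × kernel {linear,rbf}`). Deep features are extracted once
before CV — the backbone is frozen, so this leaks no labels. The standalone
mode drops the deep block but shares folds and machinery, so hybrid and
standalone scores are paired. A `TrainedPipeline` bundle freezes every
fitted stage (imputation fills, normalization extremes, feature order, toy
backbone weights, tuned classifier, CV fold table) into one versioned file.

## Synthetic data generator

The default backend is a class-conditional Gaussian copula — deterministic,
dependency-light, and under the same sampling contract a neural tabular GAN
adapter could fill. Per target class it stores:

- numeric marginals as the sorted sample values (sampling = inverse
  empirical CDF with linear interpolation);
- nominal marginals as category frequencies (sampling = thresholding the
  latent normal at the cumulative frequencies);
- a latent correlation matrix, estimated from rank-based normal scores:
  van der Waerden scores for numerics and truncated-normal conditional means
  per category bin for nominals, combined with the moment correction
  `r̂ = Cov(s_i, s_j) / (Var(s_i) · Var(s_j))` — a polyserial/polychoric
  approximation that is self-consistent with the thresholded sampler, so
  resampling reproduces the observed Pearson correlations. The matrix is
  repaired to positive semi-definite by eigenvalue clipping and rescaled to
  unit diagonal.

Class labels are allocated by largest remainder on the fitted prevalence
and all randomness flows from one explicit seed per call, so identical
seeds give identical tables.

Quality evaluation follows the three-part protocol: (1) per-feature
correlation MAE — for feature i, the mean over partners j≠i of
|corr_real(i,j) − corr_synth(i,j)| using Pearson correlation on coded
values, averaged over features — with constant features treated as
correlation 0 under a warning; (2) a 50:50 split of the reference providing
the sampling-noise baseline for the same statistic; (3) two-sample KS tests
per numeric feature and chi-square tests per nominal feature (categories
pooled smallest-first until all expected counts reach 5, Yates correction
off so identical tables give exactly χ² = 0, p = 1), with a feature passing
iff p ≥ 0.05.

### Reference study conditions

The bundled reference population (`heart_reference_model`) defines the
study conditions for desk-scale experiments: per-class truncated-normal /
gamma numeric marginals and nominal frequencies set to values characteristic
of the public heart-disease tables (the disease class is younger with higher
`thalach` and lower `oldpeak`, dominated by `thal = 2` and low `ca`),
disease prevalence 0.51, and a fixed sparse within-class latent correlation
(`HEART_LATENT_COUPLINGS`, e.g. age–thalach −0.40, oldpeak–slope +0.45).
These values were chosen once for clinical plausibility. What the generator
emulates — realistic marginals, class imbalance, a nontrivial correlation
structure — it emulates faithfully; what it does not emulate includes
measurement error modes, site effects, missingness mechanisms, and any
nonlinear or non-monotone dependence beyond a Gaussian copula. Passing
tests on this population therefore certify the pipeline's mechanics and
calibration, not clinical performance on real cohorts.

## Metrics

From TP/TN/FP/FN with class 1 positive: accuracy = (TP+TN)/total,
precision = TP/(TP+FP), recall = sensitivity = TP/(TP+FN),
F1 = harmonic mean of precision and recall, specificity = TN/(FP+TN).
Sensitivity and recall are the same formula and are asserted identical.
Ratios with zero denominators surface as explicit undefined markers with a
reason; proportions are kept on [0, 1] internally and become percentages
only at presentation. Unseen-data evaluation applies a frozen bundle
without refitting and refuses schema mismatches; the comparison report
emits a long (family × mode × metric) table with per-family
hybrid-minus-standalone deltas.

## Shapley explanations

The value of coalition S is the interventional expectation over a finite
background set: features outside S are replaced by each background row's
values and the pipeline's class-1 scores are averaged. The exact enumerator
computes all 2^M coalition values (8,192 for the 13 clinical features) and
satisfies efficiency to round-off; the dummy, symmetry and linearity axioms
are verified in tests. The sampled estimator averages marginal contributions
along seeded random permutations, reports per-feature Monte-Carlo standard
errors, telescopes exactly (the summed estimates equal f(x) − base for any
number of permutations), and converges to the enumerator, which serves as
its oracle in tests.

Explanations are computed over the 13 raw tabular inputs of the end-to-end
pipeline — masking happens before normalization and image conversion, so
the deep block reacts to coalitions — not over the 13+d_cnn fused columns,
whose attributions would be uninterpretable. The default background is 20
training rows. Exact mode at the 224-px image side is expensive (2^13 ×
background pipeline evaluations); desk-scale work uses a smaller image side
(16–32 px), under which one record explains in seconds.

## Numerical choices and degenerate inputs

- Stratified splitting allocates per-class test counts within 1 of
  `round(class_count × fraction)` and keeps both parts non-empty per class.
- CSV parsing uses correctly-rounded float conversion so written datasets
  reload bit-exactly; nominal codes are written as integers.
- Constant features: warned and handled everywhere (correlation 0 in
  ordering and MAE, degenerate marginals in the generator, scale-to-0 in
  normalization).
- Latent correlation estimates are clipped to [−1, 1] before PSD repair; a
  10⁻¹⁰ jitter stabilizes the Cholesky factorization at sampling time.
- Chi-square tests on tables left with a single category after pooling are
  skipped with an explicit note rather than reported as numbers.

## Problem sizes

Tests and the acceptance script run at desk scale by choice: reference
populations of 1,000–5,000 rows, pipelines trained on 120–200 rows at image
side 16–32 with the toy backbone, 50-seed estimator-agreement studies at
M ≤ 4, and 200-replicate null-calibration studies at n = 300. The 224-px /
4×4 structural contract is asserted exactly on single records.

## Known limitations

- The copula generator cannot represent dependence structures outside the
  Gaussian copula family (e.g. tail dependence), and its chi-square pass
  rates degrade for very rare categories at small reference sizes.
- The toy backbone is a fixed random projection pipeline: useful as a
  deterministic stand-in with real convolutional structure, but its features
  carry no pretrained semantics.
- Fused-space attributions for tree models are not implemented; explanations
  are tabular-input-space only.
- The unseen-data harness requires the evaluation table to match the
  training schema exactly (after any user-side recoding); it performs no
  automatic code mapping.
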