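# Methods

`msngrad` implements an individualized morphometric-similarity-network
(MSN) gradient analysis for case–control cortical morphometry, together
with the group statistics, topology, cognition and transcriptomic
association analyses that consume the gradients, and a synthetic-data
generator that provides a fully self-contained test bed.  This note
documents the models, the conventions that had to be pinned where the
field's tooling leaves them open, and what the synthetic test bed does
and does not establish.

## Morphometric similarity networks

Each subject contributes a regions × 5 table of cortical features:
thickness (CT, mm), volume (CV, mm³), area (CA, mm²), gaussian
curvature (GC, 1/mm²) and mean curvature (MC, 1/mm).  Features are
z-scored across regions (sample SD, ddof = 1) and the MSN entry
(i, j) is the Pearson correlation between regions i and j's
standardized 5-feature profiles.  Conventions:

- **Diagonal = 0.** Self-similarity is uninformative and would always
  survive row sparsification, so it is excluded from the matrix, from
  regional strength (the off-diagonal row sum) and from thresholding.
- Correlation over 5 points is noisy; no shrinkage is applied — the
  5-feature Pearson MSN is the object of study, not an estimator to be
  improved.
- A region with a constant feature profile has undefined correlations;
  its entries are set to 0 with a warning (defensive only — the
  generator cannot produce one).

## Gradient decomposition

Per subject: (1) keep the top 10% of entries per MSN row by signed
value (⌊0.10·n⌋ entries, diagonal excluded; the result is
row-sparse and generally asymmetric); (2) cosine similarity between
the full-length sparsified rows, mapped to a normalized angle
affinity `1 − arccos(clip(cos, −1, 1))/π ∈ [0, 1]`; (3) diffusion map
embedding of the affinity kernel with α = 0.5, diffusion time t = 0
(the multiscale `λ/(1−λ)` variant) and k = 10 components — the
defaults of the standard gradient toolbox.  The kernel is
α-normalized, converted to a row-stochastic operator, and
eigendecomposed through its symmetric conjugate; the trivial constant
component is dropped and the rest are ordered by descending
eigenvalue magnitude.

**Explained-variance fractions.** Reported `lambdas` are
`λ_i² / Σ_j λ_j²` over the full non-trivial spectrum, so they are
non-negative, non-increasing and sum to at most 1 over any retained
subset.  No single convention is standard across toolboxes; this one
is fixed here and documented.

**Alignment.** A template is embedded from the element-wise mean MSN
over all subjects (both groups).  The template's orientation is fixed
by requiring the largest-|score| region of each component to be
positive; each subject is then aligned to the template by orthogonal
Procrustes rotation (no scaling), which resolves the per-subject
eigenvector sign/rotation indeterminacy without touching the
explained-variance fractions.  Global gradient-1 metrics are the
explained fraction, the score range (max − min), and the score
variance (ddof = 1).

Downstream analyses use gradient 1 only; components 2…k are computed
and stored.

## Group statistics

- **Harmonization**: parametric empirical-Bayes ComBat (location and
  scale), with group, age, sex and education protected as biological
  covariates.  The implementation matches Bioconductor `sva::ComBat`
  to ~1e-14 on shared fixtures (asserted in the test suite).  Sites
  need ≥ 2 subjects; a single site passes values through unchanged.
- **Regional contrast**: per-region OLS with intercept, group (AD = 1),
  age, sex, education; t is the group coefficient over its standard
  error, p two-sided from the residual-df t distribution, q from
  Benjamini–Hochberg step-up (monotone, capped at 1).  FDR is applied
  within each family separately (regions; Von Economo classes; Yeo
  networks) — the families are reported separately and never pooled.
- **Label aggregation**: class/network values are arithmetic means of
  member regions per subject; the same GLM runs on them.
- **Distribution tests**: two-sample Kolmogorov–Smirnov.  The operand
  is the *pooled* per-subject regional gradient values per group
  (globally or within a class); comparing per-subject label means
  instead is available via `subject_means=True`.  Pooling gives
  well-powered ECDFs at any cohort size.  The p-value uses scipy's
  automatic method: exact where feasible, asymptotic at scale (they
  coincide where both apply).  Note that with equal sample sizes the D
  statistic is coarsely discrete, so its p-value — while exactly
  calibrated — carries large atoms; calibration checks in the test
  suite therefore use coprime sample sizes.

## Graph topology

The signed dense MSN becomes an undirected weighted graph by keeping
the top `⌊density · n(n−1)/2⌋` positive off-diagonal edges (default
density 0.10, mirroring the gradient sparsification; configurable,
and a binarized mode exists because the thresholding convention used
with the standard connectivity toolbox is not uniquely determined).
Clustering is the network mean of the Onnela weighted per-node
coefficient on max-normalized weights; path length is the mean
shortest-path distance over node pairs with edge length 1/weight,
computed on the largest component (with a warning) if the graph
disconnects.  Both reduce exactly to the binary definitions for equal
weights.  The kernels are vectorized (matrix-power triangle counting,
sparse Dijkstra) and validated against networkx.

## Cognition

- **Partial correlation** between class-level gradient means and each
  score: Pearson correlation of OLS residuals on [intercept, age, sex,
  education], p from the t transform with df = n − k − 2.
- **Prediction**: linear-kernel support vector regression on
  region-level gradient-1 scores, nested 5-fold cross-validation
  (inner 5-fold grid search over C ∈ {0.01…100} log-spaced and
  ε ∈ {0.01, 0.1, 1}); feature standardization and tuning are fit on
  training folds only.  Performance is the Pearson r between the
  target and concatenated out-of-fold predictions; significance comes
  from permuting the target and re-running the whole nested pipeline,
  `p = (1 + #{r_perm ≥ r_obs}) / (1 + n_perm)` (default 1000
  permutations).  A comparator feature set — regional MSN strength —
  is evaluated with identical folds.  The linear kernel is the default
  in this p ≫ n regime; RBF is configurable.

## Transcriptomic association

PLS regression with z-scored regional expression as predictors and the
unthresholded regional t-map as the single response.  For a univariate
response the first component is analytic: weights ∝ `Xᵀy` (unit norm),
scores = `Xw`, explained variance = R² of y on the scores; orientation
is fixed so that r(scores, y) ≥ 0.  Significance of the explained
variance and of |r| comes from region-label permutation (default
10000); gene contributions are ranked by bootstrap z — regions
resampled with replacement, the component refit and sign-aligned to
the original weights by the sign of the inner product, z = weight /
bootstrap SD — converted to two-sided standard-normal p and BH-FDR q
(default threshold q < 0.001), then split into positively and
negatively weighted significant sets.  The permutation null shuffles
region labels and does **not** preserve spatial autocorrelation; a
hook (`null_maps`) accepts user-supplied surrogate maps.

## Synthetic data

The generator emulates the statistical structure the analyses assume,
not any particular imaging dataset:

- Regions sit on a latent 1-D axis; each feature's regional mean is a
  smooth (half-period trigonometric + linear) profile of that axis
  with amplitude 2.5 relative to the unit within-region noise SD, so
  MSNs have block structure and a meaningful principal gradient.  The
  covariance structure of real cortical morphometry is unknown to us;
  the smooth-profile choice is a modeling convenience.
- Group effects are signed per-region shifts (in noise-SD units) added
  to every feature mean of AD subjects; site effects are additive
  per-feature offsets (ComBat's location model), with optional
  multiplicative scale factors.
- Age and education are clipped Gaussians (73 ± 6 y, 16 ± 2.5 y); sex
  is 0/1 Bernoulli(½); sites are assigned uniformly at random.
- The two 7-level atlas labelings (Von Economo classes, Yeo networks)
  are contiguous blocks of the region ordering, offset by half a block
  from each other; a shuffled option exists.
- Cognition scores are one shared linear combination of per-subject
  class-level gradient means (standardized across subjects in the
  pipeline) plus independent Gaussian noise (default SD 1.0); the
  generating weights are returned for recovery tests.
- Expression plants a designated gene subset at a target correlation ρ
  with a supplied region map via `ρ·z(map) + √(1−ρ²)·noise`; remaining
  genes are independent noise.  In the pipeline the supplied map is the
  *realized* gradient t-map — the morphometric effect map propagates
  nonlinearly through MSN construction and embedding, so planting
  against it would leave no recoverable transcriptomic signal.

Everything is reproducible byte-for-byte from a seed.  Passing tests on
this test bed establish that the machinery recovers structure it is
designed to detect and stays calibrated under the null; they say
nothing about effect sizes, spatial autocorrelation, or feature
covariance in real cohorts.

## Pipeline and problem sizes

The `msngrad` CLI chains simulate → msn → gradients → stats → graph →
cognition → pls, writing flat TSV artifacts (dense stacks as raw
`.npy`, which — unlike zip-based archives — round-trips bit-exactly)
and a YAML manifest with per-artifact SHA-256 hashes.  One master seed
derives every stage seed; the same configuration reproduces every
artifact bit for bit.

Analysis defaults mirror the study settings (10% density, k = 10,
nested 5-fold CV with 1000 prediction permutations, 10000 PLS
permutations and bootstraps, gene threshold q < 0.001).  The packaged
demo and the acceptance script run at desk scale — 400 regions,
60 subjects per group, 2000 genes with 50 planted — with permutation
counts reduced (49 for prediction, 1000 for PLS), chosen so a full run
completes in a few minutes on one CPU while every inferential
mechanism is still exercised.

## Known limitations

- Regions are abstract: no surface geometry, no parcellation
  computation, no imaging preprocessing.
- The PLS permutation null ignores spatial autocorrelation (see hook
  above).
- Whether weighted or binarized networks, and which graph threshold,
  best match the field's reference analyses is genuinely open; both
  modes are implemented and the default (weighted, density 0.10) is
  fixed for reproducibility.
- Pearson over 5 feature points makes single-edge MSN estimates noisy
  by construction; all inference here operates on whole matrices or
  maps, never single edges.
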