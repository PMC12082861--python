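# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic cohort generator does
and does not emulate, and the numerical conventions that make results
reproducible.

## Synthetic cohort model

The generator produces a cohort of `n_samples` patients with a binary
outcome (recurrence/metastasis vs none) at a configurable class balance
(default 70/144 positive, matching a near-balanced surgical cohort) and a
list of typed omics blocks.

**Continuous blocks** (protein / phosphosite abundances after upstream
median normalisation and log2 transform) are modelled as per-class
Gaussians with shared variance `noise_sd²`. Informative features carry a
between-class mean difference of `effect_size × noise_sd`, split
symmetrically (class means ∓ shift/2); non-informative features are
identically distributed across classes. This is exactly the
location-shift alternative under which the pooled-variance *t* test is the
likelihood-based choice, and under which the Mann-Whitney and ANOVA tests
applied downstream are consistent.

**Discrete blocks** (clinical categories, mutation presence/absence) are
binary. Non-informative features share one Bernoulli rate per feature
(drawn uniformly from 0.15–0.85 so that tables are not degenerate);
informative features start from a baseline rate of 0.3 in the
outcome-negative class and shift it by `effect_size` on the log-odds
scale in the positive class, i.e. the generating model is precisely the
2×2-contingency alternative the discrete tests target.

Missing outcomes are an explicit integer sentinel (`MISSING_LABEL = -1`),
never NaN, so the completeness filter has a testable contract: it removes
exactly the flagged samples from the labels, the sample ids and every
block, preserving order.

The default desk-scale configuration is 144 samples with blocks
clinical 10 (3 informative), mutation 20 (3), proteomics 600 (89),
phospho 1,000 (15). The informative counts mirror the feature counts a
real selection run retains in this application at full scale, while the
total width (1,630 features) keeps the whole test suite in seconds. The
default planted effects — one within-class SD for continuous features,
1.5 log-odds for discrete ones — were fixed once as values at which a
144-sample two-arm comparison has essentially full power per feature
(standardised difference 1.0 at n ≈ 72 per class gives z ≈ 6), i.e. the
regime in which the real analysis claims to operate.

**What the generator does not emulate:** correlation structure within and
between blocks (features are independent given the class), batch effects,
heavy-tailed abundance distributions, missing feature values, and any
clinical-covariate realism (all discrete features are binary codes). A
consequence worth stating plainly: with 89 independent informative
proteomic features at a one-SD shift each, the between-class separation in
the selected feature space is ≈ √89 SDs, so the reduced design is almost
perfectly separable and every reasonable classifier reaches ceiling
accuracy. Passing evaluation tests therefore demonstrates correctness of
the machinery (fold hygiene, metric arithmetic, ensemble plumbing), not a
realistic effect size for patient data; the comparison becomes
discriminative when the generator is run at smaller effects.

## Feature selection

All test statistics are computed from first principles; scipy supplies
only the reference distributions.

* **Fisher's exact test** enumerates the full hypergeometric support of
  the observed margins in exact integer arithmetic (binomial-coefficient
  numerators over a common denominator) and sums the probabilities of all
  tables no more probable than the observed one. Because the comparison is
  between integers, the two-sided p has no floating-point tie ambiguity.
  An empty table returns p = 1 with a warning.
* **Chi-square** uses the Pearson statistic with margin-derived expected
  counts and no continuity correction; a zero expected cell raises an
  error directing the caller to Fisher's test. Under the default
  `auto` rule a 2×2 table is tested by Fisher whenever its smallest
  expected count is below 5 — the conventional validity condition — and by
  chi-square otherwise; either test can be forced.
* **Student's t** is the pooled-variance two-sample statistic with
  n₁+n₂−2 df. Zero pooled variance with equal means gives t = 0, p = 1;
  with unequal means it is flagged degenerate with p = 0. Welch's variant
  is deliberately not the default: the pooled form is the one the
  pipeline's formula set specifies.
* **Mann-Whitney U** is defined by the pairwise double sum with ties
  scoring 0.5. The p-value uses the tie-corrected normal approximation
  without continuity correction; at the relevant group sizes (≈ 70 per
  class) the approximation error is far below the α = 0.05 decision
  threshold, and the choice is recorded here rather than hidden. The
  block-level path computes U via average ranks (algebraically identical
  to the double sum; the equivalence is asserted in the test suite).
* **One-way ANOVA** follows the SS/DF decomposition; for two groups
  F = t² exactly, which the suite verifies to 1e-10 relative tolerance.

Continuous features are kept when **all three** tests reject at α
(default 0.05). The intersection is the most conservative combiner
consistent with "integrating" three tests, and its null behaviour is
calibrated in the acceptance suite (selected fraction ≤ α because the
tests are positively dependent — t and F are identical for two groups, so
the intersection is effectively t ∧ U). `majority` and `any` rules and an
optional per-block Benjamini-Hochberg adjustment are available and are
recorded in the selection report. No multiplicity correction is applied by
default, reflecting the workflow this package operationalises; the flag
exists for users who want it.

## Dimension reduction

Each continuous block's selected features are centred (no unit-variance
scaling by default, because abundances are already column-normalised and
log-transformed upstream; a `scale` flag exists) and decomposed by SVD.
The first L = 2 components per block are retained — the choice the
original workflow motivates by visual class separation in the 2-D score
space, which the suite asserts quantitatively on synthetic data
(PC-space centroid distance > 1 pooled within-class SD). Conventions:

* loadings are orthonormal to 1e-8 and ordered by decreasing variance;
* each loading column is signed so its largest-magnitude element is
  positive, making outputs backend-independent;
* requesting more components than `min(n−1, p)` or than the numerical
  rank (singular values > 1e-12 of the largest) is an error that reports
  the attainable maximum; a block with fewer selected features than L
  retains what it has, with a warning.

Selected discrete features pass through untouched. Column order is
deterministic: blocks in cohort order, pass-through features in block
order, then components by index. On a full-scale run this yields the
3 + 3 + 2 + 2 = 10-column design; a reported headline of "11" final
features in the source workflow's prose conflicts with its own
enumeration of 10, and this implementation follows the enumeration.

## Sample-size estimation and augmentation

For every selected feature the classical two-sample normal-approximation
requirement is computed:

    n = σ² (Q₁⁻¹ + Q₂⁻¹)(μ_α + μ_β)² / δ²

with σ the pooled SD, δ the difference of class means, Q₁/Q₂ the class
proportions, and μ_α, μ_β the standard-normal critical values (defaults:
two-sided α = 0.05 → 1.960, β = 0.2 → 0.8416), rounded up. δ = 0 yields an
infinite requirement, flagged rather than silently dropped. Q₁/Q₂ are
taken as the observed class proportions (the natural reading when the
dichotomisation is the outcome itself). Per-block requirements aggregate
by **maximum** — only the maximum guarantees every retained feature is
adequately powered — with `mean` as an option; the cohort-level
requirement is the maximum over blocks, and augmentation triggers when the
labelled cohort is smaller.

**SMOTE** is used here for whole-dataset augmentation, not minority
rebalancing: every row (both classes) seeds `m` synthetic rows,
interpolated towards one of its `k = 5` same-label Euclidean nearest
neighbours with a single uniform gap multiplier per generated row
(`x_new = x_i + u·(x_ij − x_i)`, u ~ U(0,1) scalar — the per-coordinate
variant is intentionally not the default, keeping generated points on the
seed-neighbour segment). Consequences that the suite asserts: output size
is exactly (1+m)·n, class balance is preserved, every generated coordinate
lies within its segment, and the generator is seed-deterministic.
Augmentation operates on the post-reduction design matrix; pass-through
discrete columns are interpolated and then snapped to the nearest original
category so discrete semantics survive. Distances are Euclidean on the
unscaled design columns; neighbours are ordered by distance with index as
a deterministic tie-break. A class smaller than k+1 falls back to its
attainable neighbour count with a warning.

**Quality gate.** The maximum Fisher discriminant ratio
F1 = maxᵢ (μ₁ᵢ − μ₂ᵢ)²/(σ₁ᵢ² + σ₂ᵢ²) (per-class sample variances,
ddof = 1; a standard-error variant is available behind a flag) scores
class overlap before and after augmentation — higher means less overlap.
SMOTE interpolates within classes and thus shrinks within-class spread,
raising F1; the Gaussian-jitter baseline (per-feature ε ~ N(0,(scale·sd)²),
default scale 0.1) inflates it, lowering F1. The acceptance suite verifies
this ordering over 20 seeded cohorts, and the population limit
(N(0,1) vs N(2,1) → F1 → 2) at n = 10⁴ within 5%.

## Boosted ensemble with logistic stacking

Labels {0,1} are mapped to {−1,+1} for the boosting algebra and back for
the stacking layer. Each of the three families (logistic regression with
C = 1, RBF SVC with C = 1 and scale gamma, Gaussian naive Bayes — all
weight-capable, so weighted fitting is the default, with seeded weighted
resampling as an alternative mode) is boosted for up to T rounds:

* D₁(i) = 1/n; per round ε_t = Σ_miss D_t(i),
  α_t = ½ ln((1−ε_t)/ε_t) with ε clipped to [1e-10, 1−1e-10];
  D_{t+1} ∝ D_t·e^{∓α_t}, renormalised (every D_t sums to 1 ± 1e-10,
  asserted).
* A round at or above chance (ε ≥ 0.5) re-initialises the weights to
  uniform once; a second such round stops boosting. A perfect round keeps
  its (clip-ceiling) α and stops, since the distribution no longer moves.
* T defaults to 10 — small, conventional, and sufficient for the desk
  scale; it is a config knob, not a fitted quantity.

The member score is the signed sum H_mT(x) = Σ_t α_t h_t(x) with hard ±1
votes (a probability-score variant was considered and rejected as the
default because the weighted-vote form is what the α-derivation assumes).
The three scores are fused by logistic regression,
log(H/(1−H)) = c₀ + Σ c_m H_mT(x). Two stacking modes exist:
`in_sample` (meta-fit on the members' own training scores — faithful to
the original single-fit workflow) and `out_of_fold` (scores from an
internal stratified 5-fold split; the evaluation default, avoiding the
optimism of fitting the combiner on resubstitution scores). Constant
score columns are excluded from the meta-fit, their coefficients set to 0,
with a warning.

## Evaluation

Stratified K-fold (default K = 5, seeded). Three augmentation policies:

* `none`;
* `train_folds_only` (default): SMOTE is re-run inside each training
  fold, so no synthetic row ever derives from a held-out sample;
* `whole_dataset_first`: the augment-then-train ordering of the original
  workflow — the whole design is augmented once and every synthetic row
  joins every training set. Even here, folds are formed over original rows
  only and held-out scoring is restricted to originals by construction,
  which the suite asserts structurally.

Metrics come from exact confusion-count arithmetic (ratios with zero
denominators are 0 and flagged); ROC curves sweep the unique scores with
ties entering simultaneously and AUC is trapezoidal, which makes
AUC ≡ U/(n·m) — verified against the selection module's pairwise U to
1e-10 including ties. Per-fold accuracies of each baseline are compared
to the ensemble's with a paired two-sided t test (folds are paired across
models); identical fold vectors report p = 1 rather than NaN.

## Pipeline and reproducibility

A single master seed fans out to stages as the low 31 bits of
SHA-256(`"{seed}:{stage}"`), so stages are independently reproducible and
adding a stage never perturbs another's stream. Every run directory gets a
`manifest.json` listing each artifact with its SHA-256; no timestamps are
written, so identical configs produce byte-identical artifacts. The YAML
config is validated against a committed key/type schema
(`omicsboost run-all --validate`).

## Known limitations

* Feature independence in the generator overstates the effective signal
  of wide blocks (see above); no attempt is made to simulate proteome
  covariance.
* The Mann-Whitney p is asymptotic; exact enumeration for tiny samples is
  not implemented because the pipeline's group sizes never require it.
* The sample-size formula assumes normality and equal variances, the same
  assumptions the generator satisfies by construction; on real data it is
  a planning heuristic, not a guarantee.
* The gradient-boosted-tree comparator is used strictly off the shelf
  (scikit-learn defaults, seeded); its internals are out of scope.
* Binary outcomes only; no calibration analysis; no nonlinear embeddings.
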