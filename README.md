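# omicsboost

Predicting postoperative recurrence and metastasis from multiomics tumour
profiles is a small-n / large-p problem: a cohort of ~144 surgical
colorectal-cancer patients, each described by a handful of clinical
covariates, binary somatic-mutation indicators, and thousands of
log2-normalised protein and phosphosite abundances, with a near-balanced
binary outcome. `omicsboost` implements the complete analysis pipeline for
this setting as a tested, reusable Python package:

1. **Univariate statistical feature selection**, typed per block — discrete
   features are screened with Fisher's exact test (exact hypergeometric
   enumeration) or the Pearson chi-square test; continuous features with an
   integrated battery of the pooled-variance Student *t* test, the
   Mann-Whitney *U* test (pairwise scoring with 0.5 for ties) and one-way
   ANOVA, a feature being retained when all three reject at level α.
2. **PCA block reduction**: each continuous block's selected features are
   centred and projected onto their first *L* = 2 principal components
   (*T<sub>L</sub>* = *X W<sub>L</sub>*); selected discrete features pass
   through, giving one unified design matrix.
3. **Sample-size-driven augmentation**: the per-feature two-sample
   requirement *n* = σ²(Q₁⁻¹ + Q₂⁻¹)(μ<sub>α</sub> + μ<sub>β</sub>)²/δ² is
   aggregated per block (maximum); if the cohort falls short, whole-dataset
   SMOTE (each sample interpolated towards one of its *k* = 5 same-label
   nearest neighbours, *m* = 1 synthetic row per original) grows it, and
   quality is gated by the maximum Fisher discriminant ratio
   F1 = max<sub>i</sub> (μ₁ − μ₂)²/(σ₁² + σ₂²) against a Gaussian-noise
   baseline.
4. **A boosted heterogeneous ensemble**: AdaBoost
   (ε<sub>t</sub> = Σ<sub>miss</sub> D<sub>t</sub>(i),
   α<sub>t</sub> = ½ ln((1 − ε<sub>t</sub>)/ε<sub>t</sub>),
   multiplicative weight updates) applied separately to logistic-regression,
   RBF support-vector and Gaussian naive-Bayes weak learners; the three
   boosted scores H<sub>mT</sub>(x) = Σ<sub>t</sub> α<sub>t</sub>
   h<sub>t</sub>(x) are fused by a logistic stacking layer
   log(H/(1 − H)) = c₀ + Σ c<sub>m</sub> H<sub>mT</sub>(x).
5. **Stratified K-fold evaluation** against LR, SVM, naive-Bayes and a
   gradient-boosted-tree comparator, with accuracy / precision /
   sensitivity / specificity / F-measure, ROC + AUC, and paired *t* tests
   on per-fold accuracies.

Because patient-level data cannot ship with code, the package includes a
first-class **synthetic cohort generator** that emulates the statistical
structure the analysis assumes (typed blocks, planted informative subsets
with known effect sizes, missing-outcome records), so every stage is
testable end to end — including selection calibration under the null and
recovery of the planted features.

## Worked example

```python
import omicsboost as ob

cfg = ob.default_config(seed=7, n_samples=146, label_missing_count=2)
cohort = ob.filter_labelled(ob.generate_cohort(cfg))
print(f"labelled samples: {cohort.n_samples}")

report = ob.select_features(cohort, alpha=0.05)
for block in cohort.blocks:
    print(f"{block.name}: {len(report.selected_ids(block.name))} features selected")

design = ob.assemble_design(cohort, report, L_per_block=2)
print(f"design matrix: {design.X.shape[0]} x {design.X.shape[1]}")

need = ob.estimate_block_sizes(cohort, report)
print("required n per block:", {k: int(v) for k, v in need.items()})

aug = ob.smote(design.X, design.y, m=1, k=5, seed=7,
               discrete_cols=design.passthrough_columns)
print(f"augmented: {len(aug.y)} rows, F1 {aug.f1_before:.3f} -> {aug.f1_after:.3f}")

rep = ob.kfold_evaluate(design, K=5, seed=7)
print(rep.summary[["accuracy_mean", "accuracy_sd"]].round(3))
print("AUC:", {k: round(v, 3) for k, v in rep.auc.items()})
```

prints

```
labelled samples: 144
clinical: 3 features selected
mutation: 3 features selected
proteomics: 111 features selected
phospho: 60 features selected
design matrix: 144 x 10
required n per block: {'clinical': 97, 'mutation': 85, 'proteomics': 289, 'phospho': 281}
augmented: 288 rows, F1 44.388 -> 45.514
          accuracy_mean  accuracy_sd
model
GDBT              0.986        0.032
LR                1.000        0.000
NB                1.000        0.000
SVM               1.000        0.000
ensemble          1.000        0.000
AUC: {'LR': 1.0, 'SVM': 1.0, 'NB': 1.0, 'GDBT': 1.0, 'ensemble': 1.0}
```

Reading the output: two of the 146 generated records lack an outcome and
are dropped by the completeness filter; the selection stage recovers the
planted informative features (plus the expected handful of α-level false
positives in the wide blocks); the unified design has 3 + 3 pass-through
discrete columns plus two principal components per continuous block; the
most demanding block requires ~289 samples, so SMOTE doubles the cohort to
288 rows and raises the F1 overlap score (higher = better-separated
classes). At the default planted effect sizes the design is strongly
separable, so all linear-ish models sit at ceiling accuracy; the
comparison becomes discriminative at smaller effects
(`default_config(continuous_effect=0.3, ...)`).

The same workflow is scriptable from a shell:

```bash
omicsboost run-all -c examples/config.yaml --seed 7 -o run/
omicsboost run-all -c examples/config.yaml --validate
```

which writes every stage artifact (`selection_report.csv`, `design.csv`,
`augmentation_report.json`, `model/`, `eval_report.json`, `metrics.csv`,
`roc_*.csv`) plus a `manifest.json` with a SHA-256 hash of each file;
re-running with the same config reproduces the artifacts byte-identically.

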