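# Full pipeline configuration (all keys optional; defaults shown).
# Validate with:  omicsboost run-all -c examples/config.yaml --validate

# input: omit cohort_dir to generate a synthetic cohort
cohort_dir: null
n_samples: 146
label_missing_count: 2
continuous_effect: 1.0      # planted standardized mean shift
discrete_effect: 1.5        # planted log-odds shift

# feature selection
alpha: 0.05
integration_rule: all       # all | majority | any
discrete_method: auto       # auto | fisher | chi2
correction: null            # null | bh

# dimension reduction
L_per_block: 2
pca_scale: false

# sample-size estimation and SMOTE
size_alpha: 0.05
size_beta: 0.2
size_agg: max               # max | mean
smote_m: 1
smote_k: 5
force_augmentation: false

# ensemble and evaluation
T: 10
stacking_mode: out_of_fold  # out_of_fold | in_sample
K: 5
augmentation_policy: train_folds_only   # none | train_folds_only | whole_dataset_first

seed: 0
out_dir: run
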