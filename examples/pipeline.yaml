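# Full analysis from the packaged generator profile.
# Run with:  qolclasses run --config examples/pipeline.yaml
profile: aqol_paper_profile
out_dir: results/pipeline_run
seed: 1
k_range: [1, 6]
k_final: 4
cv_schemes: [kfold, loso, splithalf]
n_folds: 10
n_restarts: 20
n_imputations: 20
stages: [simulate, score, describe, select, fit, validate]
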