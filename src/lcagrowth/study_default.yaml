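# Default study configuration: the full published design.
# 27 conditions (3 sample sizes x 3 smaller-class proportions x 3
# separation levels), 1,000-replication target per condition and method.
# Pass --reps to run-study for a desk-scale version.
base_seed: 20180222
replication_target: 1000
max_replication_factor: 5
methods: [one_step, three_step, case_weight]
n_starts: 16
n_starts_os3: 8
tol: 1.0e-7
max_iter: 500
compute_ses: true
se_method_cw: sandwich
fit_comparison_models: true
n_jobs: 1
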