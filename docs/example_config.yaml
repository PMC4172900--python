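# Full-pipeline configuration for `gemtree run --config docs/example_config.yaml`
mode: simulate          # simulate | cohort_csv | ct_csv
out_dir: gemtree_out
seed: 11
n_patients: 26
endpoints: [os, pfs]
permutations: 199
alpha: 0.05
amalgamation_alpha: 1.0   # 1.0 = leaves are the final classes
min_events: 1
min_subjects: 3
max_depth: 5
log_level: INFO
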