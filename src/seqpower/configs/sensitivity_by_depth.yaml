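# Singleton-detection sensitivity vs. read depth at fixed cohort size
# (reference curve: N = 1000, e = 0.01, per-site FPR 1e-3).
name: sensitivity_by_depth
kind: sensitivity
n_total: 1000
error_rate: 0.01
false_positive_rate: 1.0e-3
replicates: 200000
seed: 0
depths: [2, 4, 6, 8, 10, 12, 14, 16, 18, 20, 22, 25, 30, 35, 40, 45, 50]
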