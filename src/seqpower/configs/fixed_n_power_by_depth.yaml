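# Association power by depth for a constant cohort of 10,000 samples:
# power rises with depth and plateaus once detection saturates.
name: fixed_n_power_by_depth
kind: sweep
n_total: 10000
error_rate: 0.01
false_positive_rate: 1.0e-3
replicates: 200000
seed: 0
ratio: [1, 1]
alpha: 2.5e-6
depths: [5, 10, 15, 20, 25, 30, 35, 40, 45, 50]
diseases:
  - {relative_risk: 15, prevalence: 0.2, singleton_freq: 0.008, gene_length: 1000}
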