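# Association power by depth under a fixed sequencing capacity of 100,000x
# with no library/prep cost, for several relative risks (1:1 cases:controls).
name: budget_power_by_depth
kind: sweep
capacity: 100000
prep_cost: 0
error_rate: 0.01
false_positive_rate: 1.0e-3
replicates: 200000
seed: 0
ratio: [1, 1]
alpha: 2.5e-6
diseases:
  - {relative_risk: 5, prevalence: 0.2, singleton_freq: 0.01, gene_length: 1000}
  - {relative_risk: 10, prevalence: 0.2, singleton_freq: 0.01, gene_length: 1000}
  - {relative_risk: 15, prevalence: 0.2, singleton_freq: 0.01, gene_length: 1000}
  - {relative_risk: 20, prevalence: 0.2, singleton_freq: 0.01, gene_length: 1000}
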