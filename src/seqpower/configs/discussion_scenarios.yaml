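# Two worked disease scenarios sharing one budget (capacity 200,000x, c = 5):
# very different power, near-identical NCP-optimal depth.
name: discussion_scenarios
kind: optimize
capacity: 200000
prep_cost: 5
error_rate: 0.01
false_positive_rate: 1.0e-3
replicates: 200000
seed: 0
ratio: [1, 1]
alpha: 2.5e-6
diseases:
  - {relative_risk: 10, prevalence: 0.2, singleton_freq: 0.008, gene_length: 1000}
  - {relative_risk: 12.5, prevalence: 0.2, singleton_freq: 0.01, gene_length: 1000}
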