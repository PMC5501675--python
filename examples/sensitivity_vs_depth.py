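"""How singleton-detection sensitivity grows with read depth.

A singleton — a variant present on exactly one chromosome in the whole
cohort — is the hardest variant to call.  This example calibrates the
likelihood-ratio caller to a per-site false-positive rate of 1e-3 for a
cohort of 1,000 and sweeps depth.  Replicates are reduced for a quick run;
the defaults use 200,000.
"""

from seqpower import DetectionSpec, SequencingModel, estimate_sensitivity

COHORT = 1000
print(f"depth  sensitivity  (cohort N={COHORT}, error 1%, per-site FPR 1e-3)")
for depth in (4, 8, 12, 16, 20, 25, 30):
    est = estimate_sensitivity(
        SequencingModel(mean_depth=depth, error_rate=0.01),
        DetectionSpec(cohort_size=COHORT, replicates=20_000, seed=1),
    )
    print(f"{depth:>4}x  {est.sensitivity:10.3f}  +/- {est.monte_carlo_se:.3f}")
print(
    "\nSensitivity climbs steeply up to ~20x and plateaus near 1 by 25-30x:"
    "\nbeyond that, extra depth buys almost no additional singleton discovery."
)
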