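"""Detection sensitivity beyond singletons: common rare variants are easier.

At higher minor allele frequencies several carriers are present per site, so
even shallow sequencing usually catches the variant in someone.  This
example compares the singleton curve with MAF 0.01 and 0.05 at low depth.
"""

from seqpower import (
    DetectionSpec,
    SequencingModel,
    estimate_sensitivity,
    estimate_sensitivity_at_frequency,
)

N = 500
spec = DetectionSpec(N, false_positive_rate=1e-3, replicates=20_000, seed=1)
print(f"depth  singleton  MAF=0.01  MAF=0.05   (N={N}, e=0.01)")
for depth in (4, 8, 12, 20, 30):
    model = SequencingModel(depth, 0.01)
    s0 = estimate_sensitivity(model, spec).sensitivity
    s1 = estimate_sensitivity_at_frequency(model, spec, 0.01).sensitivity
    s5 = estimate_sensitivity_at_frequency(model, spec, 0.05).sensitivity
    print(f"{depth:>4}x  {s0:9.3f}  {s1:8.3f}  {s5:8.3f}")
print(
    "\nSingletons need the one carrier to be well covered; at MAF 0.05 some of"
    "\nthe ~50 expected carriers is almost always seen, even at 4-8x.  If"
    "\nsingletons are not the target, shallower sequencing is preferable."
)
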