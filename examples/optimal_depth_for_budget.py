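"""Where to spend a fixed sequencing budget: depth or samples?

With total capacity N*(c+d) fixed, deeper sequencing means fewer samples.
This example sweeps depth under a 200,000x budget with library/prep cost
c = 5 and reports the depth that maximizes the burden test's non-centrality
parameter (a power surrogate that does not saturate at 1).
"""

import warnings

from seqpower import (
    CostModel,
    DetectionSpec,
    DiseaseModel,
    SequencingModel,
    optimal_depth_by_ncp,
    sweep_depths,
)

warnings.filterwarnings("ignore", message="carrier-conditional")

sweep = sweep_depths(
    CostModel(prep_cost=5, capacity=200_000),
    DiseaseModel(relative_risk=10, prevalence=0.2, singleton_freq=0.008),
    SequencingModel(1.0, error_rate=0.01),  # depth is filled per grid point
    DetectionSpec(2, false_positive_rate=1e-3, replicates=20_000, seed=1),
    depths=range(6, 41, 2),
)
print("depth      N   sensitivity    NCP    power")
for pt in sweep:
    print(f"{pt.depth:4.0f}x {pt.n_total:>6}  {pt.sensitivity:10.3f}  {pt.ncp:6.3f}  "
          f"{100 * pt.power:6.2f}%")

opt = optimal_depth_by_ncp(sweep)
lo, hi = opt.near_optimal_depths
print(
    f"\nNCP is maximized at {opt.best.depth:.0f}x (N={opt.best.n_total}, "
    f"power {100 * opt.best.power:.2f}%); depths {lo:.0f}-{hi:.0f}x stay within "
    "99% of the maximum.\nShallower designs miss singletons; deeper ones buy "
    "too few samples - the optimum sits in the 15-20x window."
)
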