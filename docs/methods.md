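# Methods

`seqpower` models one study-design decision: given a fixed sequencing
budget, how deep should a rare-variant case-control study sequence, and how
many samples should it enroll?  The package couples a Monte-Carlo model of
singleton detection to closed-form burden-test power and searches a depth
grid for the design that maximizes the test's non-centrality parameter.

## Singleton detection model

At a single genomic site in a cohort of `N` individuals sequenced to mean
depth `d`:

- each individual's read count is `n_i ~ Poisson(d)`;
- a non-carrier shows a variant base only through sequencing error,
  `k_i ~ Binomial(n_i, e)`;
- a heterozygous carrier samples one of its two chromosomes per read, so a
  variant base appears with probability `0.5(1-e) + 0.5e = 0.5` and
  `k_i ~ Binomial(n_i, 0.5)`.

The caller compares two hypotheses across the *whole cohort*: everyone is
reference, or a variant segregates at frequency `pi = 1/(2N)`.  The site
statistic is `sum_i log g(n_i, k_i)` with

```
g(n, k) = (1 - pi) + pi * B(k; n, 0.5) / B(k; n, e)
```

where `B` is the binomial pmf; the binomial coefficients cancel in the
ratio, and all arithmetic is done in log space (`logaddexp`), so the
statistic is stable at arbitrary depth.  Aggregating over all `N`
individuals (rather than scoring only the putative carrier) is what makes
the caller grow more stringent as cohorts grow — the empirically observed
slow decay of sensitivity with `N` — because larger cohorts offer more
opportunities for error pile-ups that the null quantile must clear.

**Calibration.** The detection threshold is the empirical `(1-gamma)`
quantile (order statistic at index `ceil((1-gamma)*R)` of `R` sorted null
replicates) of the statistic under no-carrier simulations at the same
`(d, N, e)`.  `gamma` is therefore a per-site false-positive rate.  Ties at
the threshold count as non-detection (strict inequality).  A warning is
emitted when `gamma * replicates < 10`, where the tail order statistic is
unstable; at `gamma = 1e-3` the default 200,000 replicates put ~200 null
draws beyond the quantile.  Sensitivity is the fraction of carrier
replicates exceeding the threshold; carriers that draw zero reads are
retained as non-detections.

**Aggregated sampling.** Non-carrier individuals are i.i.d. over a
truncated `(n, k)` grid (depth truncated at the smallest `n_max` with
Poisson tail mass < 1e-12, residual folded into `n_max`).  Per replicate a
single multinomial draw yields the number of individuals in each cell, and
the statistic is the dot product of those counts with the per-cell log
factors.  Cells are ordered by decreasing probability so the multinomial
sampler exhausts its budget early.  This makes 200,000 replicates at
`N = 20,000` run in seconds; the carrier is always drawn individually.
`sample_site_read_counts`/`site_log_lr` provide the direct per-individual
path, and an exact-enumeration oracle (`exact_sensitivity_oracle`,
cohorts <= 3) convolves the per-individual statistic distributions and is
used in the tests to verify the sampler end to end.

**Null/carrier streams.** Both replicate streams are independent
sub-streams spawned from the user seed, so estimates are bit-reproducible
and threshold calibration never reuses carrier randomness.

## Disease model and burden-test power

A gene of length `L` bp (default 1,000) carries singletons at rate `p` per
gene per person.  Carrying one multiplies disease risk by `r` against
prevalence `f`.  Bayes' rule gives `P(singleton | case)` and
`P(singleton | control)` (closed forms in `seqpower.burden`).  At finite
depth the observed ("detected") per-site frequencies fold in the caller:

```
p_A* = s * P(s|case)    + gamma * (1 - P(s|case))
p_U* = s * P(s|control) + gamma * (1 - P(s|control))
```

The false-positive term is kept exactly as written even though it adds
equal signal to both arms; `gamma` is per site, so its per-gene
contribution is `L * gamma`.  Per-gene counts are treated as Poisson
(variance = mean; no overdispersion option), giving the two-sample t
non-centrality

```
lambda = L (p_A* - p_U*) / sqrt(L p_A*/N_A + L p_U*/N_U)
```

with `nu = N_A + N_U - 2` degrees of freedom (the conventional two-sample
choice; at these cohort sizes the value of `nu` is numerically immaterial).
Power is the *sum of both tails* of the non-central t beyond the central-t
critical value at `alpha = 2.5e-6` (~20,000 independent gene regions); the
distribution is asymmetric, so one tail is never doubled.  Because
`scipy.stats.nct` returns NaN for some large-`nu`/non-centrality
combinations, the tail mass is computed by quadrature of the normal tails
of `(Z + lambda)/sqrt(W/nu)` over the chi-square density of `W`; tests
cross-check it against `scipy.stats.nct` at moderate `nu` and against the
normal limit at large `nu` (agreement < 1e-3 for `nu > 1000`).

A note on extreme parameter sets: designs with `r * f` near or above 1
(e.g. `r = 15`, `f = 0.2`) imply a carrier-conditional risk above 1, and
the control carrier frequency from the closed form goes slightly negative.
These corner cases are standard inputs in this literature, so the model
evaluates the formulas as written and emits a `UserWarning` instead of
refusing; `noncentrality` raises only if a *detected* frequency is negative
(the `gamma` term normally keeps it positive).

## Cost model and depth optimization

Study cost is proportional to `N * (c + d)`: `c` expresses per-sample
library/preparation cost in depth-equivalent units.  For capacity `C` the
affordable cohort is `N = floor(C / (c + d))` (truncation, not rounding).
`sweep_depths` walks a depth grid (default 2-50x in 1x steps), re-calibrates
the caller at each `(d, N)` pair, and chains the power computation;
case/control allocation splits proportionally with the remainder assigned
to cases, and depths leaving an arm below 2 samples are skipped with a
warning.  `optimal_depth_by_ncp` reports the grid point of maximal
non-centrality (ties to the lower depth, i.e. the larger sample) together
with the depth interval holding >= 99% of the maximum, since the optimum is
a broad plateau: power saturates at 1 and hides differences that the NCP
still resolves.  Sensitivity depends only on `(d, N, e, gamma, replicates,
seed)`, so a sweep's sensitivity cache is reusable across disease scenarios
at the same budget.

## Rare variants beyond singletons

`estimate_sensitivity_at_frequency` generalizes the carrier model: under
the alternative, genotypes are Hardy-Weinberg at the chosen minor allele
frequency (heterozygote read probability 0.5, homozygote `1 - e`), the
mixture weight in `g` is the allele frequency, and replicates are
conditioned on at least one carrier (optionally exactly one heterozygote,
which recovers the singleton case at frequency `1/(2N)`).  The carrier
configuration and likelihood prior for this extension are a reasoned
reconstruction rather than a uniquely determined procedure, so the
package validates its behavior qualitatively (ordering and saturation with
depth) rather than against printed values.

## Defaults and what the simulations do not model

Defaults: `e = 0.01`, `gamma = 1e-3`, 200,000 replicates, seed 0,
`L = 1000` bp, `alpha = 2.5e-6`, depth grid 2-50x.  These are the operating
conditions under which the reference sensitivity and power values were
established; reduce `replicates` for exploratory runs, but note that the
threshold is a far-tail order statistic — at 20,000 replicates its noise
alone can move sensitivity by a couple of points, which dominates the
binomial error of the sensitivity fraction itself.  The acceptance script
uses 200,000 replicates for sensitivity points, 1,000,000 for the power
design points (whose chains amplify the threshold noise), and 100,000 per
point for the 49-depth budget sweep — roughly ten minutes on one CPU.

The read simulator draws even Poisson coverage and a single fixed per-base
error rate.  Real sequencing has uneven coverage, mixed base qualities,
mapping artifacts and indels, all of which shift absolute sensitivities —
empirical callers on down-sampled data differ from this model by a few
points in either direction.  Passing tests therefore validate the model's
internal consistency and its design *rankings* (where the optimum lies, how
it shifts with cost structure), not exact sensitivities on any particular
platform.  Dollar-denominated costing, multi-stage designs,
quantitative-trait endpoints and genotype-level tests on real call sets are
out of scope.
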