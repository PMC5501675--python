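"""Monte-Carlo simulation of singleton detection under a site-level likelihood-ratio caller.

A cohort of ``N`` individuals is sequenced to a mean depth ``d``; at a given
genomic site each individual contributes ``n_i ~ Poisson(d)`` reads.  A
non-carrier shows a variant base only through sequencing error
(``k_i ~ Binomial(n_i, e)``), while a heterozygous carrier samples one of its
two chromosomes per read, so the marginal variant-read probability is
``0.5*(1-e) + 0.5*e = 0.5``.

The caller evaluates, per site, the likelihood of the observed read counts
under two hypotheses: all individuals match the reference, or a rare variant
segregates at frequency ``1/(2N)``.  The per-individual likelihood factor is

    g(n, k) = (1 - pi) + pi * B(k; n, 0.5) / B(k; n, e),    pi = 1/(2N),

(binomial coefficients cancel in the ratio), and the site statistic is
``sum_i log g(n_i, k_i)``.  A site is called when the statistic exceeds the
empirical ``(1 - gamma)`` quantile of null (no-carrier) simulations run at
the same depth, cohort size and error rate, so ``gamma`` is the per-site
false-positive rate of the caller.

Sensitivity -- the probability that a true singleton is called -- is the
fraction of carrier replicates whose statistic strictly exceeds that
threshold.  Replicates with an unlucky zero-depth carrier count as
non-detections; they are part of the sensitivity, not excluded.

For tractability at large ``N`` the i.i.d. non-carrier individuals are not
sampled one by one: their joint (depth, variant reads) outcomes live on a
truncated grid and a single multinomial draw per replicate yields the count
of individuals in each grid cell, which is then dotted with the per-cell log
factors.  The carrier is always drawn individually.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

__all__ = [
    "SequencingModel",
    "DetectionSpec",
    "SiteReadCounts",
    "SensitivityEstimate",
    "sample_site_read_counts",
    "site_log_lr",
    "calibrate_threshold",
    "threshold_from_null",
    "simulate_null_log_lrs",
    "simulate_carrier_log_lrs",
    "estimate_sensitivity",
    "exact_sensitivity_oracle",
    "estimate_sensitivity_at_frequency",
]

#: Poisson upper-tail mass allowed beyond the truncated depth grid.
GRID_TAIL_MASS = 1e-12

# Sub-stream indices spawned from the master seed; null and carrier
# replicates never share a stream.
_STREAM_NULL = 0
_STREAM_CARRIER = 1
_STREAM_FREQ_NULL = 2
_STREAM_FREQ_ALT = 3


@dataclass(frozen=True)
class SequencingModel:
    """Per-site sequencing process: mean read depth and per-base error rate."""

    mean_depth: float
    error_rate: float

    def __post_init__(self) -> None:
        if not self.mean_depth > 0:
            raise ValueError(f"mean_depth must be positive, got {self.mean_depth}")
        if not 0 < self.error_rate < 0.5:
            raise ValueError(f"error_rate must be in (0, 0.5), got {self.error_rate}")


@dataclass(frozen=True)
class DetectionSpec:
    """Caller operating point: cohort size, per-site false-positive rate, replicates, seed."""

    cohort_size: int
    false_positive_rate: float = 1e-3
    replicates: int = 200_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cohort_size < 1:
            raise ValueError("cohort_size must be >= 1")
        if not 0 < self.false_positive_rate < 1:
            raise ValueError("false_positive_rate must be in (0, 1)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class SiteReadCounts:
    """Per-individual (total reads, variant reads) at one site."""

    total_reads: np.ndarray
    variant_reads: np.ndarray

    def __post_init__(self) -> None:
        self.total_reads = np.asarray(self.total_reads, dtype=np.int64)
        self.variant_reads = np.asarray(self.variant_reads, dtype=np.int64)
        if self.total_reads.shape != self.variant_reads.shape:
            raise ValueError("total_reads and variant_reads must have equal length")
        if np.any(self.variant_reads < 0) or np.any(self.variant_reads > self.total_reads):
            raise ValueError("variant_reads must satisfy 0 <= k_i <= n_i")

    def __len__(self) -> int:
        return self.total_reads.size


@dataclass(frozen=True)
class SensitivityEstimate:
    sensitivity: float
    monte_carlo_se: float
    threshold: float
    replicates_used: int


def _log_factor(n, k, error_rate: float, prior: float):
    """log g(n, k) with mixture weight ``prior`` on the heterozygote branch.

    Evaluated in log space via logaddexp so the likelihood ratio
    B(k; n, 0.5)/B(k; n, e) never overflows at high depth.
    """
    n = np.asarray(n, dtype=np.float64)
    k = np.asarray(k, dtype=np.float64)
    log_ratio = n * np.log(0.5) - (k * np.log(error_rate) + (n - k) * np.log1p(-error_rate))
    return np.logaddexp(np.log1p(-prior), np.log(prior) + log_ratio)


def _carrier_prior(spec: DetectionSpec) -> float:
    return 1.0 / (2.0 * spec.cohort_size)


def _rng_for(spec: DetectionSpec, stream: int) -> np.random.Generator:
    children = np.random.SeedSequence(spec.seed).spawn(4)
    return np.random.default_rng(children[stream])


def sample_site_read_counts(
    model: SequencingModel,
    spec: DetectionSpec,
    carrier_present: bool,
    rng: np.random.Generator,
) -> SiteReadCounts:
    """Draw one site's read counts for the whole cohort.

    When ``carrier_present``, individual 0 is the heterozygous carrier and its
    variant reads are Binomial(n, 0.5); everyone else shows variant bases only
    through error, Binomial(n, e).
    """
    n = rng.poisson(model.mean_depth, size=spec.cohort_size)
    k = rng.binomial(n, model.error_rate)
    if carrier_present:
        k[0] = rng.binomial(n[0], 0.5)
    return SiteReadCounts(n, k)


def site_log_lr(counts: SiteReadCounts, model: SequencingModel, spec: DetectionSpec) -> float:
    """Site log likelihood ratio: sum of per-individual log factors."""
    if len(counts) != spec.cohort_size:
        raise ValueError(
            f"counts has {len(counts)} individuals, spec.cohort_size is {spec.cohort_size}"
        )
    pi = _carrier_prior(spec)
    return float(
        np.sum(_log_factor(counts.total_reads, counts.variant_reads, model.error_rate, pi))
    )


class _SiteGrid:
    """Truncated (n, k) outcome grid for one non-carrier individual.

    Depth is truncated at the smallest n_max whose Poisson upper-tail mass is
    below GRID_TAIL_MASS; the residual mass is folded into n_max.  Cells are
    ordered by decreasing probability, which lets the multinomial sampler
    exhaust the draw early.
    """

    def __init__(self, model: SequencingModel, prior: float, read_prob: float | None = None):
        d, e = model.mean_depth, model.error_rate
        if read_prob is None:
            read_prob = e
        n_max = max(1, int(stats.poisson.isf(GRID_TAIL_MASS, d)) + 1)
        depths = np.arange(n_max + 1)
        p_depth = stats.poisson.pmf(depths, d)
        p_depth[-1] += stats.poisson.sf(n_max, d)
        ns = np.repeat(depths, depths + 1)
        ks = np.concatenate([np.arange(n + 1) for n in depths])
        p = p_depth[ns] * stats.binom.pmf(ks, ns, read_prob)
        logg = _log_factor(ns, ks, e, prior)
        order = np.argsort(p)[::-1]
        self.ns = ns[order]
        self.ks = ks[order]
        self.p = p[order] / p[order].sum()
        self.logg = logg[order]

    @property
    def n_cells(self) -> int:
        return self.p.size


def _aggregate_llrs(
    grid: _SiteGrid, n_individuals: int, replicates: int, rng: np.random.Generator
) -> np.ndarray:
    """Sum of log factors over ``n_individuals`` i.i.d. grid draws, per replicate."""
    if n_individuals == 0:
        return np.zeros(replicates)
    out = np.empty(replicates)
    chunk = max(1, int(4e6 / grid.n_cells))
    pos = 0
    while pos < replicates:
        m = min(chunk, replicates - pos)
        counts = rng.multinomial(n_individuals, grid.p, size=m)
        out[pos : pos + m] = counts @ grid.logg
        pos += m
    return out


def _carrier_llr_terms(
    model: SequencingModel, prior: float, replicates: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-replicate log factor of a heterozygous carrier (drawn individually)."""
    n = rng.poisson(model.mean_depth, size=replicates)
    k = rng.binomial(n, 0.5)
    return _log_factor(n, k, model.error_rate, prior)


def threshold_from_null(null_llrs: np.ndarray, false_positive_rate: float) -> float:
    """Empirical (1-gamma) quantile: order statistic at ceil((1-gamma)*m)."""
    m = null_llrs.size
    idx = int(np.ceil((1.0 - false_positive_rate) * m)) - 1
    return float(np.partition(null_llrs, idx)[idx])


def simulate_null_log_lrs(model: SequencingModel, spec: DetectionSpec) -> np.ndarray:
    """The null (no-carrier) site log-LR replicate stream, one value per replicate."""
    grid = _SiteGrid(model, _carrier_prior(spec))
    rng = _rng_for(spec, _STREAM_NULL)
    return _aggregate_llrs(grid, spec.cohort_size, spec.replicates, rng)


def simulate_carrier_log_lrs(model: SequencingModel, spec: DetectionSpec) -> np.ndarray:
    """The carrier (one heterozygote, N-1 non-carriers) site log-LR stream."""
    pi = _carrier_prior(spec)
    rng = _rng_for(spec, _STREAM_CARRIER)
    grid = _SiteGrid(model, pi)
    llrs = _aggregate_llrs(grid, spec.cohort_size - 1, spec.replicates, rng)
    return llrs + _carrier_llr_terms(model, pi, spec.replicates, rng)


def calibrate_threshold(model: SequencingModel, spec: DetectionSpec) -> float:
    """Detection threshold: empirical (1-gamma) quantile of null site log-LRs.

    Deterministic given ``spec.seed`` (the null replicate stream is derived
    from it).  Warns when fewer than ~10 null replicates are expected beyond
    the quantile, where the tail order statistic is unstable.
    """
    if spec.false_positive_rate * spec.replicates < 10:
        warnings.warn(
            "false_positive_rate * replicates < 10: the calibrated threshold is an "
            "unstable tail quantile",
            stacklevel=2,
        )
    return threshold_from_null(simulate_null_log_lrs(model, spec), spec.false_positive_rate)


def estimate_sensitivity(model: SequencingModel, spec: DetectionSpec) -> SensitivityEstimate:
    """Monte-Carlo singleton-detection sensitivity at the calibrated threshold.

    Runs ``spec.replicates`` carrier replicates (one heterozygous carrier,
    N-1 non-carriers) and reports the fraction whose site log-LR strictly
    exceeds the null-calibrated threshold, with its binomial standard error.
    Null and carrier replicates use independent sub-streams of ``spec.seed``,
    so results are reproducible bit-for-bit.
    """
    threshold = calibrate_threshold(model, spec)
    llrs = simulate_carrier_log_lrs(model, spec)
    sens = float(np.mean(llrs > threshold))
    se = float(np.sqrt(sens * (1.0 - sens) / spec.replicates))
    return SensitivityEstimate(sens, se, threshold, spec.replicates)


# ---------------------------------------------------------------------------
# Exact enumeration oracle (small cohorts)
# ---------------------------------------------------------------------------

_ORACLE_MAX_COHORT = 3
_VALUE_DECIMALS = 9


def _individual_distribution(
    model: SequencingModel, prior: float, read_prob: float, n_max: int
) -> tuple[np.ndarray, np.ndarray]:
    depths = np.arange(n_max + 1)
    p_depth = stats.poisson.pmf(depths, model.mean_depth)
    p_depth[-1] += stats.poisson.sf(n_max, model.mean_depth)
    ns = np.repeat(depths, depths + 1)
    ks = np.concatenate([np.arange(n + 1) for n in depths])
    probs = p_depth[ns] * stats.binom.pmf(ks, ns, read_prob)
    values = np.round(_log_factor(ns, ks, model.error_rate, prior), _VALUE_DECIMALS)
    return _collapse(values, probs)


def _collapse(values: np.ndarray, probs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq, inverse = np.unique(values, return_inverse=True)
    return uniq, np.bincount(inverse, weights=probs)


def _convolve(
    a: tuple[np.ndarray, np.ndarray], b: tuple[np.ndarray, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    values = np.round(a[0][:, None] + b[0][None, :], _VALUE_DECIMALS).ravel()
    probs = (a[1][:, None] * b[1][None, :]).ravel()
    return _collapse(values, probs)


def exact_sensitivity_oracle(
    model: SequencingModel,
    spec: DetectionSpec,
    depth_truncation: int | None = None,
    threshold: float | None = None,
) -> SensitivityEstimate:
    """Sensitivity by exhaustive enumeration -- no sampling.

    Enumerates every (n, k) outcome per individual up to ``depth_truncation``
    reads, convolves the exact site log-LR distributions under the null and
    the one-carrier configuration, and returns the exact probability mass
    strictly above the exact (1-gamma) null quantile.  Cohorts above 3 are
    refused: the support grows geometrically with cohort size.

    The empirical quantile of a Monte-Carlo calibration can land on either of
    two adjacent support atoms when the null cdf sits near ``1 - gamma``;
    pass ``threshold`` to evaluate the exact tail above a given (e.g. the
    Monte-Carlo calibrated) threshold instead of the exact quantile.
    """
    n_ind = spec.cohort_size
    if n_ind > _ORACLE_MAX_COHORT:
        raise ValueError(
            f"exact enumeration supports cohort_size <= {_ORACLE_MAX_COHORT}, got {n_ind}"
        )
    if depth_truncation is None:
        depth_truncation = max(1, int(stats.poisson.isf(GRID_TAIL_MASS, model.mean_depth)) + 1)
    pi = _carrier_prior(spec)
    null_one = _individual_distribution(model, pi, model.error_rate, depth_truncation)
    carrier_one = _individual_distribution(model, pi, 0.5, depth_truncation)

    null_dist = null_one
    for _ in range(n_ind - 1):
        null_dist = _convolve(null_dist, null_one)
    alt_dist = carrier_one
    for _ in range(n_ind - 1):
        alt_dist = _convolve(alt_dist, null_one)

    if threshold is None:
        values, probs = null_dist
        order = np.argsort(values)
        cdf = np.cumsum(probs[order])
        i = int(np.searchsorted(cdf, 1.0 - spec.false_positive_rate, side="left"))
        i = min(i, values.size - 1)
        threshold = float(values[order][i])
    else:
        # align with the rounded support; ties at the threshold never detect
        threshold = float(np.round(threshold, _VALUE_DECIMALS))

    alt_values, alt_probs = alt_dist
    sens = float(alt_probs[alt_values > threshold + 10.0**-_VALUE_DECIMALS / 2].sum())
    return SensitivityEstimate(sens, 0.0, threshold, 0)


# ---------------------------------------------------------------------------
# Generalized rare-variant frequencies (Hardy-Weinberg carriers)
# ---------------------------------------------------------------------------


def estimate_sensitivity_at_frequency(
    model: SequencingModel,
    spec: DetectionSpec,
    allele_frequency: float,
    conditioning: str = "at_least_one",
) -> SensitivityEstimate:
    """Detection sensitivity for a variant at the given population frequency.

    Generalizes the singleton simulation: under the alternative each
    individual's genotype is drawn from Hardy-Weinberg proportions at
    ``allele_frequency`` (variant-read probability 0.5 for heterozygotes,
    1-e for homozygotes), the per-individual likelihood factor uses the
    allele frequency as its mixture weight, and replicates are conditioned on
    carriers being present: ``"at_least_one"`` (default) or
    ``"exactly_one_het"``.  With ``allele_frequency = 1/(2N)`` and the
    single-heterozygote conditioning this recovers the singleton case.
    """
    q = allele_frequency
    if not 0 < q <= 0.5:
        raise ValueError("allele_frequency must be in (0, 0.5]")
    if conditioning not in ("at_least_one", "exactly_one_het"):
        raise ValueError("conditioning must be 'at_least_one' or 'exactly_one_het'")
    n_ind, reps = spec.cohort_size, spec.replicates
    if spec.false_positive_rate * reps < 10:
        warnings.warn(
            "false_positive_rate * replicates < 10: unstable tail quantile", stacklevel=2
        )
    ref_grid = _SiteGrid(model, q)  # non-carrier outcomes, prior weight = q

    rng_null = _rng_for(spec, _STREAM_FREQ_NULL)
    null = _aggregate_llrs(ref_grid, n_ind, reps, rng_null)
    threshold = threshold_from_null(null, spec.false_positive_rate)

    rng = _rng_for(spec, _STREAM_FREQ_ALT)
    geno_p = [(1 - q) ** 2, 2 * q * (1 - q), q**2]
    geno = rng.multinomial(n_ind, geno_p, size=reps)
    if conditioning == "at_least_one":
        rejected = lambda g: g[:, 1] + g[:, 2] == 0  # noqa: E731
    else:  # exactly one heterozygous carrier
        rejected = lambda g: (g[:, 1] != 1) | (g[:, 2] != 0)  # noqa: E731
    for _ in range(10_000):
        bad = rejected(geno)
        if not bad.any():
            break
        geno[bad] = rng.multinomial(n_ind, geno_p, size=int(bad.sum()))
    else:  # pragma: no cover - would need astronomically small q * N
        raise RuntimeError("failed to draw replicates satisfying the carrier conditioning")

    llrs = np.zeros(reps)
    # homozygous-reference individuals: aggregated multinomial draws,
    # grouped by how many such individuals each replicate has
    for m_ref in np.unique(geno[:, 0]):
        rows = np.flatnonzero(geno[:, 0] == m_ref)
        if m_ref > 0:
            llrs[rows] += _aggregate_llrs(ref_grid, int(m_ref), rows.size, rng)
    # carriers drawn individually
    for col, read_prob in ((1, 0.5), (2, 1.0 - model.error_rate)):
        m = geno[:, col]
        total = int(m.sum())
        if total == 0:
            continue
        rep_idx = np.repeat(np.arange(reps), m)
        n = rng.poisson(model.mean_depth, size=total)
        k = rng.binomial(n, read_prob)
        terms = _log_factor(n, k, model.error_rate, q)
        llrs += np.bincount(rep_idx, weights=terms, minlength=reps)

    sens = float(np.mean(llrs > threshold))
    se = float(np.sqrt(sens * (1.0 - sens) / reps))
    return SensitivityEstimate(sens, se, threshold, reps)


def singleton_spec(spec: DetectionSpec, **changes) -> DetectionSpec:
    """Convenience: a copy of ``spec`` with fields replaced."""
    return replace(spec, **changes)
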