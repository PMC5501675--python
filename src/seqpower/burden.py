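"""Closed-form power of the case-control singleton burden test.

Disease model
-------------
A gene of length ``L`` bp carries singletons at rate ``p`` per gene per
person, i.e. ``p/L`` per site per person.  Carrying a singleton multiplies
disease risk by the relative risk ``r`` against a background prevalence
``f``.  Writing ``f0 = f / (r*p/L + 1 - p/L)`` for the non-carrier risk,
Bayes' rule gives the carrier probabilities conditional on disease status:

    P(singleton | case)    = (r*p/L) / (r*p/L + 1 - p/L)
    P(singleton | control) = (p/L) * (r*p/L + 1 - p/L - r*f)
                             / ((1 - f) * (r*p/L + 1 - p/L))

At finite sequencing depth a singleton is only observed through the caller;
with sensitivity ``s`` and per-site false-positive rate ``gamma`` the
*detected* per-site frequencies are

    p_A* = s * P(singleton|case)    + gamma * (1 - P(singleton|case))
    p_U* = s * P(singleton|control) + gamma * (1 - P(singleton|control))

Burden test
-----------
Per-gene singleton counts are modelled as Poisson with mean (and variance)
``L * p*``.  The two-sample t statistic comparing mean counts between
``N_A`` cases and ``N_U`` controls then has non-centrality

    lambda = L*(p_A* - p_U*) / sqrt(L*p_A*/N_A + L*p_U*/N_U)

and power is the two-sided tail mass of the non-central t with
``nu = N_A + N_U - 2`` degrees of freedom beyond the central-t critical
value at significance ``alpha`` (default 2.5e-6, i.e. ~20,000 genes).

Note on extreme models: for large ``r*f`` the implied carrier-conditional
risk ``r*f0`` exceeds 1 and the control carrier frequency goes (slightly)
negative; the closed forms are still evaluated, with a warning, because the
false-positive term usually keeps the detected frequencies positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

__all__ = [
    "DiseaseModel",
    "DetectionOperatingPoint",
    "BurdenTestSetup",
    "PowerResult",
    "carrier_prob_case",
    "carrier_prob_control",
    "detected_frequencies",
    "noncentrality",
    "power_from_ncp",
    "power_at_design",
]

DEFAULT_ALPHA = 2.5e-6


@dataclass(frozen=True)
class DiseaseModel:
    """Relative risk r, prevalence f, singletons per gene per person p, gene length L."""

    relative_risk: float
    prevalence: float
    singleton_freq: float
    gene_length: float = 1000.0

    def __post_init__(self) -> None:
        r, f, p, L = self.relative_risk, self.prevalence, self.singleton_freq, self.gene_length
        if r < 1:
            raise ValueError("relative_risk must be >= 1")
        if not 0 < f < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if p < 0:
            raise ValueError("singleton_freq must be >= 0")
        if L < 1:
            raise ValueError("gene_length must be >= 1")
        if p / L >= 1:
            raise ValueError("per-site carrier probability p/L must be < 1")
        if self.carrier_risk > 1:
            warnings.warn(
                f"carrier-conditional disease risk r*f0 = {self.carrier_risk:.3g} exceeds 1; "
                "the disease model is epidemiologically inconsistent and the control "
                "carrier frequency will be negative",
                stacklevel=2,
            )

    @property
    def per_site_freq(self) -> float:
        return self.singleton_freq / self.gene_length

    @property
    def _norm(self) -> float:
        """r*p/L + 1 - p/L, the prevalence normalizer."""
        pl = self.per_site_freq
        return self.relative_risk * pl + 1.0 - pl

    @property
    def baseline_risk(self) -> float:
        """Non-carrier disease risk f0 implied by the overall prevalence."""
        return self.prevalence / self._norm

    @property
    def carrier_risk(self) -> float:
        return self.relative_risk * self.baseline_risk


@dataclass(frozen=True)
class DetectionOperatingPoint:
    """Caller operating point entering the detected frequencies."""

    sensitivity: float
    false_positive_rate: float

    def __post_init__(self) -> None:
        if not 0 <= self.sensitivity <= 1:
            raise ValueError("sensitivity must be in [0, 1]")
        if not 0 <= self.false_positive_rate <= 1:
            raise ValueError("false_positive_rate must be in [0, 1]")


@dataclass(frozen=True)
class BurdenTestSetup:
    n_cases: int
    n_controls: int
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if self.n_cases < 2 or self.n_controls < 2:
            raise ValueError("each arm needs >= 2 samples for a two-sample t-test")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @property
    def degrees_freedom(self) -> int:
        return self.n_cases + self.n_controls - 2


@dataclass(frozen=True)
class PowerResult:
    ncp: float
    degrees_freedom: int
    power: float
    detected_freq_cases: float
    detected_freq_controls: float


def carrier_prob_case(model: DiseaseModel) -> float:
    """P(singleton | case) under the relative-risk disease model."""
    pl = model.per_site_freq
    return model.relative_risk * pl / model._norm


def carrier_prob_control(model: DiseaseModel) -> float:
    """P(singleton | control); negative if the carrier risk exceeds 1."""
    pl = model.per_site_freq
    r, f = model.relative_risk, model.prevalence
    return pl * (model._norm - r * f) / ((1.0 - f) * model._norm)


def detected_frequencies(
    model: DiseaseModel, op_point: DetectionOperatingPoint
) -> tuple[float, float]:
    """Detected per-site singleton frequencies (p_A*, p_U*) in cases and controls."""
    s, g = op_point.sensitivity, op_point.false_positive_rate
    pa = carrier_prob_case(model)
    pu = carrier_prob_control(model)
    return s * pa + g * (1.0 - pa), s * pu + g * (1.0 - pu)


def noncentrality(
    p_a_star: float, p_u_star: float, model: DiseaseModel, setup: BurdenTestSetup
) -> float:
    """Burden-test non-centrality lambda from the detected frequencies."""
    if p_a_star == 0 and p_u_star == 0:
        raise ZeroDivisionError("both detected frequencies are zero; lambda undefined")
    if p_a_star < 0 or p_u_star < 0:
        raise ValueError(
            "negative detected frequency: the Poisson count variance is undefined "
            f"(p_A*={p_a_star:.3g}, p_U*={p_u_star:.3g})"
        )
    L = model.gene_length
    var = L * p_a_star / setup.n_cases + L * p_u_star / setup.n_controls
    return L * (p_a_star - p_u_star) / np.sqrt(var)


def power_from_ncp(ncp: float, setup: BurdenTestSetup) -> float:
    """Two-sided power P(|T| > t_{alpha/2}(nu)) for T ~ noncentral t(nu, lambda).

    Both tails are summed (the distribution is asymmetric).  The tail mass is
    computed by integrating the normal tails of (Z + lambda)/sqrt(W/nu) over
    the chi-square denominator W, which stays accurate for the very large
    degrees of freedom typical of sequencing studies.
    """
    nu = setup.degrees_freedom
    t_crit = stats.t.isf(setup.alpha / 2.0, nu)

    def tails(w: np.ndarray) -> np.ndarray:
        scale = np.sqrt(w / nu)
        return stats.chi2.pdf(w, nu) * (
            stats.norm.sf(t_crit * scale - ncp) + stats.norm.cdf(-t_crit * scale - ncp)
        )

    lo = stats.chi2.ppf(1e-13, nu)
    hi = stats.chi2.isf(1e-13, nu)
    power, _ = integrate.quad(tails, lo, hi, limit=200)
    return float(min(max(power, 0.0), 1.0))


def power_at_design(
    model: DiseaseModel, setup: BurdenTestSetup, op_point: DetectionOperatingPoint
) -> PowerResult:
    """Full chain: carrier probabilities -> detected frequencies -> lambda -> power."""
    p_a, p_u = detected_frequencies(model, op_point)
    lam = noncentrality(p_a, p_u, model, setup)
    power = power_from_ncp(lam, setup)
    return PowerResult(
        ncp=float(lam),
        degrees_freedom=setup.degrees_freedom,
        power=power,
        detected_freq_cases=p_a,
        detected_freq_controls=p_u,
    )
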