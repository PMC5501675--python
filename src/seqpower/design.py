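"""Fixed-budget study design: cost model, depth sweeps and the NCP-optimal depth.

Total study cost is proportional to ``N * (c + d)`` where ``d`` is the mean
sequencing depth and ``c`` expresses per-sample library/preparation cost in
depth-equivalent units.  For a fixed sequencing capacity, sample size and
depth therefore trade off inversely: ``N = floor(capacity / (c + d))``.

``sweep_depths`` walks a depth grid, sizes the cohort from the budget at
each depth, re-calibrates the variant caller at that (depth, N), and chains
the detected-frequency / non-centrality / power computation.  Because the
caller's sensitivity depends only on (d, N, e, gamma, replicates, seed) and
not on the disease model, a sensitivity cache can be shared across disease
scenarios at the same budget.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import pandas as pd

from .burden import (
    DEFAULT_ALPHA,
    BurdenTestSetup,
    DetectionOperatingPoint,
    DiseaseModel,
    power_at_design,
)
from .detection import DetectionSpec, SensitivityEstimate, SequencingModel, estimate_sensitivity

__all__ = [
    "CostModel",
    "DesignPoint",
    "OptimalDepth",
    "samples_for_budget",
    "allocate_cases_controls",
    "sweep_depths",
    "sweep_depths_fixed_n",
    "optimal_depth_by_ncp",
    "design_points_frame",
]

logger = logging.getLogger(__name__)

DEFAULT_DEPTH_GRID = tuple(range(2, 51))


@dataclass(frozen=True)
class CostModel:
    """Prep cost c (depth-equivalent units/sample) and total capacity N*(c+d)."""

    prep_cost: float
    capacity: float

    def __post_init__(self) -> None:
        if self.prep_cost < 0:
            raise ValueError("prep_cost must be >= 0")
        if self.capacity < 0:
            raise ValueError("capacity must be >= 0")


@dataclass(frozen=True)
class DesignPoint:
    """One candidate study: a depth, the cohort it buys, and its resulting power."""

    depth: float
    n_total: int
    n_cases: int
    n_controls: int
    sensitivity: float
    sensitivity_se: float
    threshold: float
    ncp: float
    power: float

    def __post_init__(self) -> None:
        if self.n_cases + self.n_controls != self.n_total:
            raise ValueError("case/control split must sum to n_total")


@dataclass(frozen=True)
class OptimalDepth:
    best: DesignPoint
    near_optimal_depths: tuple[float, float]  # interval attaining >= 99% of max NCP


def samples_for_budget(cost: CostModel, depth: float) -> int:
    """Largest affordable cohort at the given depth: floor(capacity / (c + d))."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    return int(math.floor(cost.capacity / (cost.prep_cost + depth)))


def allocate_cases_controls(
    n_total: int, ratio_cases: int = 1, ratio_controls: int = 1
) -> tuple[int, int]:
    """Split a cohort in the given case:control ratio; the remainder goes to cases."""
    if ratio_cases <= 0 or ratio_controls <= 0:
        raise ValueError("ratio parts must be positive")
    n_controls = (n_total * ratio_controls) // (ratio_cases + ratio_controls)
    n_cases = n_total - n_controls
    if n_cases < 2 or n_controls < 2:
        raise ValueError(
            f"allocation ({n_cases}, {n_controls}) leaves an arm with < 2 samples"
        )
    return n_cases, n_controls


def _cached_sensitivity(
    seq: SequencingModel,
    spec: DetectionSpec,
    cache: dict | None,
) -> SensitivityEstimate:
    if cache is None:
        return estimate_sensitivity(seq, spec)
    key = (
        seq.mean_depth,
        spec.cohort_size,
        seq.error_rate,
        spec.false_positive_rate,
        spec.replicates,
        spec.seed,
    )
    if key not in cache:
        cache[key] = estimate_sensitivity(seq, spec)
    return cache[key]


def _design_point(
    depth: float,
    n_total: int,
    ratio: tuple[int, int],
    disease: DiseaseModel,
    seq_template: SequencingModel,
    spec_template: DetectionSpec,
    alpha: float,
    cache: dict | None,
) -> DesignPoint | None:
    try:
        n_cases, n_controls = allocate_cases_controls(n_total, *ratio)
    except ValueError as err:
        logger.warning("skipping depth %sx: %s", depth, err)
        return None
    seq = replace(seq_template, mean_depth=float(depth))
    spec = replace(spec_template, cohort_size=n_total)
    est = _cached_sensitivity(seq, spec, cache)
    op = DetectionOperatingPoint(est.sensitivity, spec.false_positive_rate)
    setup = BurdenTestSetup(n_cases, n_controls, alpha)
    result = power_at_design(disease, setup, op)
    return DesignPoint(
        depth=float(depth),
        n_total=n_total,
        n_cases=n_cases,
        n_controls=n_controls,
        sensitivity=est.sensitivity,
        sensitivity_se=est.monte_carlo_se,
        threshold=est.threshold,
        ncp=result.ncp,
        power=result.power,
    )


def sweep_depths(
    cost: CostModel,
    disease: DiseaseModel,
    seq_template: SequencingModel,
    spec_template: DetectionSpec,
    depths=DEFAULT_DEPTH_GRID,
    ratio: tuple[int, int] = (1, 1),
    alpha: float = DEFAULT_ALPHA,
    cache: dict | None = None,
) -> list[DesignPoint]:
    """Fixed-budget sweep: at each depth, size the cohort and compute power.

    Depths where the budget leaves an arm with fewer than 2 samples are
    skipped with a warning.
    """
    if len(depths) == 0:
        raise ValueError("depth grid is empty")
    points = []
    for depth in depths:
        n_total = samples_for_budget(cost, depth)
        point = _design_point(
            depth, n_total, ratio, disease, seq_template, spec_template, alpha, cache
        )
        if point is not None:
            points.append(point)
    return points


def sweep_depths_fixed_n(
    n_total: int,
    disease: DiseaseModel,
    seq_template: SequencingModel,
    spec_template: DetectionSpec,
    depths=DEFAULT_DEPTH_GRID,
    ratio: tuple[int, int] = (1, 1),
    alpha: float = DEFAULT_ALPHA,
    cache: dict | None = None,
) -> list[DesignPoint]:
    """Depth sweep at constant sample size (the cost model bypassed)."""
    if len(depths) == 0:
        raise ValueError("depth grid is empty")
    points = []
    for depth in depths:
        point = _design_point(
            depth, n_total, ratio, disease, seq_template, spec_template, alpha, cache
        )
        if point is not None:
            points.append(point)
    return points


def optimal_depth_by_ncp(sweep: list[DesignPoint]) -> OptimalDepth:
    """The sweep point of maximal non-centrality.

    Ties break toward the lower depth (the larger sample).  Also reports the
    contiguous bounding interval of depths attaining at least 99% of the
    maximum NCP, a measure of how flat the optimum is.
    """
    if not sweep:
        raise ValueError("empty sweep")
    ordered = sorted(sweep, key=lambda pt: pt.depth)
    best = max(ordered, key=lambda pt: pt.ncp)  # max() keeps the first = lowest depth
    near = [pt.depth for pt in ordered if pt.ncp >= 0.99 * best.ncp]
    return OptimalDepth(best=best, near_optimal_depths=(min(near), max(near)))


def design_points_frame(points: list[DesignPoint]) -> pd.DataFrame:
    """Tidy table of a sweep, one row per design point."""
    return pd.DataFrame([vars(pt) for pt in points])
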