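"""Unit and property tests for the singleton-detection simulator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqpower.detection import (
    DetectionSpec,
    SequencingModel,
    SiteReadCounts,
    calibrate_threshold,
    estimate_sensitivity,
    estimate_sensitivity_at_frequency,
    exact_sensitivity_oracle,
    sample_site_read_counts,
    site_log_lr,
)

pytestmark = pytest.mark.filterwarnings(
    "ignore:false_positive_rate \\* replicates < 10"
)


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestReadCountSampling:
    def test_distribution_moments(self):
        model = SequencingModel(10, 0.01)
        spec = DetectionSpec(3, 1e-3, 100, 0)
        rng = _rng(1)
        n_tot, k_tot, draws = 0.0, 0.0, 4000
        for _ in range(draws):
            counts = sample_site_read_counts(model, spec, False, rng)
            n_tot += counts.total_reads.sum()
            k_tot += counts.variant_reads.sum()
        assert n_tot / (3 * draws) == pytest.approx(10, rel=0.02)
        assert k_tot / (3 * draws) == pytest.approx(0.1, rel=0.2)

    def test_vanishing_depth_gives_no_reads(self):
        model = SequencingModel(1e-9, 0.01)
        spec = DetectionSpec(5, 1e-3, 100, 0)
        counts = sample_site_read_counts(model, spec, True, _rng(0))
        assert counts.total_reads.sum() == 0
        assert counts.variant_reads.sum() == 0

    def test_carrier_reads_are_half_variant(self):
        # heterozygote: 0.5*(1-e) + 0.5*e = 0.5 regardless of e
        model = SequencingModel(20, 0.01)
        spec = DetectionSpec(1, 1e-3, 100, 0)
        rng = _rng(2)
        k_tot = n_tot = 0
        for _ in range(3000):
            counts = sample_site_read_counts(model, spec, True, rng)
            n_tot += counts.total_reads[0]
            k_tot += counts.variant_reads[0]
        assert k_tot / n_tot == pytest.approx(0.5, abs=0.01)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError, match="k_i <= n_i"):
            SiteReadCounts([2, 2], [3, 0])


class TestSiteLogLR:
    def test_no_reads_no_information(self):
        model = SequencingModel(10, 0.01)
        spec = DetectionSpec(1, 1e-3, 100, 0)
        assert site_log_lr(SiteReadCounts([0], [0]), model, spec) == pytest.approx(0.0)

    def test_single_variant_read_hand_value(self):
        # N=1: pi=1/2, g(1,1) = 0.5 + 0.5 * (0.5/0.01) = 25.5
        model = SequencingModel(10, 0.01)
        spec = DetectionSpec(1, 1e-3, 100, 0)
        got = site_log_lr(SiteReadCounts([1], [1]), model, spec)
        assert got == pytest.approx(math.log(25.5), rel=1e-12)

    @given(
        st.lists(
            st.tuples(st.integers(0, 40), st.integers(0, 40)).map(
                lambda nk: (max(nk), min(nk))
            ),
            min_size=2,
            max_size=6,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_additive_over_individuals(self, pairs):
        # the product likelihood is a sum of per-individual log factors
        model = SequencingModel(10, 0.01)
        spec = DetectionSpec(len(pairs), 1e-3, 100, 0)
        ns = [n for n, _ in pairs]
        ks = [k for _, k in pairs]
        total = site_log_lr(SiteReadCounts(ns, ks), model, spec)
        parts = sum(
            site_log_lr(SiteReadCounts([0] * (len(pairs) - 1) + [n], [0] * (len(pairs) - 1) + [k]), model, spec)
            for n, k in pairs
        )
        assert total == pytest.approx(parts, abs=1e-9)

    def test_cohort_size_mismatch_raises(self):
        model = SequencingModel(10, 0.01)
        spec = DetectionSpec(3, 1e-3, 100, 0)
        with pytest.raises(ValueError, match="cohort_size"):
            site_log_lr(SiteReadCounts([1], [0]), model, spec)


class TestCalibration:
    def test_threshold_monotone_in_fpr(self):
        model = SequencingModel(10, 0.01)
        lo = calibrate_threshold(model, DetectionSpec(50, 1e-3, 20000, 7))
        hi = calibrate_threshold(model, DetectionSpec(50, 1e-2, 20000, 7))
        assert lo >= hi

    def test_unstable_tail_warns(self):
        model = SequencingModel(10, 0.01)
        with pytest.warns(UserWarning, match="unstable"):
            calibrate_threshold(model, DetectionSpec(10, 1e-4, 1000, 0))

    def test_seed_determinism(self):
        model = SequencingModel(8, 0.01)
        spec = DetectionSpec(100, 1e-3, 5000, 11)
        a = estimate_sensitivity(model, spec)
        b = estimate_sensitivity(model, spec)
        assert a == b
        c = estimate_sensitivity(model, DetectionSpec(100, 1e-3, 5000, 12))
        assert c.threshold != a.threshold or c.sensitivity != a.sensitivity

    def test_realized_null_exceedance_matches_fpr(self):
        # fresh null draws exceed the calibrated threshold at rate ~gamma
        model = SequencingModel(6, 0.01)
        gamma, n_ind, m = 0.01, 50, 20000
        thr = calibrate_threshold(model, DetectionSpec(n_ind, gamma, 20000, 3))
        spec = DetectionSpec(n_ind, gamma, 20000, 3)
        rng = _rng(99)
        exceed = 0
        for _ in range(m):
            counts = sample_site_read_counts(model, spec, False, rng)
            exceed += site_log_lr(counts, model, spec) > thr
        se = math.sqrt(2 * gamma * (1 - gamma) / m)  # draw + calibration noise
        assert exceed / m == pytest.approx(gamma, abs=5 * se)


class TestSensitivityProperties:
    def test_monotone_in_depth(self):
        ests = [
            estimate_sensitivity(SequencingModel(d, 0.01), DetectionSpec(200, 1e-3, 5000, 5))
            for d in (2, 10, 25)
        ]
        for lo, hi in zip(ests, ests[1:]):
            assert hi.sensitivity >= lo.sensitivity - 3 * (lo.monte_carlo_se + hi.monte_carlo_se)

    def test_monotone_in_cohort_size(self):
        small = estimate_sensitivity(SequencingModel(10, 0.01), DetectionSpec(100, 1e-3, 20000, 5))
        large = estimate_sensitivity(SequencingModel(10, 0.01), DetectionSpec(2000, 1e-3, 20000, 5))
        assert small.sensitivity >= large.sensitivity - 3 * (
            small.monte_carlo_se + large.monte_carlo_se
        )

    def test_monotone_in_error_rate(self):
        clean = estimate_sensitivity(SequencingModel(10, 0.005), DetectionSpec(200, 1e-3, 10000, 5))
        noisy = estimate_sensitivity(SequencingModel(10, 0.02), DetectionSpec(200, 1e-3, 10000, 5))
        assert clean.sensitivity >= noisy.sensitivity - 3 * (
            clean.monte_carlo_se + noisy.monte_carlo_se
        )

    def test_monotone_in_fpr(self):
        strict = estimate_sensitivity(SequencingModel(10, 0.01), DetectionSpec(200, 1e-4, 10000, 5))
        lax = estimate_sensitivity(SequencingModel(10, 0.01), DetectionSpec(200, 1e-2, 10000, 5))
        assert lax.sensitivity >= strict.sensitivity - 3 * (
            strict.monte_carlo_se + lax.monte_carlo_se
        )

    def test_negligible_error_closed_form_limit(self):
        # with e ~ 0 the null shows no variant reads, so detection reduces to
        # the carrier sampling >= 1 read from its variant chromosome:
        # P = 1 - exp(-d/2) for Poisson(d) depth
        d = 6.0
        est = estimate_sensitivity(SequencingModel(d, 1e-6), DetectionSpec(20, 1e-3, 20000, 5))
        assert est.sensitivity == pytest.approx(1 - math.exp(-d / 2), abs=3 * est.monte_carlo_se + 1e-3)


class TestExactOracle:
    @pytest.mark.parametrize(
        "n_ind, depth, error, gamma",
        [(1, 10, 0.01, 1e-3), (1, 5, 0.02, 1e-2), (2, 8, 0.01, 1e-3), (2, 5, 0.005, 1e-2)],
    )
    def test_monte_carlo_agrees_with_enumeration(self, n_ind, depth, error, gamma):
        model = SequencingModel(depth, error)
        spec = DetectionSpec(n_ind, gamma, 20000, 13)
        exact = exact_sensitivity_oracle(model, spec)
        mc = estimate_sensitivity(model, spec)
        assert mc.sensitivity == pytest.approx(exact.sensitivity, abs=3 * mc.monte_carlo_se + 1e-3)

    def test_lax_fpr_detects_everything(self):
        model = SequencingModel(10, 0.01)
        est = exact_sensitivity_oracle(model, DetectionSpec(1, 0.999, 100, 0))
        assert est.sensitivity >= 0.99

    def test_closed_form_limit(self):
        est = exact_sensitivity_oracle(SequencingModel(10, 1e-6), DetectionSpec(1, 1e-3, 100, 0))
        assert est.sensitivity == pytest.approx(1 - math.exp(-5), abs=2e-3)

    def test_refuses_large_cohorts(self):
        with pytest.raises(ValueError, match="cohort_size"):
            exact_sensitivity_oracle(SequencingModel(10, 0.01), DetectionSpec(4, 1e-3, 100, 0))


class TestFrequencyExtension:
    def test_reduces_to_singleton_case(self):
        model = SequencingModel(10, 0.01)
        spec = DetectionSpec(100, 1e-3, 20000, 17)
        singleton = estimate_sensitivity(model, spec)
        general = estimate_sensitivity_at_frequency(
            model, spec, 1 / 200, conditioning="exactly_one_het"
        )
        tol = 3 * (singleton.monte_carlo_se + general.monte_carlo_se) + 0.02
        assert general.sensitivity == pytest.approx(singleton.sensitivity, abs=tol)

    def test_common_variants_easier_at_low_depth(self):
        model = SequencingModel(6, 0.01)
        spec = DetectionSpec(500, 1e-3, 10000, 17)
        singleton = estimate_sensitivity(model, spec)
        common = estimate_sensitivity_at_frequency(model, spec, 0.05)
        assert common.sensitivity > singleton.sensitivity

    @pytest.mark.parametrize("freq", [0.01, 0.05])
    def test_high_depth_saturates_all_frequencies(self, freq):
        model = SequencingModel(30, 0.01)
        spec = DetectionSpec(300, 1e-3, 5000, 17)
        est = estimate_sensitivity_at_frequency(model, spec, freq)
        assert est.sensitivity > 0.99

    def test_invalid_frequency_rejected(self):
        model = SequencingModel(10, 0.01)
        spec = DetectionSpec(10, 1e-3, 100, 0)
        with pytest.raises(ValueError):
            estimate_sensitivity_at_frequency(model, spec, 0.7)


class TestValidation:
    @pytest.mark.parametrize("depth, error", [(0, 0.01), (-1, 0.01), (10, 0.6), (10, 0)])
    def test_sequencing_model_invariants(self, depth, error):
        with pytest.raises(ValueError):
            SequencingModel(depth, error)

    @pytest.mark.parametrize("kwargs", [dict(cohort_size=0), dict(false_positive_rate=1.5), dict(replicates=0)])
    def test_detection_spec_invariants(self, kwargs):
        base = dict(cohort_size=10, false_positive_rate=1e-3, replicates=100, seed=0)
        with pytest.raises(ValueError):
            DetectionSpec(**{**base, **kwargs})
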