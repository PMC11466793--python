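"""Disproportionality estimators against hand arithmetic and oracles."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faerspv.signals import (ContingencyTable, EstimatorError, MgpsPrior,
                             build_table, ebgm, fit_mgps,
                             information_component, mixture_loglik, prr, ror)

from conftest import ebgm_quadrature

T = ContingencyTable


class TestBuildTable:
    def test_cells_partition_a_small_universe(self):
        universe = {str(i) for i in range(10)}
        drug = {"0", "1", "2", "3"}
        event = {"0", "1", "4"}  # 2 with drug, 1 without
        t = build_table(event, drug, universe)
        assert (t.a, t.b, t.c, t.d) == (2, 2, 1, 5)

    def test_empty_universe_is_an_error(self):
        with pytest.raises(EstimatorError):
            build_table(set(), set(), set())

    def test_degenerate_comparator_gives_undefined_estimates(self):
        universe = {"1", "2", "3"}
        t = build_table({"1"}, universe, universe)
        assert t.c == t.d == 0
        assert math.isnan(ror(t, zero_correction=None)[0])
        assert math.isnan(prr(t)[0])


class TestRor:
    def test_symmetric_table_is_null(self):
        est, lo, hi = ror(T(10, 10, 10, 10))
        assert est == pytest.approx(1.0)
        assert lo < 1 < hi

    def test_hand_computed_example(self):
        est, lo, hi = ror(T(5, 95, 10, 890))
        assert est == pytest.approx(4.684, abs=1e-3)
        assert lo == pytest.approx(1.57, abs=0.01)
        assert hi == pytest.approx(13.99, abs=0.01)

    def test_zero_cell_continuity_correction(self):
        est, _, _ = ror(T(0, 10, 10, 100), zero_correction=0.5)
        assert est == pytest.approx((0.5 * 100.5) / (10.5 * 10.5))
        assert math.isnan(ror(T(0, 10, 10, 100), zero_correction=None)[0])

    @settings(derandomize=True, max_examples=200)
    @given(st.tuples(*[st.integers(1, 500)] * 4))
    def test_transposition_symmetry_and_prr_dominance(self, cells):
        a, b, c, d = cells
        t = T(a, b, c, d)
        swapped = T(a, c, b, d)  # drug/event roles exchanged
        assert ror(t)[0] == pytest.approx(ror(swapped)[0])
        p, _ = prr(t)
        if p > 1:
            assert ror(t)[0] >= p - 1e-12


class TestPrr:
    def test_null_table(self):
        p, chi2 = prr(T(10, 10, 10, 10))
        assert p == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0)

    def test_hand_computed_example(self):
        p, chi2 = prr(T(5, 95, 10, 890))
        assert p == pytest.approx(4.50, abs=1e-2)
        assert chi2 == pytest.approx(9.21, abs=0.01)

    def test_scaling_all_cells(self):
        p1, c1 = prr(T(5, 95, 10, 890))
        p10, c10 = prr(T(50, 950, 100, 8900))
        assert p10 == pytest.approx(p1)
        assert c10 == pytest.approx(10 * c1)

    def test_yates_correction_reduces_chi2(self):
        assert prr(T(5, 95, 10, 890), yates=True)[1] < prr(T(5, 95, 10, 890))[1]


class TestInformationComponent:
    def test_observed_equals_expected_gives_zero(self):
        t = T(10, 10, 10, 10)  # E = 20*20/40 = 10 = a
        ic, _ = information_component(t)
        assert ic == pytest.approx(0.0)

    def test_hand_computed_example(self):
        ic, ic025 = information_component(T(5, 95, 10, 890))
        assert ic == pytest.approx(1.459, abs=1e-3)
        assert ic025 == pytest.approx(-0.103, abs=1e-3)

    def test_credibility_bound_tightens_with_counts(self):
        # a/E fixed at 4 while a grows: IC025 -> IC
        gaps = []
        for scale in (1, 10, 100):
            t = T(8 * scale, 92 * scale, 2 * scale, 898 * scale)
            ic, ic025 = information_component(t)
            gaps.append(ic - ic025)
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 0.15


class TestMgps:
    def test_prior_concentrates_on_unit_lambda_under_null(self):
        rng = np.random.default_rng(1)
        e = rng.uniform(0.5, 50, 5000)
        a = rng.poisson(e)  # lambda = 1 everywhere
        prior = fit_mgps(a, e)
        assert prior.converged
        assert prior.cdf(2.0) - prior.cdf(0.5) > 0.95

    def test_duplicating_every_table_leaves_the_argmax(self):
        rng = np.random.default_rng(2)
        e = rng.uniform(0.5, 20, 400)
        a = rng.poisson(1.5 * e)
        p1 = fit_mgps(a, e)
        p2 = fit_mgps(np.concatenate([a, a]), np.concatenate([e, e]))
        assert p2.loglik == pytest.approx(2 * p1.loglik, rel=1e-4)
        g1 = ebgm(7, 3.0, p1)[0]
        g2 = ebgm(7, 3.0, p2)[0]
        assert g2 == pytest.approx(g1, rel=2e-3)

    def test_component_swap_leaves_posterior_invariant(self):
        p = MgpsPrior(0.7, 0.4, 2.1, 1.9, 0.3, converged=True)
        swapped = MgpsPrior(2.1, 1.9, 0.7, 0.4, 0.7, converged=True)
        for a, e in [(0, 0.3), (4, 1.2), (40, 11.0)]:
            assert ebgm(a, e, p) == pytest.approx(ebgm(a, e, swapped))

    def test_loglik_matches_direct_sum(self):
        # direct negative-binomial mixture evaluation at a known theta
        theta = np.array([math.log(0.7), math.log(0.4), math.log(2.1),
                          math.log(1.9), 0.0])
        a = np.array([0.0, 3.0, 9.0])
        e = np.array([0.5, 2.0, 3.0])
        from scipy.stats import nbinom
        def marg(ai, ei, al, be):
            return nbinom.pmf(ai, al, be / (be + ei))
        direct = sum(math.log(0.5 * marg(ai, ei, 0.7, 0.4)
                              + 0.5 * marg(ai, ei, 2.1, 1.9))
                     for ai, ei in zip(a, e))
        assert mixture_loglik(theta, a, e) == pytest.approx(direct)


class TestEbgm:
    PRIOR = MgpsPrior(0.7, 0.4, 2.1, 1.9, 0.3, converged=True)

    def test_zero_count_shrinks_to_prior_but_stays_positive(self):
        g, lo, hi = ebgm(0, 0.05, self.PRIOR)
        assert 0 < lo < g < hi

    def test_shrinkage_vanishes_at_large_counts(self):
        g, lo, _ = ebgm(4000, 1000.0, self.PRIOR)
        assert g == pytest.approx(4.0, rel=0.02)
        assert lo == pytest.approx(4.0, rel=0.05)

    def test_unconverged_prior_is_refused(self):
        bad = MgpsPrior(0.7, 0.4, 2.1, 1.9, 0.3, converged=False)
        with pytest.raises(EstimatorError, match="unconverged"):
            ebgm(3, 1.0, bad)

    def test_matches_quadrature_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            a = int(rng.integers(0, 200))
            e = float(rng.uniform(0.05, 100))
            g, lo, hi = ebgm(a, e, self.PRIOR)
            og, olo, ohi = ebgm_quadrature(a, e, self.PRIOR)
            assert g == pytest.approx(og, abs=1e-3)
            assert lo == pytest.approx(olo, abs=1e-3)
            assert hi == pytest.approx(ohi, abs=1e-3)


def test_all_estimators_null_on_balanced_table():
    t = T(25, 25, 25, 25)
    assert ror(t)[0] == pytest.approx(1.0)
    assert prr(t)[0] == pytest.approx(1.0)
    assert information_component(t)[0] == pytest.approx(0.0, abs=0.01)
    prior = MgpsPrior(1.0, 1.0, 2.0, 2.0, 0.5, converged=True)
    g, _, _ = ebgm(t.a, t.expected, prior)
    assert 0.7 < g < 1.3
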