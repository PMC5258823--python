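"""Reach probabilities, passage-time transforms/moments, and X^max."""

import numpy as np
import pytest

from clonofate.expansion import (conditional_passage_stats, expansion_moments,
                                 lst_expansion, percentile, reach_probability,
                                 tmax_moments, xmax_distribution, xmax_mean)
from clonofate.rates import ModelParams


class TestReachProbability:
    def test_boundaries(self, hard):
        p = hard(2.0)
        assert reach_probability(p, 5, 5) == 1.0
        assert reach_probability(p, 0, 5) == 0.0

    def test_hard_niche_closed_form(self, hard):
        # zeta_k = k! at phi=1: v_{1,5} = 1/(1+1+2+6+24)
        assert reach_probability(hard(1.0), 1, 5) == pytest.approx(1 / 34, rel=1e-12)

    def test_soft_niche_single_step(self):
        p = ModelParams(mu=1, phi=1000, nu=200, n_mean=1, regime="soft")
        lam1 = 1000 / 201
        assert reach_probability(p, 1, 2) == pytest.approx(lam1 / (lam1 + 1), rel=1e-12)

    def test_contraction_direction_rejected(self, hard):
        with pytest.raises(ValueError):
            reach_probability(hard(1.0), 5, 3)

    def test_monotone_in_target_and_phi(self):
        vs = [reach_probability(ModelParams(1, 2.0), 1, ir) for ir in range(2, 12)]
        assert all(a > b for a, b in zip(vs, vs[1:]))
        by_phi = [reach_probability(ModelParams(1, phi), 1, 6)
                  for phi in (0.5, 1.0, 2.0, 5.0, 20.0)]
        assert all(a < b for a, b in zip(by_phi, by_phi[1:]))


class TestLST:
    def test_at_zero_equals_reach_probability(self, hard):
        p = hard(3.0)
        assert lst_expansion(p, 2, 7, 0.0) == pytest.approx(
            reach_probability(p, 2, 7), rel=1e-12)

    def test_boundary_and_single_factor(self, hard):
        p = hard(2.0)
        assert lst_expansion(p, 4, 4, 1.3) == 1.0
        s = 0.7
        assert lst_expansion(p, 1, 2, s) == pytest.approx(2 / (s + 1 + 2), rel=1e-12)

    def test_negative_argument_rejected(self, hard):
        with pytest.raises(ValueError):
            lst_expansion(hard(1.0), 1, 3, -0.1)

    @pytest.mark.parametrize("params", [
        ModelParams(1.0, 2.0), ModelParams(0.7, 5.0, 3.0, 4.0, "exact"),
        ModelParams(1.0, 1000.0, 200.0, 1.0, "soft"),
    ])
    @pytest.mark.parametrize("s", [0.0, 0.3, 2.0])
    def test_matches_dense_linear_solve(self, params, s, expansion_oracle):
        i_rho = 9
        phi_dense = expansion_oracle(params, i_rho, s)
        for i in range(1, i_rho):
            assert lst_expansion(params, i, i_rho, s) == pytest.approx(
                phi_dense[i], rel=1e-10)


class TestRestrictedMoments:
    def test_boundary_conditions(self, hard):
        mom = expansion_moments(hard(1.5), 1, 6, 2)
        for i in range(7):
            assert mom.reach(i) == pytest.approx(
                reach_probability(hard(1.5), i, 6), rel=1e-12)
        for k in (1, 2):
            assert mom.moment(k, 0) == 0.0
            assert mom.moment(k, 6) == 0.0

    def test_first_step_exponential(self, hard):
        # from 1 cell, reaching 2 takes an Exp(lambda_1+mu_1) time on the reach event
        p = hard(0.1)
        mom = expansion_moments(p, 1, 2, 1)
        v = mom.reach(1)
        assert v == pytest.approx(1 / 11, rel=1e-12)
        assert mom.moment(1, 1) == pytest.approx(v / 1.1, rel=1e-10)

    def test_derivative_of_lst(self, hard):
        # m1 = -d/ds phi(s) at 0, by central differences
        p = hard(2.0)
        h = 1e-5
        num = (lst_expansion(p, 2, 8, h) - lst_expansion(p, 2, 8, 0.0)) / h
        # one-sided at the boundary, second-order via Richardson
        num2 = (lst_expansion(p, 2, 8, 2 * h) - lst_expansion(p, 2, 8, 0.0)) / (2 * h)
        extrap = 2 * num - num2
        mom = expansion_moments(p, 2, 8, 1)
        assert -extrap == pytest.approx(mom.moment(1, 2), rel=1e-6)


class TestConditionalPassage:
    def test_exponential_mean_equals_sd(self, hard):
        mean, sd = conditional_passage_stats(hard(1.0), 1, 2)
        assert mean == pytest.approx(0.5, rel=1e-10)
        assert sd == pytest.approx(0.5, rel=1e-8)

    def test_competitive_intermediate_niche(self):
        # (nu, <n>, phi) = (50, 50, 50): 1/(lambda_1 + mu_1) = 0.98000
        p = ModelParams(mu=1.0, phi=50.0, nu=50.0, n_mean=50.0, regime="exact")
        mean, sd = conditional_passage_stats(p, 1, 2)
        assert mean == pytest.approx(0.98000, abs=5e-6)
        assert sd == pytest.approx(0.98000, abs=5e-6)

    def test_three_cell_target(self, hard):
        mean, _ = conditional_passage_stats(hard(1.0), 1, 3)
        assert mean == pytest.approx(1.25, rel=1e-8)

    def test_requires_growth(self, hard):
        with pytest.raises(ValueError):
            conditional_passage_stats(hard(1.0), 3, 3)


class TestXmaxDistribution:
    def test_pmf_from_v_differences(self, hard):
        d = xmax_distribution(hard(0.1), 1, 0.99)
        # zeta_k = k! 10^k: v_{1,2}=1/11, v_{1,3}=1/211
        assert d.pmf[0] == pytest.approx(1 - 1 / 11, rel=1e-12)
        assert d.pmf[1] == pytest.approx(1 / 11 - 1 / 211, rel=1e-12)

    def test_telescoping_mass(self, hard):
        d = xmax_distribution(hard(2.0), 1, 0.99)
        K = int(d.support[-1])
        v_next = reach_probability(hard(2.0), 1, K + 1)
        assert d.pmf.sum() == pytest.approx(1 - v_next, rel=1e-10)
        assert d.covered_mass >= 0.99

    def test_percentiles_match_hard_niche_table(self, hard):
        d1 = xmax_distribution(hard(1.0), 1, 0.99)
        assert [percentile(d1, q) for q in (0.25, 0.5, 0.75, 0.99)] == [1, 2, 3, 5]
        d5 = xmax_distribution(hard(5.0), 1, 0.99)
        assert percentile(d5, 0.99) == 16
        d01 = xmax_distribution(hard(0.1), 1, 0.99)
        assert percentile(d01, 0.25) == 1

    def test_percentile_beyond_truncation_rejected(self, hard):
        d = xmax_distribution(hard(1.0), 1, 0.5)
        with pytest.raises(ValueError):
            percentile(d, 0.99)

    def test_invalid_inputs(self, hard):
        with pytest.raises(ValueError):
            xmax_distribution(hard(1.0), 0, 0.99)
        with pytest.raises(ValueError):
            xmax_distribution(hard(1.0), 1, 1.5)


class TestTruncatedMeans:
    def test_xmax_mean_hard_niche(self, hard):
        assert xmax_mean(xmax_distribution(hard(0.1), 1)) == pytest.approx(
            1.08143, abs=5e-6)
        assert xmax_mean(xmax_distribution(hard(1.0), 1)) == pytest.approx(
            1.84694, abs=5e-6)

    def test_xmax_mean_intermediate_niche(self):
        p = ModelParams(mu=1.0, phi=50.0, nu=1.0, n_mean=1.0, regime="exact")
        assert xmax_mean(xmax_distribution(p, 1)) == pytest.approx(123.25013, abs=2e-4)

    def test_tmax_mean_hard_niche(self, hard):
        assert tmax_moments(hard(0.1), 1)[0] == pytest.approx(0.07834, abs=5e-6)

    def test_tmax_vanishes_when_mass_sits_at_start(self, hard):
        # phi -> 0: X^max = i0 almost surely, so T^max = 0 (empty sum)
        assert tmax_moments(hard(1e-9), 1)[0] == pytest.approx(0.0, abs=1e-8)
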