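"""Time to a given number of division events via the augmented chain."""

import numpy as np
import pytest

from clonofate.division_time import (division_time_lst, division_time_moments,
                                     division_time_reach_prob)
from clonofate.expansion import conditional_passage_stats, reach_probability
from clonofate.gillespie import estimate_descriptors
from clonofate.rates import ModelParams, build_ladder


def soft(n_mean: float) -> ModelParams:
    return ModelParams(mu=1.0, phi=1000.0, nu=200.0, n_mean=n_mean, regime="soft")


class TestReachProbability:
    def test_zero_divisions_is_certain(self):
        w, _ = division_time_reach_prob(soft(1.0), 3, 0)
        assert w == 1.0

    @pytest.mark.parametrize("i0,D,n_mean,expected", [
        (1, 1, 1.0, 0.83263), (1, 1, 10.0, 0.33322), (1, 1, 1000.0, 0.00497),
        (10, 1, 10.0, 0.98249), (100, 5, 100.0, 0.58648), (1, 5, 1.0, 0.79944),
        (10, 10, 10.0, 0.41791),
    ])
    def test_soft_niche_grid(self, i0, D, n_mean, expected):
        w, _ = division_time_reach_prob(soft(n_mean), i0, D)
        assert w == pytest.approx(expected, abs=2e-5)

    def test_single_round_closed_form(self):
        # D=1: one birth must beat the all-deaths path
        p = soft(10.0)
        i0 = 10
        ladder = build_ladder(p, i0 + 1)
        prod = np.prod(ladder.death[1:i0 + 1]
                       / (ladder.birth[1:i0 + 1] + ladder.death[1:i0 + 1]))
        w, _ = division_time_reach_prob(p, i0, 1)
        assert w == pytest.approx(1 - prod, rel=1e-12)

    def test_monotone_in_target_and_start(self):
        p = soft(10.0)
        in_D = [division_time_reach_prob(p, 5, D)[0] for D in range(0, 8)]
        assert all(a >= b for a, b in zip(in_D, in_D[1:]))
        in_i0 = [division_time_reach_prob(p, i0, 3)[0] for i0 in range(1, 8)]
        assert all(a <= b for a, b in zip(in_i0, in_i0[1:]))

    def test_log_space_matches_linear(self):
        p = soft(100.0)
        w, _ = division_time_reach_prob(p, 1, 3)
        log_w, _ = division_time_reach_prob(p, 1, 3, log=True)
        assert np.exp(log_w) == pytest.approx(w, rel=1e-10)

    def test_deep_underflow_regime_stays_finite_in_log(self):
        # hostile niche: probabilities below 1e-18 are representable as logs
        log_w, _ = division_time_reach_prob(soft(1000.0), 1, 10, log=True)
        assert log_w < np.log(1e-17)
        assert np.isfinite(log_w)


class TestLST:
    def test_at_zero_equals_reach_probability(self):
        p = soft(10.0)
        w, _ = division_time_reach_prob(p, 4, 3)
        grid = division_time_lst(p, 4, 3, 0.0)
        assert grid.value_at_start == pytest.approx(w, rel=1e-12)

    def test_single_transient_state(self):
        p = soft(1.0)
        lam1 = 1000 / 201
        s = 0.8
        grid = division_time_lst(p, 1, 1, s)
        assert grid.value_at_start == pytest.approx(lam1 / (s + lam1 + 1), rel=1e-12)

    @pytest.mark.parametrize("i0,D", [(1, 1), (2, 3), (3, 2), (3, 3)])
    @pytest.mark.parametrize("s", [0.0, 0.5, 2.0])
    def test_matches_dense_linear_solve(self, i0, D, s, division_time_oracle):
        p = ModelParams(mu=0.8, phi=4.0, nu=2.0, n_mean=3.0, regime="exact")
        grid = division_time_lst(p, i0, D, s)
        assert grid.value_at_start == pytest.approx(
            division_time_oracle(p, i0, D, s), rel=1e-10)

    def test_negative_argument_rejected(self):
        with pytest.raises(ValueError):
            division_time_lst(soft(1.0), 1, 1, -0.5)


class TestMoments:
    def test_zero_divisions(self):
        restricted, mean, sd = division_time_moments(soft(1.0), 2, 0)
        assert np.all(restricted == 0.0)
        assert mean == 0.0 and sd == 0.0

    def test_first_event_conditional_mean(self):
        # i0=1, D=1: given the first event is a birth, the time is Exp(lam+mu)
        p = soft(1.0)
        lam1 = 1000 / 201
        _, mean, sd = division_time_moments(p, 1, 1)
        assert mean == pytest.approx(1 / (lam1 + 1), rel=1e-10)
        assert sd == pytest.approx(1 / (lam1 + 1), rel=1e-8)

    def test_consistent_with_expansion_for_first_division(self):
        # from one cell, one division <=> reaching size 2
        p = soft(10.0)
        w, _ = division_time_reach_prob(p, 1, 1)
        assert w == pytest.approx(reach_probability(p, 1, 2), rel=1e-12)
        _, mean, sd = division_time_moments(p, 1, 1)
        e_mean, e_sd = conditional_passage_stats(p, 1, 2)
        assert mean == pytest.approx(e_mean, rel=1e-10)
        assert sd == pytest.approx(e_sd, rel=1e-8)


class TestAgainstSimulation:
    def test_soft_niche_division_time(self):
        # moderately friendly soft niche; paths stopped once D is resolved
        p = soft(10.0)
        i0, D = 10, 5
        w, _ = division_time_reach_prob(p, i0, D)
        _, mean, _ = division_time_moments(p, i0, D)
        est = estimate_descriptors(p, i0, 30_000, seed=11, div_target=D,
                                   until="marks")
        mc_p = est["division_reach_prob"]
        mc_t = est["division_time_given_reach"]
        assert abs(w - mc_p.value) < 3 * mc_p.std_error
        assert abs(mean - mc_t.value) < 3 * mc_t.std_error
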