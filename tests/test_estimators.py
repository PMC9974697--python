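"""Utility weights, ATT estimators, standard errors, rearrangement bounds,
and the Q-vs-W comparison, each against an independent oracle where one exists."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uwatt import (
    att_bounds,
    att_standard_error,
    compare_atts,
    compute_weights,
    conditional_gain_oracle,
    estimate_att,
    utility_weight,
    utility_weight_from_index,
)


class TestUtilityWeight:
    def test_half_gives_half_ln_two(self):
        assert utility_weight(0.5) == pytest.approx(0.5 * np.log(2), abs=1e-15)

    def test_fixed_point_at_one_minus_exp_minus_one(self):
        """At p = 1 - e^{-1}, ln(1/(1-p)) = 1 so W = p."""
        p = 1.0 - np.exp(-1.0)
        assert utility_weight(p) == pytest.approx(p, abs=1e-15)

    def test_vanishes_quadratically_for_small_p(self):
        assert utility_weight(1e-9) == pytest.approx(1e-18, rel=1e-6)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.3])
    def test_outside_open_interval_rejected(self, bad):
        with pytest.raises(ValueError):
            utility_weight(bad)

    def test_strictly_increasing(self):
        p = np.linspace(1e-6, 1 - 1e-6, 10_000)
        w = utility_weight(p)
        assert np.all(np.diff(w) > 0)

    def test_index_form_agrees_with_propensity_form(self):
        """The two printed closed forms of the weight — sigmoid(v)*softplus(v)
        at v = logit(p), and p*ln(1/(1-p)) — agree to 1e-12 over a wide grid."""
        from scipy.special import logit

        p = np.linspace(1e-6, 1 - 1e-6, 10_001)
        v = logit(p)
        assert np.max(np.abs(utility_weight_from_index(v) - utility_weight(p))) < 1e-12

    def test_normalized_weights_sum_to_one(self):
        uw = compute_weights(np.array([0.1, 0.4, 0.7, 0.9]))
        assert uw.omega.sum() == pytest.approx(1.0, abs=1e-12)
        assert (uw.W > 0).all()
        assert uw.cv > 0


class TestEstimateATT:
    @pytest.mark.parametrize(
        "effects, expected_w",
        [((1, 0, 0), 1 / 6), ((0, 1, 0), 1 / 3), ((0, 0, 1), 1 / 2)],
    )
    def test_three_site_worked_example(self, effects, expected_w):
        """Three protected sites with utility weights 1, 2, 3 and exactly one
        effectively protected: the unweighted ATT is always 1/3 while the
        weighted ATT tracks which site was protected effectively."""
        weights = (1.0, 2.0, 3.0)
        assert estimate_att(effects, "uniform").estimate == pytest.approx(1 / 3)
        assert estimate_att(effects, weights).estimate == pytest.approx(expected_w)

    def test_equal_weights_reduce_to_uniform(self):
        effects = np.array([1.0, 0.0, 1.0, 0.0, 1.0])
        assert estimate_att(effects, np.full(5, 3.7)).estimate == pytest.approx(
            estimate_att(effects, "uniform").estimate
        )

    def test_continuous_effects_supported(self):
        effects = np.array([0.21, -0.4, 1.3])
        res = estimate_att(effects, np.array([1.0, 2.0, 3.0]))
        assert res.estimate == pytest.approx((0.21 - 0.8 + 3.9) / 6)

    @pytest.mark.parametrize(
        "effects, weights, err",
        [
            ([], "uniform", "non-empty"),
            ([1.0, 0.0], [1.0, -1.0], "positive"),
            ([1.0, 0.0], [1.0], "aligned"),
        ],
    )
    def test_input_validation(self, effects, weights, err):
        with pytest.raises(ValueError, match=err):
            estimate_att(effects, weights)


class TestStandardErrors:
    def test_identical_effects_have_zero_plugin_se(self):
        assert att_standard_error([0.3] * 6, method="plugin") == 0.0

    def test_uniform_plugin_reduces_to_classical_se(self):
        rng = np.random.default_rng(0)
        d = rng.normal(size=40)
        se = att_standard_error(d, method="plugin")
        assert se == pytest.approx(d.std(ddof=1) / np.sqrt(40), abs=1e-12)

    def test_bootstrap_is_seeded_and_reproducible(self):
        d = np.random.default_rng(1).normal(size=30)
        w = np.random.default_rng(2).uniform(0.5, 2.0, size=30)
        a = att_standard_error(d, w, method="bootstrap", n_boot=200, seed=9)
        b = att_standard_error(d, w, method="bootstrap", n_boot=200, seed=9)
        assert a == b

    def test_bootstrap_matches_iid_sampling_oracle(self):
        """The treated-site bootstrap targets the sampling variability of the
        weighted mean over i.i.d. draws of (effect, weight) pairs; against a
        direct Monte-Carlo of that quantity it agrees within 25%."""
        rng = np.random.default_rng(5)
        pop_d = rng.binomial(1, 0.3, size=20_000).astype(float)
        pop_w = rng.uniform(0.2, 3.0, size=20_000)
        n = 400
        idx0 = rng.integers(0, pop_d.size, n)
        se_boot = att_standard_error(
            pop_d[idx0], pop_w[idx0], method="bootstrap", n_boot=1500, seed=11
        )
        taus = np.empty(2000)
        for b in range(2000):
            idx = rng.integers(0, pop_d.size, n)
            taus[b] = np.sum(pop_w[idx] * pop_d[idx]) / np.sum(pop_w[idx])
        sd_mc = taus.std(ddof=1)
        assert abs(se_boot - sd_mc) / sd_mc < 0.25

    def test_bootstrap_needs_replicates(self):
        with pytest.raises(ValueError):
            att_standard_error([1.0, 0.0], method="bootstrap", n_boot=1)


class TestBounds:
    def test_small_instances_against_enumeration(self):
        """Exhaustive pairing oracle on the two documented instances."""
        for effects, weights, exp_max, exp_min in [
            ((1, 0, 0), (1, 2, 3), 1 / 2, 1 / 6),
            ((1, -1, 0), (1, 2, 3), 1 / 3, -1 / 3),
        ]:
            d = np.array(effects, dtype=float)
            w = np.array(weights, dtype=float)
            taus = [
                np.sum(w * d[list(perm)]) / w.sum()
                for perm in itertools.permutations(range(len(d)))
            ]
            b = att_bounds(d, w)
            assert b.tau_max == pytest.approx(max(taus)) == pytest.approx(exp_max)
            assert b.tau_min == pytest.approx(min(taus)) == pytest.approx(exp_min)

    def test_constrained_minimum_zeroes_negative_effects(self):
        b = att_bounds(np.array([1.0, -1.0, 0.0]), np.array([1.0, 2.0, 3.0]))
        assert b.tau_min_constrained == pytest.approx(1 / 6)
        assert b.tau_min_constrained >= 0

    def test_degenerate_equal_effects(self):
        b = att_bounds(np.array([0.4, 0.4, 0.4]), np.array([1.0, 5.0, 2.0]))
        assert b.tau_max == b.tau_min == pytest.approx(0.4)
        assert np.isnan(b.correlation)

    def test_estimate_always_inside_bounds(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = rng.integers(2, 30)
            d = rng.normal(size=n)
            w = rng.uniform(0.1, 5.0, size=n)
            b = att_bounds(d, w)
            tau = estimate_att(d, w).estimate
            assert b.tau_min - 1e-12 <= tau <= b.tau_max + 1e-12

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-2, 2), min_size=2, max_size=6),
        st.lists(st.floats(0.05, 5), min_size=2, max_size=6),
    )
    def test_rearrangement_optimality_property(self, effects, weights):
        """On every small instance, the sorted pairing attains the exact
        extremes over all n! pairings."""
        n = min(len(effects), len(weights))
        d = np.asarray(effects[:n])
        w = np.asarray(weights[:n])
        taus = [
            np.sum(w * d[list(perm)]) / w.sum()
            for perm in itertools.permutations(range(n))
        ]
        b = att_bounds(d, w)
        assert b.tau_max == pytest.approx(max(taus), abs=1e-12)
        assert b.tau_min == pytest.approx(min(taus), abs=1e-12)


class TestOrderingProperties:
    def test_comonotone_weights_raise_the_estimate(self):
        """Weights positively rank-correlated with effects pull the weighted
        ATT above the unweighted one; anti-comonotone weights pull it below."""
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = rng.integers(3, 50)
            d = np.sort(rng.normal(size=n))
            w = np.sort(rng.uniform(0.1, 4.0, size=n))
            tau_u = estimate_att(d, "uniform").estimate
            assert estimate_att(d, w).estimate >= tau_u - 1e-12
            assert estimate_att(d, w[::-1]).estimate <= tau_u + 1e-12

    def test_random_permutation_average_recovers_uniform(self):
        """Averaging the weighted ATT over random weight permutations converges
        to the unweighted ATT (zero-correlation identity), within 3 MC SEs."""
        rng = np.random.default_rng(13)
        d = rng.binomial(1, 0.4, size=60).astype(float)
        w = rng.uniform(0.2, 3.0, size=60)
        tau_u = estimate_att(d, "uniform").estimate
        reps = np.array(
            [estimate_att(d, rng.permutation(w)).estimate for _ in range(4000)]
        )
        se = reps.std(ddof=1) / np.sqrt(len(reps))
        assert abs(reps.mean() - tau_u) <= 3 * se


class TestCompareATTs:
    def test_uniform_weights_give_zero_difference(self):
        d = np.array([1.0, 0.0, 1.0, 0.0])
        res = compare_atts(d, np.full(4, 2.0), n_boot=200, seed=0)
        assert res.difference == 0.0
        assert res.p_value == 1.0

    def test_worked_example_difference(self):
        res = compare_atts(np.array([1.0, 0.0, 0.0]), np.array([1.0, 2.0, 3.0]),
                           n_boot=500, seed=0)
        assert res.difference == pytest.approx(1 / 3 - 1 / 6)

    def test_size_under_the_null(self):
        """With weights drawn independently of effects the test at level 0.05
        should reject in at most 10 of 100 runs."""
        rejections = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            d = rng.binomial(1, 0.3, size=400).astype(float)
            w = rng.uniform(0.2, 3.0, size=400)
            res = compare_atts(d, w, n_boot=300, seed=seed)
            rejections += res.p_value < 0.05
        assert rejections <= 10


class TestConditionalGainOracle:
    def test_zero_index_matches_truncated_logistic_mean(self):
        """E[-U | -U > 0] for standard logistic U is 2 ln 2; the MC oracle at
        10^6 draws lands within a few MC standard errors."""
        val = conditional_gain_oracle(0.0, n_draws=1_000_000, seed=2)
        assert val == pytest.approx(2 * np.log(2), abs=0.01)

    def test_large_index_is_nearly_unconditional(self):
        val = conditional_gain_oracle(20.0, n_draws=100_000, seed=2)
        assert val == pytest.approx(20.0, abs=0.05)

    def test_monotone_in_the_index(self):
        """Common random numbers: the conditional gain increases with theta_x."""
        vals = [conditional_gain_oracle(v, n_draws=200_000, seed=4) for v in (-2, 0, 2, 5)]
        assert np.all(np.diff(vals) > 0)

    def test_empty_conditioning_event_is_an_error(self):
        with pytest.raises(ValueError):
            conditional_gain_oracle(-60.0, n_draws=10_000, seed=0)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            conditional_gain_oracle(0.0, n_draws=100, seed=0)
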