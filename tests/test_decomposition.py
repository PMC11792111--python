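import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from toxvar import (
    DataError,
    DiscreteDoseDistribution,
    DomainError,
    DoseResponseCurve,
    ExtrapolationError,
    build_observed_distribution,
    build_reference_distribution,
    decompose,
    expected_response,
    fit_smooth_curve,
    fraction_of_predicted,
    jensen_effect,
    jensen_potential,
    monte_carlo_decompose,
    observed_total_effect,
    sample_curve_draws,
    standardize_result,
)
from toxvar.decomposition import ObservedTotalEffect


def two_point(mu, delta, p_low):
    return DiscreteDoseDistribution(np.array([mu - delta, mu + delta]),
                                    np.array([p_low, 1 - p_low]))


class TestExpectedResponse:
    def test_point_mass_returns_curve_value(self):
        curve = DoseResponseCurve.hill(1, 0, 1, 2)
        d = DiscreteDoseDistribution(np.array([0.8]), np.array([1.0]))
        assert expected_response(curve, d) == curve(0.8)

    def test_linear_curve_commutes_with_expectation(self):
        curve = DoseResponseCurve.linear(0.2, -0.05)
        d = two_point(1.5, 0.5, 0.3)
        assert expected_response(curve, d) == pytest.approx(curve(d.mean), abs=1e-14)

    def test_matches_enumeration_oracle(self):
        curve = DoseResponseCurve.hill(1, 0, 1, 2)
        d = two_point(1.0, 0.5, 0.5)
        want = oracles.expected_value(
            lambda x: oracles.hill(1, 0, 1, 2, x), d.support, d.probs)
        assert expected_response(curve, d) == pytest.approx(want, abs=1e-14)

    def test_extrapolation_guard(self):
        fit = fit_smooth_curve(np.geomspace(0.5, 4.0, 8),
                               np.log(np.geomspace(0.5, 4.0, 8)))
        curve = DoseResponseCurve.from_smooth_fit(fit)
        d = two_point(5.0, 0.5, 0.5)  # support up to 5.5 > 4.0
        with pytest.raises(ExtrapolationError):
            expected_response(curve, d)
        assert np.isfinite(expected_response(curve, d, allow_extrapolation=True))


class TestJensenEffect:
    def test_point_mass_is_zero(self):
        curve = DoseResponseCurve.hill(1, 0, 1, 2)
        d = DiscreteDoseDistribution(np.array([1.3]), np.array([1.0]))
        assert jensen_effect(curve, d) == 0.0

    def test_sign_tracks_local_convexity(self):
        curve = DoseResponseCurve.hill(1, 0, 1, 2)
        for mu in (0.4, 3.0):
            d = two_point(mu, 0.02 * mu, 0.5)
            assert np.sign(jensen_effect(curve, d)) == np.sign(
                jensen_potential(curve, mu))

    def test_concave_region_lowers_the_average(self):
        """Variation over a concave stretch yields a lower average response
        than the response at the average dose (a decreasing sigmoid is
        concave below its inflection)."""
        curve = DoseResponseCurve.hill(1, 0, 1, 2)
        d = two_point(0.25, 0.1, 0.5)
        assert jensen_effect(curve, d) < 0


class TestDecompose:
    def test_linear_curve_kills_both_jensen_terms(self):
        curve = DoseResponseCurve.linear(0.5, -0.2)
        xo = two_point(1.0, 0.4, 0.7)
        xr = two_point(1.0, 0.4, 0.5)
        t = decompose(curve, xo, xr)
        assert abs(t.jr) < 1e-14 and abs(t.js) < 1e-14
        assert t.s == pytest.approx(-0.2 * (xo.mean - xr.mean), abs=1e-12)

    def test_no_selectivity_leaves_only_jr(self):
        curve = DoseResponseCurve.hill(1, 0, 1, 2)
        xr = two_point(1.0, 0.4, 0.5)
        t = decompose(curve, xr, xr)
        assert t.s == 0.0 and t.js == 0.0
        assert t.t_hat == t.jr

    def test_matches_brute_force_oracle(self):
        """Hill(1,0,1,2), mu=1, delta=0.5, weights (0.7, 0.3): all four terms
        against independent enumeration."""
        curve = DoseResponseCurve.hill(1, 0, 1, 2)
        xo = build_observed_distribution(1.0, 0.5, (0.7, 0.3))
        xr = build_reference_distribution(1.0, 0.5)
        got = decompose(curve, xo, xr)
        want = oracles.decompose(lambda x: oracles.hill(1, 0, 1, 2, x),
                                 xo.support, xo.probs, xr.support, xr.probs)
        for g, w in zip(got, want):
            assert g == pytest.approx(w, abs=1e-12)

    def test_additivity_identity(self):
        curve = DoseResponseCurve.hill(0.2, 0.9, 1.7, 2.4)
        xo = two_point(2.0, 0.6, 0.8)
        xr = two_point(2.0, 0.6, 0.5)
        t = decompose(curve, xo, xr)
        direct = expected_response(curve, xo) - curve(xr.mean)
        assert t.t_hat == pytest.approx(direct, abs=1e-12)

    @given(mu=st.floats(0.5, 5), dfrac=st.floats(0.01, 0.9),
           p=st.floats(0.01, 0.99), n=st.floats(0.5, 4))
    @settings(max_examples=60, deadline=None)
    def test_small_variance_limit_and_identity(self, mu, dfrac, p, n):
        curve = DoseResponseCurve.hill(1, 0, 1.3, n)
        delta = dfrac * mu
        xo = two_point(mu, delta, p)
        xr = two_point(mu, delta, 0.5)
        t = decompose(curve, xo, xr)
        assert t.t_hat == pytest.approx(t.jr + t.s + t.js, abs=1e-10)


class TestObservedTotalEffect:
    def test_identical_arms_give_zero(self, toy_cages):
        flat = toy_cages.copy()
        flat["rgr_per_h"] = np.tile([0.10, 0.35, -0.15], 2)
        t = observed_total_effect(flat, "rgr", "high", n_draws=10, seed=0)
        assert t.estimate == pytest.approx(0.0, abs=1e-12)

    def test_toy_standardized_difference(self, toy_cages):
        """Arm means 0.05 vs 0.10 with pooled link SD 0.25 -> -0.2 SD."""
        t = observed_total_effect(toy_cages, "rgr", "high", n_draws=10, seed=0)
        assert t.sd_link == pytest.approx(0.25)
        assert t.estimate == pytest.approx(-0.2)

    def test_seed_reproducibility(self, toy_cages):
        a = observed_total_effect(toy_cages, "rgr", "high", n_draws=25, seed=4)
        b = observed_total_effect(toy_cages, "rgr", "high", n_draws=25, seed=4)
        assert np.array_equal(a.draws, b.draws)

    def test_missing_arm_rejected(self, toy_cages):
        const_only = toy_cages[toy_cages.variation_treatment == "constant"]
        with pytest.raises(DataError):
            observed_total_effect(const_only, "rgr", "high")


class TestMonteCarlo:
    @pytest.fixture()
    def curve_draws(self):
        rng = np.random.default_rng(0)
        d = np.geomspace(0.031, 16.1, 10)
        y = 1.0 / (1.0 + d) + rng.normal(0, 0.05, 10)
        fit = fit_smooth_curve(d, y)
        return fit, sample_curve_draws(fit, 20, seed=1)

    def test_full_cartesian_cross(self, curve_draws):
        _, draws = curve_draws
        W = np.abs(np.random.default_rng(2).normal(0.2, 0.05, (30, 2)))
        res = monte_carlo_decompose(draws, W, mu=1.89, delta=0.61)
        assert len(res.draws) == 20 * 30

    def test_single_draw_degenerate_summaries(self, curve_draws):
        fit, _ = curve_draws
        one = sample_curve_draws(fit, 1, seed=0)
        res = monte_carlo_decompose(one, np.array([[0.2, 0.1]]),
                                    mu=1.89, delta=0.61)
        s = res.summaries.set_index("quantity")
        assert len(res.draws) == 1
        for q in ("jr", "s", "js", "t_hat"):
            assert s.loc[q, "lower"] == s.loc[q, "upper"] == s.loc[q, "mean"]

    def test_identical_draws_have_zero_width(self, curve_draws):
        fit, _ = curve_draws
        point = [DoseResponseCurve.from_smooth_fit(fit)] * 15
        res = monte_carlo_decompose(point, np.tile([0.2, 0.1], (10, 1)),
                                    mu=1.89, delta=0.61)
        s = res.summaries.set_index("quantity")
        for q in ("jr", "s", "js"):
            assert s.loc[q, "upper"] - s.loc[q, "lower"] == pytest.approx(0, abs=1e-14)

    def test_per_draw_identities(self, curve_draws):
        _, draws = curve_draws
        W = np.abs(np.random.default_rng(3).normal(0.2, 0.05, (25, 2)))
        t_obs = ObservedTotalEffect(-0.2, np.full(7, -0.2), 0.25)
        res = monte_carlo_decompose(draws, W, mu=1.89, delta=0.61, t_obs=t_obs)
        d = res.draws
        assert np.abs(d.jr + d.s + d.js - d.t_hat).max() < 1e-10
        assert np.abs(d.t_obs - d.t_hat - d.eps).max() < 1e-10

    def test_empty_draws_rejected(self, curve_draws):
        _, draws = curve_draws
        with pytest.raises(DomainError):
            monte_carlo_decompose([], np.array([[0.2, 0.1]]), 1.89, 0.61)
        with pytest.raises(DomainError):
            monte_carlo_decompose(draws, np.zeros((0, 2)), 1.89, 0.61)

    def test_doubling_draws_is_stable(self, curve_draws):
        """Summary means move by less than twice the Monte-Carlo SE when the
        number of draws doubles."""
        fit, _ = curve_draws
        W = np.abs(np.random.default_rng(5).normal(0.2, 0.04, (40, 2)))
        r1 = monte_carlo_decompose(sample_curve_draws(fit, 100, seed=8), W,
                                   1.89, 0.61)
        r2 = monte_carlo_decompose(sample_curve_draws(fit, 200, seed=9), W,
                                   1.89, 0.61)
        for q in ("jr", "s", "js", "t_hat"):
            # curve draws dominate: effective MC sample sizes are 100 and 200;
            # 3-sigma bound on the difference of two independent MC means
            se = np.hypot(r1.draws[q].std() / np.sqrt(100),
                          r2.draws[q].std() / np.sqrt(200))
            assert abs(r1.draws[q].mean() - r2.draws[q].mean()) < 3 * se + 1e-12


class TestStandardizeAndShares:
    @pytest.fixture()
    def result(self):
        rng = np.random.default_rng(0)
        d = np.geomspace(0.031, 16.1, 10)
        fit = fit_smooth_curve(d, 1.0 / (1.0 + d) + rng.normal(0, 0.05, 10))
        draws = sample_curve_draws(fit, 10, seed=1)
        W = np.abs(rng.normal(0.2, 0.04, (10, 2)))
        t_obs = ObservedTotalEffect(-0.2, rng.normal(-0.2, 0.05, 10), 0.25)
        return monte_carlo_decompose(draws, W, 1.89, 0.61, t_obs=t_obs)

    def test_unit_sd_is_identity(self, result):
        out = standardize_result(result, 1.0)
        assert np.array_equal(out.draws.to_numpy(), result.draws.to_numpy())

    def test_halving_and_identity_preserved(self, result):
        out = standardize_result(result, 2.0)
        assert np.allclose(out.draws["jr"], result.draws["jr"] / 2)
        d = out.draws
        assert np.abs(d.jr + d.s + d.js - d.t_hat).max() < 1e-10

    def test_round_trip(self, result):
        back = standardize_result(standardize_result(result, 0.25), 1 / 0.25)
        assert np.allclose(back.draws.to_numpy(), result.draws.to_numpy(),
                           atol=1e-12)

    def test_nonpositive_sd_rejected(self, result):
        with pytest.raises(DomainError):
            standardize_result(result, 0.0)

    def test_single_draw_shares(self):
        df = pd.DataFrame({"jr": [0.8], "s": [0.15], "js": [0.05],
                           "t_hat": [1.0], "t_obs": [np.nan], "eps": [np.nan]})
        from toxvar.decomposition import DecompositionResult
        shares = fraction_of_predicted(DecompositionResult(df))
        got = shares.set_index("quantity")["median"]
        assert got["jr"] == pytest.approx(80.0)
        assert got["s"] == pytest.approx(15.0)
        assert got["js"] == pytest.approx(5.0)

    def test_linear_curve_gives_pure_selectivity_share(self):
        curve = [DoseResponseCurve.linear(0.5, -0.1)] * 3
        res = monte_carlo_decompose(curve, np.tile([0.3, 0.1], (4, 1)),
                                    1.89, 0.61)
        shares = fraction_of_predicted(res).set_index("quantity")["median"]
        assert shares["s"] == pytest.approx(100.0, abs=1e-6)

    def test_shares_sum_to_100_and_match_oracle(self, result):
        shares = fraction_of_predicted(result)
        d = result.draws
        keep = np.abs(d.t_hat) >= 1e-12
        assert (100 * (d.jr + d.s + d.js)[keep] / d.t_hat[keep]).max() \
            == pytest.approx(100.0, abs=1e-8)
        want = oracles.decompose(  # oracle shares on a pinned configuration
            lambda x: oracles.hill(1, 0, 1, 2, x),
            [0.5, 1.5], [0.7, 0.3], [0.5, 1.5], [0.5, 0.5])
        assert sum(w / want[3] for w in want[:3]) == pytest.approx(1.0)

    def test_all_near_zero_t_hat_rejected(self):
        from toxvar.decomposition import DecompositionResult
        df = pd.DataFrame({q: [0.0] for q in
                           ("jr", "s", "js", "t_hat", "t_obs", "eps")})
        with pytest.raises(DataError):
            fraction_of_predicted(DecompositionResult(df))
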