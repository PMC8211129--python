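"""Unit tests of the JZS Bayes factor machinery against independent oracles."""

import math

import numpy as np
import pytest
from scipy import stats

from bspm import (
    PriorSpec,
    R_MEDIUM,
    R_ULTRAWIDE,
    R_WIDE,
    TStatistic,
    bf_to_posterior,
    cauchy_prior_mass,
    delta_posterior,
    jzs_bf_interval,
    jzs_bf_point,
    resolve_scale,
)

from oracles import bf_interval_grid, bf_point_grid


class TestPointBF:
    def test_matches_grid_oracle_reference_case(self):
        # paired n=20, t=5, medium prior
        t = TStatistic(5.0, 19, 20)
        mine = jzs_bf_point(t, PriorSpec(r=R_MEDIUM)).bf10
        oracle = bf_point_grid(5.0, 19, 20, R_MEDIUM)
        assert mine == pytest.approx(oracle, rel=1e-6)

    @pytest.mark.parametrize("t,n,r", [
        (2.0, 10, R_WIDE),
        (-3.5, 15, R_ULTRAWIDE),
        (0.0, 6, R_MEDIUM),
        (8.0, 30, R_MEDIUM),
        (1.2, 4, R_WIDE),
    ])
    def test_matches_grid_oracle(self, t, n, r):
        mine = jzs_bf_point(TStatistic(t, n - 1, n), PriorSpec(r=r)).bf10
        assert mine == pytest.approx(bf_point_grid(t, n - 1, n, r), rel=1e-6)

    @pytest.mark.parametrize("t,n,r", [
        (2.5, 12, 0.707), (5.0, 20, 0.707), (-1.0, 8, 1.0), (3.3, 40, 1.414),
    ])
    def test_matches_pingouin_reference(self, t, n, r):
        # pingouin's JZS routine is itself validated against JASP and the
        # R reference implementation -- a fully external cross-check
        pingouin = pytest.importorskip("pingouin")
        mine = jzs_bf_point(TStatistic(t, n - 1, n), PriorSpec(r=r)).bf10
        ref = float(pingouin.bayesfactor_ttest(t, n, paired=True, r=r))
        assert mine == pytest.approx(ref, rel=1e-6)

    def test_two_sample_effective_n(self):
        # two-sample BF uses n1*n2/(n1+n2) with nu = n1+n2-2
        pingouin = pytest.importorskip("pingouin")
        n1, n2, t = 8, 12, 2.7
        n_eff = n1 * n2 / (n1 + n2)
        mine = jzs_bf_point(TStatistic(t, n1 + n2 - 2, n_eff), PriorSpec()).bf10
        ref = float(pingouin.bayesfactor_ttest(t, n1, n2, paired=False, r=R_MEDIUM))
        assert mine == pytest.approx(ref, rel=1e-6)

    def test_scale_invariance_of_data_units(self, rng):
        # t (hence BF) is unchanged by multiplicative rescaling of the data
        x = rng.normal(1.0, 2.0, size=25)

        def bf_from(data):
            t = data.mean() / (data.std(ddof=1) / math.sqrt(len(data)))
            return jzs_bf_point(TStatistic(t, len(data) - 1, len(data)),
                                PriorSpec()).bf10

        assert bf_from(x) == pytest.approx(bf_from(10.0 * x), rel=1e-12)

    def test_degenerate_prior_limit_is_one(self):
        # as r -> 0 the alternative collapses onto the null
        bf = jzs_bf_point(TStatistic(2.5, 11, 12), PriorSpec(r=1e-5)).bf10
        assert bf == pytest.approx(1.0, abs=1e-3)

    def test_even_function_of_t(self):
        prior = PriorSpec(r=R_WIDE)
        a = jzs_bf_point(TStatistic(2.3, 9, 10), prior).bf10
        b = jzs_bf_point(TStatistic(-2.3, 9, 10), prior).bf10
        assert a == pytest.approx(b, rel=1e-10)

    def test_monotone_and_unbounded_in_t(self):
        # consistency in information: BF10 grows without bound in |t|
        prior = PriorSpec()
        bfs = [jzs_bf_point(TStatistic(t, 14, 15), prior).bf10
               for t in np.linspace(0, 12, 25)]
        assert np.all(np.diff(bfs) > 0)
        assert bfs[-1] > 1e6

    def test_consistency_with_sample_size(self, rng):
        # median BF shrinks under a true null and explodes under delta=0.8
        # as n grows
        def median_bf(delta, n, reps=200):
            x = rng.normal(delta, 1.0, size=(reps, n))
            ts = x.mean(axis=1) / (x.std(axis=1, ddof=1) / math.sqrt(n))
            return np.median([
                jzs_bf_point(TStatistic(float(t), n - 1, n), PriorSpec()).bf10
                for t in ts])

        null_medians = [median_bf(0.0, n) for n in (10, 50, 200)]
        alt_medians = [median_bf(0.8, n) for n in (10, 50, 200)]
        assert null_medians[0] > null_medians[1] > null_medians[2]
        assert alt_medians[0] < alt_medians[1] < alt_medians[2]
        assert null_medians[2] < 0.2 and alt_medians[2] > 1e6

    def test_reciprocal_identity_and_error_estimate(self):
        res = jzs_bf_point(TStatistic(1.7, 19, 20), PriorSpec())
        assert res.bf10 * res.bf01 == pytest.approx(1.0, rel=1e-12)
        assert res.log_bf10 == pytest.approx(math.log(res.bf10))
        assert res.numerical_error_estimate >= 0

    def test_overflow_is_capped_with_flag(self):
        with pytest.warns(RuntimeWarning, match="capped"):
            res = jzs_bf_point(TStatistic(1e4, 199, 200), PriorSpec())
        assert res.capped
        assert res.log_bf10 == pytest.approx(700.0)

    @pytest.mark.parametrize("bad", [
        lambda: TStatistic(float("nan"), 10, 10),
        lambda: TStatistic(float("inf"), 10, 10),
        lambda: TStatistic(1.0, 0.5, 10),
        lambda: TStatistic(1.0, 10, 0.0),
    ])
    def test_invalid_statistics_rejected(self, bad):
        with pytest.raises(ValueError):
            bad()

    def test_invalid_prior_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(r=-1.0)
        with pytest.raises(ValueError):
            PriorSpec(c=-0.1)
        with pytest.raises(ValueError):
            PriorSpec(prior_odds=0.0)
        with pytest.raises(ValueError):
            resolve_scale("enormous")

    def test_one_sided_priors(self):
        # positive-sided prior rewards positive t and penalises negative t;
        # the two one-sided BFs average to the two-sided one
        t = TStatistic(3.0, 14, 15)
        pos = jzs_bf_point(t, PriorSpec(sided="positive")).bf10
        neg = jzs_bf_point(t, PriorSpec(sided="negative")).bf10
        two = jzs_bf_point(t, PriorSpec()).bf10
        assert pos > two > neg
        assert 0.5 * (pos + neg) == pytest.approx(two, rel=1e-6)


class TestDeltaPosterior:
    def test_symmetric_at_t_zero(self):
        post = delta_posterior(TStatistic(0.0, 9, 10), PriorSpec())
        assert post.mean() == pytest.approx(0.0, abs=1e-10)

    def test_normalised_and_nonnegative(self):
        post = delta_posterior(TStatistic(4.2, 19, 20), PriorSpec(r=R_WIDE))
        assert (post.density >= 0).all()
        assert np.trapezoid(post.density, post.delta) == pytest.approx(1.0, abs=1e-6)

    def test_positive_t_shifts_mass_positive(self):
        post = delta_posterior(TStatistic(3.0, 14, 15), PriorSpec(r=R_WIDE))
        above = post.mass(0.0, post.delta[-1])
        assert above > 1.0 - above

    def test_interval_mass_consistent_with_interval_bf(self):
        # reconstructing the interval BF from the gridded posterior agrees
        # with the quadrature route
        t = TStatistic(2.0, 11, 12)
        prior = PriorSpec(c=0.2)
        post = delta_posterior(t, prior)
        p_in = post.mass(-0.2, 0.2)
        prior_in = cauchy_prior_mass(prior.r, -0.2, 0.2)
        bf_from_grid = ((1 - p_in) / (1 - prior_in)) / (p_in / prior_in)
        assert jzs_bf_interval(t, prior).bf10 == pytest.approx(
            bf_from_grid, rel=1e-4)


class TestIntervalBF:
    def test_matches_grid_oracle_reference_case(self):
        t = TStatistic(2.5, 9, 10)
        prior = PriorSpec(r=R_MEDIUM, c=0.2)
        mine = jzs_bf_interval(t, prior).bf10
        assert mine == pytest.approx(bf_interval_grid(2.5, 9, 10, R_MEDIUM, 0.2),
                                     rel=1e-5)

    @pytest.mark.parametrize("t,n,r,c", [
        (0.0, 50, R_MEDIUM, 0.2),
        (4.0, 20, R_WIDE, 0.3),
        (-1.2, 8, R_ULTRAWIDE, 0.2),
        (6.0, 12, R_MEDIUM, 0.2),
    ])
    def test_matches_grid_oracle(self, t, n, r, c):
        mine = jzs_bf_interval(TStatistic(t, n - 1, n), PriorSpec(r=r, c=c)).bf10
        assert mine == pytest.approx(bf_interval_grid(t, n - 1, n, r, c), rel=1e-5)

    def test_nested_model_limit_c_to_zero(self):
        t = TStatistic(2.5, 9, 10)
        point = jzs_bf_point(t, PriorSpec()).bf10
        interval = jzs_bf_interval(t, PriorSpec(c=1e-4)).bf10
        assert interval == pytest.approx(point, rel=1e-3)

    def test_null_data_favours_interval_null(self):
        bf = jzs_bf_interval(TStatistic(0.0, 99, 100), PriorSpec(c=0.2)).bf10
        assert bf < 1.0

    def test_c_zero_rejected(self):
        with pytest.raises(ValueError, match="c > 0"):
            jzs_bf_interval(TStatistic(1.0, 9, 10), PriorSpec(c=0.0))

    def test_degenerate_posterior_mass_capped(self):
        # posterior mass in [-c, c] underflows for an enormous, precisely
        # estimated effect
        with pytest.warns(RuntimeWarning):
            res = jzs_bf_interval(TStatistic(100.0, 9999, 10000),
                                  PriorSpec(c=0.2))
        assert res.capped
        assert res.bf10 == pytest.approx(math.exp(700.0))


class TestPosteriorConversion:
    def test_bf_five_gives_five_sixths(self):
        pp = bf_to_posterior(5.0, prior_odds=1.0)
        assert pp.pp_h1 == pytest.approx(5.0 / 6.0, abs=1e-15)
        assert pp.pp_h0 == pytest.approx(1.0 / 6.0, abs=1e-15)

    def test_equal_evidence(self):
        pp = bf_to_posterior(1.0)
        assert pp.pp_h0 == pp.pp_h1 == 0.5

    def test_prior_odds_multiply(self):
        pp = bf_to_posterior(2.0, prior_odds=3.0)
        assert pp.pp_h1 == pytest.approx(6.0 / 7.0)

    def test_probabilities_sum_to_one(self):
        for bf in (1e-8, 0.3, 1.0, 7.7, 1e9):
            pp = bf_to_posterior(bf, prior_odds=2.5)
            assert pp.pp_h0 + pp.pp_h1 == pytest.approx(1.0, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bf_to_posterior(0.0)
        with pytest.raises(ValueError):
            bf_to_posterior(1.0, prior_odds=-2.0)


class TestCauchyPriorMass:
    @pytest.mark.parametrize("r", [R_MEDIUM, R_WIDE, R_ULTRAWIDE])
    def test_half_mass_between_minus_r_and_r(self, r):
        assert cauchy_prior_mass(r, -r, r) == pytest.approx(0.5, abs=1e-15)

    def test_total_mass(self):
        assert cauchy_prior_mass(1.0, -math.inf, math.inf) == pytest.approx(1.0)

    def test_quarter_mass_on_half_central_interval(self):
        assert cauchy_prior_mass(1.0, 0.0, 1.0) == pytest.approx(0.25)

    def test_agrees_with_scipy_cdf(self):
        r, a, b = 0.6, -0.3, 1.7
        expected = stats.cauchy.cdf(b, scale=r) - stats.cauchy.cdf(a, scale=r)
        assert cauchy_prior_mass(r, a, b) == pytest.approx(expected, rel=1e-12)

    def test_invalid(self):
        with pytest.raises(ValueError):
            cauchy_prior_mass(-1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            cauchy_prior_mass(1.0, 2.0, 1.0)
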