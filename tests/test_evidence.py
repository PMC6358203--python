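"""Post-experimental machinery: Bayes factors, bounds, priors."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import norm

from rejodds import (
    NORMAL_LOCATION,
    ModelSpec,
    PriorOdds,
    PriorSpec,
    bayes_factor,
    bf_best_nonincreasing,
    bf_bound_from_p,
    bf_sup_all_priors,
    evidence_report,
    intrinsic_prior_normal,
    marginal_likelihood,
    p_from_statistic,
    post_odds,
    variance_test_lr,
    z_from_counts,
)


class TestPValues:
    def test_one_sided(self):
        assert round(p_from_statistic(2.06, 1), 2) == 0.02
        assert p_from_statistic(0.0, 1) == pytest.approx(0.5)

    def test_two_sided(self):
        assert round(p_from_statistic(1.96, 2), 2) == 0.05
        assert p_from_statistic(-1.96, 2) == p_from_statistic(1.96, 2)


class TestZFromCounts:
    def test_vaccine_trial(self, vaccine_counts):
        assert round(z_from_counts(**vaccine_counts), 2) == 2.06

    def test_identical_rates_and_antisymmetry(self, vaccine_counts):
        assert z_from_counts(7, 100, 7, 100) == pytest.approx(0.0, abs=1e-12)
        forward = z_from_counts(**vaccine_counts)
        swapped = z_from_counts(
            vaccine_counts["events2"], vaccine_counts["n2"],
            vaccine_counts["events1"], vaccine_counts["n1"])
        assert swapped == pytest.approx(-forward, rel=1e-12)

    def test_degenerate_pooled_rate(self):
        with pytest.raises(ValueError, match="degenerate"):
            z_from_counts(0, 50, 0, 50)
        with pytest.raises(ValueError):
            z_from_counts(5, 4, 0, 10)


class TestMarginalLikelihood:
    def test_uniform_closed_form_vs_riemann(self):
        a, x = 2.95, 2.06
        grid = (np.arange(100_000) + 0.5) * a / 100_000  # midpoint rule
        oracle = np.mean(norm.pdf(x - grid))
        got = marginal_likelihood(PriorSpec.uniform_from_null(a),
                                  NORMAL_LOCATION, x)
        assert got == pytest.approx(oracle, abs=1e-6)
        assert got == pytest.approx(0.2690, abs=5e-5)

    def test_point_prior_density_at_mode(self):
        got = marginal_likelihood(PriorSpec.point(1.3), NORMAL_LOCATION, 1.3)
        assert got == pytest.approx(1 / np.sqrt(2 * np.pi), rel=1e-12)

    @given(tau2=st.floats(0.1, 5.0), x=st.floats(-4.0, 4.0))
    def test_normal_prior_convolution_identity(self, tau2, x):
        got = marginal_likelihood(PriorSpec.normal(0.0, tau2),
                                  NORMAL_LOCATION, x)
        assert got == pytest.approx(norm.pdf(x, 0, np.sqrt(1 + tau2)),
                                    rel=1e-12)

    def test_truncated_normal_prior_vs_quadrature(self):
        prior = PriorSpec.normal(0.5, 1.2, support_sides=1)
        x = 1.7
        oracle, _ = quad(lambda t: norm.pdf(x - t) * prior.pdf(t), 0, 30,
                         limit=200)
        assert marginal_likelihood(prior, NORMAL_LOCATION, x) == \
            pytest.approx(oracle, rel=1e-8)

    def test_grid_prior_matches_mixture(self):
        prior = PriorSpec.grid([0.5, 1.5], [0.25, 0.75])
        x = 1.0
        expected = 0.25 * norm.pdf(0.5) + 0.75 * norm.pdf(-0.5)
        assert marginal_likelihood(prior, NORMAL_LOCATION, x) == \
            pytest.approx(expected, rel=1e-12)

    def test_scale_model_rejected(self):
        model = ModelSpec("normal_scale", sigma1_sq=1.1)
        with pytest.raises(TypeError):
            marginal_likelihood(PriorSpec.point(1.0), model, 1.96)


class TestBayesFactor:
    def test_vaccine_uniform_prior(self, uniform_295):
        assert round(bayes_factor(uniform_295, NORMAL_LOCATION, 2.06), 2) == 5.63

    def test_point_mass_at_mle_reaches_supremum(self):
        z = 2.06
        got = bayes_factor(PriorSpec.point(z), NORMAL_LOCATION, z)
        assert got == pytest.approx(np.exp(z * z / 2), rel=1e-12)
        assert round(got, 2) == 8.35

    def test_intrinsic_prior_closed_form(self):
        construction = intrinsic_prior_normal()
        assert construction.q == 1
        prior = construction.prior
        assert (prior.kind, prior.mean, prior.var) == ("normal", 0.0, 2.0)
        # defining integral: average the posterior Normal(x*, 1) over
        # imaginary data x* ~ Normal(0, 1); result must be Normal(0, 2)
        for theta in np.linspace(-4, 4, 20):
            defining, _ = quad(
                lambda xs, th=theta: norm.pdf(th - xs) * norm.pdf(xs),
                -12, 12, limit=200)
            assert defining == pytest.approx(prior.pdf(theta), abs=1e-6)
        for z in (0.0, 2.06):
            got = bayes_factor(prior, NORMAL_LOCATION, z)
            assert got == pytest.approx(np.exp(z * z / 3) / np.sqrt(3),
                                        rel=1e-12)
        assert round(bayes_factor(prior, NORMAL_LOCATION, 2.06), 3) == 2.376

    @given(z=st.floats(-3.0, 4.0), a=st.floats(0.05, 8.0),
           tau2=st.floats(0.1, 4.0))
    def test_no_prior_beats_the_supremum(self, z, a, tau2):
        sup = bf_sup_all_priors(z) * (1 + 1e-9)
        for prior in (PriorSpec.uniform_from_null(a),
                      PriorSpec.normal(0.0, tau2, support_sides=1),
                      PriorSpec.grid([0.3, 1.1, 2.2], [0.2, 0.5, 0.3])):
            assert bayes_factor(prior, NORMAL_LOCATION, z) <= sup


class TestBestNonincreasing:
    def test_vaccine_example(self):
        a_star, bf = bf_best_nonincreasing(2.06)
        assert round(a_star, 2) == 2.95
        assert round(bf, 2) == 5.63
        assert bf <= bf_sup_all_priors(2.06)

    def test_matches_grid_search_oracle(self):
        z = 1.645
        grid = np.linspace(1e-4, z + 10, 10_000)
        bfs = [bayes_factor(PriorSpec.uniform_from_null(a), NORMAL_LOCATION, z)
               for a in grid]
        _, best = bf_best_nonincreasing(z)
        assert best == pytest.approx(max(bfs), abs=1e-4)

    def test_requires_positive_z(self):
        with pytest.raises(ValueError):
            bf_best_nonincreasing(-0.5)


class TestBound:
    @pytest.mark.parametrize(
        "p,expected,digits",
        [(0.05, 2.456, 3), (0.001, 53.25, 1), (0.005, 13.9, 1)],
    )
    def test_printed_values(self, p, expected, digits):
        assert round(bf_bound_from_p(p), digits) == pytest.approx(expected,
                                                                  abs=10**-digits)

    def test_boundary_and_not_applicable(self):
        assert bf_bound_from_p(1 / np.e) == pytest.approx(1.0, rel=1e-12)
        assert bf_bound_from_p(0.5) is None

    def test_domain(self):
        for bad in (0.0, 1.0, -0.1, 1.2):
            with pytest.raises(ValueError):
                bf_bound_from_p(bad)

    @given(st.floats(1e-8, 1 / np.e - 1e-9), st.floats(1e-6, 1e-1))
    def test_strictly_decreasing(self, p, shrink):
        smaller = p * (1 - shrink)
        assert bf_bound_from_p(smaller) > bf_bound_from_p(p)

    @given(z=st.floats(0.3, 2.1), a=st.floats(0.05, 8.0))
    def test_two_sided_symmetric_priors_dominated_for_moderate_evidence(
            self, z, a):
        """Symmetric nonincreasing priors never beat the two-sided bound in
        the moderate-evidence zone (the bound is an approximation for the
        normal class and is only crossed, slightly, beyond z ~ 2.4)."""
        p = p_from_statistic(z, 2)
        if p > 1 / np.e:
            return
        prior = PriorSpec.uniform_from_null(a, support_sides=2)
        bf = bayes_factor(prior, NORMAL_LOCATION, z)
        assert bf <= bf_bound_from_p(p) * (1 + 1e-9)

    def test_excess_over_bound_is_minor(self):
        """Strong evidence can push nonincreasing-prior Bayes factors above
        the p-only bound, but only by a small factor: ~12% two-sided and
        under a factor of two one-sided across z <= 6."""
        one_exceeded = False
        for z in np.linspace(0.95, 6.0, 40):
            a_star, bf1 = bf_best_nonincreasing(z)
            bound1 = bf_bound_from_p(p_from_statistic(z, 1))
            one_exceeded |= bf1 > bound1
            assert bf1 <= 2.0 * bound1
            prior2 = PriorSpec.uniform_from_null(max(a_star, 1.0),
                                                 support_sides=2)
            bf2 = bayes_factor(prior2, NORMAL_LOCATION, z)
            bound2 = bf_bound_from_p(p_from_statistic(z, 2))
            assert bf2 <= 1.12 * bound2
        assert one_exceeded  # the one-sided violation is real, just bounded


class TestVarianceTest:
    @pytest.mark.parametrize(
        "x,s2,expected,digits",
        [(1.96, 1.1, 1.135, 3), (3.29, 4.0, 28.96, 2), (4.42, 16.0, 2372, 0)],
    )
    def test_printed_values(self, x, s2, expected, digits):
        assert round(variance_test_lr(x, s2), digits) == pytest.approx(
            expected, abs=10.0**-digits)

    def test_center_value_and_closed_form(self):
        for s2 in (1.1, 4.0, 9.0):
            assert variance_test_lr(0.0, s2) == pytest.approx(
                1 / np.sqrt(s2), rel=1e-12)
        x, s2 = 2.3, 2.5
        assert variance_test_lr(x, s2) == pytest.approx(
            np.exp(x * x * (1 - 1 / s2) / 2) / np.sqrt(s2), rel=1e-12)

    def test_domain(self):
        with pytest.raises(ValueError):
            variance_test_lr(1.0, 1.0)
        with pytest.raises(ValueError):
            variance_test_lr(1.0, -2.0)


def test_post_odds_products():
    assert post_odds(PriorOdds.even(), 5.63) == pytest.approx(5.63)
    assert post_odds(PriorOdds.from_odds(1e-5), 2e6) == pytest.approx(20.0)
    assert post_odds(PriorOdds.from_odds(0.1), 10.0) == pytest.approx(1.0)
    assert post_odds(0.1, 10.0) == pytest.approx(1.0)  # bare odds accepted


def test_evidence_report_consistency(uniform_295):
    rep = evidence_report(2.06, uniform_295, sides=1,
                          prior_odds=PriorOdds.even())
    assert rep.r_post == pytest.approx(
        rep.marginal / norm.pdf(2.06), rel=1e-9)
    assert rep.o_post == pytest.approx(rep.r_post, rel=1e-12)
    assert round(rep.p_value, 2) == 0.02
    assert rep.bound is not None
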