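"""Analytic interspike-interval law: transforms, moments, densities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from bindneuron import (
    BindingNeuronSpec,
    InterArrivalModel,
    LifetimeModel,
    conditional_density,
    invert_laplace,
    isi_cdf,
    isi_cv,
    isi_density,
    isi_laplace,
    isi_law,
    isi_mean,
    isi_quantile,
    isi_survival,
    isi_variance,
    success_probability,
)

LN2 = math.log(2.0)


def exp_det(lam, tau):
    return BindingNeuronSpec(InterArrivalModel.exponential(lam),
                             LifetimeModel.deterministic(tau))


class TestSuccessProbability:
    def test_exponential_deterministic(self, exp_det_spec):
        assert success_probability(exp_det_spec) == pytest.approx(0.5)

    def test_two_iid_exponentials(self, exp_exp_spec):
        assert success_probability(exp_exp_spec) == pytest.approx(0.5)

    def test_uniform_deterministic(self, uniform_det_spec):
        assert success_probability(uniform_det_spec) == pytest.approx(0.5)

    def test_general_quadrature_route(self):
        # uniform input with random (exponential) lifetime
        spec = BindingNeuronSpec(InterArrivalModel.uniform(0.0, 2.0),
                                 LifetimeModel.exponential(1.0))
        expected = (1.0 - math.exp(-2.0)) / 2.0  # int_0^2 e^{-t}/2 dt
        assert success_probability(spec) == pytest.approx(expected, rel=1e-10)


class TestConditionalDensities:
    def test_beta_at_origin(self, exp_det_spec):
        # f(0)/q = 1/0.5
        assert conditional_density(exp_det_spec, 0.0, "beta") == \
            pytest.approx(2.0)

    def test_alpha_vanishes_below_tau(self, exp_det_spec):
        assert conditional_density(exp_det_spec, 0.5, "alpha") == 0.0

    @pytest.mark.parametrize("branch", ["alpha", "beta"])
    def test_normalization(self, exp_exp_spec, branch):
        val, _ = integrate.quad(
            lambda t: float(conditional_density(exp_exp_spec, t, branch)),
            0, 60, limit=200)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_degenerate_branch_raises(self):
        # tau >= b: every arrival fires, alpha unconditioned
        spec = BindingNeuronSpec(InterArrivalModel.uniform(0.0, 1.0),
                                 LifetimeModel.deterministic(2.0))
        with pytest.raises(ValueError):
            conditional_density(spec, 0.5, "alpha")


class TestLaplaceTransform:
    def test_normalization_at_zero(self, exp_det_spec, exp_exp_spec,
                                   uniform_det_spec):
        for spec in (exp_det_spec, exp_exp_spec, uniform_det_spec):
            assert isi_laplace(spec, 0.0) == pytest.approx(1.0, abs=1e-12)

    def test_rational_value(self, exp_exp_spec):
        # lam (s + lam) / (s^2 + s (2 lam + mu) + lam^2) at s = 1 is 2/5
        assert isi_laplace(exp_exp_spec, 1.0) == pytest.approx(0.4, abs=1e-12)

    @pytest.mark.parametrize("s", [0.5, 1.0, 2.0])
    def test_transform_matches_density_quadrature(
            self, s, exp_det_spec, exp_exp_spec, uniform_det_spec):
        for spec in (exp_det_spec, exp_exp_spec, uniform_det_spec):
            val, _ = integrate.quad(
                lambda t: math.exp(-s * t) * float(isi_density(spec, t)),
                0, 80, limit=400)
            assert val == pytest.approx(isi_laplace(spec, s), abs=1e-6)


class TestMoments:
    def test_mean_worked_cases(self, exp_det_spec, exp_exp_spec,
                               uniform_det_spec):
        for spec in (exp_det_spec, exp_exp_spec, uniform_det_spec):
            assert isi_mean(spec) == pytest.approx(2.0, rel=1e-12)

    def test_uniform_mean_formulas_agree(self, uniform_det_spec):
        a, b = 0.0, 2.0
        tau = 1.0
        closed = (b**2 - a**2) / (2.0 * (tau - a))
        via_q = ((a + b) / 2.0) / success_probability(uniform_det_spec)
        assert isi_mean(uniform_det_spec) == pytest.approx(closed, abs=1e-12)
        assert closed == pytest.approx(via_q, abs=1e-12)

    def test_exp_exp_mean_from_rates(self):
        for lam, mu in [(1.0, 1.0), (2.0, 1.0), (0.5, 3.0)]:
            spec = BindingNeuronSpec(InterArrivalModel.exponential(lam),
                                     LifetimeModel.exponential(mu))
            assert isi_mean(spec) == pytest.approx((lam + mu) / lam**2,
                                                   rel=1e-12)

    def test_variance_exp_det(self, exp_det_spec):
        assert isi_variance(exp_det_spec) == pytest.approx(4.0 * (1.0 + LN2),
                                                           rel=1e-12)

    def test_variance_long_lifetime_limit(self):
        # tau -> inf: T -> Z, Var -> 1/lam^2
        assert isi_variance(exp_det(1.0, 60.0)) == pytest.approx(1.0,
                                                                 rel=1e-9)

    def test_cv_exp_det(self, exp_det_spec):
        assert isi_cv(exp_det_spec) == pytest.approx(math.sqrt(1.0 + LN2),
                                                     rel=1e-12)

    @pytest.mark.parametrize("tau", [1e-4, 60.0])
    def test_cv_poisson_limits(self, tau):
        # both tau -> 0 (thinned Poisson) and tau -> inf (T = Z) give CV 1
        assert isi_cv(exp_det(1.0, tau)) == pytest.approx(1.0, abs=1e-3)

    def test_short_lifetime_mean_diverges(self):
        assert isi_mean(exp_det(1.0, 1e-8)) > 1e7

    @pytest.mark.parametrize("case", ["exp_det", "exp_exp", "uniform_det"])
    def test_moments_match_transform_derivatives(self, case, exp_det_spec,
                                                 exp_exp_spec,
                                                 uniform_det_spec):
        spec = {"exp_det": exp_det_spec, "exp_exp": exp_exp_spec,
                "uniform_det": uniform_det_spec}[case]
        h = 1e-4
        lm, l0, lp = (isi_laplace(spec, s) for s in (-h, 0.0, h))
        mean_fd = -(lp - lm) / (2.0 * h)
        second_fd = (lp - 2.0 * l0 + lm) / h**2
        var_fd = second_fd - mean_fd**2
        assert isi_mean(spec) == pytest.approx(mean_fd, rel=1e-5)
        assert isi_variance(spec) == pytest.approx(var_fd, rel=1e-5)

    def test_variance_general_quadrature_route(self):
        # uniform input, exponential lifetime: numeric branch-moment route
        spec = BindingNeuronSpec(InterArrivalModel.uniform(0.0, 2.0),
                                 LifetimeModel.exponential(1.0))
        h = 1e-4
        lm, l0, lp = (isi_laplace(spec, s) for s in (-h, 0.0, h))
        mean_fd = -(lp - lm) / (2.0 * h)
        var_fd = (lp - 2.0 * l0 + lm) / h**2 - mean_fd**2
        assert isi_mean(spec) == pytest.approx(mean_fd, rel=1e-5)
        assert isi_variance(spec) == pytest.approx(var_fd, rel=1e-4)

    def test_never_firing_configuration_raises(self):
        spec = BindingNeuronSpec(InterArrivalModel.uniform(1.0, 2.0),
                                 LifetimeModel.deterministic(0.5))
        with pytest.raises(ValueError):
            isi_mean(spec)

    def test_analytics_require_threshold_two(self):
        spec = BindingNeuronSpec(InterArrivalModel.exponential(1.0),
                                 LifetimeModel.deterministic(1.0),
                                 threshold=3)
        with pytest.raises(ValueError):
            isi_mean(spec)


class TestDensityAndCdf:
    def test_series_below_tau_is_input_density(self):
        # for t < tau only the first term survives: h(t) = lam e^{-lam t}
        spec = exp_det(1.0, 1.0)
        assert isi_density(spec, 0.5) == pytest.approx(math.exp(-0.5),
                                                       rel=1e-12)

    def test_biexp_at_origin(self, exp_exp_spec):
        assert isi_density(exp_exp_spec, 0.0) == pytest.approx(1.0, rel=1e-12)

    def test_biexp_root_invariants(self, exp_exp_spec):
        law = isi_law(exp_exp_spec)
        lam, mu = 1.0, 1.0
        assert law.r1 * law.r2 == pytest.approx(lam**2, abs=1e-10)
        assert law.r1 + law.r2 == pytest.approx(-(2 * lam + mu), abs=1e-10)
        assert law.r1 < 0 and law.r2 < 0

    def test_series_matches_numeric_inversion(self):
        # grid avoids multiples of tau, where the density is discontinuous
        spec = exp_det(1.0, 1.0)
        grid = np.linspace(0.05, 4.95, 50)
        series = np.asarray(isi_density(spec, grid))
        from bindneuron.isi_analytics import _numeric_density
        numeric = _numeric_density(spec, grid)
        assert np.max(np.abs(series - numeric)) < 1e-5

    @pytest.mark.parametrize("case", ["exp_det", "exp_exp", "uniform_det"])
    def test_density_normalization(self, case, exp_det_spec, exp_exp_spec,
                                   uniform_det_spec):
        spec = {"exp_det": exp_det_spec, "exp_exp": exp_exp_spec,
                "uniform_det": uniform_det_spec}[case]
        val, _ = integrate.quad(lambda t: float(isi_density(spec, t)),
                                0, 80, limit=400)
        assert abs(val - 1.0) < 1e-6

    def test_cdf_at_origin(self, exp_det_spec, exp_exp_spec,
                           uniform_det_spec):
        for spec in (exp_det_spec, exp_exp_spec, uniform_det_spec):
            assert isi_cdf(spec, 0.0) == 0.0

    def test_cdf_tends_to_one(self, exp_exp_spec):
        assert isi_cdf(exp_exp_spec, 60.0) == pytest.approx(1.0, abs=1e-9)

    def test_cdf_nondecreasing(self, exp_det_spec):
        vals = np.asarray(isi_cdf(exp_det_spec, np.linspace(0, 20, 200)))
        assert np.all(np.diff(vals) >= -1e-12)

    def test_cdf_matches_density_quadrature(self, exp_det_spec):
        for t in (0.3, 1.0, 2.5, 6.0):
            val, _ = integrate.quad(
                lambda u: float(isi_density(exp_det_spec, u)), 0, t,
                limit=200)
            assert isi_cdf(exp_det_spec, t) == pytest.approx(val, abs=1e-9)

    def test_quantile_inverts_cdf(self, exp_det_spec):
        for u in (0.1, 0.5, 0.9):
            t = isi_quantile(exp_det_spec, u)
            assert isi_cdf(exp_det_spec, t) == pytest.approx(u, abs=1e-9)

    def test_negative_time_rejected(self, exp_det_spec):
        with pytest.raises(ValueError):
            isi_density(exp_det_spec, -1.0)


class TestInvertLaplace:
    def test_exponential_pair(self):
        est = invert_laplace(lambda s: 1.0 / (s + 1.0), 1.0)
        assert abs(est - math.exp(-1.0)) < 1e-7

    def test_uniform_density_pair(self):
        est = invert_laplace(lambda s: (1.0 - np.exp(-s)) / s, 0.5)
        assert abs(est - 1.0) < 1e-7

    def test_rational_isi_pair(self, exp_exp_spec):
        est = invert_laplace(lambda s: isi_laplace(exp_exp_spec, s), 1.0)
        assert abs(est - isi_density(exp_exp_spec, 1.0)) < 1e-7

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            invert_laplace(lambda s: 1.0 / (s + 1.0), 0.0)


class TestStochasticOrdering:
    """Shorter lifetimes make firing stochastically slower."""

    def test_survival_dominance_at_deciles(self):
        s1, s2 = exp_det(1.0, 0.5), exp_det(1.0, 2.0)
        deciles = [isi_quantile(s2, u) for u in np.arange(0.1, 0.95, 0.1)]
        surv1 = np.asarray(isi_survival(s1, np.array(deciles)))
        surv2 = np.asarray(isi_survival(s2, np.array(deciles)))
        assert np.all(surv1 >= surv2)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(tau1=st.floats(0.1, 2.0), delta=st.floats(0.05, 3.0),
           t=st.floats(0.01, 12.0))
    def test_survival_dominance_property(self, tau1, delta, t):
        s_short, s_long = exp_det(1.0, tau1), exp_det(1.0, tau1 + delta)
        assert isi_survival(s_short, t) >= isi_survival(s_long, t) - 1e-12


class TestLimits:
    def test_long_lifetime_recovers_input_law(self):
        # lam tau = 50: every arrival fires, T -> Z
        spec = exp_det(1.0, 50.0)
        grid = np.linspace(0.01, 10.0, 200)
        input_cdf = 1.0 - np.exp(-grid)
        dist = np.max(np.abs(np.asarray(isi_cdf(spec, grid)) - input_cdf))
        assert dist < 0.01

    def test_short_lifetime_mean_unbounded(self):
        means = [isi_mean(exp_det(1.0, tau)) for tau in (1e-2, 1e-4, 1e-6)]
        assert means[0] < means[1] < means[2]
        assert means[-1] > 1e5
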