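import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from scipy.integrate import quad

import saxsflex as sf
from saxsflex.errors import InsufficientDataError


class TestLognormalPdf:
    def test_value_at_median(self):
        mu, sigma = 3.0, 0.4
        expected = 1.0 / (np.exp(mu) * sigma * np.sqrt(2 * np.pi))
        assert sf.lognormal_pdf(np.exp(mu), sf.RgLogNormal(mu, sigma)) == pytest.approx(
            expected, rel=1e-12
        )

    def test_zero_at_origin(self):
        assert sf.lognormal_pdf(0.0, sf.RgLogNormal(3.0, 0.3)) == 0.0

    @given(mu=st.floats(1.0, 5.0), sigma=st.floats(0.05, 1.5))
    def test_normalization(self, mu, sigma):
        d = sf.RgLogNormal(mu, sigma)
        # substitute r = e^u so the integrand is a smooth Gaussian bump
        total, _ = quad(
            lambda u: sf.lognormal_pdf(np.exp(u), d) * np.exp(u),
            mu - 8 * sigma, mu + 8 * sigma, limit=200,
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            sf.RgLogNormal(3.0, 0.0)


class TestEntropy:
    @pytest.mark.parametrize("mu", np.linspace(1.0, 5.0, 5))
    @pytest.mark.parametrize("sigma", np.linspace(0.05, 1.5, 5))
    def test_closed_form_matches_quadrature(self, mu, sigma):
        """S = μ + 1/2 + ln(σ√2π) must equal −∫P ln P numerically."""
        p = sf.RgLogNormal(mu, sigma)
        assert sf.entropy(p) == pytest.approx(sf.entropy_quadrature(p), abs=1e-8)

    def test_standard_case(self):
        assert sf.entropy(sf.RgLogNormal(0.0, 1.0)) == pytest.approx(
            0.5 + np.log(np.sqrt(2 * np.pi)), abs=1e-12
        )

    def test_agrees_with_scipy_entropy(self):
        p = sf.RgLogNormal(2.7, 0.33)
        assert sf.entropy(p) == pytest.approx(
            float(stats.lognorm(s=0.33, scale=np.exp(2.7)).entropy()), abs=1e-10
        )

    @given(mu=st.floats(-2, 5), sigma=st.floats(0.01, 2.0), delta=st.floats(-1, 1))
    def test_translation_in_log_space(self, mu, sigma, delta):
        lhs = sf.entropy(sf.RgLogNormal(mu + delta, sigma))
        rhs = sf.entropy(sf.RgLogNormal(mu, sigma)) + delta
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_gradient_by_finite_differences(self):
        mu, sigma, h = 3.0, 0.4, 1e-6
        ds_dmu = (sf.entropy(sf.RgLogNormal(mu + h, sigma)) - sf.entropy(sf.RgLogNormal(mu - h, sigma))) / (2 * h)
        ds_dsigma = (sf.entropy(sf.RgLogNormal(mu, sigma + h)) - sf.entropy(sf.RgLogNormal(mu, sigma - h))) / (2 * h)
        assert ds_dmu == pytest.approx(1.0, abs=1e-6)
        assert ds_dsigma == pytest.approx(1.0 / sigma, abs=1e-5)

    def test_unbounded_below_as_sigma_shrinks(self):
        values = [sf.entropy(sf.RgLogNormal(3.0, s)) for s in (0.1, 0.01, 0.001, 1e-8)]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert values[-1] < -10


class TestModelIntensity:
    def test_delta_limit_matches_sphere(self):
        rg = 20.0
        q = np.linspace(0.0, 5.0 / rg, 80)
        mi = sf.model_intensity(q, sf.RgLogNormal(np.log(rg), 1e-3))
        np.testing.assert_allclose(mi, sf.sphere_intensity(q, rg), atol=1e-4)

    def test_unity_at_zero_angle(self):
        for mu, sigma in [(2.5, 0.1), (3.0, 0.5), (4.0, 1.0)]:
            assert sf.model_intensity(np.array([0.0]), sf.RgLogNormal(mu, sigma))[0] == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("mu,sigma", [(3.0, 0.3), (2.6, 0.15), (3.8, 0.7)])
    def test_monte_carlo_oracle(self, mu, sigma):
        """Quadrature must agree with a seeded Monte-Carlo ensemble average
        of sphere intensities within 3 standard errors at every q."""
        n_draws = 200_000
        rng = np.random.default_rng(123)
        draws = rng.lognormal(mean=mu, sigma=sigma, size=n_draws)
        q = np.linspace(0.005, 0.3, 40)
        # accumulate in chunks to bound memory
        total = np.zeros_like(q)
        total_sq = np.zeros_like(q)
        from saxsflex.sphere import _intensity_matrix

        for chunk in np.array_split(draws, 10):
            mat = _intensity_matrix(q, chunk)
            total += mat.sum(axis=1)
            total_sq += (mat**2).sum(axis=1)
        mc_mean = total / n_draws
        mc_se = np.sqrt((total_sq / n_draws - mc_mean**2) / n_draws)
        model = sf.model_intensity(q, sf.RgLogNormal(mu, sigma))
        assert np.all(np.abs(model - mc_mean) <= 3.0 * mc_se + 1e-12)

    def test_coverage_error_when_grid_too_small(self):
        with pytest.raises(sf.CoverageError):
            sf.model_intensity(np.array([0.1]), sf.RgLogNormal(3.0, 0.5), tail_mass=0.01)


class TestMisfit:
    def test_zero_at_truth(self, lognormal_profile):
        profile, truth = lognormal_profile
        c = truth["components"][0]
        params = sf.RgLogNormal(c["mu"], c["sigma"])
        assert sf.misfit(profile, params, scale=truth["scale"]) < 1e-12

    def test_positive_when_perturbed(self, lognormal_profile):
        profile, truth = lognormal_profile
        c = truth["components"][0]
        params = sf.RgLogNormal(c["mu"] + 0.5, c["sigma"])
        assert sf.misfit(profile, params, scale=truth["scale"]) > 1e-4

    def test_chi2_zero_when_model_equals_data(self, lognormal_profile):
        profile, truth = lognormal_profile
        c = truth["components"][0]
        with_sigma = sf.ScatteringProfile(
            profile.q, profile.intensity, np.abs(profile.intensity), profile.label
        )
        params = sf.RgLogNormal(c["mu"], c["sigma"])
        assert sf.misfit(with_sigma, params, scale=truth["scale"], weighting="chi2") < 1e-12

    def test_too_few_points_in_window(self, lognormal_profile):
        profile, _ = lognormal_profile
        with pytest.raises(InsufficientDataError):
            sf.misfit(profile, sf.RgLogNormal(3.0, 0.3), 1.0, q_window=(0.005, 0.006))


class TestFit:
    def test_noiseless_recovery(self, lognormal_fit):
        fit, truth = lognormal_fit
        c = truth["components"][0]
        assert fit.converged
        assert fit.mu_hat == pytest.approx(c["mu"], abs=1e-3)
        assert fit.sigma_hat == pytest.approx(c["sigma"], abs=1e-3)
        assert fit.entropy == pytest.approx(truth["entropy"], abs=0.01)
        # reported entropy is exactly the closed form at the fitted params
        assert fit.entropy == sf.entropy(sf.RgLogNormal(fit.mu_hat, fit.sigma_hat))

    def test_noisy_recovery(self, noisy_fit):
        fit, truth = noisy_fit
        c = truth["components"][0]
        assert fit.mu_hat == pytest.approx(c["mu"], abs=0.05)
        assert fit.sigma_hat == pytest.approx(c["sigma"], abs=0.05)

    def test_scale_invariance(self, lognormal_profile, lognormal_fit):
        profile, _ = lognormal_profile
        fit, _ = lognormal_fit
        scaled = sf.ScatteringProfile(profile.q, profile.intensity * 137.0, None, profile.label)
        refit = sf.fit_rgd(scaled)
        assert refit.mu_hat == pytest.approx(fit.mu_hat, abs=1e-6)
        assert refit.sigma_hat == pytest.approx(fit.sigma_hat, abs=1e-6)
        assert refit.entropy == pytest.approx(fit.entropy, abs=1e-6)
        assert refit.scale == pytest.approx(fit.scale * 137.0, rel=1e-5)

    def test_q_window_inside_profile(self, lognormal_fit, lognormal_profile):
        fit, _ = lognormal_fit
        profile, _ = lognormal_profile
        assert profile.q[0] <= fit.q_window[0] < fit.q_window[1] <= profile.q[-1]

    def test_two_point_profile_rejected(self):
        with pytest.raises(InsufficientDataError):
            sf.fit_rgd(sf.ScatteringProfile(np.array([0.01, 0.02]), np.array([1.0, 0.9])))


class TestEntropyError:
    def test_zero_sigma_gives_zero(self, lognormal_profile, lognormal_fit):
        profile, _ = lognormal_profile
        fit, _ = lognormal_fit
        zero_sigma = sf.ScatteringProfile(
            profile.q, profile.intensity, np.zeros_like(profile.q), profile.label
        )
        assert sf.entropy_error(zero_sigma, fit, n_resamples=10, seed=0) == 0.0

    def test_positive_and_seed_stable(self, noisy_profile, noisy_fit):
        profile, _ = noisy_profile
        fit, _ = noisy_fit
        e1 = sf.entropy_error(profile, fit, n_resamples=30, seed=11)
        e2 = sf.entropy_error(profile, fit, n_resamples=30, seed=12)
        assert e1 > 0 and e2 > 0
        # two independent seeds must agree on the spread within 50%
        assert abs(e1 - e2) / max(e1, e2) < 0.5
        # and be reproducible for the same seed
        assert sf.entropy_error(profile, fit, n_resamples=30, seed=11) == e1

    def test_preconditions(self, lognormal_profile, lognormal_fit, noisy_profile, noisy_fit):
        bare, _ = lognormal_profile
        fit, _ = lognormal_fit
        with pytest.raises(ValueError):
            sf.entropy_error(bare, fit, n_resamples=10)
        noisy, _ = noisy_profile
        nfit, _ = noisy_fit
        with pytest.raises(ValueError):
            sf.entropy_error(noisy, nfit, n_resamples=1)
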