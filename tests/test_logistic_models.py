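"""Mixed logistic (LRI/LRC) and GEE analyses against independent oracles."""

import math
import warnings

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.integrate import quad as scipy_quad
from scipy.special import expit, logit
from scipy.stats import norm

from partnest.datagen import TrialDesign, simulate_trial
from partnest.latent_link import LatentScenario, QuadratureSpec
from partnest.logistic_models import (
    FitError,
    SeparationError,
    fit_lgee,
    fit_lri,
    fit_lrc,
    fitted_manifest_quantities,
    loglik,
    lrt,
    wald_test,
)

from conftest import make_data


def lrc_quiet(*args, **kwargs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return fit_lrc(*args, **kwargs)


def brute_force_loglik(data, model, alpha, delta, sigma):
    """Direct numerical integration of the marginal likelihood, cluster by cluster."""
    total = 0.0
    tab = data.cluster_table()
    for _, row in tab.iterrows():
        def integrand(z, m=row["m"], r=row["r"]):
            p = expit(alpha + delta + sigma * z)
            return p ** r * (1 - p) ** (m - r) * norm.pdf(z)
        val, _ = scipy_quad(integrand, -np.inf, np.inf)
        total += math.log(val)
    for y in data.outcome[data.arm == 0]:
        if model == "lri":
            def integrand(z, y=y):
                p = expit(alpha + sigma * z)
                return (p if y else 1 - p) * norm.pdf(z)
            val, _ = scipy_quad(integrand, -np.inf, np.inf)
        else:
            p = expit(alpha)
            val = p if y else 1 - p
        total += math.log(val)
    return total


@pytest.fixture(scope="module")
def clustered_data():
    """Moderate non-null dataset with real clustering."""
    scen = LatentScenario.from_manifest(0.25, 0.5, 0.1)
    return simulate_trial(scen, TrialDesign.equal(20, 10, 200), 101)


class TestLikelihood:
    @pytest.mark.parametrize("model", ["lri", "lrc"])
    @pytest.mark.parametrize(
        "params", [(-0.3, 0.8, 0.6), (0.5, -1.0, 1.4), (0.0, 0.0, 0.0)]
    )
    def test_matches_brute_force_integration(self, tiny_clustered, model, params):
        got = loglik(tiny_clustered, model, *params)
        want = brute_force_loglik(tiny_clustered, model, *params)
        assert got == pytest.approx(want, abs=1e-8)

    def test_quadrature_order_insensitive(self, clustered_data):
        f20 = fit_lri(clustered_data, QuadratureSpec(20))
        f40 = fit_lri(clustered_data, QuadratureSpec(40))
        assert f20.delta == pytest.approx(f40.delta, abs=1e-5)
        assert f20.loglik == pytest.approx(f40.loglik, abs=1e-5)


class TestMixedFits:
    def test_lri_lrc_unconstrained_logliks_agree(self, clustered_data):
        """The two parameterisations are reparameterisations of one another
        for this design, so the maximised log-likelihoods coincide."""
        f_lri = fit_lri(clustered_data)
        f_lrc = lrc_quiet(clustered_data)
        assert f_lri.loglik == pytest.approx(f_lrc.loglik, abs=1e-6)
        # ... but the fitted treatment effects differ when sigma_U > 0
        assert f_lri.sigma_u > 0.02
        assert abs(f_lri.delta - f_lrc.delta) > 1e-4

    def test_null_constrained_logliks_differ(self, clustered_data):
        n_lri = fit_lri(clustered_data, constrain_null=True)
        n_lrc = lrc_quiet(clustered_data, constrain_null=True)
        assert abs(n_lri.loglik - n_lrc.loglik) > 1e-3

    def test_null_nested_in_full(self, clustered_data):
        assert fit_lri(clustered_data).loglik >= fit_lri(
            clustered_data, constrain_null=True
        ).loglik - 1e-9

    def test_independent_data_matches_plain_logistic(self):
        """With sigma_U = 0 in truth, delta_hat tracks the unclustered MLE."""
        scen = LatentScenario.from_manifest(0.3, 0.4, 0.0)
        data = simulate_trial(scen, TrialDesign.equal(4000, 10, 40_000), 7)
        f = fit_lri(data)
        glm = sm.Logit(data.outcome, sm.add_constant(data.arm.astype(float))).fit(
            disp=False
        )
        assert f.delta == pytest.approx(glm.params[1], abs=0.01)

    def test_lrc_asymptotic_null_bias_in_printed_interval(self):
        """Very large null dataset at pi = 0.1, rho = 0.1: the LRC treatment
        effect converges to a markedly negative log-odds ratio."""
        scen = LatentScenario.from_manifest(0.1, 0.1, 0.1)
        data = simulate_trial(scen, TrialDesign.equal(20_000, 10, 200_000), 13)
        f = lrc_quiet(data)
        assert -0.430 < f.delta < -0.387

    def test_lri_null_consistency(self):
        """Null on the proportion scale implies a null LRI effect."""
        scen = LatentScenario.from_manifest(0.3, 0.3, 0.1)
        data = simulate_trial(scen, TrialDesign.equal(30_000, 10, 300_000), 29)
        f = fit_lri(data)
        assert abs(f.delta) < 0.03

    def test_warns_about_lrc_inconsistency(self, tiny_clustered):
        with pytest.warns(UserWarning, match="inconsistent"):
            fit_lrc(tiny_clustered)

    def test_separation_raises(self):
        data = make_data([0, 0, 0], [4, 4, 4], 3, 10)
        with pytest.raises(SeparationError):
            fit_lri(data)


class TestWaldAndLrt:
    def test_wald_pvalues(self, clustered_data):
        f = fit_lri(clustered_data)
        res = wald_test(f)
        assert res.p_lower + res.p_upper == pytest.approx(1.0, abs=1e-15)
        z = f.delta / f.se_delta
        assert res.p_two == pytest.approx(2 * norm.cdf(-abs(z)), abs=1e-15)
        assert res.scale == "logodds_cluster_specific"

    def test_lrt_identical_fits(self, clustered_data):
        f = fit_lri(clustered_data)
        res = lrt(f, f)
        assert res.statistic == 0.0
        assert res.p_two == pytest.approx(1.0)

    def test_lrt_statistic_nonnegative_and_directional(self, clustered_data):
        full = fit_lri(clustered_data)
        null = fit_lri(clustered_data, constrain_null=True)
        res = lrt(full, null)
        assert res.statistic >= 0
        # rejection attributed to the tail matching sign(delta_hat) < 0 here
        assert full.delta < 0
        assert res.p_lower == pytest.approx(res.p_two / 2)

    def test_lrt_conservative_under_independence_null(self):
        """With rho = 0 the boundary constraint sigma_U >= 0 makes the LRT
        p-value distribution stochastically larger than uniform."""
        scen = LatentScenario.from_manifest(0.3, 0.3, 0.0)
        design = TrialDesign.equal(20, 5, 100)
        pvals = []
        for rep in range(400):
            data = simulate_trial(scen, design, [17, rep])
            try:
                full = fit_lri(data)
                null = fit_lri(data, constrain_null=True)
            except FitError:
                continue
            pvals.append(lrt(full, null).p_two)
        pvals = np.asarray(pvals)
        frac = (pvals <= 0.1).mean()
        se = math.sqrt(0.1 * 0.9 / pvals.size)
        assert frac < 0.1 + 2 * se  # not anti-conservative


class TestGee:
    def test_all_singletons_equals_plain_logistic(self):
        data = make_data([0, 1, 1, 0, 1, 1, 0, 1], [1] * 8, 4, 10)
        for working in ("independence", "exchangeable"):
            g = fit_lgee(data, working)
            glm = sm.Logit(data.outcome, sm.add_constant(data.arm.astype(float))).fit(
                disp=False
            )
            assert g.delta == pytest.approx(glm.params[1], abs=1e-6)
            assert g.alpha == pytest.approx(glm.params[0], abs=1e-6)

    def test_large_sample_marginal_logodds(self):
        scen = LatentScenario.from_manifest(0.2, 0.4, 0.0)
        data = simulate_trial(scen, TrialDesign.equal(2000, 10, 20_000), 3)
        g = fit_lgee(data)
        want = math.log((0.2 / 0.8) / (0.4 / 0.6))
        assert g.delta == pytest.approx(want, abs=0.06)

    def test_marginal_attenuated_vs_cluster_specific(self, clustered_data):
        g = fit_lgee(clustered_data)
        f = fit_lri(clustered_data)
        assert abs(g.delta) <= abs(f.delta) + 1e-10

    def test_sandwich_close_to_model_based_when_independent(self):
        data = make_data(
            list(np.random.default_rng(5).integers(0, 2, 5000)), [1] * 5000, 2400, 5000
        )
        g = fit_lgee(data, "independence")
        glm = sm.Logit(data.outcome, sm.add_constant(data.arm.astype(float))).fit(
            disp=False
        )
        assert g.se_delta == pytest.approx(glm.bse[1], rel=0.1)

    def test_robust_vcov_symmetric_psd(self, clustered_data):
        v = fit_lgee(clustered_data).robust_vcov
        assert np.allclose(v, v.T)
        assert np.all(np.linalg.eigvalsh(v) >= -1e-12)


class TestManifestBackTransform:
    def test_sigma_zero_gives_zero_icc(self):
        scen = LatentScenario.from_manifest(0.3, 0.4, 0.0)
        data = simulate_trial(scen, TrialDesign.equal(50, 5, 250), 9)
        f = fit_lri(data)
        if f.sigma_u == 0:
            assert fitted_manifest_quantities(f)[2] == 0.0

    def test_parameter_recovery_large_sample(self):
        scen = LatentScenario.from_manifest(0.3, 0.5, 0.1)
        data = simulate_trial(scen, TrialDesign.equal(5000, 10, 50_000), 23)
        pi_g, pi_c, rho = fitted_manifest_quantities(fit_lri(data))
        assert pi_g == pytest.approx(0.3, abs=0.02)
        assert pi_c == pytest.approx(0.5, abs=0.02)
        assert rho == pytest.approx(0.1, abs=0.02)

    def test_lri_control_marginal_includes_random_effect(self, clustered_data):
        f = fit_lri(clustered_data)
        _, pi_c, _ = fitted_manifest_quantities(f)
        if f.sigma_u > 0.1 and f.alpha < -0.05:
            assert pi_c > expit(f.alpha)  # integral exceeds expit for alpha < 0
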