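"""Likelihood and estimating-equation analyses on the log-odds scale.

Two mixed logistic parameterisations for a partially nested design:

* logistic random intercept (LRI): ``logit pi_i = alpha + delta I_i + u_j``
  with the normal random effect in *both* arms — every control subject is a
  singleton cluster sharing sigma_U.  A null ``delta`` then implies a null
  difference of marginal proportions.
* logistic random coefficient (LRC): ``logit pi_i = alpha + delta I_i +
  I_i u_j`` — the random effect enters only the clustered arm, so the model
  compares a cluster-specific effect with a marginal control and is *not*
  consistent with a null on the proportion scale (see
  :func:`partnest.latent_link.lrc_null_bias`).

The marginal likelihood integrates the random effect by fixed-order
Gauss–Hermite quadrature.  Because outcomes are exchangeable within a
cluster, the likelihood depends on a cluster only through (size, event
count); clusters are aggregated into such patterns with multiplicities, which
makes the fit cost independent of the number of clusters.

Marginal (population-averaged) analysis is provided by logistic GEE with a
robust sandwich covariance, delegated to statsmodels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import minimize
from scipy.special import expit, log_expit, logsumexp, logit

import statsmodels.api as sm

from .datagen import PartiallyNestedData
from .latent_link import (
    QuadratureSpec,
    gauss_hermite,
    manifest_icc,
    marginal_prob,
    sigma_from_latent_icc,
)
from .prop_tests import anova_icc
from .results import AnalysisResult

__all__ = [
    "MixedLogisticFit",
    "GEEFit",
    "FitError",
    "SeparationError",
    "fit_lri",
    "fit_lrc",
    "wald_test",
    "lrt",
    "fit_lgee",
    "fitted_manifest_quantities",
]

DEFAULT_FIT_NODES = 40

_LRC_WARNING = (
    "The logistic random-coefficient model compares a cluster-specific effect "
    "in the clustered arm with a marginal effect in the control arm, and is "
    "inconsistent for a null treatment effect on the proportion scale unless "
    "pi = 0.5 or sigma_U = 0."
)


class FitError(RuntimeError):
    """Raised when a model fit fails to converge."""


class SeparationError(FitError):
    """Raised when an arm's observed event rate is 0 or 1."""


@dataclass
class MixedLogisticFit:
    """Maximum-likelihood fit of an LRI or LRC model."""

    model: str  # "lri" | "lrc"
    alpha: float
    delta: float
    sigma_u: float
    loglik: float
    converged: bool
    n_quad: int
    constrained_null: bool
    n_group: int
    n_control: int
    _patterns: "_Patterns" = field(repr=False, default=None)
    _vcov: np.ndarray | None = field(repr=False, default=None)

    @property
    def vcov(self) -> np.ndarray:
        """Observed-information covariance of (alpha, delta, sigma_u).

        Computed lazily by differencing the analytic score; the row/column of
        a parameter fixed at a boundary or by a null constraint is zeroed.
        """
        if self._vcov is None:
            self._vcov = _observed_vcov(self)
        return self._vcov

    @property
    def se_delta(self) -> float:
        v = self.vcov[1, 1]
        if not np.isfinite(v) or v <= 0:
            raise FitError(
                f"observed information for delta is not positive (var={v:g})"
            )
        return float(math.sqrt(v))


@dataclass(frozen=True)
class GEEFit:
    """Logistic GEE fit with robust (sandwich) covariance."""

    alpha: float
    delta: float
    robust_vcov: np.ndarray
    working: str
    working_corr: float
    n_group: int
    n_control: int

    @property
    def se_delta(self) -> float:
        return float(math.sqrt(self.robust_vcov[1, 1]))


# --------------------------------------------------------------------------
# pattern aggregation and marginal likelihood
# --------------------------------------------------------------------------


@dataclass
class _Patterns:
    """Clusters aggregated by (size, events, arm, has-random-effect)."""

    m: np.ndarray
    r: np.ndarray
    mult: np.ndarray
    arm: np.ndarray
    random: np.ndarray  # boolean

    @classmethod
    def build(cls, data: PartiallyNestedData, model: str) -> "_Patterns":
        tab = data.cluster_table()
        gm = tab["m"].to_numpy(dtype=np.int64)
        gr = tab["r"].to_numpy(dtype=np.int64)
        pairs, counts = np.unique(np.column_stack([gm, gr]), axis=0, return_counts=True)
        n_c = data.n_control
        r_c = data.control_events
        ctrl_random = model == "lri"
        m = np.concatenate([pairs[:, 0], [1, 1]])
        r = np.concatenate([pairs[:, 1], [0, 1]])
        mult = np.concatenate([counts, [n_c - r_c, r_c]])
        arm = np.concatenate([np.ones(len(pairs)), [0.0, 0.0]])
        random = np.concatenate(
            [np.ones(len(pairs), bool), np.full(2, ctrl_random)]
        )
        keep = mult > 0
        return cls(m[keep].astype(float), r[keep].astype(float), mult[keep].astype(float),
                   arm[keep], random[keep])


def _negloglik_grad(theta, pat: _Patterns, z, logw, null: bool):
    """Negative marginal log-likelihood and gradient over free parameters.

    theta = (alpha, delta, sigma) unconstrained, (alpha, sigma) under the
    null constraint delta = 0.
    """
    if null:
        alpha, sigma = theta
        delta = 0.0
    else:
        alpha, delta, sigma = theta
    eta0 = alpha + delta * pat.arm

    ll = 0.0
    g_eta = np.zeros_like(pat.m)  # d loglik_pattern / d eta (per cluster)
    g_sig = np.zeros_like(pat.m)

    rnd = pat.random
    if rnd.any():
        eta = eta0[rnd, None] + sigma * z[None, :]
        la = log_expit(eta)
        lb = log_expit(-eta)
        logf = pat.r[rnd, None] * la + (pat.m[rnd, None] - pat.r[rnd, None]) * lb
        logint = logf + logw[None, :]
        lp = logsumexp(logint, axis=1)
        s = np.exp(logint - lp[:, None])  # posterior quadrature weights
        resid = pat.r[rnd, None] - pat.m[rnd, None] * np.exp(la)
        g_eta[rnd] = (s * resid).sum(axis=1)
        g_sig[rnd] = (s * resid * z[None, :]).sum(axis=1)
        ll += float(pat.mult[rnd] @ lp)
    fix = ~rnd
    if fix.any():
        la = log_expit(eta0[fix])
        lb = log_expit(-eta0[fix])
        ll += float(pat.mult[fix] @ (pat.r[fix] * la + (pat.m[fix] - pat.r[fix]) * lb))
        g_eta[fix] = pat.r[fix] - pat.m[fix] * np.exp(la)

    g_alpha = float(pat.mult @ g_eta)
    g_sigma = float(pat.mult @ g_sig)
    if null:
        grad = np.array([g_alpha, g_sigma])
    else:
        g_delta = float(pat.mult @ (g_eta * pat.arm))
        grad = np.array([g_alpha, g_delta, g_sigma])
    return -ll, -grad


def loglik(
    data: PartiallyNestedData,
    model: str,
    alpha: float,
    delta: float,
    sigma_u: float,
    quad: QuadratureSpec | None = None,
) -> float:
    """Marginal log-likelihood at fixed parameters (for oracles/diagnostics)."""
    quad = quad or QuadratureSpec(DEFAULT_FIT_NODES)
    z, w = gauss_hermite(quad.n_nodes)
    pat = _Patterns.build(data, model)
    nll, _ = _negloglik_grad(
        np.array([alpha, delta, sigma_u]), pat, z, np.log(w), null=False
    )
    return -nll


def _check_separation(data: PartiallyNestedData) -> None:
    for arm in (0, 1):
        y = data.outcome[data.arm == arm]
        rate = y.mean()
        if rate == 0.0 or rate == 1.0:
            raise SeparationError(
                f"observed event rate is {rate:g} in arm {arm}; "
                "log-odds parameters are not identifiable"
            )


def _fit_mixed(
    data: PartiallyNestedData,
    model: str,
    quad: QuadratureSpec | None,
    constrain_null: bool,
) -> MixedLogisticFit:
    _check_separation(data)
    quad = quad or QuadratureSpec(DEFAULT_FIT_NODES)
    z, w = gauss_hermite(quad.n_nodes)
    logw = np.log(w)
    pat = _Patterns.build(data, model)

    p_c = np.clip(data.control_events / data.n_control, 0.02, 0.98)
    tab = data.cluster_table()
    p_g = np.clip(tab["r"].sum() / tab["m"].sum(), 0.02, 0.98)
    rho0 = min(anova_icc(data).estimate, 0.9)
    sigma0 = np.clip(sigma_from_latent_icc(rho0), 0.05, 3.0)
    alpha0 = float(logit(p_c))
    delta0 = float(logit(p_g) - alpha0)

    # bounds well outside any plausible optimum; a solution pinned to them
    # signals a degenerate likelihood ridge and is reported as a failure
    loc_lim, sig_lim = 20.0, 8.0
    if constrain_null:
        x0 = np.array([float(logit((p_c + p_g) / 2)), sigma0])
        bounds = [(-loc_lim, loc_lim), (0.0, sig_lim)]
    else:
        x0 = np.array([alpha0, delta0, sigma0])
        bounds = [(-loc_lim, loc_lim), (-2 * loc_lim, 2 * loc_lim), (0.0, sig_lim)]

    res = minimize(
        _negloglik_grad,
        x0,
        args=(pat, z, logw, constrain_null),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"ftol": 1e-13, "gtol": 1e-9, "maxiter": 500},
    )
    grad_norm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success or grad_norm < 1e-5)
    if not converged:
        raise FitError(
            f"{model.upper()} fit did not converge: {res.message} "
            f"(|grad|={grad_norm:.2e})"
        )
    if constrain_null:
        alpha, sigma = res.x
        delta = 0.0
    else:
        alpha, delta, sigma = res.x
    if sigma > sig_lim - 0.1 or abs(alpha) > loc_lim - 0.1 or abs(delta) > 2 * loc_lim - 0.1:
        raise FitError(
            f"{model.upper()} fit diverged to the parameter-space boundary "
            f"(alpha={alpha:.2f}, delta={delta:.2f}, sigma={sigma:.2f})"
        )
    return MixedLogisticFit(
        model=model,
        alpha=float(alpha),
        delta=float(delta),
        sigma_u=float(sigma),
        loglik=float(-res.fun),
        converged=converged,
        n_quad=quad.n_nodes,
        constrained_null=constrain_null,
        n_group=data.n_group,
        n_control=data.n_control,
        _patterns=pat,
    )


def fit_lri(
    data: PartiallyNestedData,
    quad: QuadratureSpec | None = None,
    constrain_null: bool = False,
) -> MixedLogisticFit:
    """ML fit of the logistic random intercept model (random effect in both arms)."""
    return _fit_mixed(data, "lri", quad, constrain_null)


def fit_lrc(
    data: PartiallyNestedData,
    quad: QuadratureSpec | None = None,
    constrain_null: bool = False,
) -> MixedLogisticFit:
    """ML fit of the logistic random coefficient model (clustered arm only).

    .. warning:: inconsistent under a proportion-scale null; see module docs.
    """
    warnings.warn(_LRC_WARNING, UserWarning, stacklevel=2)
    return _fit_mixed(data, "lrc", quad, constrain_null)


def _observed_vcov(fit: MixedLogisticFit, h: float = 1e-5) -> np.ndarray:
    """Finite-difference Hessian of -loglik using the analytic score."""
    z, w = gauss_hermite(fit.n_quad)
    logw = np.log(w)
    x = np.array([fit.alpha, fit.delta, fit.sigma_u])
    free = [0, 2] if fit.constrained_null else [0, 1, 2]
    if fit.sigma_u <= 1e-8 and 2 in free:
        free = [i for i in free if i != 2]  # boundary: no curvature info
    hess = np.zeros((len(free), len(free)))
    for a, i in enumerate(free):
        for sgn in (+1, -1):
            xp = x.copy()
            xp[i] += sgn * h
            theta = xp[[0, 2]] if fit.constrained_null else xp
            _, g = _negloglik_grad(theta, fit._patterns, z, logw, fit.constrained_null)
            gfull = np.zeros(3)
            gfull[[0, 2] if fit.constrained_null else [0, 1, 2]] = g
            hess[a] += sgn * gfull[free] / (2 * h)
    try:
        cov_free = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov_free = np.linalg.pinv(hess)
    vcov = np.zeros((3, 3))
    for a, i in enumerate(free):
        for b, j in enumerate(free):
            vcov[i, j] = cov_free[a, b]
    return vcov


# --------------------------------------------------------------------------
# tests
# --------------------------------------------------------------------------


def wald_test(fit, alpha: float = 0.05) -> AnalysisResult:
    """z test of the treatment log-odds ratio delta from a model fit."""
    if isinstance(fit, MixedLogisticFit):
        if not fit.converged:
            raise FitError("cannot test a non-converged fit")
        if fit.constrained_null:
            raise ValueError("Wald test needs the unconstrained fit")
        scale = "logodds_cluster_specific"
        method = f"{fit.model}_wald"
    elif isinstance(fit, GEEFit):
        scale = "logodds_marginal"
        method = "lgee_wald"
    else:
        raise TypeError(f"unsupported fit type {type(fit)!r}")
    se = fit.se_delta
    stat = fit.delta / se
    p_lower = float(stats.norm.cdf(stat))
    crit = float(stats.norm.ppf(1 - alpha / 2))
    return AnalysisResult(
        method=method,
        scale=scale,
        estimate=float(fit.delta),
        se=se,
        statistic=float(stat),
        df=math.inf,
        p_two=float(2 * min(p_lower, 1 - p_lower)),
        p_lower=p_lower,
        p_upper=1 - p_lower,
        ci_low=float(fit.delta - crit * se),
        ci_high=float(fit.delta + crit * se),
    )


def lrt(
    fit_full: MixedLogisticFit, fit_null: MixedLogisticFit, alpha: float = 0.05
) -> AnalysisResult:
    """Likelihood-ratio test of delta = 0 on a chi-squared(1) reference.

    The two-sided p-value is attributed to a tail by the sign of the fitted
    delta (a rejection counts toward the direction of the estimate); an
    exactly zero delta is attributed to neither tail.
    """
    if fit_full.model != fit_null.model:
        raise ValueError("LRT fits must share the model")
    stat = 2.0 * (fit_full.loglik - fit_null.loglik)
    if stat < -1e-6:
        raise FitError(f"negative LR statistic {stat:.3e}: optimisation failure")
    stat = max(stat, 0.0)
    p_two = float(stats.chi2.sf(stat, 1))
    if fit_full.delta < 0:
        p_lower, p_upper = p_two / 2, 1 - p_two / 2
    elif fit_full.delta > 0:
        p_lower, p_upper = 1 - p_two / 2, p_two / 2
    else:
        p_lower = p_upper = 0.5
    se = fit_full.se_delta
    crit = float(stats.norm.ppf(1 - alpha / 2))
    return AnalysisResult(
        method=f"{fit_full.model}_lrt",
        scale="logodds_cluster_specific",
        estimate=float(fit_full.delta),
        se=se,
        statistic=float(stat),
        df=1.0,
        p_two=p_two,
        p_lower=float(p_lower),
        p_upper=float(p_upper),
        ci_low=float(fit_full.delta - crit * se),
        ci_high=float(fit_full.delta + crit * se),
    )


# --------------------------------------------------------------------------
# GEE
# --------------------------------------------------------------------------


def fit_lgee(data: PartiallyNestedData, working: str = "exchangeable") -> GEEFit:
    """Logistic GEE for the marginal treatment log-odds ratio.

    Working correlation 'independence' weights subjects equally;
    'exchangeable' applies minimum-variance weights with the common
    correlation estimated from clustered-arm residuals.  Inference uses the
    robust sandwich covariance (scale fixed at 1 for binary data).
    """
    _check_separation(data)
    if working == "independence":
        cov = sm.cov_struct.Independence()
    elif working == "exchangeable":
        cov = sm.cov_struct.Exchangeable()
    else:
        raise ValueError(f"unknown working correlation {working!r}")
    exog = np.column_stack(
        [np.ones(data.outcome.shape[0]), data.arm.astype(float)]
    )
    model = sm.GEE(
        data.outcome.astype(float),
        exog,
        groups=data.cluster_id,
        family=sm.families.Binomial(),
        cov_struct=cov,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=200, scale=1.0)
    corr = 0.0
    if working == "exchangeable":
        corr = float(np.atleast_1d(cov.dep_params)[0])
    return GEEFit(
        alpha=float(res.params[0]),
        delta=float(res.params[1]),
        robust_vcov=np.asarray(res.cov_params()),
        working=working,
        working_corr=corr,
        n_group=data.n_group,
        n_control=data.n_control,
    )


def fitted_manifest_quantities(
    fit: MixedLogisticFit,
) -> tuple[float, float, float]:
    """Back-transform a mixed fit to (pi_G, pi_C, manifest rho).

    pi_G integrates the clustered-arm linear predictor over the random
    effect; pi_C does the same for the LRI (whose controls share the random
    effect) and is expit(alpha) for the LRC.  rho is the manifest ICC of the
    clustered arm.
    """
    if not fit.converged:
        raise FitError("cannot back-transform a non-converged fit")
    pi_g = marginal_prob(fit.alpha + fit.delta, fit.sigma_u)
    if fit.model == "lri":
        pi_c = marginal_prob(fit.alpha, fit.sigma_u)
    else:
        pi_c = float(expit(fit.alpha))
    rho = (
        0.0
        if fit.sigma_u == 0
        else manifest_icc(fit.alpha + fit.delta, fit.sigma_u)
    )
    return pi_g, pi_c, rho
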