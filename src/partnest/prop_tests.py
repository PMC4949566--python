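"""Proportion-scale analyses for partially nested binary data.

Three related tests of the risk difference p_G - p_C:

* the summary-measures test (SMT): one proportion per cluster, compared with
  the individual control outcomes using an unequal-variance z statistic;
* the Satterthwaite test (SATT): the same statistic referred to a
  t-distribution with moment-matched degrees of freedom;
* the adjusted test of proportions (ATP): a two-sample test of proportions
  whose clustered-arm variance is inflated by a design effect D that depends
  on the cluster weighting (equal, size or minimum-variance weights).

The intra-cluster correlation entering D is estimated by one-way ANOVA on the
clustered arm.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np
from scipy import stats

from .datagen import PartiallyNestedData
from .results import AnalysisResult

__all__ = [
    "AnovaIcc",
    "summary_measures_test",
    "satterthwaite_test",
    "anova_icc",
    "design_effect",
    "adjusted_prop_test",
]

WEIGHTINGS = ("equal", "size", "minvar")


class DegenerateDataError(ValueError):
    """Raised when a test statistic is undefined for the data at hand."""


def _summaries(data: PartiallyNestedData):
    tab = data.cluster_table()
    m = tab["m"].to_numpy(dtype=float)
    r = tab["r"].to_numpy(dtype=float)
    q = tab["q"].to_numpy(dtype=float)
    n_c = data.n_control
    p_c = data.control_events / n_c
    return m, r, q, n_c, p_c


def _zt_result(
    method: str,
    estimate: float,
    se: float,
    df: float,
    alpha: float,
    se_null: float | None = None,
    icc: float | None = None,
    extra: dict | None = None,
) -> AnalysisResult:
    stat = estimate / (se_null if se_null is not None else se)
    if math.isinf(df):
        p_lower = float(stats.norm.cdf(stat))
        crit = float(stats.norm.ppf(1 - alpha / 2))
    else:
        p_lower = float(stats.t.cdf(stat, df))
        crit = float(stats.t.ppf(1 - alpha / 2, df))
    p_upper = 1.0 - p_lower
    return AnalysisResult(
        method=method,
        scale="risk_difference",
        estimate=float(estimate),
        se=float(se),
        se_null=None if se_null is None else float(se_null),
        statistic=float(stat),
        df=df,
        p_two=float(2 * min(p_lower, p_upper)),
        p_lower=p_lower,
        p_upper=p_upper,
        ci_low=float(estimate - crit * se),
        ci_high=float(estimate + crit * se),
        icc_estimate=icc,
        extra=extra or {},
    )


def _smt_parts(data: PartiallyNestedData):
    m, r, q, n_c, p_c = _summaries(data)
    k = m.size
    if k < 2:
        raise DegenerateDataError("summary-measures test needs >= 2 clusters")
    p_g = float(q.mean())  # equal cluster weights
    s_g2 = float(q.var(ddof=1))
    s_c2 = p_c * (1 - p_c) * n_c / (n_c - 1)  # moment (ddof=1) estimator
    if s_g2 == 0 and s_c2 == 0:
        raise DegenerateDataError("zero variance in both arms")
    se = math.sqrt(s_g2 / k + s_c2 / n_c)
    return p_g, p_c, s_g2, s_c2, k, n_c, se


def summary_measures_test(
    data: PartiallyNestedData, alpha: float = 0.05
) -> AnalysisResult:
    """Unequal-variance z test of cluster proportions vs control outcomes."""
    p_g, p_c, s_g2, s_c2, k, n_c, se = _smt_parts(data)
    return _zt_result("smt", p_g - p_c, se, math.inf, alpha)


def satterthwaite_test(
    data: PartiallyNestedData, alpha: float = 0.05
) -> AnalysisResult:
    """Summary-measures test on a t reference with Satterthwaite df."""
    p_g, p_c, s_g2, s_c2, k, n_c, se = _smt_parts(data)
    a, b = s_g2 / k, s_c2 / n_c
    nu = (a + b) ** 2 / (a**2 / (k - 1) + b**2 / (n_c - 1))
    return _zt_result("satt", p_g - p_c, se, float(nu), alpha)


class AnovaIcc(NamedTuple):
    estimate: float  # truncated below at 0
    raw: float
    degenerate: bool


def anova_icc(data: PartiallyNestedData) -> AnovaIcc:
    """One-way ANOVA estimator of the manifest ICC on the clustered arm.

    rho = (MSB - MSW) / (MSB + (m0 - 1) MSW) with
    m0 = (N - sum m_j^2 / N) / (k - 1).  Negative estimates are truncated to
    zero (the raw value is retained); completely degenerate data (all
    outcomes identical) return 0 with a flag.
    """
    m, r, q, _, _ = _summaries(data)
    k = m.size
    if k < 2:
        raise DegenerateDataError("ANOVA ICC needs >= 2 clusters")
    n = m.sum()
    events = r.sum()
    if events == 0 or events == n:
        return AnovaIcc(0.0, 0.0, True)
    ybar = events / n
    ssb = float((m * (q - ybar) ** 2).sum())
    # within-cluster sum of squares for 0/1 data: r_j (1 - q_j) + (m_j - r_j) q_j^2
    ssw = float((r * (1 - q) ** 2 + (m - r) * q**2).sum())
    msb = ssb / (k - 1)
    if n - k == 0:
        return AnovaIcc(1.0 if msb > 0 else 0.0, 1.0 if msb > 0 else 0.0, msb == 0)
    msw = ssw / (n - k)
    m0 = (n - (m**2).sum() / n) / (k - 1)
    denom = msb + (m0 - 1) * msw
    if denom == 0:
        return AnovaIcc(0.0, 0.0, True)
    raw = float((msb - msw) / denom)
    return AnovaIcc(max(raw, 0.0), raw, False)


def design_effect(
    cluster_sizes, rho: float, weighting: str = "size"
) -> float:
    """Variance inflation D of the clustered-arm proportion estimator.

    equal:  D = m_bar [rho + ((1-rho)/k) sum 1/m_j]
    size:   D = 1 + (sum m_j^2 / sum m_j - 1) rho
    minvar: D = N_G / sum[m_j / (1 + (m_j - 1) rho)]

    All reduce to 1 + (m-1) rho for equal cluster sizes.
    """
    m = np.asarray(list(cluster_sizes), dtype=float)
    if m.size == 0:
        raise ValueError("empty cluster-size list")
    if not 0 <= rho < 1:
        raise ValueError(f"rho must lie in [0,1), got {rho}")
    if weighting == "equal":
        k = m.size
        return float(m.mean() * (rho + (1 - rho) / k * (1.0 / m).sum()))
    if weighting == "size":
        return float(1 + ((m**2).sum() / m.sum() - 1) * rho)
    if weighting == "minvar":
        return float(m.sum() / (m / (1 + (m - 1) * rho)).sum())
    raise ValueError(f"unknown weighting {weighting!r}")


def adjusted_prop_test(
    data: PartiallyNestedData,
    weighting: str = "minvar",
    alpha: float = 0.05,
    rho_source: str = "anova",
    rho: float | None = None,
) -> AnalysisResult:
    """Two-sample test of proportions with a cluster design effect.

    The clustered-arm estimate is a weighted mean of cluster proportions; its
    variance is pi_G(1-pi_G) D / N_G with D from :func:`design_effect`.  The
    null standard error pools both arms (pooled p = total events / total
    subjects); the non-null SE (used for the CI) keeps arm-specific terms.
    """
    if weighting not in WEIGHTINGS:
        raise ValueError(f"unknown weighting {weighting!r}")
    m, r, q, n_c, p_c = _summaries(data)
    n_g = m.sum()
    if rho_source == "supplied":
        if rho is None:
            raise ValueError("rho_source='supplied' needs a rho value")
        rho_hat, icc_info = float(rho), None
    elif rho_source == "anova":
        icc_info = anova_icc(data)
        rho_hat = icc_info.estimate
    else:
        raise ValueError(f"unknown rho_source {rho_source!r}")

    if weighting == "equal":
        w = np.ones_like(m)
    elif weighting == "size":
        w = m
    else:
        w = m / (1 + (m - 1) * rho_hat)
    p_g = float((w * q).sum() / w.sum())
    d = design_effect(m, rho_hat, weighting)

    events = r.sum() + p_c * n_c
    pooled = events / (n_g + n_c)
    se_null = math.sqrt(pooled * (1 - pooled) * (d / n_g + 1 / n_c))
    se = math.sqrt(p_g * (1 - p_g) * d / n_g + p_c * (1 - p_c) / n_c)
    if se_null == 0:
        raise DegenerateDataError("all outcomes identical; test undefined")
    return _zt_result(
        f"atp_{weighting}",
        p_g - p_c,
        se,
        math.inf,
        alpha,
        se_null=se_null,
        icc=rho_hat,
        extra={"design_effect": d, "raw_icc": None if icc_info is None else icc_info.raw},
    )
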