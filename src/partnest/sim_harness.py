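"""Monte-Carlo engine for test-size, bias and power experiments.

A :class:`Scenario` bundles a population (pi_G, pi_C, rho), a trial design,
the analysis methods to run, a replication count and a seed.
:func:`run_scenario` simulates replicates (each on an independent random
stream keyed by ``(seed, replicate)``, so results do not depend on execution
order), runs every requested method, and aggregates empirical two-sided and
per-tail test size/power, estimate bias against each method's own estimand,
mean ICC estimates, normal-approximation Monte-Carlo confidence intervals and
failure counts.  Replicates where a method fails (non-convergence, or an
observed event rate of 0 or 1) are excluded from that method's denominator
and reported separately; ``count_failures_as_nonreject=True`` keeps them in
the denominator as non-rejections for sensitivity analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace as _dc_replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logit

from .datagen import PartiallyNestedData, TrialDesign, simulate_trial
from .latent_link import LatentScenario
from .logistic_models import (
    FitError,
    QuadratureSpec,
    fit_lgee,
    fit_lri,
    fit_lrc,
    fitted_manifest_quantities,
    lrt,
    wald_test,
)
from .power import PowerResult
from .prop_tests import (
    DegenerateDataError,
    adjusted_prop_test,
    satterthwaite_test,
    summary_measures_test,
)
from .results import AnalysisResult

__all__ = [
    "Scenario",
    "MethodSummary",
    "SimulationReport",
    "METHODS",
    "estimand_for",
    "run_scenario",
    "run_grid",
    "compare_power",
    "mc_ci",
]

_FAILURES = (FitError, DegenerateDataError)


@dataclass(frozen=True)
class Scenario:
    """One cell of a simulation grid."""

    pi_g: float
    pi_c: float
    rho: float
    design: TrialDesign
    methods: tuple[str, ...] = ("atp", "smt", "satt")
    n_reps: int = 2000
    alpha: float = 0.05
    seed: int = 0
    count_failures_as_nonreject: bool = False

    def __post_init__(self) -> None:
        if self.n_reps < 100:
            raise ValueError("use at least 100 replicates")
        unknown = [m for m in self.methods if m not in METHODS]
        if unknown:
            raise ValueError(f"unknown methods {unknown}; choose from {list(METHODS)}")

    def latent(self) -> LatentScenario:
        return LatentScenario.from_manifest(self.pi_g, self.pi_c, self.rho)

    @property
    def label(self) -> str:
        d = self.design
        return (
            f"piG={self.pi_g},piC={self.pi_c},rho={self.rho},"
            f"k={d.k},NG={d.n_group},NC={d.n_control}"
        )


# ---------------------------------------------------------------------------
# analysis-method registry
# ---------------------------------------------------------------------------


def _run_replicate(
    data: PartiallyNestedData,
    methods: Sequence[str],
    alpha: float,
    quad: QuadratureSpec | None,
) -> dict[str, AnalysisResult | Exception]:
    """All requested analyses on one dataset, sharing mixed-model fits."""
    out: dict[str, AnalysisResult | Exception] = {}
    lri_full = lri_null = None
    for name in methods:
        try:
            if name == "smt":
                out[name] = summary_measures_test(data, alpha)
            elif name == "satt":
                out[name] = satterthwaite_test(data, alpha)
            elif name == "atp":
                out[name] = adjusted_prop_test(data, alpha=alpha)
            elif name in ("lgee", "lgee_ind"):
                working = "exchangeable" if name == "lgee" else "independence"
                gee = fit_lgee(data, working)
                out[name] = _dc_replace(
                    wald_test(gee, alpha), icc_estimate=gee.working_corr
                )
            elif name in ("lri_wald", "lri_lrt"):
                if lri_full is None:
                    lri_full = fit_lri(data, quad)
                    _, _, lri_rho = fitted_manifest_quantities(lri_full)
                if name == "lri_wald":
                    out[name] = _dc_replace(
                        wald_test(lri_full, alpha), icc_estimate=lri_rho
                    )
                else:
                    if lri_null is None:
                        lri_null = fit_lri(data, quad, constrain_null=True)
                    out[name] = _dc_replace(
                        lrt(lri_full, lri_null, alpha), icc_estimate=lri_rho
                    )
            elif name == "lrc_wald":
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    out[name] = wald_test(fit_lrc(data, quad), alpha)
            else:  # pragma: no cover - guarded by Scenario validation
                raise ValueError(f"unknown method {name!r}")
        except _FAILURES as exc:
            out[name] = exc
    return out


METHODS: dict[str, str] = {
    "smt": "summary measures test",
    "satt": "Satterthwaite test",
    "atp": "adjusted test of proportions",
    "lgee": "logistic GEE (exchangeable, robust SE)",
    "lgee_ind": "logistic GEE (independence, robust SE)",
    "lri_wald": "logistic random intercept, Wald test",
    "lri_lrt": "logistic random intercept, likelihood ratio test",
    "lrc_wald": "logistic random coefficient, Wald test",
}


def estimand_for(method: str, scenario: LatentScenario) -> float:
    """The population quantity each method's estimate targets.

    Proportion-scale methods: pi_G - pi_C.  GEE: the marginal log-odds ratio
    log[odds(pi_G)/odds(pi_C)].  Mixed logistic models: the cluster-specific
    log-odds ratio eta_G - eta_C, where eta_C solves the marginal-probability
    equation at pi_C with the data-generating sigma_U.
    """
    if method in ("smt", "satt", "atp"):
        return scenario.pi_g - scenario.pi_c
    if method in ("lgee", "lgee_ind"):
        return scenario.marginal_logodds_ratio
    if method in ("lri_wald", "lri_lrt", "lrc_wald"):
        return scenario.cluster_specific_logodds_ratio
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


@dataclass
class MethodSummary:
    method: str
    estimand: float
    n_attempted: int
    n_failed: int
    n_used: int
    rate_two: float
    rate_lower: float
    rate_upper: float
    ci_two: tuple[float, float]
    ci_lower: tuple[float, float]
    ci_upper: tuple[float, float]
    mean_estimate: float
    bias: float
    bias_ci: tuple[float, float]
    mean_icc: float  # nan where the method reports no ICC

    def as_row(self) -> dict:
        return {
            "method": self.method,
            "estimand": self.estimand,
            "n_attempted": self.n_attempted,
            "n_failed": self.n_failed,
            "rate_two": self.rate_two,
            "rate_lower": self.rate_lower,
            "rate_upper": self.rate_upper,
            "ci_two_low": self.ci_two[0],
            "ci_two_high": self.ci_two[1],
            "mean_estimate": self.mean_estimate,
            "bias": self.bias,
            "bias_ci_low": self.bias_ci[0],
            "bias_ci_high": self.bias_ci[1],
            "mean_icc": self.mean_icc,
        }


@dataclass
class SimulationReport:
    scenario: Scenario
    summaries: dict[str, MethodSummary]

    def __getitem__(self, method: str) -> MethodSummary:
        return self.summaries[method]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.summaries.values():
            row = {"scenario": self.scenario.label, **s.as_row()}
            rows.append(row)
        return pd.DataFrame(rows)


def mc_ci(rate: float, n_effective: int) -> tuple[float, float]:
    """Normal-approximation 95% Monte-Carlo CI for an empirical rate."""
    if n_effective <= 0:
        raise ValueError("n_effective must be positive")
    if not 0 <= rate <= 1:
        raise ValueError("rate must lie in [0,1]")
    if rate in (0.0, 1.0):
        return (rate, rate)  # degenerate: binomial variance collapses
    half = 1.96 * math.sqrt(rate * (1 - rate) / n_effective)
    return (rate - half, rate + half)


def run_scenario(
    scenario: Scenario, quad: QuadratureSpec | None = None
) -> SimulationReport:
    """Simulate and analyse ``n_reps`` trials; aggregate per method."""
    latent = scenario.latent()
    alpha = scenario.alpha
    acc: dict[str, dict] = {
        m: {"est": [], "icc": [], "two": 0, "lo": 0, "up": 0, "fail": 0}
        for m in scenario.methods
    }
    for rep in range(scenario.n_reps):
        rng = np.random.default_rng([scenario.seed, rep])
        data = simulate_trial(latent, scenario.design, rng)
        results = _run_replicate(data, scenario.methods, alpha, quad)
        for m, res in results.items():
            a = acc[m]
            if isinstance(res, Exception):
                a["fail"] += 1
                continue
            a["est"].append(res.estimate)
            a["icc"].append(
                np.nan if res.icc_estimate is None else res.icc_estimate
            )
            a["two"] += res.rejects(alpha, "two")
            a["lo"] += res.rejects(alpha, "lower")
            a["up"] += res.rejects(alpha, "upper")

    summaries = {}
    for m in scenario.methods:
        a = acc[m]
        n_attempted = scenario.n_reps
        n_ok = len(a["est"])
        denom = n_attempted if scenario.count_failures_as_nonreject else n_ok
        if denom == 0:
            raise RuntimeError(f"every replicate failed for method {m!r}")
        est = np.asarray(a["est"])
        estimand = estimand_for(m, latent)
        bias = float(est.mean() - estimand)
        half = 1.96 * est.std(ddof=1) / math.sqrt(n_ok) if n_ok > 1 else math.nan
        rt, rl, ru = a["two"] / denom, a["lo"] / denom, a["up"] / denom
        summaries[m] = MethodSummary(
            method=m,
            estimand=estimand,
            n_attempted=n_attempted,
            n_failed=a["fail"],
            n_used=denom,
            rate_two=rt,
            rate_lower=rl,
            rate_upper=ru,
            ci_two=mc_ci(rt, denom),
            ci_lower=mc_ci(rl, denom),
            ci_upper=mc_ci(ru, denom),
            mean_estimate=float(est.mean()),
            bias=bias,
            bias_ci=(bias - half, bias + half),
            mean_icc=(
                float(np.nanmean(icc_arr))
                if n_ok and not np.isnan(icc_arr := np.asarray(a["icc"])).all()
                else math.nan
            ),
        )
    return SimulationReport(scenario=scenario, summaries=summaries)


def run_grid(
    scenarios: Iterable[Scenario], quad: QuadratureSpec | None = None
) -> pd.DataFrame:
    """Run several scenarios and stack the long-format summaries."""
    frames = [run_scenario(s, quad).to_frame() for s in scenarios]
    return pd.concat(frames, ignore_index=True)


def compare_power(
    report: SimulationReport, calculated: Sequence[PowerResult]
) -> pd.DataFrame:
    """Empirical minus calculated power, in percentage points.

    One row per (analysis method, calculation method).  The calculated
    results must refer to the same design (sizes are checked).
    """
    design = report.scenario.design
    rows = []
    for calc in calculated:
        if (
            round(calc.n_control) != design.n_control
            or round(calc.n_group) != design.n_group
        ):
            raise ValueError(
                f"calculated sizes (NC={calc.n_control}, NG={calc.n_group}) do not "
                f"match the simulated design (NC={design.n_control}, "
                f"NG={design.n_group})"
            )
        for m, s in report.summaries.items():
            rows.append(
                {
                    "analysis": m,
                    "calculation": calc.method,
                    "empirical_pct": 100 * s.rate_two,
                    "calculated_pct": 100 * calc.power,
                    "diff_pp": 100 * (s.rate_two - calc.power),
                }
            )
    return pd.DataFrame(rows)
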