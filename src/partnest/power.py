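"""Power and sample size for partially nested binary designs.

Normal-approximation power on three scales — the difference of proportions
(PROP), the log-odds ratio (LOG-ODDS) and the double-arcsine-root transform
(ARC-SINE) — each with the clustered arm's variance inflated by the design
effect DE = 1 + (m-1) rho, plus Satterthwaite small-k variants on a
noncentral-t reference, allocation-ratio optimisation, and a cluster-size-CV
adjustment to the design effect.

Sample-size formulas return whole subjects and whole clusters: N_C is
rounded up, the number of clusters k = ceil(lambda N_C / m), N_G = k m, and
the achieved power is recomputed at the rounded sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from scipy.special import logit

__all__ = [
    "PowerRequest",
    "PowerResult",
    "design_effect_cv",
    "power_prop",
    "n_prop",
    "power_logodds",
    "n_logodds",
    "power_arcsine",
    "n_arcsine",
    "power_satt",
    "lambda_eq",
    "lambda_max",
    "power_given_total",
]

_SCALES = ("prop", "logodds", "arcsine")


@dataclass(frozen=True)
class PowerRequest:
    """Design parameters for a power or sample-size calculation.

    Exactly one of ``n_control`` (power mode) or ``target_power``
    (sample-size mode) must be set.  ``lam`` is the allocation ratio
    lambda = N_G / N_C; ``cv_m`` the coefficient of variation of cluster
    size (0 for equal clusters).
    """

    pi_g: float
    pi_c: float
    m: int
    rho: float
    alpha: float = 0.05
    lam: float = 1.0
    n_control: int | None = None
    target_power: float | None = None
    cv_m: float = 0.0

    def __post_init__(self) -> None:
        for name, p in (("pi_g", self.pi_g), ("pi_c", self.pi_c)):
            if not 0 < p < 1:
                raise ValueError(f"{name} must lie in (0,1), got {p}")
        if not 0 <= self.rho < 1:
            raise ValueError(f"rho must lie in [0,1), got {self.rho}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0,1), got {self.alpha}")
        if self.m < 1:
            raise ValueError("cluster size m must be >= 1")
        if self.lam <= 0:
            raise ValueError("allocation ratio must be positive")
        if self.cv_m < 0:
            raise ValueError("cv_m must be >= 0")
        if (self.n_control is None) == (self.target_power is None):
            raise ValueError("set exactly one of n_control / target_power")
        if self.target_power is not None:
            if self.target_power <= self.alpha:
                raise ValueError("target power must exceed alpha")
            if self.pi_g == self.pi_c:
                raise ValueError("sample-size mode needs pi_g != pi_c")

    @property
    def de(self) -> float:
        return design_effect_cv(self.m, self.rho, self.cv_m)


@dataclass(frozen=True)
class PowerResult:
    method: str
    power: float
    n_control: int | float
    n_group: int | float
    k: int | float
    design_effect: float
    df: float | None = None


def design_effect_cv(m: int, rho: float, cv_m: float = 0.0) -> float:
    """Design effect with a cluster-size coefficient-of-variation inflation.

    DE = 1 + ((1 + cv^2) m - 1) rho; cv = 0 recovers 1 + (m-1) rho.  A
    cluster-size *variance* sigma_m^2 converts via cv = sigma_m / m.
    """
    if cv_m < 0:
        raise ValueError("cv_m must be >= 0")
    return 1.0 + ((1.0 + cv_m**2) * m - 1.0) * rho


def _effects(req: PowerRequest, scale: str) -> tuple[float, float, float]:
    """(effect, clustered-arm unit variance, control unit variance)."""
    if scale == "prop":
        eff = req.pi_g - req.pi_c
        vg = req.pi_g * (1 - req.pi_g)
        vc = req.pi_c * (1 - req.pi_c)
    elif scale == "logodds":
        eff = float(logit(req.pi_g) - logit(req.pi_c))
        vg = 1.0 / (req.pi_g * (1 - req.pi_g))
        vc = 1.0 / (req.pi_c * (1 - req.pi_c))
    elif scale == "arcsine":
        eff = 2 * math.asin(math.sqrt(req.pi_g)) - 2 * math.asin(math.sqrt(req.pi_c))
        vg = 1.0
        vc = 1.0
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return eff, vg, vc


def _normal_power(
    req: PowerRequest, scale: str, n_control: float, n_group: float, two_term: bool
) -> float:
    eff, vg, vc = _effects(req, scale)
    se = math.sqrt(vc / n_control + vg * req.de / n_group)
    zcrit = stats.norm.ppf(1 - req.alpha / 2)
    shift = abs(eff) / se
    power = float(stats.norm.sf(zcrit - shift))
    if two_term:
        power += float(stats.norm.cdf(-zcrit - shift))
    return power


def _power_mode(req: PowerRequest, scale: str, method: str, two_term: bool) -> PowerResult:
    n_c = req.n_control
    n_g = req.lam * n_c
    k = n_g / req.m
    return PowerResult(
        method=method,
        power=_normal_power(req, scale, n_c, n_g, two_term),
        n_control=n_c,
        n_group=n_g,
        k=k,
        design_effect=req.de,
    )


def _size_mode(req: PowerRequest, scale: str, method: str, two_term: bool) -> PowerResult:
    eff, vg, vc = _effects(req, scale)
    za = stats.norm.ppf(1 - req.alpha / 2)
    zb = stats.norm.ppf(req.target_power)
    n_c_raw = (za + zb) ** 2 / eff**2 * (vc + vg * req.de / req.lam)
    n_c = math.ceil(n_c_raw - 1e-9)
    k = math.ceil(req.lam * n_c / req.m - 1e-9)
    n_g = k * req.m
    return PowerResult(
        method=method,
        power=_normal_power(req, scale, n_c, n_g, two_term),
        n_control=n_c,
        n_group=n_g,
        k=k,
        design_effect=req.de,
    )


def power_prop(req: PowerRequest, two_term: bool = False) -> PowerResult:
    """Power on the difference-of-proportions scale (PROP)."""
    return _power_mode(req, "prop", "prop", two_term)


def n_prop(req: PowerRequest, two_term: bool = False) -> PowerResult:
    """Sample size on the difference-of-proportions scale (PROP)."""
    return _size_mode(req, "prop", "prop", two_term)


def power_logodds(req: PowerRequest, two_term: bool = False) -> PowerResult:
    """Power on the log-odds-ratio scale (LOG-ODDS)."""
    return _power_mode(req, "logodds", "logodds", two_term)


def n_logodds(req: PowerRequest, two_term: bool = False) -> PowerResult:
    return _size_mode(req, "logodds", "logodds", two_term)


def power_arcsine(req: PowerRequest, two_term: bool = False) -> PowerResult:
    """Power on the 2 arcsin(sqrt pi) scale (ARC-SINE); no pi(1-pi) term."""
    return _power_mode(req, "arcsine", "arcsine", two_term)


def n_arcsine(req: PowerRequest, two_term: bool = False) -> PowerResult:
    return _size_mode(req, "arcsine", "arcsine", two_term)


def power_satt(req: PowerRequest, scale: str = "prop") -> PowerResult:
    """Satterthwaite power at population-variance degrees of freedom.

    The clustered arm contributes k cluster summaries with variance
    pi_G(1-pi_G) DE / m (prop scale) or DE / m (arcsine scale); the control
    arm contributes N_C subjects.  Power is the rejection probability of a
    noncentral-t variate at the two-sided critical value of a central t with
    the Satterthwaite df computed from these population variances.
    """
    if scale not in ("prop", "arcsine"):
        raise ValueError("Satterthwaite power supports scales 'prop' and 'arcsine'")
    if req.n_control is None:
        raise ValueError("power_satt operates in power mode (needs n_control)")
    n_c = req.n_control
    n_g = req.lam * n_c
    k = n_g / req.m
    if k < 2:
        raise ValueError("need at least 2 clusters for a Satterthwaite test")
    eff, vg, vc = _effects(req, scale)
    v1 = vg * req.de / req.m  # variance of one cluster summary
    a, b = v1 / k, vc / n_c
    df = (a + b) ** 2 / (a**2 / (k - 1) + b**2 / (n_c - 1))
    se = math.sqrt(a + b)
    ncp = abs(eff) / se
    tcrit = stats.t.ppf(1 - req.alpha / 2, df)
    power = float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))
    return PowerResult(
        method=f"satt_{scale}",
        power=power,
        n_control=n_c,
        n_group=n_g,
        k=k,
        design_effect=req.de,
        df=float(df),
    )


def lambda_eq(method: str, req: PowerRequest) -> float:
    """Allocation ratio giving the same power as 1:1 at fixed total size."""
    de = req.de
    vg = req.pi_g * (1 - req.pi_g)
    vc = req.pi_c * (1 - req.pi_c)
    if method == "prop":
        return vg / vc * de
    if method == "logodds":
        return vc / vg * de
    if method == "arcsine":
        return de
    raise ValueError(f"unknown method {method!r}")


def lambda_max(method: str, req: PowerRequest) -> float:
    """Allocation ratio maximising power at fixed total size: sqrt(lambda_eq)."""
    return math.sqrt(lambda_eq(method, req))


def power_given_total(
    method: str, req: PowerRequest, lam: float, total_n: float
) -> float:
    """Normal-approximation power at total size N_C + N_G = total_n, N_G = lam N_C.

    Continuous sizes (no rounding); used to study the allocation ratio.
    """
    if method not in _SCALES:
        raise ValueError(f"unknown method {method!r}")
    n_c = total_n / (1 + lam)
    n_g = lam * n_c
    return _normal_power(req, method, n_c, n_g, two_term=False)
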