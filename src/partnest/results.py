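"""Common result container for all hypothesis tests."""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field

__all__ = ["AnalysisResult"]

SCALES = ("risk_difference", "logodds_marginal", "logodds_cluster_specific")


@dataclass(frozen=True)
class AnalysisResult:
    """Estimate, standard error and two-sided plus per-tail inference.

    ``p_lower`` is the p-value against the alternative "effect < 0"
    (the cdf of the statistic for z/t references), ``p_upper`` against
    "effect > 0"; for symmetric references they sum to 1 and
    ``p_two = 2 min(p_lower, p_upper)``.
    """

    method: str
    scale: str
    estimate: float
    se: float
    statistic: float
    df: float  # math.inf for a normal reference
    p_two: float
    p_lower: float
    p_upper: float
    ci_low: float
    ci_high: float
    se_null: float | None = None
    icc_estimate: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown effect scale {self.scale!r}")

    def rejects(self, alpha: float, tail: str = "two") -> bool:
        """Rejection at level ``alpha`` (per-tail tests use level alpha/2)."""
        if tail == "two":
            return self.p_two <= alpha
        if tail == "lower":
            return self.p_lower <= alpha / 2
        if tail == "upper":
            return self.p_upper <= alpha / 2
        raise ValueError(f"unknown tail {tail!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        if math.isinf(d["df"]):
            d["df"] = None
        return d
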