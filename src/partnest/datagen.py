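"""Seeded generation and CSV I/O of partially nested binary trial data.

The clustered (group-therapy) arm has ``k`` clusters; each cluster draws a
latent log-odds ``eta_j ~ N(eta_G, sigma_U^2)`` once and its members are
Bernoulli(expit(eta_j)).  Control-arm subjects are independent
Bernoulli(pi_C) and carry unique singleton cluster ids so that every analysis
method can consume the same table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .latent_link import LatentScenario

__all__ = [
    "TrialDesign",
    "PartiallyNestedData",
    "DataFormatError",
    "simulate_trial",
    "write_data",
    "read_data",
]

COLUMNS = ("outcome", "arm", "cluster_id")


class DataFormatError(ValueError):
    """Raised for malformed trial-data tables."""


@dataclass(frozen=True)
class TrialDesign:
    """Cluster sizes of the nested arm and the number of independent controls."""

    cluster_sizes: tuple[int, ...]
    n_control: int

    def __post_init__(self) -> None:
        sizes = tuple(int(m) for m in self.cluster_sizes)
        object.__setattr__(self, "cluster_sizes", sizes)
        if len(sizes) < 2:
            raise ValueError("need at least 2 clusters in the nested arm")
        if any(m < 1 for m in sizes):
            raise ValueError("cluster sizes must be positive")
        if self.n_control < 1:
            raise ValueError("n_control must be positive")

    @classmethod
    def equal(cls, k: int, m: int, n_control: int) -> "TrialDesign":
        return cls(cluster_sizes=(m,) * k, n_control=n_control)

    @property
    def k(self) -> int:
        return len(self.cluster_sizes)

    @property
    def n_group(self) -> int:
        return int(sum(self.cluster_sizes))

    @property
    def allocation_ratio(self) -> float:
        """lambda = N_G / N_C."""
        return self.n_group / self.n_control


@dataclass
class PartiallyNestedData:
    """Subject-level outcomes with arm and cluster labels.

    ``arm`` is 1 for the clustered arm, 0 for control; every control subject
    has a distinct singleton ``cluster_id``.
    """

    outcome: np.ndarray
    arm: np.ndarray
    cluster_id: np.ndarray

    def __post_init__(self) -> None:
        self.outcome = np.asarray(self.outcome, dtype=np.int64)
        self.arm = np.asarray(self.arm, dtype=np.int64)
        self.cluster_id = np.asarray(self.cluster_id, dtype=object)
        self.validate()

    def validate(self) -> None:
        n = self.outcome.shape[0]
        if n == 0:
            raise DataFormatError("dataset is empty")
        if self.arm.shape[0] != n or self.cluster_id.shape[0] != n:
            raise DataFormatError("outcome, arm and cluster_id lengths differ")
        bad = np.flatnonzero(~np.isin(self.outcome, (0, 1)))
        if bad.size:
            raise DataFormatError(f"non-binary outcome at row {bad[0]}")
        bad = np.flatnonzero(~np.isin(self.arm, (0, 1)))
        if bad.size:
            raise DataFormatError(f"arm indicator not 0/1 at row {bad[0]}")
        ctrl = self.cluster_id[self.arm == 0]
        if len(set(ctrl)) != ctrl.shape[0]:
            raise DataFormatError("control cluster_ids must be unique singletons")
        grp = set(self.cluster_id[self.arm == 1])
        if grp & set(ctrl):
            raise DataFormatError("a cluster_id appears in both arms")
        if self.arm.sum() and len(grp) < 1:
            raise DataFormatError("clustered-arm subject without cluster_id")

    # -- convenient views -------------------------------------------------
    @property
    def n_group(self) -> int:
        return int(self.arm.sum())

    @property
    def n_control(self) -> int:
        return int((self.arm == 0).sum())

    def cluster_table(self) -> pd.DataFrame:
        """Per-cluster size, event count and proportion for the clustered arm."""
        mask = self.arm == 1
        df = pd.DataFrame(
            {"cluster_id": self.cluster_id[mask], "outcome": self.outcome[mask]}
        )
        tab = df.groupby("cluster_id", sort=True)["outcome"].agg(["size", "sum"])
        tab.columns = ["m", "r"]
        tab["q"] = tab["r"] / tab["m"]
        return tab.reset_index()

    @property
    def control_events(self) -> int:
        return int(self.outcome[self.arm == 0].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "outcome": self.outcome,
                "arm": self.arm,
                "cluster_id": self.cluster_id,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PartiallyNestedData":
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise DataFormatError(f"missing columns: {missing}")
        for col in ("outcome", "arm"):
            vals = df[col]
            if vals.isna().any():
                raise DataFormatError(
                    f"missing {col} at row {int(vals.isna().idxmax())}"
                )
        return cls(
            outcome=df["outcome"].to_numpy(),
            arm=df["arm"].to_numpy(),
            cluster_id=df["cluster_id"].astype(str).to_numpy(dtype=object),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PartiallyNestedData):
            return NotImplemented
        return (
            np.array_equal(self.outcome, other.outcome)
            and np.array_equal(self.arm, other.arm)
            and np.array_equal(self.cluster_id, other.cluster_id)
        )


def simulate_trial(
    scenario: LatentScenario,
    design: TrialDesign,
    seed: int | np.random.Generator,
) -> PartiallyNestedData:
    """One partially nested trial under the logistic-normal model.

    Clustered arm: one latent draw per cluster, then Bernoulli outcomes at the
    cluster-specific probability.  Control arm: iid Bernoulli(pi_C).
    Identical seeds give identical datasets.
    """
    if not np.isfinite(scenario.eta_g) or scenario.sigma_u < 0:
        raise ValueError("scenario latent parameters are not populated")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    sizes = np.asarray(design.cluster_sizes)
    eta_j = rng.normal(scenario.eta_g, scenario.sigma_u, size=design.k)
    p_j = expit(eta_j)
    grp_out = (rng.random(design.n_group) < np.repeat(p_j, sizes)).astype(np.int64)
    ctl_out = (rng.random(design.n_control) < scenario.pi_c).astype(np.int64)

    grp_ids = np.repeat(
        np.array([f"g{j + 1:04d}" for j in range(design.k)], dtype=object), sizes
    )
    ctl_ids = np.array(
        [f"c{i + 1:06d}" for i in range(design.n_control)], dtype=object
    )
    return PartiallyNestedData(
        outcome=np.concatenate([grp_out, ctl_out]),
        arm=np.concatenate(
            [np.ones(design.n_group, np.int64), np.zeros(design.n_control, np.int64)]
        ),
        cluster_id=np.concatenate([grp_ids, ctl_ids]),
    )


def write_data(data: PartiallyNestedData, path: str | Path) -> None:
    data.to_frame().to_csv(path, index=False)


def read_data(path: str | Path) -> PartiallyNestedData:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"cluster_id": str})
    except pd.errors.EmptyDataError as exc:
        raise DataFormatError(f"{path} is empty") from exc
    if df.empty:
        raise DataFormatError(f"{path} has a header but no rows")
    return PartiallyNestedData.from_frame(df)
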