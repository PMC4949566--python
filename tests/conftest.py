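import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from partnest.datagen import PartiallyNestedData

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_data(cluster_events, cluster_sizes, control_events, n_control):
    """Build a dataset with prescribed per-cluster and control event counts."""
    out, arm, cid = [], [], []
    for j, (r, m) in enumerate(zip(cluster_events, cluster_sizes)):
        out.extend([1] * r + [0] * (m - r))
        arm.extend([1] * m)
        cid.extend([f"g{j}"] * m)
    out.extend([1] * control_events + [0] * (n_control - control_events))
    arm.extend([0] * n_control)
    cid.extend([f"c{i}" for i in range(n_control)])
    return PartiallyNestedData(
        outcome=np.array(out), arm=np.array(arm), cluster_id=np.array(cid, object)
    )


@pytest.fixture(scope="session")
def worked_data():
    """Three clusters of 5 with proportions (0.2, 0.4, 0.6); 2 of 10 controls."""
    return make_data([1, 2, 3], [5, 5, 5], 2, 10)


@pytest.fixture(scope="session")
def tiny_clustered():
    """2 clusters of 2 and 4 controls, mixed outcomes (for likelihood oracles)."""
    return make_data([1, 2], [2, 2], 1, 4)


@pytest.fixture(scope="session")
def normal_draws():
    """Large standard-normal sample for Monte-Carlo integration oracles."""
    return np.random.default_rng(20150612).standard_normal(10_000_000)
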