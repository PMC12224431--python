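import numpy as np
import pandas as pd
import pytest

from brainentropy import SyntheticCohortConfig, build_entropy_table, simulate_cohort


def ar1(phi: float, n: int, rng: np.random.Generator, burn: int = 200) -> np.ndarray:
    """Stationary AR(1) series with unit innovation variance."""
    eps = rng.standard_normal(n + burn)
    x = np.empty(n + burn)
    x[0] = eps[0]
    for t in range(1, n + burn):
        x[t] = phi * x[t - 1] + eps[t]
    return x[burn:]


def entropy_table_from_values(values: dict[tuple[str, str, str], dict[int, float]]) -> pd.DataFrame:
    """Hand-built long-form entropy table: {(subject, condition, session): {node: value}}."""
    rows = []
    for (sid, cond, sess), nodes in values.items():
        for nid, val in nodes.items():
            rows.append(dict(subject_id=sid, condition=cond, session=sess,
                             node_id=nid, sampen=val, valid=np.isfinite(val), note=None))
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_cohort():
    """Small effect cohort shared by simulation/stats/network tests."""
    config = SyntheticCohortConfig(
        n_subjects=8, n_nodes=10, n_timepoints=200,
        effect_nodes=(1, 2, 3), seed=7,
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def small_entropy_table(small_cohort):
    return build_entropy_table(small_cohort.matrices)
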