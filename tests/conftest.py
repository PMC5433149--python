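import numpy as np
import pandas as pd
import pytest

from osteomir.containers import ExpressionMatrix, SurvivalTable
from osteomir import synthdata as sd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort():
    """60-sample cohort with a 10-feature signal block (fast, reused)."""
    cfg = sd.CohortConfig(n_samples=60, n_features=80, n_cluster_features=10, seed=7)
    return sd.generate_cohort(cfg)


@pytest.fixture
def expr_matrix(rng):
    vals = rng.normal(size=(12, 8))
    return ExpressionMatrix(
        pd.DataFrame(
            vals,
            index=[f"f{i}" for i in range(12)],
            columns=[f"s{j}" for j in range(8)],
        )
    )


def make_survival(time, event, prefix="s"):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    return SurvivalTable(
        pd.DataFrame(
            {"time": time, "event": event},
            index=[f"{prefix}{i}" for i in range(len(time))],
        )
    )


@pytest.fixture
def make_surv():
    return make_survival
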