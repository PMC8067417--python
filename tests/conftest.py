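import numpy as np
import pandas as pd
import pytest

from fidlmm import ModelSpec, SyntheticConfig, build_design, simulate_dataset
from fidlmm.model_core import DesignRealization, Theta

MODEL1_TERMS = (
    "tertile",
    "sbp_baseline",
    "cognition",
    "physical_challenges_w1",
    "cognition:tertile",
    "physical_challenges_w1:tertile",
)

MODEL4_TERMS = (
    "tertile",
    "sbp_baseline",
    "cognition",
    "physical_challenges_w1",
    "physical_challenges_w2",
    "cognition:tertile",
    "physical_challenges_w2:tertile",
    "cognition:physical_challenges_w2",
    "cognition:physical_challenges_w2:tertile",
)


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig(seed=2024)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    return simulate_dataset(default_config)


@pytest.fixture(scope="session")
def default_design(default_config, default_dataset):
    table, _ = default_dataset
    return build_design(table, default_config.model_spec())


def random_instance(rng: np.random.Generator, n_groups: int = 3, p: int = 2,
                    max_group: int = 8):
    """A small random design + random interior Theta for oracle checks."""
    sizes = rng.integers(1, max_group + 1, size=n_groups)
    n = int(sizes.sum())
    while n <= p + 2:
        sizes = rng.integers(2, max_group + 1, size=n_groups)
        n = int(sizes.sum())
    group_index = np.repeat(np.arange(n_groups), sizes)
    X = np.column_stack([np.ones(n)] + [rng.standard_normal(n) for _ in range(p - 1)])
    y = rng.standard_normal(n) * 2.0
    theta = Theta(
        beta=rng.standard_normal(p),
        var_subject=float(rng.uniform(0.0, 3.0)),
        var_resid=float(rng.uniform(0.2, 3.0)),
    )
    design = DesignRealization(y=y, X=X, group_index=group_index,
                               column_names=[f"c{i}" for i in range(p)])
    return design, theta


@pytest.fixture
def toy_two_subject_table():
    """4 rows, 2 subjects, hand-checkable covariates."""
    return pd.DataFrame({
        "subject_id": ["a", "a", "b", "b"],
        "tertile": [1, 2, 1, 2],
        "a": [1.0, 2.0, 3.0, 4.0],
        "b": [1.0, 0.0, 1.0, 0.0],
        "y": [0.5, 1.0, 1.5, 2.0],
    })
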