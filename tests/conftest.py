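import numpy as np
import pandas as pd
import pytest

from arnfkb.containers import ExpressionMatrix
from arnfkb.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort shared across read-only tests."""
    return generate_cohort(SimulationConfig(seed=11))


@pytest.fixture()
def small_matrix():
    """20 genes x 10 samples (7 tumors, 3 normals) of plain Gaussian noise."""
    rng = np.random.default_rng(5)
    genes = [f"G{i:03d}" for i in range(20)]
    samples = [f"T{i}" for i in range(7)] + [f"N{i}" for i in range(3)]
    values = pd.DataFrame(rng.normal(7, 1, (20, 10)), index=genes, columns=samples)
    roles = pd.Series(["tumor"] * 7 + ["normal"] * 3, index=samples)
    return ExpressionMatrix(values, roles)


def make_matrix(values, roles=None):
    values = pd.DataFrame(values)
    if roles is None:
        roles = pd.Series("tumor", index=values.columns)
    return ExpressionMatrix(values, pd.Series(roles, index=values.columns))
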