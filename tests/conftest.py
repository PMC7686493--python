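import numpy as np
import pandas as pd
import pytest

import bloodmir as bm


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort reused by read-only tests."""
    return bm.simulate_cohort(n_samples=300, n_mirnas=200, seed=11)


@pytest.fixture(scope="session")
def recovery_cohort():
    """The planted-recovery cohort: 500 samples, 1000 miRNAs."""
    return bm.simulate_cohort(n_samples=500, n_mirnas=1000, seed=5)


@pytest.fixture(scope="session")
def recovery_records(recovery_cohort):
    expr, meta, _ = recovery_cohort
    records = bm.associate(expr, meta)
    return bm.compute_dc(expr, meta, records)


@pytest.fixture()
def tiny_matrix():
    values = pd.DataFrame(
        [[1.5, 2.0], [0.0, -1.25], [3.0, 4.5]],
        index=pd.Index(["mir-a", "mir-b", "mir-c"], name="feature_id"),
        columns=["s1", "s2"],
    )
    return bm.ExpressionMatrix(values)
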