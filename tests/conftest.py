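import numpy as np
import pytest

import chemosig as cs


@pytest.fixture
def tiny_expr():
    """3 genes x 4 samples of raw counts."""
    vals = np.array([[10.0, 20, 30, 40],
                     [5, 5, 5, 5],
                     [100, 50, 25, 12]])
    return cs.ExpressionMatrix(["G1", "G2", "G3"], ["S1", "S2", "S3", "S4"], vals)


@pytest.fixture
def labeled_cohort():
    """Deterministic 120-patient cohort with one strong and one null gene."""
    rng = np.random.default_rng(11)
    n = 120
    z = rng.standard_normal((3, n))
    eta = 1.5 * z[0]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    expr = cs.ExpressionMatrix(
        ["STRONG", "NULL1", "NULL2"], [f"P{i}" for i in range(n)],
        z, "external_normalized")
    return cs.LabeledCohort(expr, y)
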