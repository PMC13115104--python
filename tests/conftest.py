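import numpy as np
import pytest

import dwfuse as dw


@pytest.fixture(scope="session")
def small_cohort():
    """Compact synthetic cohort (140 patients, full 70-feature panel)."""
    cfg = dw.SyntheticCohortConfig(n_resistant=40, n_sensitive=100, seed=3)
    return dw.generate(cfg)


@pytest.fixture(scope="session")
def tiny_matrix():
    """200 x 20 matrix with a mild class signal, for leakage probes."""
    rng = np.random.default_rng(42)
    n, p = 200, 20
    y = np.zeros(n, dtype=int)
    y[:60] = 1
    X = rng.normal(size=(n, p))
    X[y == 1, :4] += 0.5
    # sprinkle a few missing cells so the imputer has work to do
    holes = rng.random((n, p)) < 0.02
    X[holes] = np.nan
    ids = np.array([f"T{i:03d}" for i in range(n)])
    names = [f"f{j:02d}" for j in range(p)]
    return dw.CohortTable(ids, X, names, y)
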