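import numpy as np
import pandas as pd
import pytest

import pairrank as pr


@pytest.fixture(scope="session")
def bundled_signature():
    return pr.load_bundled_signature()


@pytest.fixture(scope="session")
def cohort():
    """One synthetic cohort with strong planted pair effects (shared, read-only)."""
    spec = pr.CohortSpec(n_samples=300, n_genes=15, n_informative_pairs=5,
                         censoring_rate=0.3, seed=11)
    expr, surv, truth = pr.simulate_cohort(spec)
    return expr, surv, truth


@pytest.fixture()
def small_expr():
    rng = np.random.default_rng(42)
    values = rng.uniform(1, 10, size=(6, 8))
    return pd.DataFrame(
        values,
        index=[f"GENE{i}" for i in range(6)],
        columns=[f"s{j}" for j in range(8)],
    )
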