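import numpy as np
import pandas as pd
import pytest

import vaxresp as v


@pytest.fixture(scope="session")
def small_cohort():
    """40-subject, 60-gene cohort with the default planted structure."""
    return v.generate_cohort(v.SimConfig(n_subjects=40, n_genes=60, seed=11))


@pytest.fixture(scope="session")
def normalized(small_cohort):
    return v.normalize(small_cohort.expression)


@pytest.fixture(scope="session")
def labels(small_cohort):
    return v.classify_response(small_cohort.samples)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def two_group_matrix():
    """200 heteroscedastic null genes, 6 + 6 samples, fixed seed."""
    g = np.random.default_rng(7)
    G, n = 200, 12
    sds = g.uniform(0.5, 2.0, G)
    Y = pd.DataFrame(
        g.normal(0, 1, (G, n)) * sds[:, None] + 5,
        index=[f"g{i}" for i in range(G)],
        columns=[f"s{j}" for j in range(n)],
    )
    design = pd.DataFrame(
        {"intercept": 1.0, "group": np.r_[np.zeros(6), np.ones(6)]},
        index=Y.columns,
    )
    return Y, design
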