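import numpy as np
import pandas as pd
import pytest

from dtameta import chga_colon_tables, generate_paperlike_set, study_indices


@pytest.fixture(scope="session")
def chga_tables():
    """The five published CHGA colon-cancer 2x2 tables."""
    return chga_colon_tables()


@pytest.fixture(scope="session")
def chga_indices(chga_tables):
    return [study_indices(t) for t in chga_tables]


@pytest.fixture(scope="session")
def paperlike_set():
    """One deterministic five-cohort synthetic study set."""
    return generate_paperlike_set(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def toy_matrix():
    """5-gene x 6-sample matrix with known correlation structure."""
    rng = np.random.default_rng(0)
    base = rng.normal(8, 1, 6)
    data = np.vstack([
        base,
        base * 2 + 1,          # r = +1 with TARGET
        -base,                 # r = -1
        rng.normal(8, 1, 6),   # noise
        rng.normal(8, 1, 6),   # noise
    ])
    return pd.DataFrame(
        data,
        index=["TARGET", "TWIN", "ANTI", "N1", "N2"],
        columns=[f"s{i}" for i in range(6)],
    )
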