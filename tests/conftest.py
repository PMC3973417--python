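import numpy as np
import pandas as pd
import pytest

import soilfert as sf


@pytest.fixture(scope="session")
def standard():
    """The packaged 6-index, 6-grade standard matrix."""
    return sf.default_standard()


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def fixture_table():
    """The deterministic 52-sample synthetic study table."""
    return sf.study_fixture(seed=1)


def random_boundaries(rng, k):
    """Strictly decreasing positive boundaries for a K-grade index."""
    b = np.sort(rng.uniform(0.5, 100.0, size=k - 1))[::-1]
    while np.any(np.diff(b) >= -1e-6):  # enforce a gap so anchors are distinct
        b = np.sort(rng.uniform(0.5, 100.0, size=k - 1))[::-1]
    return b


def random_simplex(rng, k, size=None):
    """Uniform Dirichlet(1) vectors on the K-simplex."""
    g = rng.gamma(1.0, size=(size or 1, k))
    g /= g.sum(axis=1, keepdims=True)
    return g[0] if size is None else g


def small_table(values_by_group, index_names=("A", "B")):
    """Tiny sample table from {group: [[v per index], ...]}."""
    rows = []
    i = 0
    for group, samples in values_by_group.items():
        for vals in samples:
            row = {"sample_id": f"s{i}", "group": group}
            row.update(dict(zip(index_names, vals)))
            rows.append(row)
            i += 1
    return pd.DataFrame(rows)
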