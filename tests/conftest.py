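import numpy as np
import pytest

import brainsage as bs
from brainsage.graph import build_graph


@pytest.fixture(scope="session")
def small_cohort():
    """80 subjects x 12 ROIs, 3 latent clusters — raw volumes plus truth."""
    cfg = bs.SyntheticConfig(m_subjects=80, n_rois=12, n_clusters=3, seed=7)
    return bs.generate_cohort(cfg)


@pytest.fixture(scope="session")
def std_cohort(small_cohort):
    table, _ = small_cohort
    norm = bs.normalize_by_tiv(table)
    return bs.apply_standardizer(norm, bs.fit_standardizer(norm))


@pytest.fixture(scope="session")
def small_graph(std_cohort):
    return bs.learn_graph(std_cohort, bs.LassoConfig(lam=0.06))


def graph_from_adjacency(a):
    return build_graph(np.asarray(a, dtype=float), edge_eps=1e-12)


@pytest.fixture
def path3_graph():
    """3-node path 0-1-2."""
    a = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
    return graph_from_adjacency(a)


@pytest.fixture
def ring_graph():
    """6-node ring (2-regular)."""
    n = 6
    a = np.zeros((n, n))
    for i in range(n):
        a[i, (i + 1) % n] = a[(i + 1) % n, i] = 1.0
    return graph_from_adjacency(a)
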