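import numpy as np
import pytest

from llgcrep.core import SimilarityMatrix, TripartiteNetwork


@pytest.fixture
def tiny_net() -> TripartiteNetwork:
    """3 drugs × 2 diseases × 2 targets, hand-checkable by eye.

    Associations: (d0,s0), (d1,s0), (d2,s1).  Interactions: (d0,t0),
    (d1,t1).  Target edge: t0–t1.
    """
    return TripartiteNetwork(
        ["d0", "d1", "d2"],
        ["s0", "s1"],
        ["t0", "t1"],
        A_ds=np.array([[1, 0], [1, 0], [0, 1]]),
        A_dt=np.array([[1, 0], [0, 1], [0, 0]]),
        A_tt=np.array([[0, 1], [1, 0]]),
    )


@pytest.fixture
def tiny_sims(tiny_net):
    drug = SimilarityMatrix(
        tiny_net.drug_ids,
        np.array([[1.0, 0.7, 0.2], [0.7, 1.0, 0.3], [0.2, 0.3, 1.0]]),
    )
    disease = SimilarityMatrix(
        tiny_net.disease_ids, np.array([[1.0, 0.4], [0.4, 1.0]])
    )
    return drug, disease


def random_network(rng: np.random.Generator, n_d=5, n_s=4, n_t=3, p=0.4) -> TripartiteNetwork:
    """Random dense-ish tripartite network for oracle comparisons."""
    A_ds = (rng.random((n_d, n_s)) < p).astype(int)
    if not A_ds.any():
        A_ds[0, 0] = 1
    A_dt = (rng.random((n_d, n_t)) < p).astype(int)
    A_tt = np.triu((rng.random((n_t, n_t)) < p).astype(int), k=1)
    return TripartiteNetwork(
        [f"d{i}" for i in range(n_d)],
        [f"s{i}" for i in range(n_s)],
        [f"t{i}" for i in range(n_t)],
        A_ds,
        A_dt,
        A_tt + A_tt.T,
    )


def random_similarity(rng: np.random.Generator, ids) -> SimilarityMatrix:
    n = len(ids)
    v = rng.random((n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 1.0)
    return SimilarityMatrix(list(ids), v)
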