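"""Topology-derived similarities and their fusion with biological similarity.

Two topology similarities are built from the association network alone:

* sharing-degree similarity — two drugs are similar when they are associated
  with many common diseases (and symmetrically for diseases sharing drugs);
  raw shared-neighbor counts are cosine-normalized so they live on the same
  [0, 1] scale as the correlation-based similarity below;
* shortest-path profile similarity — each drug is described by its vector of
  shortest-path lengths (in the fully integrated M4 graph) to every disease,
  and two drugs are similar when these profiles are Pearson-correlated
  (diseases use profiles of distances to drugs).

The two are fused by a weighted geometric mean into a single topology
similarity, which is then blended linearly with the biological similarity
matrix (chemical structure for drugs, phenotype for diseases).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

import networkx as nx

from .core import (
    DimensionError,
    GraphLevel,
    IntegratedGraph,
    SimilarityMatrix,
    TripartiteNetwork,
    ValidationError,
    build_integrated_graph,
)

__all__ = [
    "SimilarityFusionConfig",
    "sharing_degree_matrix",
    "normalize_sharing_degree",
    "pearson",
    "shortest_path_profile_similarity",
    "combine_geometric",
    "combine_linear",
    "topology_similarity",
    "integrated_similarities",
]


@dataclass
class SimilarityFusionConfig:
    """Weights of the similarity fusion.

    ``w_sd`` is the geometric-mean weight of the (normalized) sharing-degree
    similarity against the shortest-path profile similarity; ``lambda_drug``
    and ``lambda_disease`` weight the biological matrix in the final linear
    blend (1.0 means biology only, 0.0 topology only).
    """

    w_sd: float = 0.5
    lambda_drug: float = 0.5
    lambda_disease: float = 0.5
    tau: float = 0.5  # drug-drug edge threshold when building M2+

    def __post_init__(self) -> None:
        for name in ("w_sd", "lambda_drug", "lambda_disease", "tau"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")


def sharing_degree_matrix(A: np.ndarray, axis: str = "rows") -> np.ndarray:
    """Shared-neighbor counts between rows (or columns) of a binary matrix.

    For ``axis="rows"`` entry (i, j) counts the columns where rows i and j
    both have a 1 — for a drug×disease association matrix this is the number
    of diseases shared by drugs i and j.  Equals A·Aᵀ; the diagonal is the
    row degree.
    """
    A = np.asarray(A)
    if not np.isin(A, (0, 1)).all():
        raise ValidationError("sharing_degree_matrix requires a binary matrix")
    if axis not in ("rows", "columns"):
        raise ValidationError(f"axis must be 'rows' or 'columns', got {axis!r}")
    A = A.astype(np.int64)
    if axis == "columns":
        A = A.T
    return A @ A.T


def normalize_sharing_degree(SD: np.ndarray, ids: list[str] | None = None) -> np.ndarray | SimilarityMatrix:
    """Cosine-normalize sharing counts to [0, 1]: SD_ij / sqrt(SD_ii·SD_jj).

    Pairs where either diagonal count is zero get similarity 0; the diagonal
    is forced to 1.  With ``ids`` given, returns a :class:`SimilarityMatrix`.
    """
    SD = np.asarray(SD, dtype=float)
    if SD.ndim != 2 or SD.shape[0] != SD.shape[1]:
        raise DimensionError("sharing-degree matrix must be square")
    d = np.sqrt(np.diagonal(SD))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = SD / np.outer(d, d)
    out[~np.isfinite(out)] = 0.0
    np.fill_diagonal(out, 1.0)
    out = np.clip((out + out.T) / 2.0, 0.0, 1.0)
    if ids is not None:
        return SimilarityMatrix(list(ids), out)
    return out


def pearson(x, y) -> float:
    """Product-moment correlation; 0 when either sequence is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DimensionError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValidationError("pearson requires sequences of length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def _profile_correlation(profiles: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation with the constant-row → 0 convention."""
    n = profiles.shape[0]
    const = np.ptp(profiles, axis=1) == 0
    out = np.zeros((n, n))
    live = ~const
    if live.sum() >= 1 and profiles.shape[1] >= 2:
        sub = profiles[live]
        c = np.corrcoef(sub) if sub.shape[0] > 1 else np.ones((1, 1))
        c = np.atleast_2d(c)
        out[np.ix_(live, live)] = c
    out = np.nan_to_num(out, nan=0.0)
    np.fill_diagonal(out, 1.0)
    return out


def shortest_path_profile_similarity(
    g: IntegratedGraph, node_kind: str
) -> SimilarityMatrix:
    """Similarity of shortest-path-length profiles in the integrated graph.

    For drugs the profile is the vector of shortest-path lengths to every
    disease; for diseases, to every drug.  Unreachable pairs get a finite
    sentinel equal to the node count (exceeds any true path length).
    Similarity is the Pearson correlation of two profiles with negatives
    clipped to 0 and unit diagonal; constant profiles (isolated nodes, or
    single-column profiles) get correlation 0 by convention.
    """
    if node_kind not in ("drugs", "diseases"):
        raise ValidationError(f"node_kind must be 'drugs' or 'diseases', got {node_kind!r}")
    graph = g.graph
    if graph.number_of_nodes() == 0:
        raise ValidationError("cannot compute path profiles on an empty graph")
    nodelist = list(graph.nodes)
    pos = {n: i for i, n in enumerate(nodelist)}
    adj = nx.to_scipy_sparse_array(graph, nodelist=nodelist, format="csr")
    dist = _csgraph_shortest_path(adj, method="D", unweighted=True)
    sentinel = float(len(nodelist))
    dist[np.isinf(dist)] = sentinel

    row_kind, col_kind = ("drug", "disease") if node_kind == "drugs" else ("disease", "drug")
    rows = [n for n in nodelist if n[0] == row_kind]
    cols = [n for n in nodelist if n[0] == col_kind]
    profiles = dist[np.ix_([pos[n] for n in rows], [pos[n] for n in cols])]
    corr = np.clip(_profile_correlation(profiles), 0.0, 1.0)
    return SimilarityMatrix.from_raw([n[1] for n in rows], corr)


def _check_same_ids(a: SimilarityMatrix, b: SimilarityMatrix) -> None:
    if a.ids != b.ids:
        raise ValidationError("similarity matrices are over different identifier lists")


def combine_geometric(S1: SimilarityMatrix, S2: SimilarityMatrix, w: float) -> SimilarityMatrix:
    """Weighted geometric mean S1^w · S2^(1−w), entrywise."""
    _check_same_ids(S1, S2)
    if not 0.0 <= w <= 1.0:
        raise ValidationError(f"weight w={w} outside [0, 1]")
    # a zero factor with positive weight yields 0; 0**0 == 1 handles the edges
    v = S1.values**w * S2.values ** (1.0 - w)
    return SimilarityMatrix.from_raw(S1.ids, v)


def combine_linear(S_bio: SimilarityMatrix, S_topo: SimilarityMatrix, lam: float) -> SimilarityMatrix:
    """Linear blend lam·S_bio + (1−lam)·S_topo."""
    _check_same_ids(S_bio, S_topo)
    if not 0.0 <= lam <= 1.0:
        raise ValidationError(f"weight lam={lam} outside [0, 1]")
    return SimilarityMatrix.from_raw(S_bio.ids, lam * S_bio.values + (1.0 - lam) * S_topo.values)


def topology_similarity(
    net: TripartiteNetwork,
    cfg: SimilarityFusionConfig | None = None,
    drug_sim_for_graph: SimilarityMatrix | None = None,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Fused topology similarity matrices (drugs, diseases).

    Sharing-degree similarity comes straight from the association matrix;
    path-profile similarity needs the integrated M4 graph, whose drug–drug
    edges require a drug similarity matrix (``drug_sim_for_graph``; when
    absent, M4 is built without drug–drug edges, i.e. with an identity
    threshold no similarity reaches).
    """
    cfg = cfg or SimilarityFusionConfig()
    sd_drug = normalize_sharing_degree(
        sharing_degree_matrix(net.A_ds, "rows"), net.drug_ids
    )
    sd_disease = normalize_sharing_degree(
        sharing_degree_matrix(net.A_ds, "columns"), net.disease_ids
    )
    graph_sim = drug_sim_for_graph
    tau = cfg.tau
    if graph_sim is None:
        graph_sim = SimilarityMatrix(list(net.drug_ids), np.eye(net.n_drugs))
        tau = 1.0  # identity never clears the bar: no drug-drug edges
    m4 = build_integrated_graph(net, GraphLevel.M4, graph_sim, tau=tau)
    sp_drug = shortest_path_profile_similarity(m4, "drugs")
    sp_disease = shortest_path_profile_similarity(m4, "diseases")
    # align path-profile ids (graph order) to network order
    sp_drug = _reindex(sp_drug, net.drug_ids)
    sp_disease = _reindex(sp_disease, net.disease_ids)
    drug_topo = combine_geometric(sd_drug, sp_drug, cfg.w_sd)
    disease_topo = combine_geometric(sd_disease, sp_disease, cfg.w_sd)
    return drug_topo, disease_topo


def _reindex(sim: SimilarityMatrix, ids: list[str]) -> SimilarityMatrix:
    order = [sim.index(i) for i in ids]
    return SimilarityMatrix(list(ids), sim.values[np.ix_(order, order)])


def integrated_similarities(
    net: TripartiteNetwork,
    drug_bio: SimilarityMatrix,
    disease_bio: SimilarityMatrix,
    cfg: SimilarityFusionConfig | None = None,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Final drug and disease similarities: linear blend of biology and topology."""
    cfg = cfg or SimilarityFusionConfig()
    drug_bio = _reindex(drug_bio, net.drug_ids)
    disease_bio = _reindex(disease_bio, net.disease_ids)
    drug_topo, disease_topo = topology_similarity(net, cfg, drug_sim_for_graph=drug_bio)
    return (
        combine_linear(drug_bio, drug_topo, cfg.lambda_drug),
        combine_linear(disease_bio, disease_topo, cfg.lambda_disease),
    )
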