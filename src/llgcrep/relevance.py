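"""Graph relevance vectors and the Gaussian interaction profile kernel.

Each drug–disease pair ⟨d, s⟩ is encoded by one relevance score per network
node (blocks ordered drugs → diseases → targets):

* drug block — row of the integrated drug similarity at d;
* disease block — row of the integrated disease similarity at s;
* target block — for each target t: 1 when (d, t) is a known interaction,
  otherwise the best similarity between d and any drug known to hit t; the
  disease contributes analogously through its associated drugs, and the
  pair takes the elementwise maximum of the two contributions.

The pair's feature vector is then its Gaussian interaction profile (GIP)
kernel against the relevance vectors of all known associated pairs:
K(p, i) = exp(−r‖v_p − v_i‖²), with bandwidth r = n / Σᵢ‖vᵢ‖² so that the
kernel is scaled to the mean squared norm of the known profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .core import SimilarityMatrix, TripartiteNetwork, ValidationError

__all__ = [
    "RelevanceVector",
    "FeatureMatrix",
    "drug_relevance",
    "disease_relevance",
    "pair_relevance",
    "relevance_matrix",
    "gip_bandwidth",
    "feature_matrix",
]


@dataclass
class RelevanceVector:
    """Relevance of one drug–disease pair to every node in the network."""

    pair: tuple[str, str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1:
            raise ValidationError("relevance scores must be a 1-D vector")
        if self.scores.min() < 0 or self.scores.max() > 1:
            raise ValidationError("relevance scores must lie in [0, 1]")

    def __len__(self) -> int:
        return self.scores.size


@dataclass
class FeatureMatrix:
    """GIP-kernel features of pairs against the known associated pairs."""

    pairs: list[tuple[str, str]]
    features: np.ndarray
    r: float

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape[0] != len(self.pairs):
            raise ValidationError("feature row count must match pair count")
        if self.r <= 0:
            raise ValidationError("kernel bandwidth r must be positive")

    @property
    def n_known(self) -> int:
        return self.features.shape[1]


def _aligned(sim: SimilarityMatrix, ids: Sequence[str]) -> np.ndarray:
    order = [sim.index(i) for i in ids]
    return sim.values[np.ix_(order, order)]


def _drug_target_block(net: TripartiteNetwork, drug_sim: np.ndarray) -> np.ndarray:
    """Target relevance of every drug: known interactions score 1, otherwise the
    best similarity to a drug that interacts with the target (0 if none does)."""
    n_d, n_t = net.n_drugs, net.n_targets
    R = np.zeros((n_d, n_t))
    A_dt = net.A_dt.astype(bool)
    for t in range(n_t):
        hitters = A_dt[:, t]
        if hitters.any():
            R[:, t] = drug_sim[:, hitters].max(axis=1)
    R[A_dt] = 1.0
    return R


def relevance_matrix(
    net: TripartiteNetwork,
    drug_sim: SimilarityMatrix,
    disease_sim: SimilarityMatrix,
    pairs: Sequence[tuple[str, str]],
) -> np.ndarray:
    """Relevance vectors for many pairs at once, one row per pair.

    Vectorized equivalent of :func:`pair_relevance`; the per-pair functions
    are the readable reference, this is the work-horse the pipeline calls.
    """
    Sd = _aligned(drug_sim, net.drug_ids)
    Ss = _aligned(disease_sim, net.disease_ids)
    Rd_t = _drug_target_block(net, Sd)  # (n_drugs, n_targets)

    # disease target block: best drug-target relevance over associated drugs
    n_s, n_t = net.n_diseases, net.n_targets
    Rs_t = np.zeros((n_s, n_t))
    A_ds = net.A_ds.astype(bool)
    for s in range(n_s):
        assoc = A_ds[:, s]
        if assoc.any():
            Rs_t[s] = Rd_t[assoc].max(axis=0)

    d_index = {d: i for i, d in enumerate(net.drug_ids)}
    s_index = {s: i for i, s in enumerate(net.disease_ids)}
    di = np.array([d_index[d] for d, _ in pairs], dtype=int)
    si = np.array([s_index[s] for _, s in pairs], dtype=int)
    drug_block = Sd[di]
    disease_block = Ss[si]
    target_block = np.maximum(Rd_t[di], Rs_t[si])
    return np.hstack([drug_block, disease_block, target_block])


def drug_relevance(
    net: TripartiteNetwork, drug_sim: SimilarityMatrix, d: str
) -> np.ndarray:
    """Relevance of drug ``d`` to every node (drugs → diseases → targets).

    Disease block is the 0/1 association row; drug block the similarity row;
    target block follows the known-interaction / best-similar-drug rule.
    """
    i = net.drug_index(d)
    Sd = _aligned(drug_sim, net.drug_ids)
    target_block = _drug_target_block(net, Sd)[i]
    return np.concatenate([Sd[i], net.A_ds[i].astype(float), target_block])


def disease_relevance(
    net: TripartiteNetwork,
    disease_sim: SimilarityMatrix,
    drug_sim: SimilarityMatrix,
    s: str,
) -> np.ndarray:
    """Relevance of disease ``s`` to every node (drugs → diseases → targets).

    Drug block is the 0/1 association column; disease block the similarity
    row; a target scores the best drug-relevance among the drugs associated
    with ``s`` (0 when the disease has no associated drug).
    """
    j = net.disease_index(s)
    Ss = _aligned(disease_sim, net.disease_ids)
    Sd = _aligned(drug_sim, net.drug_ids)
    Rd_t = _drug_target_block(net, Sd)
    assoc = net.A_ds[:, j].astype(bool)
    target_block = Rd_t[assoc].max(axis=0) if assoc.any() else np.zeros(net.n_targets)
    return np.concatenate([net.A_ds[:, j].astype(float), Ss[j], target_block])


def pair_relevance(
    net: TripartiteNetwork,
    drug_sim: SimilarityMatrix,
    disease_sim: SimilarityMatrix,
    d: str,
    s: str,
) -> RelevanceVector:
    """Relevance vector of the pair ⟨d, s⟩ over all network nodes.

    Drug block from the drug, disease block from the disease, target block
    the elementwise maximum of the two target contributions.
    """
    vd = drug_relevance(net, drug_sim, d)
    vs = disease_relevance(net, disease_sim, drug_sim, s)
    n_d, n_s = net.n_drugs, net.n_diseases
    scores = np.concatenate(
        [
            vd[:n_d],
            vs[n_d : n_d + n_s],
            np.maximum(vd[n_d + n_s :], vs[n_d + n_s :]),
        ]
    )
    return RelevanceVector(pair=(d, s), scores=scores)


def gip_bandwidth(known_vectors: Sequence[RelevanceVector] | np.ndarray) -> float:
    """Kernel bandwidth r = n / Σᵢ‖vᵢ‖² over the known pairs' vectors."""
    if isinstance(known_vectors, np.ndarray):
        V = np.asarray(known_vectors, dtype=float)
    else:
        if len(known_vectors) == 0:
            raise ValidationError("gip_bandwidth requires at least one known vector")
        V = np.vstack([v.scores for v in known_vectors])
    total = float((V**2).sum())
    if total == 0.0:
        raise ValidationError("bandwidth undefined: all known vectors are zero")
    return V.shape[0] / total


def feature_matrix(
    all_vectors: np.ndarray | Sequence[RelevanceVector],
    known_vectors: np.ndarray | Sequence[RelevanceVector],
    r: float,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> FeatureMatrix:
    """GIP kernel of every pair against every known pair: exp(−r‖v_p − v_i‖²)."""
    if r <= 0:
        raise ValidationError("kernel bandwidth r must be positive")

    def _stack(vs) -> tuple[np.ndarray, list[tuple[str, str]] | None]:
        if isinstance(vs, np.ndarray):
            return np.asarray(vs, dtype=float), None
        return np.vstack([v.scores for v in vs]), [v.pair for v in vs]

    V_all, inferred_pairs = _stack(all_vectors)
    V_known, _ = _stack(known_vectors)
    sq = cdist(V_all, V_known, metric="sqeuclidean")
    K = np.exp(-r * sq)
    if pairs is None:
        pairs = inferred_pairs or [("?", "?")] * V_all.shape[0]
    return FeatureMatrix(pairs=list(pairs), features=K, r=r)
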