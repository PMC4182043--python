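"""Topology statistics of the integrated networks.

Seven statistics characterize each integration level M1–M4: edge count,
diameter, characteristic path length, global connectivity efficiency,
average degree, degree coefficient of variation, clustering coefficient,
and the degree-share structure entropy with its star/uniform normalization

    I_i = k_i / Σ_j k_j,   En = −Σ_i I_i ln I_i,
    En_max = ln m (uniform degrees),   En_min = ½ ln(4(m−1)) (star graph),
    NE = (En − En_min) / (En_max − En_min), clipped to [0, 1].

Path-based statistics on disconnected graphs follow the largest-component
convention for the diameter and average only over reachable pairs for the
characteristic path length; unreachable pairs contribute 0 to efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path as _csgraph_sp

from .core import IntegratedGraph, ValidationError

__all__ = [
    "TopologyReport",
    "all_pairs_shortest_paths",
    "diameter",
    "characteristic_path_length",
    "efficiency",
    "average_degree",
    "degree_cv",
    "clustering",
    "structure_entropy",
    "degree_distribution_summary",
    "topology_report",
]


def _as_graph(g) -> nx.Graph:
    return g.graph if isinstance(g, IntegratedGraph) else g


@dataclass
class TopologyReport:
    """One row of the per-level topology table."""

    n_edges: int
    diameter: int
    char_path_length: float
    efficiency: float
    avg_degree: float
    degree_cv: float
    clustering: float
    entropy: float
    entropy_normalized: float

    def to_series(self) -> pd.Series:
        return pd.Series(asdict(self))


def all_pairs_shortest_paths(g) -> np.ndarray:
    """Unweighted shortest-path length matrix in node-list order.

    Unreachable pairs are ``np.inf`` in the returned array (callers decide
    how to present them; TSV writers should mark them, not print inf).
    """
    graph = _as_graph(g)
    if graph.number_of_nodes() == 0:
        raise ValidationError("graph has no nodes")
    adj = nx.to_scipy_sparse_array(graph, nodelist=list(graph.nodes), format="csr")
    return _csgraph_sp(adj, method="D", unweighted=True)


def diameter(g) -> int:
    """Longest shortest path; on disconnected graphs, of the largest component.

    Component ties break toward more edges, then the lexicographically
    smallest node set.
    """
    graph = _as_graph(g)
    if graph.number_of_edges() == 0:
        raise ValidationError("diameter undefined on an edgeless graph")
    comps = [graph.subgraph(c) for c in nx.connected_components(graph)]
    comps.sort(
        key=lambda c: (
            -c.number_of_nodes(),
            -c.number_of_edges(),
            sorted(map(str, c.nodes)),
        )
    )
    return int(nx.diameter(comps[0]))


def characteristic_path_length(g) -> float:
    """Mean shortest-path length over unordered reachable node pairs."""
    dist = all_pairs_shortest_paths(g)
    iu = np.triu_indices(dist.shape[0], k=1)
    vals = dist[iu]
    finite = vals[np.isfinite(vals) & (vals > 0)]
    if finite.size == 0:
        raise ValidationError("no reachable node pair")
    return float(finite.mean())


def efficiency(g) -> float:
    """Global connectivity efficiency: mean inverse shortest-path length.

    E = (2 / m(m−1)) Σ_{i<j} 1/d_ij with unreachable pairs contributing 0;
    equals 1 on a complete graph and 0 on an edgeless one.
    """
    graph = _as_graph(g)
    m = graph.number_of_nodes()
    if m < 2:
        raise ValidationError("efficiency needs at least two nodes")
    dist = all_pairs_shortest_paths(graph)
    iu = np.triu_indices(m, k=1)
    vals = dist[iu]
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(vals) & (vals > 0), 1.0 / vals, 0.0)
    return float(inv.sum() / (m * (m - 1) / 2.0))


def average_degree(g) -> float:
    """Mean node degree 2B/m."""
    graph = _as_graph(g)
    m = graph.number_of_nodes()
    if m == 0:
        raise ValidationError("graph has no nodes")
    return 2.0 * graph.number_of_edges() / m


def degree_cv(g) -> float:
    """Degree coefficient of variation: population sd of degrees / mean degree."""
    graph = _as_graph(g)
    degrees = np.array([d for _, d in graph.degree()], dtype=float)
    if degrees.size == 0 or degrees.mean() == 0:
        raise ValidationError("degree CV undefined without edges")
    return float(degrees.std() / degrees.mean())


def clustering(g) -> tuple[dict, float]:
    """Per-node clustering coefficients and their mean over all nodes.

    C_v = 2E_v / (k_v (k_v − 1)) with E_v the edge count among v's
    neighbors; nodes of degree < 2 get 0 and still enter the mean.
    """
    graph = _as_graph(g)
    if graph.number_of_nodes() == 0:
        raise ValidationError("graph has no nodes")
    per_node = nx.clustering(graph)
    return per_node, float(np.mean(list(per_node.values())))


def structure_entropy(g) -> tuple[float, float]:
    """Degree-share entropy and its star/uniform normalization.

    Returns ``(entropy, normalized)``; degree-0 nodes contribute nothing
    (x ln x → 0), and the normalized value is clipped to [0, 1] because
    isolated nodes can push the raw entropy below the star-graph minimum.
    """
    graph = _as_graph(g)
    m = graph.number_of_nodes()
    k = np.array([d for _, d in graph.degree()], dtype=float)
    total = k.sum()
    if total == 0:
        raise ValidationError("structure entropy undefined on an edgeless graph")
    I = k[k > 0] / total
    en = float(-(I * np.log(I)).sum())
    if m < 2:
        return en, 1.0
    en_max = np.log(m)
    en_min = 0.5 * np.log(4.0 * (m - 1))
    if en_max <= en_min:  # only for m <= 3, where the two bounds cross
        return en, 1.0
    ne = (en - en_min) / (en_max - en_min)
    return en, float(np.clip(ne, 0.0, 1.0))


_DEFAULT_THRESHOLDS = ("k=1", "k<=5", "k<=10", "k<=15", "k>20")


def degree_distribution_summary(g, thresholds=_DEFAULT_THRESHOLDS) -> pd.Series:
    """Proportions of nodes in coarse degree classes, plus the max degree.

    Threshold strings use the forms ``k=N``, ``k<=N`` and ``k>N``.
    """
    graph = _as_graph(g)
    degrees = np.array([d for _, d in graph.degree()], dtype=int)
    if degrees.size == 0:
        raise ValidationError("graph has no nodes")
    out: dict[str, float] = {"max_degree": int(degrees.max())}
    for spec in thresholds:
        s = spec.replace(" ", "")
        if s.startswith("k<="):
            mask = degrees <= int(s[3:])
        elif s.startswith("k>"):
            mask = degrees > int(s[2:])
        elif s.startswith("k="):
            mask = degrees == int(s[2:])
        else:
            raise ValidationError(f"unrecognized degree threshold {spec!r}")
        out[spec] = float(mask.mean())
    return pd.Series(out)


def topology_report(g) -> TopologyReport:
    """All seven statistics of one graph in a single report row."""
    _, mean_clust = clustering(g)
    en, ne = structure_entropy(g)
    return TopologyReport(
        n_edges=_as_graph(g).number_of_edges(),
        diameter=diameter(g),
        char_path_length=characteristic_path_length(g),
        efficiency=efficiency(g),
        avg_degree=average_degree(g),
        degree_cv=degree_cv(g),
        clustering=mean_clust,
        entropy=en,
        entropy_normalized=ne,
    )
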