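"""Domain types and I/O for tripartite drug–disease–target networks.

A study network has three node sets — drugs, diseases, protein targets —
linked by three binary relations: drug–disease associations (the labels the
method tries to extend), drug–target interactions, and target–target
interactions.  Biological similarity matrices (chemical structure for drugs,
phenotype for diseases) are consumed as square TSV matrices; the package
never computes them from raw structures or text.

All matrices are indexed by the identifier lists fixed at load time; the
identifier order is the single source of truth for every downstream array.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LlgcrepError",
    "ParseError",
    "DimensionError",
    "ValidationError",
    "ConfigurationError",
    "UnknownIdentifierError",
    "EdgeKind",
    "GraphLevel",
    "TripartiteNetwork",
    "SimilarityMatrix",
    "IntegratedGraph",
    "read_edge_list",
    "write_edge_list",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "build_integrated_graph",
    "assemble_network",
]


class LlgcrepError(Exception):
    """Base class for package errors."""


class ParseError(LlgcrepError):
    """A file could not be parsed; the message names the offending line."""


class DimensionError(LlgcrepError):
    """Array shapes are inconsistent with the declared identifiers."""


class ValidationError(LlgcrepError):
    """A value violates a domain-type invariant."""


class ConfigurationError(LlgcrepError):
    """Arguments are inconsistent with the requested operation."""


class UnknownIdentifierError(LlgcrepError):
    """An identifier was referenced that is absent from the relevant set."""


class EdgeKind(str, Enum):
    """Which relation an edge list encodes; bipartite kinds reject self-loops."""

    DRUG_DISEASE = "drug-disease"
    DRUG_TARGET = "drug-target"
    TARGET_TARGET = "target-target"

    @property
    def bipartite(self) -> bool:
        return self is not EdgeKind.TARGET_TARGET


class GraphLevel(str, Enum):
    """Nested integration levels of the heterogeneous network.

    M1 is the drug–disease association network alone; M2 adds drug–drug
    edges (similarity thresholded); M3 adds drug–target interactions; M4
    adds the target–target network.  Edge sets are nested: M1 ⊆ M2 ⊆ M3 ⊆ M4.
    """

    M1 = "M1"
    M2 = "M2"
    M3 = "M3"
    M4 = "M4"

    @property
    def rank(self) -> int:
        return int(self.value[1])


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate {what} identifier: {dup!r}")
    return ids


def _check_binary(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a)
    if not np.isin(a, (0, 1)).all():
        raise ValidationError(f"{name} must contain only 0/1 entries")
    return a.astype(np.int8)


@dataclass
class TripartiteNetwork:
    """Drug–disease–target network with binary adjacency blocks.

    ``A_ds`` is drugs × diseases, ``A_dt`` drugs × targets, ``A_tt`` a
    symmetric zero-diagonal targets × targets matrix.
    """

    drug_ids: list[str]
    disease_ids: list[str]
    target_ids: list[str]
    A_ds: np.ndarray
    A_dt: np.ndarray
    A_tt: np.ndarray

    def __post_init__(self) -> None:
        self.drug_ids = _check_unique(self.drug_ids, "drug")
        self.disease_ids = _check_unique(self.disease_ids, "disease")
        self.target_ids = _check_unique(self.target_ids, "target")
        self.A_ds = _check_binary(self.A_ds, "A_ds")
        self.A_dt = _check_binary(self.A_dt, "A_dt")
        self.A_tt = _check_binary(self.A_tt, "A_tt")
        nd, ns, nt = len(self.drug_ids), len(self.disease_ids), len(self.target_ids)
        if self.A_ds.shape != (nd, ns):
            raise DimensionError(f"A_ds shape {self.A_ds.shape} != ({nd}, {ns})")
        if self.A_dt.shape != (nd, nt):
            raise DimensionError(f"A_dt shape {self.A_dt.shape} != ({nd}, {nt})")
        if self.A_tt.shape != (nt, nt):
            raise DimensionError(f"A_tt shape {self.A_tt.shape} != ({nt}, {nt})")
        if not np.array_equal(self.A_tt, self.A_tt.T):
            raise ValidationError("A_tt must be symmetric")
        if np.diagonal(self.A_tt).any():
            raise ValidationError("A_tt must have a zero diagonal")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    @property
    def n_nodes(self) -> int:
        return self.n_drugs + self.n_diseases + self.n_targets

    def drug_index(self, drug_id: str) -> int:
        try:
            return self.drug_ids.index(drug_id)
        except ValueError:
            raise UnknownIdentifierError(f"unknown drug: {drug_id!r}") from None

    def disease_index(self, disease_id: str) -> int:
        try:
            return self.disease_ids.index(disease_id)
        except ValueError:
            raise UnknownIdentifierError(f"unknown disease: {disease_id!r}") from None

    def known_pairs(self) -> list[tuple[str, str]]:
        """Drug–disease pairs with a recorded association, in matrix order."""
        di, si = np.nonzero(self.A_ds)
        return [(self.drug_ids[d], self.disease_ids[s]) for d, s in zip(di, si)]

    def all_pairs(self) -> list[tuple[str, str]]:
        return [(d, s) for d in self.drug_ids for s in self.disease_ids]

    def masked(self, pairs: Iterable[tuple[str, str]]) -> "TripartiteNetwork":
        """Copy of the network with the given associations removed from A_ds."""
        A = self.A_ds.copy()
        for d, s in pairs:
            A[self.drug_index(d), self.disease_index(s)] = 0
        return TripartiteNetwork(
            list(self.drug_ids), list(self.disease_ids), list(self.target_ids),
            A, self.A_dt.copy(), self.A_tt.copy(),
        )

    def write(self, directory: str | Path) -> None:
        """Write the three edge lists plus node rosters to a directory."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_edge_list(
            directory / "drug_disease.tsv",
            [(self.drug_ids[i], self.disease_ids[j]) for i, j in zip(*np.nonzero(self.A_ds))],
        )
        write_edge_list(
            directory / "drug_target.tsv",
            [(self.drug_ids[i], self.target_ids[j]) for i, j in zip(*np.nonzero(self.A_dt))],
        )
        iu = np.triu_indices(self.n_targets, k=1)
        tt_mask = self.A_tt[iu].astype(bool)
        write_edge_list(
            directory / "target_target.tsv",
            [
                (self.target_ids[i], self.target_ids[j])
                for i, j in zip(iu[0][tt_mask], iu[1][tt_mask])
            ],
        )
        for name, ids in (
            ("drugs.txt", self.drug_ids),
            ("diseases.txt", self.disease_ids),
            ("targets.txt", self.target_ids),
        ):
            (directory / name).write_text("\n".join(ids) + "\n")

    @classmethod
    def read(cls, directory: str | Path) -> "TripartiteNetwork":
        """Inverse of :meth:`write`."""
        directory = Path(directory)
        drug_ids = (directory / "drugs.txt").read_text().split()
        disease_ids = (directory / "diseases.txt").read_text().split()
        target_ids = (directory / "targets.txt").read_text().split()
        return assemble_network(
            drug_ids,
            disease_ids,
            target_ids,
            read_edge_list(directory / "drug_disease.tsv", EdgeKind.DRUG_DISEASE),
            read_edge_list(directory / "drug_target.tsv", EdgeKind.DRUG_TARGET),
            read_edge_list(directory / "target_target.tsv", EdgeKind.TARGET_TARGET),
        )


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity over one node set: values in [0,1], unit diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = _check_unique(self.ids, "similarity")
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise DimensionError(f"similarity matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("similarity matrix must be symmetric within 1e-12")
        if v.min() < 0 or v.max() > 1:
            raise ValidationError("similarity values must lie in [0, 1]")
        if not np.allclose(np.diagonal(v), 1.0):
            raise ValidationError("similarity diagonal must be 1")
        self.values = v

    @classmethod
    def from_raw(cls, ids: Sequence[str], values: np.ndarray) -> "SimilarityMatrix":
        """Coerce a raw matrix: symmetrize, clip to [0,1], force unit diagonal."""
        v = np.asarray(values, dtype=float)
        v = (v + v.T) / 2.0
        if v.min() < 0 or v.max() > 1:
            warnings.warn("similarity values clipped to [0, 1]", stacklevel=2)
            v = np.clip(v, 0.0, 1.0)
        np.fill_diagonal(v, 1.0)
        return cls(list(ids), v)

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self, node_id: str) -> int:
        try:
            return self.ids.index(node_id)
        except ValueError:
            raise UnknownIdentifierError(f"unknown identifier: {node_id!r}") from None

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])


@dataclass
class IntegratedGraph:
    """One of the nested heterogeneous networks M1–M4 as an undirected graph.

    Nodes are ``(kind, id)`` tuples with kind in {drug, disease, target}, so
    identical identifier strings in different node sets never collide.
    """

    level: GraphLevel
    graph: nx.Graph = field(repr=False)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes_of_kind(self, kind: str) -> list[tuple[str, str]]:
        return [n for n in self.graph.nodes if n[0] == kind]


# ---------------------------------------------------------------------------
# TSV I/O


def read_edge_list(path: str | Path, kind: EdgeKind | str = EdgeKind.DRUG_DISEASE) -> list[tuple[str, str]]:
    """Read a two-column TSV edge list, de-duplicated in file order.

    A first line whose fields are ``source_id``/``target_id`` (any case) is
    treated as a header.  Duplicated edges are dropped with a log message;
    a line without exactly two fields raises :class:`ParseError` naming the
    line; a self-loop in a bipartite list raises :class:`ValidationError`.
    """
    kind = EdgeKind(kind)
    path = Path(path)
    edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate space-separated files
                fields = line.split()
            if len(fields) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 columns, found {len(fields)}"
                )
            a, b = fields[0].strip(), fields[1].strip()
            if lineno == 1 and {a.lower(), b.lower()} == {"source_id", "target_id"}:
                continue
            if kind.bipartite and a == b:
                raise ValidationError(
                    f"{path}:{lineno}: self-loop {a!r} in bipartite {kind.value} list"
                )
            edge = (a, b)
            if edge in seen:
                n_dup += 1
                continue
            seen.add(edge)
            edges.append(edge)
    if n_dup:
        logger.warning("%s: dropped %d duplicate edge(s)", path, n_dup)
    return edges


def write_edge_list(path: str | Path, edges: Iterable[tuple[str, str]]) -> None:
    with Path(path).open("w") as fh:
        fh.write("source_id\ttarget_id\n")
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def read_similarity_matrix(path: str | Path) -> SimilarityMatrix:
    """Read a square TSV matrix (header row = ids, first column = ids).

    The matrix is symmetrized as (M + Mᵀ)/2, the diagonal forced to 1 and
    values clipped to [0,1] (with a warning when clipping changes anything).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[0] != df.shape[1]:
        raise DimensionError(
            f"{path}: matrix is {df.shape[0]}×{df.shape[1]}, expected square"
        )
    if not df.map(lambda x: isinstance(x, (int, float, np.number))).to_numpy().all():
        bad = df.map(lambda x: not isinstance(x, (int, float, np.number)))
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    ids = [str(i) for i in df.index]
    if [str(c) for c in df.columns] != ids:
        raise ValidationError(f"{path}: row and column identifiers differ")
    return SimilarityMatrix.from_raw(ids, df.to_numpy(dtype=float))


def write_similarity_matrix(path: str | Path, sim: SimilarityMatrix) -> None:
    pd.DataFrame(sim.values, index=sim.ids, columns=sim.ids).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def assemble_network(
    drug_ids: Sequence[str],
    disease_ids: Sequence[str],
    target_ids: Sequence[str],
    ds_edges: Iterable[tuple[str, str]],
    dt_edges: Iterable[tuple[str, str]] = (),
    tt_edges: Iterable[tuple[str, str]] = (),
) -> TripartiteNetwork:
    """Build a network from identifier rosters and edge lists.

    Any edge endpoint absent from its roster is a hard error: silently
    intersecting identifier sets hides data bugs.
    """
    drug_ids = list(drug_ids)
    disease_ids = list(disease_ids)
    target_ids = list(target_ids)
    d_idx = {d: i for i, d in enumerate(drug_ids)}
    s_idx = {s: i for i, s in enumerate(disease_ids)}
    t_idx = {t: i for i, t in enumerate(target_ids)}

    def _lookup(idx: dict[str, int], key: str, what: str) -> int:
        if key not in idx:
            raise UnknownIdentifierError(f"{what} {key!r} not in identifier roster")
        return idx[key]

    A_ds = np.zeros((len(drug_ids), len(disease_ids)), dtype=np.int8)
    for d, s in ds_edges:
        A_ds[_lookup(d_idx, d, "drug"), _lookup(s_idx, s, "disease")] = 1
    A_dt = np.zeros((len(drug_ids), len(target_ids)), dtype=np.int8)
    for d, t in dt_edges:
        A_dt[_lookup(d_idx, d, "drug"), _lookup(t_idx, t, "target")] = 1
    A_tt = np.zeros((len(target_ids), len(target_ids)), dtype=np.int8)
    for a, b in tt_edges:
        i, j = _lookup(t_idx, a, "target"), _lookup(t_idx, b, "target")
        if i == j:
            continue  # self-interactions carry no edge
        A_tt[i, j] = A_tt[j, i] = 1
    return TripartiteNetwork(drug_ids, disease_ids, target_ids, A_ds, A_dt, A_tt)


# ---------------------------------------------------------------------------
# Integrated graphs M1–M4


def build_integrated_graph(
    net: TripartiteNetwork,
    level: GraphLevel | str,
    drug_sim: SimilarityMatrix | None = None,
    tau: float = 0.5,
) -> IntegratedGraph:
    """Embed the relation networks into one undirected graph at a given level.

    M1: drug–disease edges only.  M2: plus drug–drug edges between drugs
    whose similarity is ≥ ``tau`` (i ≠ j).  M3: plus drug–target edges.
    M4: plus target–target edges.  Every node of the tripartite network is
    retained even when isolated at the chosen level.
    """
    level = GraphLevel(level)
    if level.rank >= 2 and drug_sim is None:
        raise ConfigurationError(f"drug_sim is required to build {level.value}")
    g: nx.Graph = nx.Graph()
    g.add_nodes_from(("drug", d) for d in net.drug_ids)
    g.add_nodes_from(("disease", s) for s in net.disease_ids)
    g.add_nodes_from(("target", t) for t in net.target_ids)
    for i, j in zip(*np.nonzero(net.A_ds)):
        g.add_edge(("drug", net.drug_ids[i]), ("disease", net.disease_ids[j]))
    if level.rank >= 2:
        assert drug_sim is not None
        order = [drug_sim.index(d) for d in net.drug_ids]
        sim = drug_sim.values[np.ix_(order, order)]
        ii, jj = np.nonzero(np.triu(sim >= tau, k=1))
        for i, j in zip(ii, jj):
            g.add_edge(("drug", net.drug_ids[i]), ("drug", net.drug_ids[j]))
    if level.rank >= 3:
        for i, j in zip(*np.nonzero(net.A_dt)):
            g.add_edge(("drug", net.drug_ids[i]), ("target", net.target_ids[j]))
    if level.rank >= 4:
        for i, j in zip(*np.nonzero(np.triu(net.A_tt, k=1))):
            g.add_edge(("target", net.target_ids[i]), ("target", net.target_ids[j]))
    return IntegratedGraph(level=level, graph=g)
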