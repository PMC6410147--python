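"""In-memory domain containers shared by every module.

All downstream computation consumes these types; file formats live in
:mod:`lfemda.io` only.  Matrices are plain ``numpy`` arrays with ordered
string label lists, the convention used throughout: row ``i`` of an
entity-by-k factor matrix is the latent vector of entity ``i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "MiRNARecord",
    "SimilarityMatrix",
    "AssociationMatrix",
    "DiseaseOntology",
    "ScoreMatrix",
]

RNA_ALPHABET = frozenset("ACGU")

#: tolerance below which asymmetries in a similarity matrix are repaired
#: by averaging; larger violations are rejected.
SYMMETRY_ATOL = 1e-6


@dataclass(frozen=True)
class MiRNARecord:
    """A miRNA identifier and its RNA sequence (uppercase, {A,C,G,U})."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("miRNA record has an empty id")
        if not self.sequence:
            raise ValueError(f"miRNA {self.id!r} has an empty sequence")
        for pos, ch in enumerate(self.sequence):
            if ch not in RNA_ALPHABET:
                raise ValueError(
                    f"miRNA {self.id!r}: invalid character {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def _check_unique(labels: list[str], what: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValueError(f"duplicate {what} label {lab!r}")
        seen.add(lab)


@dataclass
class SimilarityMatrix:
    """Labeled square similarity matrix: symmetric, unit diagonal, values in [0,1].

    Plays two roles: ``MS`` (miRNA functional similarity) and ``DS``
    (disease semantic similarity).
    """

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        _check_unique(self.labels, "similarity")
        vals = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if vals.shape != (n, n):
            raise ValueError(
                f"similarity matrix shape {vals.shape} does not match {n} labels"
            )
        asym = np.abs(vals - vals.T).max(initial=0.0)
        if asym > SYMMETRY_ATOL:
            raise ValueError(f"similarity matrix asymmetric (max deviation {asym:.3g})")
        if asym > 0:
            vals = (vals + vals.T) / 2.0
        if n and np.abs(np.diag(vals) - 1.0).max() > SYMMETRY_ATOL:
            raise ValueError("similarity matrix diagonal must equal 1")
        np.fill_diagonal(vals, 1.0)
        if n and (vals.min() < -1e-12 or vals.max() > 1.0 + 1e-12):
            raise ValueError("similarity values must lie in [0, 1]")
        self.values = np.clip(vals, 0.0, 1.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown label {label!r}") from None

    def restrict(self, labels: list[str]) -> "SimilarityMatrix":
        """Submatrix over ``labels`` in the given order."""
        idx = [self.index_of(l) for l in labels]
        return SimilarityMatrix(list(labels), self.values[np.ix_(idx, idx)])


@dataclass
class AssociationMatrix:
    """Binary miRNA-by-disease matrix R of experimentally confirmed pairs.

    An entry of 1 is a confirmed positive; 0 means *unknown*, never a
    confirmed negative.
    """

    mirna_labels: list[str]
    disease_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        _check_unique(self.mirna_labels, "miRNA")
        _check_unique(self.disease_labels, "disease")
        vals = np.asarray(self.values)
        shape = (len(self.mirna_labels), len(self.disease_labels))
        if vals.shape != shape:
            raise ValueError(f"association matrix shape {vals.shape} != {shape}")
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("association matrix entries must be 0 or 1")
        self.values = vals.astype(np.int8)

    @property
    def n_positives(self) -> int:
        return int(self.values.sum())

    def positive_pairs(self) -> list[tuple[str, str]]:
        ii, jj = np.nonzero(self.values)
        return [(self.mirna_labels[i], self.disease_labels[j]) for i, j in zip(ii, jj)]

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(
            list(self.mirna_labels), list(self.disease_labels), self.values.copy()
        )


@dataclass
class DiseaseOntology:
    """Directed acyclic graph of disease terms, edges child -> parent."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            path = " -> ".join(str(u) for u, _ in cycle) + f" -> {cycle[0][0]}"
            raise ValueError(f"ontology contains a cycle: {path}")

    @classmethod
    def from_edges(
        cls, edges: list[tuple[str, str]], isolated: list[str] | None = None
    ) -> "DiseaseOntology":
        g = nx.DiGraph()
        for child, parent in edges:
            if child == parent:
                raise ValueError(f"self-edge on node {child!r}")
            g.add_edge(child, parent)
        for node in isolated or []:
            g.add_node(node)
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def parents(self, node: str) -> set[str]:
        self._require(node)
        return set(self.graph.successors(node))

    def children(self, node: str) -> set[str]:
        self._require(node)
        return set(self.graph.predecessors(node))

    def _require(self, node: str) -> None:
        if node not in self.graph:
            raise KeyError(f"unknown ontology node {node!r}")


@dataclass
class ScoreMatrix:
    """Predicted association scores R'.

    Only the relative order of entries is meaningful; a score is not a
    probability of association.
    """

    mirna_labels: list[str]
    disease_labels: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        shape = (len(self.mirna_labels), len(self.disease_labels))
        if scores.shape != shape:
            raise ValueError(f"score matrix shape {scores.shape} != {shape}")
        if scores.size and not np.isfinite(scores).all():
            raise ValueError("score matrix contains non-finite entries")
        self.scores = scores
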