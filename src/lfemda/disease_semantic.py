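"""Wang-style disease semantic similarity over ontology DAGs.

A disease ``D`` is represented by the sub-DAG ``DAG(D)`` containing
``D`` and all of its ancestors.  Each term ``t`` in that closure
contributes

    C_D(t) = 1                                       if t == D
    C_D(t) = max{ delta * C_D(t') : t' child of t }  otherwise,

where children are taken *within* ``DAG(D)`` (contributions flow only
along paths leading to ``D``) and ``delta`` in (0, 1] is the semantic
contribution decay per edge.  The semantic value ``DV(D)`` is the sum
of contributions over the closure, and the similarity of two diseases
is the contribution mass on their shared terms normalized by the sum
of their semantic values:

    SD(d1, d2) = sum_{t in T(d1) ∩ T(d2)} (C_d1(t) + C_d2(t))
                 / (DV(d1) + DV(d2)).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .types import DiseaseOntology, SimilarityMatrix

__all__ = [
    "SemanticConfig",
    "ancestor_closure",
    "contribution_values",
    "semantic_value",
    "semantic_similarity",
    "build_disease_similarity",
]


@dataclass(frozen=True)
class SemanticConfig:
    """Semantic contribution factor ``delta``, the per-edge decay in (0, 1]."""

    delta: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.delta <= 1.0:
            raise ValueError(f"delta must be in (0, 1], got {self.delta}")


def ancestor_closure(ontology: DiseaseOntology, disease: str) -> set[str]:
    """The term set T(D): ``disease`` plus all of its transitive ancestors."""
    ontology._require(disease)
    return {disease} | nx.descendants(ontology.graph, disease)


def contribution_values(
    ontology: DiseaseOntology,
    disease: str,
    config: SemanticConfig = SemanticConfig(),
) -> dict[str, float]:
    """Contribution C_D(t) of every term t in DAG(disease).

    Computed bottom-up in topological order starting from the disease,
    taking for each ancestor the max over its in-closure children.
    """
    closure = ancestor_closure(ontology, disease)
    sub = ontology.graph.subgraph(closure)
    contrib: dict[str, float] = {disease: 1.0}
    # child->parent edges: topological order visits children before parents
    for node in nx.topological_sort(sub):
        if node == disease:
            continue
        contrib[node] = config.delta * max(
            contrib[child] for child in sub.predecessors(node)
        )
    return contrib


def semantic_value(
    ontology: DiseaseOntology,
    disease: str,
    config: SemanticConfig = SemanticConfig(),
) -> float:
    """DV(D): total contribution mass of DAG(disease); at least 1."""
    return float(sum(contribution_values(ontology, disease, config).values()))


def semantic_similarity(
    ontology: DiseaseOntology,
    d1: str,
    d2: str,
    config: SemanticConfig = SemanticConfig(),
) -> float:
    """Semantic similarity SD(d1, d2) in [0, 1]; 1 when d1 == d2."""
    c1 = contribution_values(ontology, d1, config)
    c2 = contribution_values(ontology, d2, config)
    shared = c1.keys() & c2.keys()
    if not shared:
        return 0.0
    num = sum(c1[t] + c2[t] for t in shared)
    return float(num / (sum(c1.values()) + sum(c2.values())))


def build_disease_similarity(
    ontology: DiseaseOntology,
    diseases: list[str],
    config: SemanticConfig = SemanticConfig(),
) -> SimilarityMatrix:
    """Assemble the DS matrix over ``diseases`` in the given order."""
    contribs = [contribution_values(ontology, d, config) for d in diseases]
    dvs = [sum(c.values()) for c in contribs]
    n = len(diseases)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            shared = contribs[i].keys() & contribs[j].keys()
            if shared:
                num = sum(contribs[i][t] + contribs[j][t] for t in shared)
                values[i, j] = values[j, i] = num / (dvs[i] + dvs[j])
    return SimilarityMatrix(list(diseases), values)
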