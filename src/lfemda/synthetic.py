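"""Synthetic fixtures with the statistical structure the model assumes.

Three generators cover the three input modalities: a planted low-rank
association instance (ground-truth factors, similarities derived from
those same factors, and a thresholded association matrix) for recovery
experiments; families of mutated RNA sequences with graded similarity
for the sequence pipeline; and small layered DAGs for the semantic
similarity pipeline.  Everything is seed-deterministic and emitted in
the exact text formats :mod:`lfemda.io` reads, so the full tool chain
runs without any external download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import AssociationMatrix, SimilarityMatrix

__all__ = [
    "PlantedInstance",
    "generate_planted",
    "generate_sequence_family",
    "generate_dag",
    "generate_pair_list",
]

_BASES = "ACGU"


@dataclass
class PlantedInstance:
    """Ground truth plus the observable triple (MS, DS, R) derived from it."""

    true_M: np.ndarray
    true_D: np.ndarray
    MS: SimilarityMatrix
    DS: SimilarityMatrix
    R: AssociationMatrix
    held_out: list[tuple[str, str]]


def _factor_similarity(F: np.ndarray) -> np.ndarray:
    """Cosine-style similarity of row factors: row-normalize, Gram, clip."""
    norms = np.linalg.norm(F, axis=1, keepdims=True)
    Fn = F / np.where(norms > 0, norms, 1.0)
    S = np.clip(Fn @ Fn.T, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return S


def generate_planted(
    m: int = 40,
    d: int = 30,
    k_true: int = 4,
    density: float = 0.08,
    noise_sd: float = 0.1,
    holdout_fraction: float = 0.1,
    seed: int = 0,
    require_coverage: bool = False,
) -> PlantedInstance:
    """Plant a low-rank association structure consistent with the model.

    Non-negative true factors are drawn i.i.d. uniform(0, 1); the top
    ``ceil(density*m*d)`` entries of ``true_M @ true_D.T`` plus Gaussian
    noise become the confirmed positives, so with ``noise_sd=0`` every
    positive's true score strictly exceeds every unknown's.  MS and DS
    are the clipped row-normalized Gram matrices of the same factors, so
    recovering the held-out positives tests the implementation rather
    than model misspecification.

    At low densities a global cutoff routinely leaves some miRNA or
    disease with no positive — harmless for training, whose similarity
    coupling keeps zero-positive entities well defined (that is the
    new-disease setting).  Callers that need every entity covered, e.g.
    to build fusion-stable fixtures, pass ``require_coverage=True``: the
    instance is then redrawn up to 10 times and an error is raised if
    coverage is never achieved.
    """
    if m < 2 or d < 2:
        raise ValueError("need m, d >= 2")
    if not 0.0 < density < 1.0:
        raise ValueError("density must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_pos = math.ceil(density * m * d)
    for _ in range(10):
        true_M = rng.uniform(0.0, 1.0, size=(m, k_true))
        true_D = rng.uniform(0.0, 1.0, size=(d, k_true))
        noisy = true_M @ true_D.T + rng.normal(0.0, noise_sd, size=(m, d))
        R_vals = np.zeros((m, d), dtype=np.int8)
        top = np.argsort(-noisy, axis=None, kind="mergesort")[:n_pos]
        R_vals[np.unravel_index(top, (m, d))] = 1
        if not require_coverage or (
            R_vals.sum(axis=1).min() >= 1 and R_vals.sum(axis=0).min() >= 1
        ):
            break
    else:
        raise ValueError(
            f"density {density} too low: some entity has no positive "
            "after 10 attempts"
        )

    mirnas = [f"m{i}" for i in range(m)]
    diseases = [f"d{j}" for j in range(d)]
    n_hold = int(round(holdout_fraction * n_pos))
    pos_idx = np.argwhere(R_vals == 1)
    order = rng.permutation(len(pos_idx))
    held_out: list[tuple[str, str]] = []
    for sel in order:
        if len(held_out) == n_hold:
            break
        i, j = pos_idx[sel]
        if require_coverage and (
            R_vals[i].sum() < 2 or R_vals[:, j].sum() < 2
        ):
            continue  # keep coverage intact under holdout as well
        R_vals[i, j] = 0
        held_out.append((mirnas[i], diseases[j]))

    return PlantedInstance(
        true_M=true_M,
        true_D=true_D,
        MS=SimilarityMatrix(mirnas, _factor_similarity(true_M)),
        DS=SimilarityMatrix(diseases, _factor_similarity(true_D)),
        R=AssociationMatrix(mirnas, diseases, R_vals),
        held_out=held_out,
    )


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Per-site mutation: substitution (p=0.8 of mutations), insertion or
    deletion (p=0.1 each)."""
    out: list[str] = []
    for ch in seq:
        if rng.random() >= rate:
            out.append(ch)
            continue
        kind = rng.random()
        if kind < 0.8:  # substitute with a different base
            out.append(rng.choice([b for b in _BASES if b != ch]))
        elif kind < 0.9:  # insert before the site
            out.append(str(rng.choice(list(_BASES))))
            out.append(ch)
        # else: delete the site
    return "".join(out) or str(rng.choice(list(_BASES)))


def generate_sequence_family(
    n_families: int = 5,
    per_family: int = 4,
    length: int = 22,
    mutation_rate: float = 0.1,
    seed: int = 0,
) -> str:
    """FASTA text of sequence families with graded within-family similarity.

    Each family descends from one random RNA ancestor (default length 22,
    typical of mature miRNAs); ids encode membership as ``fam{f}-{i}``
    with ``-0`` the ancestor itself.
    """
    if n_families < 1 or per_family < 1 or length < 1:
        raise ValueError("n_families, per_family and length must be positive")
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError("mutation_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    lines: list[str] = []
    for f in range(n_families):
        ancestor = "".join(rng.choice(list(_BASES), size=length))
        for i in range(per_family):
            seq = ancestor if i == 0 else _mutate(ancestor, mutation_rate, rng)
            lines.append(f">fam{f}-{i}\n{seq}")
    return "\n".join(lines) + "\n"


def generate_dag(
    depth: int = 3,
    branching: int = 2,
    n_diseases: int = 6,
    seed: int = 0,
) -> str:
    """Child→parent TSV edge list for a layered random ontology.

    Layer 0 holds the roots; each deeper layer is ``branching`` times
    wider, the deepest layer holds the ``n_diseases`` disease leaves
    (labelled ``d0..d{n-1}``), and every non-root node picks 1-2 parents
    from the layer above.  ``depth=1`` degenerates to isolated disease
    roots (identity semantic similarity).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    layers: list[list[str]] = []
    for level in range(depth - 1):
        layers.append([f"t{level}_{i}" for i in range(max(1, branching**level))])
    layers.append([f"d{i}" for i in range(n_diseases)])

    lines: list[str] = []
    if depth == 1:
        lines.extend(layers[0])  # isolated roots, single-field rows
    else:
        for level in range(1, depth):
            above = layers[level - 1]
            for node in layers[level]:
                n_par = 1 if len(above) == 1 else int(rng.integers(1, 3))
                parents = rng.choice(above, size=min(n_par, len(above)), replace=False)
                lines.extend(f"{node}\t{p}" for p in parents)
    return "\n".join(lines) + "\n"


def generate_pair_list(
    mirna_ids: list[str],
    disease_ids: list[str],
    density: float = 0.2,
    seed: int = 0,
) -> str:
    """Two-column association TSV linking the given ids at ``density``.

    At least one pair per miRNA and per disease is guaranteed so the
    result is trainable after fusion.
    """
    rng = np.random.default_rng(seed)
    pairs = {
        (m, str(rng.choice(disease_ids))) for m in mirna_ids
    } | {
        (str(rng.choice(mirna_ids)), d) for d in disease_ids
    }
    for m in mirna_ids:
        for d in disease_ids:
            if rng.random() < density:
                pairs.add((m, d))
    return "".join(
        f"{m}\t{d}\n" for m, d in sorted(pairs)
    )
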