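"""Sequence-derived miRNA functional similarity.

The similarity of two miRNA sequences is defined from an edit distance
bounded by the *summed* sequence lengths,

    SM(m1, m2) = 1 - dist(m1, m2) / (len(m1) + len(m2)),

which pins down the distance as the insertion/deletion-only edit
distance (substitutions disallowed, equivalently cost 2): it equals
``len1 + len2 - 2*LCS(s1, s2)`` and attains the bound ``len1 + len2``
exactly when the sequences share no common subsequence.  The standard
Levenshtein distance (bounded by ``max(len1, len2)``) is available as a
variant for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import RNA_ALPHABET, MiRNARecord, SimilarityMatrix

__all__ = [
    "EditDistanceResult",
    "levenshtein_prime",
    "sequence_similarity",
    "build_mirna_similarity",
]


@dataclass(frozen=True)
class EditDistanceResult:
    """An edit distance together with the two sequence lengths."""

    distance: int
    len1: int
    len2: int


def _check_rna(s: str, arg: str) -> None:
    for pos, ch in enumerate(s):
        if ch not in RNA_ALPHABET:
            raise ValueError(f"{arg}: invalid character {ch!r} at position {pos}")


def _indel_distance(s1: str, s2: str) -> int:
    # len1 + len2 - 2*LCS via the indel-only DP, single rolling row
    prev = np.arange(len(s2) + 1, dtype=np.int64)
    cur = np.empty_like(prev)
    for i, c1 in enumerate(s1, start=1):
        cur[0] = i
        for j, c2 in enumerate(s2, start=1):
            if c1 == c2:
                cur[j] = prev[j - 1]
            else:
                cur[j] = min(prev[j], cur[j - 1]) + 1
        prev, cur = cur, prev
    return int(prev[len(s2)])


def _levenshtein_distance(s1: str, s2: str) -> int:
    prev = np.arange(len(s2) + 1, dtype=np.int64)
    cur = np.empty_like(prev)
    for i, c1 in enumerate(s1, start=1):
        cur[0] = i
        for j, c2 in enumerate(s2, start=1):
            cur[j] = min(
                prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (c1 != c2)
            )
        prev, cur = cur, prev
    return int(prev[len(s2)])


def levenshtein_prime(
    s1: str, s2: str, variant: str = "indel"
) -> EditDistanceResult:
    """Edit distance between two RNA sequences.

    ``variant="indel"`` (default) counts insertions and deletions only,
    giving a distance bounded by ``len1 + len2``; ``"levenshtein"``
    additionally allows unit-cost substitutions.
    """
    _check_rna(s1, "s1")
    _check_rna(s2, "s2")
    if variant == "indel":
        dist = _indel_distance(s1, s2)
    elif variant == "levenshtein":
        dist = _levenshtein_distance(s1, s2)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return EditDistanceResult(dist, len(s1), len(s2))


def sequence_similarity(s1: str, s2: str, variant: str = "indel") -> float:
    """Functional similarity SM in [0, 1]; 1 iff the sequences are identical."""
    if not s1 and not s2:
        raise ValueError("similarity of two empty sequences is undefined (0/0)")
    res = levenshtein_prime(s1, s2, variant=variant)
    return 1.0 - res.distance / (res.len1 + res.len2)


def build_mirna_similarity(
    records: list[MiRNARecord], variant: str = "indel"
) -> SimilarityMatrix:
    """Pairwise SM matrix over ``records`` in input order."""
    if not records:
        raise ValueError("need at least one miRNA record")
    labels = [r.id for r in records]
    n = len(records)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = sequence_similarity(
                records[i].sequence, records[j].sequence, variant=variant
            )
    return SimilarityMatrix(labels, values)
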