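"""Readers and writers for every on-disk format the tool touches.

Formats are deliberately minimal and text-based: FASTA for miRNA
sequences, two-column TSV pair lists for confirmed associations, labeled
square TSV for similarity matrices, and child/parent TSV edge lists for
the disease ontology.  Downstream modules never see a file path — only
the domain types from :mod:`lfemda.types`.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .types import (
    AssociationMatrix,
    DiseaseOntology,
    MiRNARecord,
    ScoreMatrix,
    SimilarityMatrix,
)

__all__ = [
    "read_fasta",
    "read_associations",
    "read_association_matrix",
    "read_similarity_matrix",
    "read_dag",
    "write_fasta",
    "write_associations",
    "write_similarity_matrix",
    "write_scores",
    "write_ranking",
]


def read_fasta(path: str | os.PathLike) -> list[MiRNARecord]:
    """Read miRNA sequences from FASTA.

    The header token before the first whitespace becomes the record id.
    Sequences are uppercased and DNA-style ``T`` is transliterated to
    ``U`` (public miRNA FASTA files mix the two alphabets); any other
    non-{A,C,G,U} character is an error.
    """
    records: list[MiRNARecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        rid = entry.id
        if rid in seen:
            raise ValueError(f"duplicate miRNA id {rid!r} in {path}")
        seen.add(rid)
        seq = str(entry.seq).upper().replace("T", "U")
        records.append(MiRNARecord(rid, seq))
    return records


def write_fasta(records: Iterable[MiRNARecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_associations(path: str | os.PathLike) -> AssociationMatrix:
    """Read a two-column TSV of confirmed (miRNA, disease) pairs.

    Label order is first-appearance order; duplicate rows collapse to a
    single positive.  An empty pair list is rejected: a matrix without a
    single confirmed positive cannot be trained on.
    """
    mirnas: dict[str, int] = {}
    diseases: dict[str, int] = {}
    pairs: set[tuple[int, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) != 2 or not all(fields):
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, got {line!r}"
                )
            m, d = fields
            mi = mirnas.setdefault(m, len(mirnas))
            dj = diseases.setdefault(d, len(diseases))
            pairs.add((mi, dj))
    if not pairs:
        raise ValueError(f"{path}: no association pairs (nothing to train on)")
    values = np.zeros((len(mirnas), len(diseases)), dtype=np.int8)
    for mi, dj in pairs:
        values[mi, dj] = 1
    return AssociationMatrix(list(mirnas), list(diseases), values)


def read_association_matrix(path: str | os.PathLike) -> AssociationMatrix:
    """Read a dense labeled TSV whose body is guarded to {0, 1}."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy()
    if values.size and not np.isin(values, (0, 1)).all():
        raise ValueError(f"{path}: dense association body must contain only 0/1")
    mat = AssociationMatrix(
        [str(l).strip() for l in df.index],
        [str(l).strip() for l in df.columns],
        values,
    )
    if mat.n_positives == 0:
        raise ValueError(f"{path}: no association pairs (nothing to train on)")
    return mat


def write_associations(mat: AssociationMatrix, path: str | os.PathLike) -> None:
    """Write the positive pairs of ``mat`` as a two-column TSV."""
    with open(path, "w") as fh:
        for m, d in mat.positive_pairs():
            fh.write(f"{m}\t{d}\n")


def read_similarity_matrix(path: str | os.PathLike) -> SimilarityMatrix:
    """Read a labeled square similarity TSV.

    Asymmetries up to 1e-6 are repaired by averaging; anything larger,
    a diagonal off 1, out-of-range entries or a non-square body is an
    error (delegated to the :class:`SimilarityMatrix` invariants).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    rows = [str(l).strip() for l in df.index]
    cols = [str(l).strip() for l in df.columns]
    if rows != cols:
        raise ValueError(f"{path}: row labels differ from column labels")
    try:
        return SimilarityMatrix(rows, df.to_numpy(dtype=float))
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_similarity_matrix(sim: SimilarityMatrix, path: str | os.PathLike) -> None:
    pd.DataFrame(sim.values, index=sim.labels, columns=sim.labels).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def read_dag(path: str | os.PathLike) -> DiseaseOntology:
    """Read a child→parent TSV edge list into a disease ontology.

    Single-field rows declare isolated root terms.  Self-edges and
    cycles are rejected.
    """
    edges: list[tuple[str, str]] = []
    isolated: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t") if f.strip()]
            if len(fields) == 1:
                isolated.append(fields[0])
            elif len(fields) == 2:
                edges.append((fields[0], fields[1]))
            else:
                raise ValueError(
                    f"{path}:{lineno}: expected 1 or 2 fields, got {line!r}"
                )
    return DiseaseOntology.from_edges(edges, isolated=isolated)


def write_scores(scores: ScoreMatrix, path: str | os.PathLike) -> None:
    """Write the full labeled score matrix as TSV."""
    pd.DataFrame(
        scores.scores, index=scores.mirna_labels, columns=scores.disease_labels
    ).to_csv(path, sep="\t", float_format="%.10g")


def write_ranking(
    ranked: Sequence[tuple[str, float]], path: str | os.PathLike
) -> None:
    """Write a candidate ranking as ``rank, miRNA, score`` TSV (descending)."""
    with open(path, "w") as fh:
        fh.write("rank\tmirna\tscore\n")
        for rank, (label, score) in enumerate(ranked, start=1):
            fh.write(f"{rank}\t{label}\t{score:.10g}\n")
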