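"""Restrict MS, DS and R to their common entity sets.

The three inputs typically come from different sources (sequence files,
an ontology, an association database) and need not agree on entities.
Fusion keeps the miRNAs present in both MS and R and the diseases
present in both DS and R, then prunes entities left without a single
confirmed association, so that training sees a mutually consistent
triple.  Diseases with zero positives can optionally be retained — that
is what new-disease prediction needs, since such a disease's factor is
driven purely by the similarity coupling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .types import AssociationMatrix, SimilarityMatrix

__all__ = ["FusionReport", "fuse"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FusionReport:
    n_mirnas: int
    n_diseases: int
    n_positives: int
    dropped_mirnas: int
    dropped_diseases: int
    dropped_positives: int

    def __str__(self) -> str:
        return (
            f"fused: {self.n_mirnas} miRNAs, {self.n_diseases} diseases, "
            f"{self.n_positives} associations "
            f"(dropped {self.dropped_mirnas}/{self.dropped_diseases}/"
            f"{self.dropped_positives})"
        )


def fuse(
    MS: SimilarityMatrix,
    DS: SimilarityMatrix,
    R: AssociationMatrix,
    keep_zero_diseases: bool = False,
) -> tuple[SimilarityMatrix, SimilarityMatrix, AssociationMatrix, FusionReport]:
    """Intersect entity sets and prune zero-association rows/columns.

    Returns restricted (MS, DS, R) with consistent ordered labels plus a
    report of what was kept and dropped.  Idempotent.  Raises if either
    entity intersection is empty.
    """
    mirnas = [m for m in R.mirna_labels if m in set(MS.labels)]
    diseases = [d for d in R.disease_labels if d in set(DS.labels)]
    if not mirnas:
        raise ValueError("no miRNA appears in both MS and R")
    if not diseases:
        raise ValueError("no disease appears in both DS and R")

    mi = [R.mirna_labels.index(m) for m in mirnas]
    dj = [R.disease_labels.index(d) for d in diseases]
    values = R.values[np.ix_(mi, dj)]

    # iterate: dropping a zero row can zero out a column and vice versa
    while True:
        keep_m = values.sum(axis=1) > 0
        keep_d = (
            np.ones(values.shape[1], bool)
            if keep_zero_diseases
            else values.sum(axis=0) > 0
        )
        if keep_m.all() and keep_d.all():
            break
        mirnas = [m for m, k in zip(mirnas, keep_m) if k]
        diseases = [d for d, k in zip(diseases, keep_d) if k]
        values = values[np.ix_(keep_m.nonzero()[0], keep_d.nonzero()[0])]
        if not mirnas or not diseases:
            raise ValueError("fusion left no entities with associations")

    fused_R = AssociationMatrix(mirnas, diseases, values)
    report = FusionReport(
        n_mirnas=len(mirnas),
        n_diseases=len(diseases),
        n_positives=fused_R.n_positives,
        dropped_mirnas=len(R.mirna_labels) - len(mirnas),
        dropped_diseases=len(R.disease_labels) - len(diseases),
        dropped_positives=R.n_positives - fused_R.n_positives,
    )
    logger.info("%s", report)
    return MS.restrict(mirnas), DS.restrict(diseases), fused_R, report
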