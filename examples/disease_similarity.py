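"""Wang semantic similarity over a small disease ontology.

Builds a five-term ontology (two sibling leaf diseases under one branch,
one disease on a separate branch) and prints contribution values,
semantic values, and the pairwise similarity matrix at delta = 0.5.
"""

from lfemda import (
    SemanticConfig,
    build_disease_similarity,
    contribution_values,
    semantic_value,
)
from lfemda.types import DiseaseOntology

# child -> parent edges: root splits into two branches; breast and lung
# neoplasms share the "neoplasms" branch, cardiomyopathy sits apart
ontology = DiseaseOntology.from_edges([
    ("neoplasms", "disease-root"),
    ("heart-disease", "disease-root"),
    ("breast-neoplasms", "neoplasms"),
    ("lung-neoplasms", "neoplasms"),
    ("cardiomyopathy", "heart-disease"),
])

config = SemanticConfig(delta=0.5)
for disease in ("breast-neoplasms", "cardiomyopathy"):
    cv = contribution_values(ontology, disease, config)
    dv = semantic_value(ontology, disease, config)
    print(f"{disease}: DV = {dv:.3f}, contributions "
          + ", ".join(f"{t}={v:.3g}" for t, v in sorted(cv.items())))

diseases = ["breast-neoplasms", "lung-neoplasms", "cardiomyopathy"]
DS = build_disease_similarity(ontology, diseases, config)
print("\nsemantic similarity matrix DS:")
for lab, row in zip(DS.labels, DS.values):
    print(f"  {lab:18s} " + " ".join(f"{v:.4f}" for v in row))

# Siblings share "neoplasms" and the root, so their similarity is high;
# the cardiomyopathy pair shares only the root, giving a smaller value.
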