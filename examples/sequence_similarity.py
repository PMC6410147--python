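"""Sequence-derived miRNA functional similarity on a real pair.

Computes the insertion/deletion-only edit distance between the mature
sequences of hsa-mir-21 and hsa-mir-155 and converts it into the
similarity score SM = 1 - dist/(len1+len2).
"""

from lfemda import build_mirna_similarity, levenshtein_prime, sequence_similarity
from lfemda.types import MiRNARecord

mir21 = MiRNARecord("hsa-mir-21", "CAACACCAGUCGAUGGGCUGU")
mir155 = MiRNARecord("hsa-mir-155", "CUCCUACAUAUUAGCAUUAACA")

res = levenshtein_prime(mir21.sequence, mir155.sequence)
print(f"lengths: {res.len1} and {res.len2}")
print(f"indel edit distance: {res.distance}")
print(f"similarity SM = 1 - {res.distance}/{res.len1 + res.len2} "
      f"= {sequence_similarity(mir21.sequence, mir155.sequence):.4f}")

MS = build_mirna_similarity([mir21, mir155])
print("\npairwise similarity matrix MS:")
for lab, row in zip(MS.labels, MS.values):
    print(f"  {lab:12s} " + " ".join(f"{v:.4f}" for v in row))

# A score of 1 means identical sequences; 0 means no shared subsequence.
# 0.5581 says these two share a 12-base common subsequence across 43 bases.
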