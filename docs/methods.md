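# Methods

## Model

`lfemda` factorizes a binary miRNA–disease association matrix R
(m miRNAs × d diseases) into latent factors M (m×k) and D (d×k) under
side information: a miRNA sequence-similarity matrix MS and a disease
semantic-similarity matrix DS. The fitted score of pair (i, j) is the
inner product M_i·D_j, and only the relative order of scores is
interpreted.

The training objective sums six terms: squared residuals (M_i·D_j − 1)²
over the *confirmed positives only* — unknown pairs contribute nothing,
which is the positive-only learning assumption; ridge penalties
λ0(‖M‖² + ‖D‖²); similarity-matching penalties λ1‖M Xᵀ − MS‖² and
λ2‖D Yᵀ − DS‖²; and couplings μ1‖M − X‖², μ2‖D − Y‖² tying the
auxiliary matrices X, Y to M, D. Without the auxiliaries, matching
M Mᵀ to MS is quartic in M and has no closed-form block update;
with them, each of the four blocks minimizes a convex quadratic:

- row-wise for M: M_i solves the k×k system
  (Σ_{j:R_ij=1} D_jᵀD_j + (λ0+μ1)I + λ1 XᵀX) with right-hand side
  Σ_j D_j + λ1 MS_i X + μ1 X_i, and symmetrically for D;
- whole-matrix for X: X = (λ1 MS M + μ1 M)(λ1 MᵀM + μ1 I)⁻¹, and
  symmetrically for Y.

A training sweep updates M, D, X, Y in that order and recomputes the
loss. Because each block update is the exact minimizer of its
subproblem, the per-sweep loss is non-increasing; the tests assert this
to 1e-9 slack and check every closed form against a generic numerical
quadratic minimizer built by exact finite differencing.

An entity with no positives (a "new disease") still receives a
well-defined update driven by its similarity row and the coupling —
this is what makes the new-disease evaluation protocol possible.

## Input similarities

**miRNA similarity** is computed from mature sequences as
SM = 1 − dist/(len1 + len2), where dist is the insertion/deletion-only
edit distance (substitutions disallowed; equal to
len1 + len2 − 2·LCS). This distance — not standard Levenshtein — is
the one bounded by the *summed* lengths, which is what the similarity
normalization requires; on the documented example pair
(hsa-mir-21/hsa-mir-155, lengths 21/22) it gives distance 19 and
similarity 0.5581, whereas standard Levenshtein would give 14. The
standard variant remains available (`variant="levenshtein"`,
CLI `--similarity levenshtein`) for sensitivity analysis. A
precomputed similarity matrix (e.g. a MISIM export converted to
labeled TSV) can be swapped in through `read_similarity_matrix`.

**Disease similarity** is the Wang measure over a child→parent
ontology DAG. For disease D, the closure T(D) holds D and its
ancestors; contributions follow C_D(D)=1 and
C_D(t) = max{Δ·C_D(t′) : t′ child of t within T(D)} — children outside
the closure are ignored, since contribution flows only along paths to
D, and multiple inheritance takes the max, never a sum. Similarity of
two diseases is the shared contribution mass normalized by the sum of
their semantic values DV. Δ defaults to 0.5. SD is symmetric, lies in
[0, 1], and equals 1 on the diagonal; positive semidefiniteness is not
guaranteed and not assumed anywhere. SD is monotone non-decreasing in
Δ for pairs with shared proper ancestors where neither term is an
ancestor of the other; for ancestor-related pairs the descendant
contributes a Δ-independent constant and monotonicity can genuinely
fail, so the property is only asserted under that precondition.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | 50 | latent dimension; no reference value exists, and the synthetic experiments use the planted rank (4) |
| λ0 | 6.0 | ridge weight on M, D |
| λ1, λ2 | 0.1 | similarity-matching weights (MS, DS) |
| μ1, μ2 | 3.0 | auxiliary coupling weights |
| Δ | 0.5 | per-edge semantic decay |
| ε | 1e-6 | convergence tolerance on the loss change |
| max_iter | 500 | sweep cap |

λ0, λ1, λ2, μ1, μ2 are the reference setting. Convergence uses the
relative criterion |ΔL| ≤ ε·max(1, L) by default because the loss
scale grows with problem size; the absolute criterion |ΔL| ≤ ε is
selectable (`convergence="absolute"`). Initialization draws all factor
entries i.i.d. uniform(0, 1/√k) — inner products start O(1) at any
k — with X, Y starting as copies of M, D so the first sweep begins
from a coupled state; everything is seeded. Linear systems are solved
by factorization (batched `numpy.linalg.solve`), never by explicit
inversion; all system matrices are SPD whenever λ0+μ1 (resp. λ0+μ2)
and μ1 (resp. μ2) are positive, and a singular system raises an error
advising nonzero regularization. MS and DS enter the loss unscaled.

## Evaluation protocols

LOOCV removes each known positive in turn, retrains from the same seed
and hyperparameters (warm-starting from the full fit is available but
off by default because the held-out pair leaks into the start point),
and ranks the held-out pair against candidates. The default candidate
pool is the *same disease's* unknown pairs, matching disease-wise
reporting; a global pool over all unknown pairs is a flag. AUC uses
the Mann–Whitney rank formulation with midrank tie handling, and the
ROC curve is built by a threshold sweep grouped at tied scores so its
trapezoidal area equals the rank AUC exactly. `loocv_per_disease` with
`min_assoc=1` realizes the new-disease protocol: the disease under
evaluation trains with zero positives.

## Synthetic data

The generator embodies the model's own assumptions so that recovery
failures indict the implementation, not model misspecification. True
factors are i.i.d. uniform(0, 1) (non-negative, as the model's
similarity-matching interpretation expects); MS and DS are the clipped
Gram matrices of the row-normalized true factors (cosine similarity of
factor profiles); positives are planted at the top ⌈density·m·d⌉
entries of true_M·true_Dᵀ plus Gaussian noise, and a fraction of them
is moved to a held-out list. Defaults (m=40, d=30, rank 4, density
0.08, noise sd 0.1, 10% holdout) define the standard recovery
experiment: training at k=4 with the reference weights reaches
held-out AUC ≥ 0.90 in at least 18 of 20 seeds (the acceptance suite
runs exactly this).

A global top-n cut at low density routinely leaves some entity with no
positive. That is deliberate and harmless — such entities are the
new-disease case — so coverage is *not* enforced by default;
`require_coverage=True` redraws up to 10 times (and then errors) for
callers that need every entity covered, e.g. fixtures that must
survive fusion pruning, and additionally protects sole positives from
being held out. Forcing coverage into the planted set itself (e.g.
planting each entity's best pair regardless of its score) was tried
and rejected: it pollutes the positives with low-true-score pairs and
changes what the recovery experiment measures.

Sequence families are produced by per-site mutation of a random
ancestor (substitution 80% of mutation events, insertion/deletion 10%
each) at a configurable rate, default length 22 nt — typical of mature
miRNAs. The ontology generator emits layered DAGs with 1–2 parents per
non-root node. Neither mimics real miRBase composition statistics or
MeSH topology: passing tests demonstrate correctness of the machinery
under the model's assumptions, not performance on real HMDD-scale data,
whose label noise, popularity bias and similarity misspecification the
fixtures do not emulate.

## Numerical and design notes

- Dense association TSVs are accepted alongside pair lists; labels
  match exactly (case-sensitive, surrounding whitespace trimmed), with
  no fuzzy disease-name resolution.
- Similarity matrices repair asymmetries up to 1e-6 by averaging and
  reject anything larger; diagonals must be 1 to the same tolerance.
- Fusion intersects entity sets, then iteratively prunes zero-positive
  rows/columns (a drop on one side can create a zero on the other);
  zero-positive diseases can be retained for new-disease scoring.
- Candidate rankings exclude known positives and break score ties by
  miRNA label, so output is fully deterministic.
- T→U transliteration on FASTA input; any other non-ACGU character is
  an error with its position.
- The model archive is a single JSON file holding factors, labels,
  hyperparameters and the loss trajectory, so prediction can never
  silently mismatch labels with factors.

## Known limitations

- LOOCV retrains once per positive; at HMDD scale (thousands of
  positives) this is expensive and the warm-start flag trades leakage
  for speed. The packaged experiments use planted instances of a few
  hundred pairs.
- The indel-only distance treats all bases equally; no biological
  substitution scoring or alignment weighting.
- Scores are not calibrated probabilities, and AUC comparisons across
  differently-fused datasets are not meaningful.
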