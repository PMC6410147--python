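"""Positive-only latent-factor model with auxiliary-variable ALS.

Known associations are the only supervised signal: the squared residual
is summed over confirmed (miRNA, disease) pairs alone, never over the
unknown zeros.  Each miRNA i and disease j gets a k-dimensional latent
vector (rows of M and D) whose inner product scores the pair.  Prior
knowledge enters through similarity-matching penalties ||M X^T - MS||
and ||D Y^T - DS||, where X and Y are auxiliary copies of M and D tied
to them by ||M - X|| and ||D - Y|| couplings; the auxiliaries remove
the quartic terms that a direct ||M M^T - MS|| penalty would create, so
every block subproblem is a convex quadratic with a closed-form
minimizer.  The full objective is

    L = sum_{R_ij = 1} (M_i D_j^T - 1)^2
      + lambda0 (||M||_F^2 + ||D||_F^2)
      + lambda1 ||M X^T - MS||_F^2 + lambda2 ||D Y^T - DS||_F^2
      + mu1 ||M - X||_F^2 + mu2 ||D - Y||_F^2,

minimized by exact block-coordinate descent in the order M, D, X, Y,
which makes the per-sweep loss monotonically non-increasing.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .types import AssociationMatrix, ScoreMatrix, SimilarityMatrix

__all__ = [
    "Hyperparameters",
    "LatentState",
    "TrainedModel",
    "initialize",
    "loss",
    "update_M",
    "update_D",
    "update_X",
    "update_Y",
    "train",
    "fit",
    "predict",
    "rank_candidates",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Hyperparameters:
    """Weights of the objective and training controls.

    Defaults follow the reference setting lambda0=6.0, lambda1=lambda2=0.1,
    mu1=mu2=3.0.  ``k`` (latent dimension) and ``epsilon`` have no
    reference value; defaults are declared here.  ``convergence`` selects
    between a relative loss-change criterion |dL| <= epsilon*max(1, L)
    (scale-robust, default) and the absolute |dL| <= epsilon.
    """

    k: int = 50
    lambda0: float = 6.0
    lambda1: float = 0.1
    lambda2: float = 0.1
    mu1: float = 3.0
    mu2: float = 3.0
    epsilon: float = 1e-6
    max_iter: int = 500
    seed: int = 0
    convergence: str = "relative"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        for name in ("lambda0", "lambda1", "lambda2", "mu1", "mu2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.convergence not in ("relative", "absolute"):
            raise ValueError("convergence must be 'relative' or 'absolute'")


@dataclass
class LatentState:
    """Factor matrices M (miRNA-by-k), D (disease-by-k) and auxiliaries X, Y."""

    M: np.ndarray
    D: np.ndarray
    X: np.ndarray
    Y: np.ndarray

    def __post_init__(self) -> None:
        k = self.M.shape[1]
        if not (
            self.D.shape[1] == k
            and self.X.shape == self.M.shape
            and self.Y.shape == self.D.shape
        ):
            raise ValueError("inconsistent latent dimensions across M, D, X, Y")

    def copy(self) -> "LatentState":
        return LatentState(self.M.copy(), self.D.copy(), self.X.copy(), self.Y.copy())


def initialize(m: int, d: int, hp: Hyperparameters) -> LatentState:
    """Seeded uniform(0, 1/sqrt(k)) factors with X, Y starting as copies of M, D.

    The 1/sqrt(k) scale keeps initial inner products O(1) regardless of k;
    starting the auxiliaries at their coupled targets makes the first sweep
    begin from a feasible coupled state.
    """
    if m < 1 or d < 1:
        raise ValueError("need at least one miRNA and one disease")
    rng = np.random.default_rng(hp.seed)
    scale = 1.0 / np.sqrt(hp.k)
    M = rng.uniform(0.0, scale, size=(m, hp.k))
    D = rng.uniform(0.0, scale, size=(d, hp.k))
    return LatentState(M, D, M.copy(), D.copy())


def _as_float(R: AssociationMatrix) -> np.ndarray:
    return R.values.astype(float)


def loss(
    state: LatentState,
    R: AssociationMatrix,
    MS: SimilarityMatrix,
    DS: SimilarityMatrix,
    hp: Hyperparameters,
) -> float:
    M, D, X, Y = state.M, state.D, state.X, state.Y
    mask = R.values.astype(bool)
    resid = (M @ D.T)[mask] - 1.0
    val = float(resid @ resid)
    val += hp.lambda0 * (np.sum(M * M) + np.sum(D * D))
    val += hp.lambda1 * np.sum((M @ X.T - MS.values) ** 2)
    val += hp.lambda2 * np.sum((D @ Y.T - DS.values) ** 2)
    val += hp.mu1 * np.sum((M - X) ** 2)
    val += hp.mu2 * np.sum((D - Y) ** 2)
    return val


def _solve_rows(
    Rf: np.ndarray,
    other: np.ndarray,
    S: np.ndarray,
    aux: np.ndarray,
    lam_sim: float,
    lam_norm: float,
    mu: float,
) -> np.ndarray:
    """Row-wise exact minimizer shared by the M and D updates.

    For each entity i:  v_i (sum_{pos} o_j^T o_j + (lam_norm+mu) I
    + lam_sim aux^T aux) = sum_{pos} o_j + lam_sim S_i aux + mu aux_i.
    Solved as batched k-by-k linear systems; rows with no positives are
    driven by the similarity and coupling terms alone.
    """
    k = other.shape[1]
    shared = lam_sim * (aux.T @ aux) + (lam_norm + mu) * np.eye(k)
    # per-row Gram of the positive partners: A_i = other^T diag(Rf_i) other
    A = np.einsum("ij,jk,jl->ikl", Rf, other, other) + shared
    B = Rf @ other + lam_sim * (S @ aux) + mu * aux
    try:
        return np.linalg.solve(A, B[..., None])[..., 0]
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "singular block system: an entity without positives has no data "
            "term; use nonzero regularization (lambda0, mu1/mu2 or "
            "lambda1/lambda2)"
        ) from None


def update_M(
    state: LatentState,
    R: AssociationMatrix,
    MS: SimilarityMatrix,
    hp: Hyperparameters,
) -> np.ndarray:
    """Exact minimizer of the loss over M with D, X, Y fixed."""
    return _solve_rows(
        _as_float(R), state.D, MS.values, state.X, hp.lambda1, hp.lambda0, hp.mu1
    )


def update_D(
    state: LatentState,
    R: AssociationMatrix,
    DS: SimilarityMatrix,
    hp: Hyperparameters,
) -> np.ndarray:
    """Exact minimizer over D; a zero-positive disease is still well defined."""
    return _solve_rows(
        _as_float(R).T, state.M, DS.values, state.Y, hp.lambda2, hp.lambda0, hp.mu2
    )


def _solve_aux(F: np.ndarray, S: np.ndarray, lam: float, mu: float) -> np.ndarray:
    """Minimize lam ||F A^T - S||^2 + mu ||F - A||^2 over A (all rows at once)."""
    if lam == 0.0:
        # only the coupling remains (or, with mu also 0, the subproblem is
        # constant): A = F is the minimizer in either case
        return F.copy()
    k = F.shape[1]
    G = lam * (F.T @ F) + mu * np.eye(k)
    rhs = lam * (S @ F) + mu * F
    try:
        return np.linalg.solve(G, rhs.T).T
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "singular auxiliary system: mu1/mu2 must be > 0 when the factor "
            "matrix is rank-deficient"
        ) from None


def update_X(state: LatentState, MS: SimilarityMatrix, hp: Hyperparameters) -> np.ndarray:
    """Exact minimizer over the miRNA auxiliary X given M."""
    return _solve_aux(state.M, MS.values, hp.lambda1, hp.mu1)


def update_Y(state: LatentState, DS: SimilarityMatrix, hp: Hyperparameters) -> np.ndarray:
    """Exact minimizer over the disease auxiliary Y given D."""
    return _solve_aux(state.D, DS.values, hp.lambda2, hp.mu2)


def train(
    R: AssociationMatrix,
    MS: SimilarityMatrix,
    DS: SimilarityMatrix,
    hp: Hyperparameters,
    init: LatentState | None = None,
) -> tuple[LatentState, list[float]]:
    """Block-coordinate descent: sweep M, D, X, Y until the loss stalls.

    Returns the final state and the loss trajectory (initial loss followed
    by one value per completed sweep).  The trajectory is non-increasing
    because every block update is the exact minimizer of its convex
    quadratic subproblem.  ``init`` warm-starts from an existing state
    instead of the seeded random initialization.
    """
    m, d = len(R.mirna_labels), len(R.disease_labels)
    if MS.n != m or DS.n != d:
        raise ValueError("MS/DS dimensions do not match R; run fuse() first")
    if R.n_positives < 1:
        raise ValueError("association matrix has no positives")

    state = init.copy() if init is not None else initialize(m, d, hp)
    trajectory = [loss(state, R, MS, DS, hp)]
    for sweep in range(hp.max_iter):
        state.M = update_M(state, R, MS, hp)
        state.D = update_D(state, R, DS, hp)
        state.X = update_X(state, MS, hp)
        state.Y = update_Y(state, DS, hp)
        current = loss(state, R, MS, DS, hp)
        if not np.isfinite(current):
            raise FloatingPointError(
                "loss diverged to a non-finite value; check hyperparameters"
            )
        trajectory.append(current)
        delta = abs(trajectory[-2] - current)
        logger.info("sweep %d: loss %.6g (delta %.3g)", sweep + 1, current, delta)
        tol = (
            hp.epsilon * max(1.0, current)
            if hp.convergence == "relative"
            else hp.epsilon
        )
        if delta <= tol:
            break
    return state, trajectory


def predict(
    state: LatentState,
    mirna_labels: list[str],
    disease_labels: list[str],
) -> ScoreMatrix:
    """Score every (miRNA, disease) pair as the inner product M_i . D_j.

    Scores are comparative only: larger means a more plausible
    association, but the value is not a probability.
    """
    return ScoreMatrix(list(mirna_labels), list(disease_labels), state.M @ state.D.T)


def rank_candidates(
    scores: ScoreMatrix,
    R: AssociationMatrix,
    disease: str,
    top_n: int | None = None,
) -> list[tuple[str, float]]:
    """Rank unknown miRNAs for one disease by descending score.

    Known positives are excluded; ties break by miRNA label so the
    ranking is fully deterministic.
    """
    if disease not in scores.disease_labels:
        raise KeyError(f"unknown disease {disease!r}")
    j = scores.disease_labels.index(disease)
    jr = R.disease_labels.index(disease)
    cand = [
        (scores.mirna_labels[i], float(scores.scores[i, j]))
        for i in range(len(scores.mirna_labels))
        if R.values[R.mirna_labels.index(scores.mirna_labels[i]), jr] == 0
    ]
    cand.sort(key=lambda t: (-t[1], t[0]))
    return cand if top_n is None else cand[:top_n]


@dataclass
class TrainedModel:
    """A fitted model with the labels and settings it was trained under.

    Serializes to a single JSON archive so prediction and evaluation can
    never silently mismatch labels with factors.
    """

    state: LatentState
    mirna_labels: list[str]
    disease_labels: list[str]
    hyperparameters: Hyperparameters
    trajectory: list[float] = field(default_factory=list)

    def predict(self) -> ScoreMatrix:
        return predict(self.state, self.mirna_labels, self.disease_labels)

    def save(self, path: str | os.PathLike) -> None:
        payload = {
            "mirna_labels": self.mirna_labels,
            "disease_labels": self.disease_labels,
            "hyperparameters": asdict(self.hyperparameters),
            "trajectory": self.trajectory,
            "M": self.state.M.tolist(),
            "D": self.state.D.tolist(),
            "X": self.state.X.tolist(),
            "Y": self.state.Y.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "TrainedModel":
        with open(path) as fh:
            payload = json.load(fh)
        state = LatentState(
            np.asarray(payload["M"], float),
            np.asarray(payload["D"], float),
            np.asarray(payload["X"], float),
            np.asarray(payload["Y"], float),
        )
        return cls(
            state,
            payload["mirna_labels"],
            payload["disease_labels"],
            Hyperparameters(**payload["hyperparameters"]),
            payload["trajectory"],
        )


def fit(
    R: AssociationMatrix,
    MS: SimilarityMatrix,
    DS: SimilarityMatrix,
    hp: Hyperparameters | None = None,
    **overrides,
) -> TrainedModel:
    """Convenience wrapper: train and package the result with its labels."""
    hp = replace(hp or Hyperparameters(), **overrides) if overrides else (hp or Hyperparameters())
    state, trajectory = train(R, MS, DS, hp)
    return TrainedModel(state, list(R.mirna_labels), list(R.disease_labels), hp, trajectory)
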