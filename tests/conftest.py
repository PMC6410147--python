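"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the code paths they check: the
quadratic minimizer differentiates the black-box loss numerically, the
LCS oracle is a plain recursion, and the Mann-Whitney oracle counts
pairs one by one.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest

from lfemda.types import AssociationMatrix, SimilarityMatrix

# the two sequences printed in the method's worked example
MIR21 = "CAACACCAGUCGAUGGGCUGU"
MIR155 = "CUCCUACAUAUUAGCAUUAACA"


def quadratic_minimizer(f, n: int) -> np.ndarray:
    """Exact minimizer of a quadratic function of n variables.

    Central differences with unit step recover the gradient and Hessian
    of a quadratic exactly (up to floating roundoff); the minimizer is
    then one linear solve.  Independent of any closed-form update.
    """
    eye = np.eye(n)
    f0 = f(np.zeros(n))
    fp = np.array([f(eye[i]) for i in range(n)])
    fm = np.array([f(-eye[i]) for i in range(n)])
    g = (fp - fm) / 2.0
    H = np.diag(fp + fm - 2.0 * f0)
    for i in range(n):
        for j in range(i + 1, n):
            H[i, j] = H[j, i] = f(eye[i] + eye[j]) - fp[i] - fp[j] + f0
    return np.linalg.solve(H, -g)


def lcs_recursive(s1: str, s2: str) -> int:
    """Longest common subsequence by memoized recursion (independent DP)."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == 0 or j == 0:
            return 0
        if s1[i - 1] == s2[j - 1]:
            return rec(i - 1, j - 1) + 1
        return max(rec(i - 1, j), rec(i, j - 1))

    return rec(len(s1), len(s2))


def mannwhitney_bruteforce(pos, neg) -> float:
    """AUC by explicit pair counting with half credit for ties."""
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def random_similarity(n: int, rng: np.random.Generator,
                      labels: list[str] | None = None) -> SimilarityMatrix:
    A = rng.random((n, n))
    S = np.clip((A + A.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(labels or [f"e{i}" for i in range(n)], S)


def random_instance(rng: np.random.Generator, m: int, d: int):
    """A random (R, MS, DS) triple with at least one positive."""
    mir = [f"m{i}" for i in range(m)]
    dis = [f"d{j}" for j in range(d)]
    Rv = (rng.random((m, d)) < 0.4).astype(np.int8)
    if Rv.sum() == 0:
        Rv[rng.integers(m), rng.integers(d)] = 1
    R = AssociationMatrix(mir, dis, Rv)
    return R, random_similarity(m, rng, mir), random_similarity(d, rng, dis)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
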