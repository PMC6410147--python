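"""Latent-factor model: loss, closed-form updates, training, prediction."""

import numpy as np
import pytest

from conftest import quadratic_minimizer, random_instance
from lfemda.core import (
    Hyperparameters,
    LatentState,
    TrainedModel,
    fit,
    initialize,
    loss,
    predict,
    rank_candidates,
    train,
    update_D,
    update_M,
    update_X,
    update_Y,
)
from lfemda.types import AssociationMatrix, SimilarityMatrix


def loss_by_hand(state, R, MS, DS, hp):
    """Independent term-by-term evaluation with explicit loops."""
    total = 0.0
    m, d = R.values.shape
    for i in range(m):
        for j in range(d):
            if R.values[i, j] == 1:
                total += (float(state.M[i] @ state.D[j]) - 1.0) ** 2
    total += hp.lambda0 * (np.sum(state.M**2) + np.sum(state.D**2))
    for i in range(m):
        for i2 in range(m):
            total += hp.lambda1 * (float(state.M[i] @ state.X[i2]) - MS.values[i, i2]) ** 2
    for j in range(d):
        for j2 in range(d):
            total += hp.lambda2 * (float(state.D[j] @ state.Y[j2]) - DS.values[j, j2]) ** 2
    total += hp.mu1 * np.sum((state.M - state.X) ** 2)
    total += hp.mu2 * np.sum((state.D - state.Y) ** 2)
    return total


def random_state(rng, m, d, k):
    return LatentState(
        rng.normal(size=(m, k)),
        rng.normal(size=(d, k)),
        rng.normal(size=(m, k)),
        rng.normal(size=(d, k)),
    )


class TestInitialize:
    def test_seed_determinism(self):
        hp = Hyperparameters(k=3, seed=7)
        a, b = initialize(4, 5, hp), initialize(4, 5, hp)
        assert np.array_equal(a.M, b.M) and np.array_equal(a.Y, b.Y)

    def test_different_seeds_differ(self):
        a = initialize(4, 5, Hyperparameters(k=3, seed=1))
        b = initialize(4, 5, Hyperparameters(k=3, seed=2))
        assert not np.array_equal(a.M, b.M)

    def test_range_and_aux_copies(self):
        st = initialize(1, 1, Hyperparameters(k=1, seed=0))
        assert 0.0 < st.M[0, 0] <= 1.0
        assert np.array_equal(st.X, st.M) and np.array_equal(st.Y, st.D)


class TestLoss:
    def test_single_positive_zero_state(self):
        R = AssociationMatrix(["m"], ["d"], np.array([[1]]))
        S1 = SimilarityMatrix(["m"], np.array([[1.0]]))
        S2 = SimilarityMatrix(["d"], np.array([[1.0]]))
        hp = Hyperparameters(k=1, lambda0=0, lambda1=0, lambda2=0, mu1=0, mu2=0)
        zeros = LatentState(*(np.zeros((1, 1)) for _ in range(4)))
        assert loss(zeros, R, S1, S2, hp) == 1.0
        exact = LatentState(np.array([[1.0]]), np.array([[1.0]]),
                            np.zeros((1, 1)), np.zeros((1, 1)))
        assert loss(exact, R, S1, S2, hp) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_term_by_term_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m, d, k = int(rng.integers(2, 6)), int(rng.integers(2, 6)), 2
        R, MS, DS = random_instance(rng, m, d)
        hp = Hyperparameters(k=k, lambda0=1.3, lambda1=0.7, lambda2=0.4,
                             mu1=2.0, mu2=0.9, seed=seed)
        st = random_state(rng, m, d, k)
        assert loss(st, R, MS, DS, hp) == pytest.approx(
            loss_by_hand(st, R, MS, DS, hp), rel=1e-10
        )


class TestBlockUpdates:
    def test_scalar_ridge_solution(self):
        """k=1, one positive, only the norm penalty: M = c/(c^2 + lambda0)."""
        R = AssociationMatrix(["m"], ["d"], np.array([[1]]))
        S = SimilarityMatrix(["m"], np.array([[1.0]]))
        hp = Hyperparameters(k=1, lambda0=0.7, lambda1=0, lambda2=0, mu1=0, mu2=0)
        c = 1.7
        st = LatentState(np.zeros((1, 1)), np.array([[c]]),
                         np.zeros((1, 1)), np.zeros((1, 1)))
        newM = update_M(st, R, S, hp)
        assert newM[0, 0] == pytest.approx(c / (c * c + 0.7), rel=1e-12)

    def test_unregularized_reduces_to_least_squares(self, rng):
        """lambda1=mu1=lambda0=0 with spanning positives: normal equations."""
        m, d, k = 3, 5, 2
        R = AssociationMatrix(
            [f"m{i}" for i in range(m)], [f"d{j}" for j in range(d)],
            np.ones((m, d), dtype=np.int8),
        )
        MS = SimilarityMatrix(R.mirna_labels, np.eye(m) * 0 + np.eye(m))
        hp = Hyperparameters(k=k, lambda0=0, lambda1=0, lambda2=0, mu1=0, mu2=0)
        st = random_state(rng, m, d, k)
        newM = update_M(st, R, MS, hp)
        expect = np.linalg.solve(st.D.T @ st.D, st.D.T @ np.ones(d))
        for i in range(m):
            assert newM[i] == pytest.approx(expect, rel=1e-9)

    def test_lambda1_zero_makes_X_equal_M(self, rng):
        st = random_state(rng, 4, 3, 2)
        MS = SimilarityMatrix([f"m{i}" for i in range(4)], np.eye(4))
        hp = Hyperparameters(k=2, lambda1=0.0, mu1=2.5)
        assert update_X(st, MS, hp) == pytest.approx(st.M)

    def test_singular_system_raises_helpful_error(self):
        R = AssociationMatrix(["m1", "m2"], ["d"], np.array([[1], [0]]))
        MS = SimilarityMatrix(["m1", "m2"], np.eye(2) + np.zeros((2, 2)))
        hp = Hyperparameters(k=1, lambda0=0, lambda1=0, lambda2=0, mu1=0, mu2=0)
        st = LatentState(np.zeros((2, 1)), np.ones((1, 1)),
                         np.zeros((2, 1)), np.ones((1, 1)))
        with pytest.raises(np.linalg.LinAlgError, match="regulari"):
            update_M(st, R, MS, hp)  # m2 has no positives, no regularization

    @pytest.mark.parametrize("seed", range(8))
    def test_each_update_matches_numerical_minimizer(self, seed):
        """Closed forms equal a generic quadratic minimizer of each subproblem."""
        rng = np.random.default_rng(seed)
        m, d = int(rng.integers(2, 7)), int(rng.integers(2, 7))
        k = int(rng.integers(1, 4))
        R, MS, DS = random_instance(rng, m, d)
        hp = Hyperparameters(
            k=k, seed=seed,
            lambda0=float(rng.uniform(0.05, 4)),
            lambda1=float(rng.uniform(0, 2)), lambda2=float(rng.uniform(0, 2)),
            mu1=float(rng.uniform(0.05, 3)), mu2=float(rng.uniform(0.05, 3)),
        )
        st = random_state(rng, m, d, k)
        blocks = {
            "M": (lambda: update_M(st, R, MS, hp), "M", (m, k)),
            "D": (lambda: update_D(st, R, DS, hp), "D", (d, k)),
            "X": (lambda: update_X(st, MS, hp), "X", (m, k)),
            "Y": (lambda: update_Y(st, DS, hp), "Y", (d, k)),
        }
        for name, (closed_fn, attr, shape) in blocks.items():
            def subloss(v, attr=attr, shape=shape):
                s2 = st.copy()
                setattr(s2, attr, v.reshape(shape))
                return loss(s2, R, MS, DS, hp)

            numeric = quadratic_minimizer(subloss, shape[0] * shape[1]).reshape(shape)
            assert np.abs(closed_fn() - numeric).max() < 1e-6, name

    @pytest.mark.parametrize("seed", range(4))
    def test_updates_never_increase_loss(self, seed):
        rng = np.random.default_rng(seed + 50)
        R, MS, DS = random_instance(rng, 5, 4)
        hp = Hyperparameters(k=2, seed=seed, lambda0=0.5, mu1=1.0, mu2=1.0)
        st = random_state(rng, 5, 4, 2)
        before = loss(st, R, MS, DS, hp)
        st.M = update_M(st, R, MS, hp)
        mid = loss(st, R, MS, DS, hp)
        assert mid <= before + 1e-9
        st.D = update_D(st, R, DS, hp)
        assert loss(st, R, MS, DS, hp) <= mid + 1e-9


class TestTrain:
    def _small(self, seed=0):
        rng = np.random.default_rng(seed)
        return random_instance(rng, 6, 5)

    def test_loss_trajectory_non_increasing(self):
        R, MS, DS = self._small()
        _, traj = train(R, MS, DS, Hyperparameters(k=2, seed=3))
        diffs = np.diff(traj)
        assert (diffs <= 1e-9).all()

    def test_huge_epsilon_single_sweep(self):
        R, MS, DS = self._small()
        _, traj = train(R, MS, DS,
                        Hyperparameters(k=2, seed=3, epsilon=1e12,
                                        convergence="absolute"))
        assert len(traj) == 2  # initial loss + one sweep

    def test_same_seed_identical_trajectories(self):
        R, MS, DS = self._small()
        hp = Hyperparameters(k=2, seed=9)
        _, t1 = train(R, MS, DS, hp)
        _, t2 = train(R, MS, DS, hp)
        assert t1 == t2

    def test_dimension_mismatch_rejected(self):
        R, MS, DS = self._small()
        bad = SimilarityMatrix(["z"], np.array([[1.0]]))
        with pytest.raises(ValueError, match="fuse"):
            train(R, bad, DS, Hyperparameters(k=2))

    def test_warm_start_init_used(self):
        R, MS, DS = self._small()
        hp = Hyperparameters(k=2, seed=3, max_iter=1)
        st1, _ = train(R, MS, DS, hp)
        st2, traj = train(R, MS, DS, hp, init=st1)
        assert traj[0] == pytest.approx(
            loss(st1, R, MS, DS, hp), rel=1e-12
        )

    def test_ridge_only_fixed_point_satisfies_normal_equations(self):
        """With all couplings 0, the converged M solves its ridge system."""
        R, MS, DS = self._small(seed=4)
        hp = Hyperparameters(k=2, seed=1, lambda0=0.5, lambda1=0, lambda2=0,
                             mu1=0, mu2=0, epsilon=1e-12, max_iter=2000)
        st, _ = train(R, MS, DS, hp)
        for i in range(len(R.mirna_labels)):
            pos = R.values[i].astype(bool)
            Dp = st.D[pos]
            lhs = st.M[i] @ (Dp.T @ Dp + hp.lambda0 * np.eye(2))
            # loss-change stopping at 1e-12 leaves ~1e-6 slack in the gradient
            assert lhs == pytest.approx(Dp.sum(axis=0), abs=1e-5)


class TestPredictAndRank:
    def test_inner_product_scores(self):
        st = LatentState(np.array([[2.0]]), np.array([[3.0]]),
                         np.zeros((1, 1)), np.zeros((1, 1)))
        sm = predict(st, ["m"], ["d"])
        assert sm.scores[0, 0] == 6.0

    def test_orthogonal_vectors_score_zero(self):
        st = LatentState(np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]]),
                         np.zeros((1, 2)), np.zeros((1, 2)))
        assert predict(st, ["m"], ["d"]).scores[0, 0] == 0.0

    def test_scores_reproduce_loss_residuals(self, rng):
        R, MS, DS = random_instance(rng, 5, 4)
        hp = Hyperparameters(k=2, seed=0, lambda0=0, lambda1=0, lambda2=0,
                             mu1=0, mu2=0)
        st = random_state(rng, 5, 4, 2)
        sm = predict(st, R.mirna_labels, R.disease_labels)
        mask = R.values.astype(bool)
        expected = float(np.sum((sm.scores[mask] - 1.0) ** 2))
        assert loss(st, R, MS, DS, hp) == pytest.approx(expected, rel=1e-12)

    def test_rank_excludes_positives_and_breaks_ties_lexicographically(self):
        R = AssociationMatrix(["a", "b", "c"], ["d1"],
                              np.array([[0], [1], [0]]))
        st = LatentState(np.array([[1.0], [9.0], [1.0]]), np.array([[1.0]]),
                         np.zeros((3, 1)), np.zeros((1, 1)))
        ranked = rank_candidates(predict(st, ["a", "b", "c"], ["d1"]), R, "d1")
        assert [r[0] for r in ranked] == ["a", "c"]  # b excluded; tie a<c

    def test_rank_unknown_disease(self):
        R = AssociationMatrix(["a"], ["d1"], np.array([[1]]))
        st = LatentState(np.ones((1, 1)), np.ones((1, 1)),
                         np.ones((1, 1)), np.ones((1, 1)))
        with pytest.raises(KeyError):
            rank_candidates(predict(st, ["a"], ["d1"]), R, "nope")

    def test_top_n_truncates(self):
        R = AssociationMatrix(["a", "b", "c"], ["d1"], np.array([[0], [0], [1]]))
        st = LatentState(np.array([[3.0], [2.0], [1.0]]), np.array([[1.0]]),
                         np.zeros((3, 1)), np.zeros((1, 1)))
        ranked = rank_candidates(predict(st, ["a", "b", "c"], ["d1"]), R, "d1", 1)
        assert ranked == [("a", 3.0)]


class TestTrainedModel:
    def test_save_load_roundtrip(self, tmp_path, rng):
        R, MS, DS = random_instance(rng, 4, 3)
        model = fit(R, MS, DS, Hyperparameters(k=2, seed=5, max_iter=10))
        path = tmp_path / "model.json"
        model.save(path)
        loaded = TrainedModel.load(path)
        assert loaded.mirna_labels == model.mirna_labels
        assert loaded.hyperparameters == model.hyperparameters
        assert np.allclose(loaded.state.M, model.state.M)
        assert np.allclose(loaded.predict().scores, model.predict().scores)
        assert loaded.trajectory == model.trajectory
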