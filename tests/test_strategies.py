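"""Query-strategy tests: scores, diversity geometry, greedy batch selection."""

import math

import numpy as np
import pytest

from alelm import (
    CandidateBatch,
    bvsb_scores,
    combined_diversity,
    cosine_similarity,
    diversity_to_set,
    entropy_scores,
    margin_scores,
    posteriors,
    random_select,
    select_batch,
    select_candidates,
    train,
)
from alelm.strategies import build_strategy, register_strategy


def greedy_oracle(features, bvsb, labeled, lam, m):
    """Independent greedy selector: plain loops, scalar cosine, argmin scan."""

    def cos(a, b):
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            return 0.0
        return float(a @ b) / (na * nb)

    picked, picked_feats, scores = [], [], []
    remaining = list(range(len(bvsb)))
    for _ in range(m):
        best_j, best_score = None, math.inf
        for j in remaining:
            div_w = max((cos(features[j], f) for f in picked_feats), default=0.0)
            div_l = max(cos(features[j], l) for l in labeled)
            s = lam * bvsb[j] + (1 - lam) * (div_w + div_l)
            if s < best_score:  # strict: ties keep the lowest index
                best_j, best_score = j, s
        picked.append(best_j)
        picked_feats.append(features[best_j])
        scores.append(best_score)
        remaining.remove(best_j)
    return picked, scores


class TestScores:
    def test_bvsb_values(self):
        P = np.array([[0.5, 0.3, 0.2], [0.25, 0.25, 0.25, 0.25][:3]])
        assert bvsb_scores(P[:1])[0] == pytest.approx(0.2)
        assert bvsb_scores(np.full((1, 4), 0.25))[0] == pytest.approx(0.0)
        assert bvsb_scores(np.array([[1.0, 0.0, 0.0]]))[0] == pytest.approx(1.0)

    def test_bvsb_requires_two_classes(self):
        with pytest.raises(ValueError):
            bvsb_scores(np.ones((3, 1)))

    def test_entropy_values(self):
        assert entropy_scores(np.array([[1.0, 0.0, 0.0]]))[0] == pytest.approx(0.0)
        assert entropy_scores(np.full((1, 4), 0.25))[0] == pytest.approx(np.log(4))
        assert entropy_scores(np.array([[0.5, 0.5]]))[0] == pytest.approx(np.log(2))

    def test_margin_values(self):
        assert margin_scores(np.array([[0.9, 0.9, -1.0]]))[0] == pytest.approx(0.0)
        assert margin_scores(np.array([[2.0, -1.0]]))[0] == pytest.approx(3.0)

    def test_margin_ordering_matches_sort_oracle(self, rng):
        F = rng.normal(size=(30, 4))
        scores = margin_scores(F)
        expected = np.sort(F, axis=1)[:, -1] - np.sort(F, axis=1)[:, -2]
        assert np.allclose(scores, expected)

    def test_scores_are_permutation_equivariant(self, rng):
        P = posteriors(rng.normal(size=(20, 3)))
        perm = rng.permutation(20)
        assert np.allclose(bvsb_scores(P)[perm], bvsb_scores(P[perm]))
        assert np.allclose(entropy_scores(P)[perm], entropy_scores(P[perm]))

    def test_score_ranges(self, rng):
        P = posteriors(rng.normal(scale=5, size=(100, 4)))
        b, e = bvsb_scores(P), entropy_scores(P)
        assert b.min() >= 0 and b.max() <= 1
        assert e.min() >= -1e-12 and e.max() <= np.log(4) + 1e-12


class TestRandomSelect:
    def test_full_pool_is_permutation(self):
        idx = random_select(5, 5, np.random.default_rng(0))
        assert sorted(idx) == [0, 1, 2, 3, 4]

    def test_seed_reproducibility(self):
        a = random_select(100, 10, np.random.default_rng(3))
        b = random_select(100, 10, np.random.default_rng(3))
        assert np.array_equal(a, b)

    def test_oversized_batch_rejected(self):
        with pytest.raises(ValueError):
            random_select(4, 5, np.random.default_rng(0))

    def test_uniform_frequency(self):
        """Over many draws each index appears ~m/pool of the time (3-sigma)."""
        rng = np.random.default_rng(42)
        pool, m, reps = 20, 4, 10_000
        counts = np.zeros(pool)
        for _ in range(reps):
            counts[random_select(pool, m, rng)] += 1
        p = m / pool
        sigma = math.sqrt(reps * p * (1 - p))
        assert np.all(np.abs(counts - reps * p) < 3.5 * sigma)


class TestCosineDiversity:
    def test_self_similarity_is_one(self, rng):
        x = rng.normal(size=5)
        assert cosine_similarity(x, x) == pytest.approx(1.0)

    def test_orthogonal_and_opposite(self):
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)
        assert cosine_similarity([1, 0], [-1, 0]) == pytest.approx(-1.0)

    def test_zero_vector_convention(self):
        assert cosine_similarity([0, 0], [1, 2]) == 0.0

    def test_scale_invariance(self, rng):
        x, y = rng.normal(size=4), rng.normal(size=4)
        assert cosine_similarity(3.7 * x, y) == pytest.approx(cosine_similarity(x, y))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cosine_similarity([1, 2], [1, 2, 3])

    def test_diversity_member_of_set(self):
        W = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert diversity_to_set(W[0], W) == pytest.approx(1.0)

    def test_diversity_45_degrees(self):
        W = np.array([[1.0, 0.0], [0.0, 1.0]])
        x = np.array([1.0, 1.0]) / np.sqrt(2)
        assert diversity_to_set(x, W) == pytest.approx(np.sqrt(2) / 2)

    def test_diversity_empty_set(self):
        assert diversity_to_set(np.array([1.0, 0.0]), np.empty((0, 2))) == 0.0

    def test_combined_diversity_duplicate_everywhere(self):
        x = np.array([2.0, 1.0])
        assert combined_diversity(x, x[None, :], x[None, :]) == pytest.approx(2.0)

    def test_combined_diversity_orthogonal(self):
        x = np.array([1.0, 0.0, 0.0])
        S = np.array([[0.0, 1.0, 0.0]])
        L = np.array([[0.0, 0.0, 1.0]])
        assert combined_diversity(x, S, L) == pytest.approx(0.0)

    def test_combined_diversity_matches_brute_force(self, rng):
        x = rng.normal(size=4)
        S = rng.normal(size=(5, 4))
        L = rng.normal(size=(7, 4))
        expected = max(cosine_similarity(x, s) for s in S) + max(
            cosine_similarity(x, l) for l in L
        )
        assert combined_diversity(x, S, L) == pytest.approx(expected)

    def test_combined_diversity_requires_labeled(self):
        with pytest.raises(ValueError):
            combined_diversity(np.ones(2), np.ones((1, 2)), np.empty((0, 2)))


class TestSelectCandidates:
    def test_whole_pool_in_bvsb_order(self, two_class_data):
        X, y = two_class_data
        model = train(X, y, M=20, seed=0)
        cand = select_candidates(model, X, h=len(X))
        scores = bvsb_scores(model.predict_proba(X))
        assert np.array_equal(cand.indices, np.argsort(scores, kind="stable"))

    def test_uniform_posterior_sample_ranked_first(self, two_class_data):
        X, y = two_class_data
        model = train(X, y, M=20, seed=0)
        # the decision boundary sits near x1 = 0; a point far along it is
        # maximally uncertain, a point deep inside a class is not
        pool = np.vstack([X[:10], [[0.0, 0.0]]])
        cand = select_candidates(model, pool, h=1)
        assert cand.indices[0] == 10

    def test_oversized_h_clamps_with_warning(self, two_class_data):
        X, y = two_class_data
        model = train(X, y, M=10, seed=0)
        with pytest.warns(UserWarning, match="clamping"):
            cand = select_candidates(model, X[:5], h=10)
        assert len(cand.indices) == 5

    def test_agrees_with_full_sort_oracle(self, small_split):
        model = train(small_split.X_labeled, small_split.y_labeled, M=25, seed=2)
        pool = small_split.X_pool
        cand = select_candidates(model, pool, h=10)
        scores = bvsb_scores(model.predict_proba(pool))
        order = sorted(range(len(pool)), key=lambda i: (scores[i], i))[:10]
        assert list(cand.indices) == order


class TestSelectBatch:
    @staticmethod
    def _random_problem(rng, h=12, p=4, n_lab=6):
        feats = rng.normal(size=(h, p))
        bvsb = rng.uniform(0, 1, size=h)
        labeled = rng.normal(size=(n_lab, p))
        return CandidateBatch(np.arange(h), feats, bvsb), labeled

    def test_lambda_one_is_top_m_bvsb(self, rng):
        W, L = self._random_problem(rng)
        batch = select_batch(W, L, lam=1.0, m=4)
        expected = np.argsort(W.bvsb, kind="stable")[:4]
        assert np.array_equal(batch.indices, expected)

    def test_lambda_zero_avoids_duplicates(self):
        """Pure diversity never takes both copies of a duplicated candidate
        while a distinct alternative with a lower score remains."""
        feats = np.array([
            [1.0, 0.0],
            [1.0, 0.0],  # exact duplicate of candidate 0
            [0.0, 1.0],
            [-1.0, 0.5],
            [0.3, -1.0],
        ])
        W = CandidateBatch(np.arange(5), feats, np.full(5, 0.5))
        L = np.array([[5.0, 5.0]])
        batch = select_batch(W, L, lam=0.0, m=3)
        assert not {0, 1} <= set(batch.indices)

    @pytest.mark.parametrize("lam", [0.0, 0.3, 0.7, 1.0])
    def test_greedy_matches_exhaustive_oracle(self, lam):
        rng = np.random.default_rng(int(lam * 10) + 1)
        for _ in range(10):
            W, L = self._random_problem(rng)
            batch = select_batch(W, L, lam=lam, m=5)
            picks, scores = greedy_oracle(W.features, W.bvsb, L, lam, 5)
            assert list(batch.indices) == picks
            assert np.allclose(batch.scores, scores)

    def test_six_candidate_worked_example(self):
        """Step-by-step scan on a printed 6-candidate fixture, lambda = 0.5."""
        feats = np.array([
            [1.0, 0.0], [0.9, 0.1], [0.0, 1.0],
            [-1.0, 0.0], [0.5, 0.5], [0.0, -1.0],
        ])
        bvsb = np.array([0.05, 0.10, 0.20, 0.30, 0.15, 0.25])
        L = np.array([[1.0, 1.0], [-1.0, 1.0]])
        W = CandidateBatch(np.arange(6), feats, bvsb)
        batch = select_batch(W, L, lam=0.5, m=2)
        picks, scores = greedy_oracle(feats, bvsb, L, 0.5, 2)
        assert list(batch.indices) == picks
        assert np.allclose(batch.scores, scores)

    def test_greedy_step_optimality(self, rng):
        """Each pick attains the step's minimum over remaining candidates."""
        W, L = self._random_problem(rng, h=20)
        batch = select_batch(W, L, lam=0.4, m=6)
        picks, scores = greedy_oracle(W.features, W.bvsb, L, 0.4, 6)
        assert np.allclose(batch.scores, scores)
        assert np.all(np.asarray(batch.scores) < np.inf)

    def test_m_exceeding_h_rejected(self, rng):
        W, L = self._random_problem(rng, h=3)
        with pytest.raises(ValueError):
            select_batch(W, L, lam=0.5, m=4)

    def test_invalid_lambda_rejected(self, rng):
        W, L = self._random_problem(rng)
        with pytest.raises(ValueError):
            select_batch(W, L, lam=1.5, m=2)


class TestRegistry:
    def test_known_strategies_registered(self):
        for name in ("d-al-elm", "al-elm", "elm-entropy", "random"):
            assert build_strategy(name) is not None

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError):
            build_strategy("does-not-exist")

    def test_user_strategy_plugs_in(self, two_class_data):
        @register_strategy("first-m")
        class FirstM:
            def select(self, model, pool, labeled, m, rng):
                return np.arange(m)

        X, y = two_class_data
        model = train(X, y, M=10, seed=0)
        idx = build_strategy("first-m").select(model, X, X, 3, None)
        assert list(idx) == [0, 1, 2]
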