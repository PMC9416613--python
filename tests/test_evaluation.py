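"""Identification metric: PCA reduction, candidates, correlation ranking, score."""

import numpy as np
import pytest

from mspgm import (
    CandidateSet,
    build_candidates,
    confidence_score,
    evaluate_testset,
    pca_reduce,
    rank_category,
)


def _data_with_variance_ratios(ratios, n=8):
    """Zero-mean data whose PCA explained-variance ratios match ``ratios``."""
    d = len(ratios)
    # orthogonal zero-mean score rows of controlled energy
    base = np.array([[1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0],
                     [1.0, 1.0, -1.0, -1.0, 1.0, 1.0, -1.0, -1.0],
                     [1.0, 1.0, 1.0, 1.0, -1.0, -1.0, -1.0, -1.0]])[:d, :n]
    scale = np.sqrt(np.asarray(ratios))
    return base * scale[:, None]


class TestPCAReduce:
    def test_hand_cumulative_sum(self):
        X = _data_with_variance_ratios([0.7, 0.2, 0.1])
        reduced, tr = pca_reduce(X, cum_ratio=0.8)
        assert tr.n_components == 2
        assert reduced.shape == (2, 8)
        np.testing.assert_allclose(
            tr.explained_variance_ratio, [0.7, 0.2], atol=1e-12
        )

    def test_first_component_suffices(self):
        X = _data_with_variance_ratios([0.85, 0.1, 0.05])
        _, tr = pca_reduce(X, cum_ratio=0.8)
        assert tr.n_components == 1

    def test_full_retention_equals_rank(self, rng):
        low_rank = rng.standard_normal((6, 2)) @ rng.standard_normal((2, 12))
        _, tr = pca_reduce(low_rank, cum_ratio=1.0)
        assert tr.n_components == 2

    def test_transform_reusable_on_new_data(self, rng):
        X = rng.standard_normal((5, 20))
        reduced, tr = pca_reduce(X, cum_ratio=0.9)
        np.testing.assert_allclose(tr.apply(X), reduced, atol=1e-10)
        y = rng.standard_normal(5)
        assert tr.apply(y).shape == (tr.n_components,)

    def test_invalid_ratio_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_reduce(rng.standard_normal((3, 5)), cum_ratio=0.0)
        with pytest.raises(ValueError):
            pca_reduce(rng.standard_normal((3, 5)), cum_ratio=1.5)


class TestBuildCandidates:
    def test_single_image_passthrough(self, rng):
        v = rng.standard_normal(4)
        w = rng.standard_normal(4)
        cands = build_candidates({"a": v, "b": w})
        np.testing.assert_allclose(cands.features[:, 0], v)

    def test_mean_of_columns(self):
        cands = build_candidates(
            {"x": np.array([[1.0, 3.0], [3.0, 5.0]]),
             "y": np.array([[0.0, 1.0], [2.0, 5.0]])}
        )
        np.testing.assert_allclose(cands.features[:, 0], [2.0, 4.0])
        np.testing.assert_allclose(cands.features[:, 1], [0.5, 3.5])

    def test_empty_category_rejected(self):
        with pytest.raises(ValueError, match="no images"):
            build_candidates({"a": np.zeros((3, 0)), "b": np.ones(3)})

    def test_duplicate_ids_and_constant_columns_rejected(self, rng):
        with pytest.raises(ValueError, match="duplicate"):
            CandidateSet(category_ids=["a", "a"], features=rng.standard_normal((3, 2)))
        with pytest.raises(ValueError, match="constant"):
            CandidateSet(
                category_ids=["a", "b"],
                features=np.column_stack([np.ones(3), rng.standard_normal(3)]),
            )


class TestRankCategory:
    def test_perfect_match_ranks_first(self, rng):
        gt_vec = rng.standard_normal(20)
        feats = np.column_stack([gt_vec] + [rng.standard_normal(20) for _ in range(4)])
        cands = CandidateSet(category_ids=list("abcde"), features=feats)
        res = rank_category(gt_vec, cands, "a")
        assert res.rank == 1 and res.score == 1.0

    def test_anticorrelated_gt_ranks_last(self, rng):
        v = rng.standard_normal(20)
        others = [v + 0.1 * rng.standard_normal(20) for _ in range(3)]
        cands = CandidateSet(
            category_ids=list("abcd"), features=np.column_stack([-v] + others)
        )
        res = rank_category(v, cands, "a")
        assert res.rank == 4 and res.score == 0.0

    def test_middle_rank_hand_case(self):
        # correlations: gt 0.5, others 0.9 and 0.1 -> G=2, S=0.5
        v = np.array([1.0, 0.0, -1.0, 0.0])

        def with_corr(r, rng):
            # construct a vector with exact correlation r to v
            perp = np.array([0.0, 1.0, 0.0, -1.0])
            return r * v / np.linalg.norm(v) + np.sqrt(1 - r**2) * perp / np.linalg.norm(perp)

        rng = np.random.default_rng(0)
        feats = np.column_stack(
            [with_corr(0.5, rng), with_corr(0.9, rng), with_corr(0.1, rng)]
        )
        cands = CandidateSet(category_ids=["gt", "hi", "lo"], features=feats)
        res = rank_category(v, cands, "gt")
        assert res.rank == 2
        assert res.score == pytest.approx(0.5)

    def test_tie_breaking_modes(self):
        v = np.array([1.0, 2.0, 3.0])
        tied = np.column_stack([v, v, np.array([3.0, 2.0, 1.0])])
        cands = CandidateSet(category_ids=["gt", "twin", "anti"], features=tied)
        assert rank_category(v, cands, "gt", ties="worst").rank == 2
        assert rank_category(v, cands, "gt", ties="best").rank == 1
        assert rank_category(v, cands, "gt", ties="mean").rank == pytest.approx(1.5)

    def test_positive_affine_rescaling_invariant(self, rng):
        v = rng.standard_normal(15)
        feats = np.column_stack([rng.standard_normal(15) for _ in range(6)])
        cands = CandidateSet(category_ids=list("abcdef"), features=feats)
        base = rank_category(v, cands, "c")
        scaled = rank_category(3.5 * v + 2.0, cands, "c")
        assert scaled.rank == base.rank
        np.testing.assert_allclose(scaled.correlations, base.correlations, atol=1e-12)

    def test_constant_estimate_rejected(self, rng):
        cands = CandidateSet(
            category_ids=["a", "b"], features=rng.standard_normal((4, 2))
        )
        with pytest.raises(ValueError, match="constant"):
            rank_category(np.ones(4), cands, "a")


class TestConfidenceScore:
    @pytest.mark.parametrize(
        "G,M,expected",
        [(1, 10000, 1.0), (10000, 10000, 0.0), (2, 3, 0.5), (1, 2, 1.0), (2, 2, 0.0)],
    )
    def test_values(self, G, M, expected):
        assert confidence_score(G, M) == pytest.approx(expected)

    def test_affine_in_rank(self):
        M = 37
        scores = [confidence_score(G, M) for G in range(1, M + 1)]
        diffs = np.diff(scores)
        np.testing.assert_allclose(diffs, diffs[0])
        assert scores[0] == 1.0 and scores[-1] == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            confidence_score(0, 10)
        with pytest.raises(ValueError):
            confidence_score(11, 10)
        with pytest.raises(ValueError):
            confidence_score(1, 1)


class TestEvaluateTestset:
    def test_perfect_predictions(self, rng):
        feats = np.column_stack([rng.standard_normal(10) for _ in range(5)])
        cands = CandidateSet(category_ids=list("abcde"), features=feats)
        summary = evaluate_testset(feats, list("abcde"), cands)
        assert summary.mean_score == 1.0

    def test_single_sample_mean(self, rng):
        feats = np.column_stack([rng.standard_normal(10) for _ in range(4)])
        cands = CandidateSet(category_ids=list("abcd"), features=feats)
        summary = evaluate_testset(feats[:, [2]], ["c"], cands)
        assert summary.mean_score == summary.results[0].score

    def test_null_estimates_score_half(self, rng):
        """Estimates independent of candidates give a uniform rank, E[S]=0.5."""
        M, n = 40, 600
        feats = np.column_stack([rng.standard_normal(25) for _ in range(M)])
        cands = CandidateSet(category_ids=list(range(M)), features=feats)
        est = rng.standard_normal((25, n))
        labels = [int(rng.integers(0, M)) for _ in range(n)]
        summary = evaluate_testset(est, labels, cands)
        # uniform rank on {1..M}: sd of S is ~sqrt(1/12)/sqrt(n)
        se = np.sqrt(1.0 / 12.0) / np.sqrt(n)
        assert abs(summary.mean_score - 0.5) < 3 * se
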