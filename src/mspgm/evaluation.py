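"""Category identification by correlation ranking of decoded visual features.

Visual features are first reduced by PCA to the smallest dimension whose
cumulative explained-variance ratio reaches a threshold (0.8 by default), the
transform being fitted on training samples only.  Candidate features are
per-category means of image feature vectors.  A decoded feature vector is
scored by its Pearson correlation with every candidate; the ground-truth
category's 1-based position ``G`` in the descending correlation order yields
the confidence category score

    S = (M - G) / (M - 1),

which is 1 when the true category ranks first among the ``M`` candidates and
0 when it ranks last.  Under the null (estimates unrelated to candidates) the
rank is uniform, so the expected score is 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
from sklearn.decomposition import PCA

__all__ = [
    "PCATransform",
    "pca_reduce",
    "CandidateSet",
    "build_candidates",
    "IdentificationResult",
    "rank_category",
    "confidence_score",
    "TestSetSummary",
    "evaluate_testset",
]


@dataclass
class PCATransform:
    """Fitted PCA projection (mean + components), reusable on held-out data."""

    mean: np.ndarray        # d_raw
    components: np.ndarray  # d_v x d_raw
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def apply(self, features: np.ndarray) -> np.ndarray:
        """Project ``d_raw x m`` columns into the retained component space."""
        features = np.asarray(features, dtype=float)
        squeeze = features.ndim == 1
        X = features[:, None] if squeeze else features
        if X.shape[0] != self.mean.shape[0]:
            raise ValueError(
                f"features have {X.shape[0]} rows, expected {self.mean.shape[0]}"
            )
        out = self.components @ (X - self.mean[:, None])
        return out[:, 0] if squeeze else out


def pca_reduce(
    features: np.ndarray, cum_ratio: float = 0.8
) -> tuple[np.ndarray, PCATransform]:
    """Reduce ``d_raw x N`` features to the fewest principal components whose
    cumulative explained-variance ratio reaches ``cum_ratio``.

    Returns the reduced training features (``d_v x N``) and the fitted
    transform to apply unchanged to validation/test data.
    """
    if not 0.0 < cum_ratio <= 1.0:
        raise ValueError("cum_ratio must lie in (0, 1]")
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] < 2:
        raise ValueError("features must be a 2-d matrix with at least 2 samples")
    pca = PCA(svd_solver="full")
    pca.fit(features.T)
    cum = np.cumsum(pca.explained_variance_ratio_)
    d_v = int(np.searchsorted(cum, cum_ratio - 1e-12) + 1)
    d_v = min(d_v, cum.size)
    transform = PCATransform(
        mean=pca.mean_.copy(),
        components=pca.components_[:d_v].copy(),
        explained_variance_ratio=pca.explained_variance_ratio_[:d_v].copy(),
    )
    return transform.apply(features), transform


@dataclass
class CandidateSet:
    """Per-category mean visual features to rank decoded estimates against."""

    category_ids: list
    features: np.ndarray  # d_v x M

    def __post_init__(self) -> None:
        self.category_ids = list(self.category_ids)
        self.features = np.asarray(self.features, dtype=float)
        M = len(self.category_ids)
        if M < 2:
            raise ValueError("need at least 2 candidate categories")
        if len(set(self.category_ids)) != M:
            raise ValueError("duplicate category ids in candidate set")
        if self.features.ndim != 2 or self.features.shape[1] != M:
            raise ValueError("features must be d_v x M, one column per category")
        if np.any(self.features.std(axis=0) == 0):
            raise ValueError(
                "a candidate column is constant; its correlation is undefined"
            )

    @property
    def n_categories(self) -> int:
        return len(self.category_ids)

    def index_of(self, category) -> int:
        try:
            return self.category_ids.index(category)
        except ValueError:
            raise KeyError(f"category {category!r} not in candidate set") from None


def build_candidates(
    features_by_category: Mapping[Hashable, np.ndarray]
) -> CandidateSet:
    """Average each category's image features into one candidate column."""
    ids, cols = [], []
    for cat, feats in features_by_category.items():
        F = np.asarray(feats, dtype=float)
        if F.ndim == 1:
            F = F[:, None]
        if F.shape[1] == 0:
            raise ValueError(f"category {cat!r} has no images")
        ids.append(cat)
        cols.append(F.mean(axis=1))
    return CandidateSet(category_ids=ids, features=np.column_stack(cols))


@dataclass
class IdentificationResult:
    """Outcome of ranking one decoded sample against the candidate set."""

    gt_category: Hashable
    rank: int
    score: float
    correlations: np.ndarray


def _pearson_against_columns(v: np.ndarray, F: np.ndarray) -> np.ndarray:
    vc = v - v.mean()
    denom_v = np.linalg.norm(vc)
    Fc = F - F.mean(axis=0, keepdims=True)
    denom_f = np.linalg.norm(Fc, axis=0)
    return (Fc.T @ vc) / (denom_v * denom_f)


def rank_category(
    v_est: np.ndarray,
    candidates: CandidateSet,
    gt: Hashable,
    ties: str = "worst",
) -> IdentificationResult:
    """Rank the ground-truth category by Pearson correlation with ``v_est``.

    Candidates are sorted by descending correlation; ``G`` is the ground
    truth's 1-based position.  Exact correlation ties are resolved per
    ``ties``: ``'worst'`` (default) gives the ground truth the largest rank in
    the tied block, ``'best'`` the smallest, ``'mean'`` the block average.
    """
    v = np.asarray(v_est, dtype=float).ravel()
    if v.shape[0] != candidates.features.shape[0]:
        raise ValueError(
            f"estimate has {v.shape[0]} entries, candidates have "
            f"{candidates.features.shape[0]} feature rows"
        )
    if v.std() == 0:
        raise ValueError("estimate is constant; Pearson correlation is undefined")
    gt_idx = candidates.index_of(gt)
    corr = _pearson_against_columns(v, candidates.features)
    c_gt = corr[gt_idx]
    n_above = int(np.sum(corr > c_gt))
    n_tied = int(np.sum(corr == c_gt))  # includes the ground truth itself
    if ties == "worst":
        G = n_above + n_tied
    elif ties == "best":
        G = n_above + 1
    elif ties == "mean":
        G = n_above + (n_tied + 1) / 2
    else:
        raise ValueError(f"unknown tie rule {ties!r}")
    M = candidates.n_categories
    return IdentificationResult(
        gt_category=gt,
        rank=int(G) if ties != "mean" else G,
        score=confidence_score(G, M),
        correlations=corr,
    )


def confidence_score(G: float, M: int) -> float:
    """Confidence category score ``S = (M - G) / (M - 1)``; 1 best, 0 worst."""
    if M < 2:
        raise ValueError("need at least 2 candidate categories")
    if not 1 <= G <= M:
        raise ValueError(f"rank G={G} outside [1, {M}]")
    return (M - G) / (M - 1)


@dataclass
class TestSetSummary:
    """Per-sample identification results with their mean confidence score."""

    results: list[IdentificationResult]
    mean_score: float
    mean_rank: float = field(default=float("nan"))

    @property
    def n_samples(self) -> int:
        return len(self.results)


def evaluate_testset(
    v_est_matrix: np.ndarray,
    gt_labels: Sequence[Hashable],
    candidates: CandidateSet,
    ties: str = "worst",
) -> TestSetSummary:
    """Rank every decoded test column and average the confidence scores."""
    V = np.asarray(v_est_matrix, dtype=float)
    if V.ndim != 2 or V.shape[1] != len(gt_labels):
        raise ValueError("one label per decoded column is required")
    results = [
        rank_category(V[:, n], candidates, gt_labels[n], ties=ties)
        for n in range(V.shape[1])
    ]
    scores = [r.score for r in results]
    ranks = [r.rank for r in results]
    return TestSetSummary(
        results=results,
        mean_score=float(np.mean(scores)),
        mean_rank=float(np.mean(ranks)),
    )
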