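"""Train/validate/test harness tying the models into one decoding workflow.

For each cross-validation fold the harness:

1. fits the multi-subject shared model on all subjects' training columns and
   one individual model per subject,
2. extracts shared and individual features for the train, validation and test
   columns (test-phase extraction uses only the subject's own data),
3. selects the decoder penalties on the fixed validation split by mean
   confidence score, fits the per-subject decoder, and
4. decodes the test columns and ranks them against the candidate set.

A fixed validation split plus k-fold cross-validation over the remainder
mirrors the small-sample regime the method targets, where rotating the
validation set is too expensive in test data.  The shared-only and
individual-only ablations reuse the same fitted models and extracted
features, differing only in which feature block the decoder sees.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold

from .decoder import fit_decoder, predict_visual
from .evaluation import CandidateSet, evaluate_testset, pca_reduce
from .individual import extract_individual, fit_individual
from .shared import SubjectData, extract_shared_subject, fit_shared
from .synthetic import BenchmarkDataset

logger = logging.getLogger("mspgm.pipeline")

__all__ = ["PipelineConfig", "split_folds", "run_pipeline", "VARIANTS"]

#: decoder input variants: which feature blocks the decoder consumes
VARIANTS = ("combined", "shared_only", "individual_only")


@dataclass
class PipelineConfig:
    """Resolved parameters of one pipeline run.

    Defaults follow the method's reference configuration: 100 shared and 100
    individual latent dimensions, 10 EM iterations, penalty grid
    ``{0.1, 1, 10}`` for each block, PCA to cumulative explained variance
    0.8, and 7 cross-validation folds with a fixed stratified validation
    split.
    """

    d_com: int = 100
    d_ind: int = 100
    em_max_iter: int = 10
    seed: int = 0
    lambda_grid: list[float] = field(default_factory=lambda: [0.1, 1.0, 10.0])
    pca_cum_ratio: float | None = 0.8
    n_folds: int = 7
    n_validation: int = 50
    ties: str = "worst"
    extraction_mode: str = "pinv"
    variants: list[str] = field(default_factory=lambda: list(VARIANTS))

    def __post_init__(self) -> None:
        if self.d_com < 1 or self.d_ind < 1:
            raise ValueError("d_com and d_ind must be >= 1 (use variants for ablations)")
        if self.em_max_iter < 1:
            raise ValueError("em_max_iter must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_validation < 1:
            raise ValueError("n_validation must be >= 1")
        if not self.lambda_grid:
            raise ValueError("lambda_grid must be non-empty")
        if any(l < 0 for l in self.lambda_grid):
            raise ValueError("penalties must be nonnegative")
        if self.pca_cum_ratio is not None and not 0 < self.pca_cum_ratio <= 1:
            raise ValueError("pca_cum_ratio must lie in (0, 1]")
        unknown = set(self.variants) - set(VARIANTS)
        if unknown:
            raise ValueError(f"unknown decoder variants: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def split_folds(
    n_samples: int,
    n_folds: int = 7,
    category_labels: Sequence | None = None,
    seed: int | None = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Disjoint, exhaustive, seeded (train, test) index folds.

    With labels, folds are category-stratified so every category is spread
    across folds as evenly as possible: a category with up to ``n_folds``
    samples lands in that many distinct folds.  (This accepts categories
    smaller than the fold count, which proportional stratifiers reject.)
    """
    if n_folds > n_samples:
        raise ValueError(f"cannot make {n_folds} folds from {n_samples} samples")
    idx = np.arange(n_samples)
    if category_labels is None:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        return [(idx[tr], idx[te]) for tr, te in splitter.split(idx[:, None])]
    if len(category_labels) != n_samples:
        raise ValueError("one label per sample is required")
    labels = np.asarray(category_labels)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cat in rng.permutation(np.unique(labels)):
        members = rng.permutation(np.flatnonzero(labels == cat))
        for start in range(0, len(members), n_folds):
            chunk = members[start : start + n_folds]
            # place the chunk into the currently smallest folds (distinct),
            # with a seeded random tie-break
            sizes = np.array([len(f) for f in folds])
            order = np.lexsort((rng.permutation(n_folds), sizes))
            for fold_pos, sample in zip(order, chunk):
                folds[fold_pos].append(int(sample))
    out = []
    for k in range(n_folds):
        te = np.sort(np.array(folds[k], dtype=int))
        tr = np.setdiff1d(idx, te)
        out.append((tr, te))
    return out


def _variant_features(variant: str, C: np.ndarray, H: np.ndarray):
    if variant == "combined":
        return C, H
    if variant == "shared_only":
        return C, H[:0]
    if variant == "individual_only":
        return C[:0], H
    raise ValueError(f"unknown variant {variant!r}")


def _grid_for(variant: str, grid: list[float]):
    """Penalty combinations searched for a variant (unused block gets 0)."""
    if variant == "combined":
        return [(lc, li) for lc in grid for li in grid]
    if variant == "shared_only":
        return [(lc, 0.0) for lc in grid]
    return [(0.0, li) for li in grid]


def run_pipeline(dataset: BenchmarkDataset, config: PipelineConfig) -> dict:
    """Run the full cross-validated decoding workflow; return a report dict.

    The report contains, per decoder variant, the mean confidence score per
    subject per fold, subject and overall averages, the selected penalties,
    and the fully resolved configuration — identical seeds reproduce it
    bit-for-bit.
    """
    labels = np.asarray(dataset.labels)
    n_total = dataset.n_samples
    n_subj = len(dataset.subjects)
    # fixed stratified validation split (first slice of an auxiliary split)
    n_slices = max(2, n_total // config.n_validation)
    _, val_idx = split_folds(
        n_total, n_folds=n_slices, category_labels=labels,
        seed=config.seed + 987654,
    )[0]
    pool_idx = np.setdiff1d(np.arange(n_total), val_idx)
    folds = split_folds(
        len(pool_idx),
        n_folds=config.n_folds,
        category_labels=labels[pool_idx],
        seed=config.seed,
    )
    d_com = min(config.d_com, min(s.n_voxels for s in dataset.subjects))
    d_ind = min(config.d_ind, min(s.n_voxels for s in dataset.subjects))
    report: dict = {
        "config": config.to_dict(),
        "n_samples": n_total,
        "n_validation": int(len(val_idx)),
        "folds": [],
        "variants": {v: {"per_fold": []} for v in config.variants},
    }
    for fold_no, (tr, te) in enumerate(folds):
        train_idx = pool_idx[tr]
        test_idx = pool_idx[te]
        logger.info(
            "fold %d: %d train / %d val / %d test",
            fold_no, len(train_idx), len(val_idx), len(test_idx),
        )
        # visual features: PCA fitted on training columns only
        V_train_raw = dataset.V[:, train_idx]
        if config.pca_cum_ratio is not None:
            V_train, transform = pca_reduce(V_train_raw, config.pca_cum_ratio)
            V_val = transform.apply(dataset.V[:, val_idx])
            cand = CandidateSet(
                category_ids=dataset.candidates.category_ids,
                features=transform.apply(dataset.candidates.features),
            )
        else:
            V_train, V_val = V_train_raw, dataset.V[:, val_idx]
            cand = dataset.candidates
        # PGM fitting on training columns
        train_subjects = [
            SubjectData(subject_id=s.subject_id, B=s.B[:, train_idx])
            for s in dataset.subjects
        ]
        shared = fit_shared(
            train_subjects, d_com,
            max_iter=config.em_max_iter, seed=config.seed + fold_no,
        )
        individuals = [
            fit_individual(
                ts, d_ind,
                max_iter=config.em_max_iter,
                seed=config.seed + 1000 * (i + 1) + fold_no,
            )
            for i, ts in enumerate(train_subjects)
        ]
        fold_entry = {
            "fold": fold_no,
            "loglik_final": shared.fit_info.loglik_trace[-1],
            "selected_lambdas": {},
        }
        for v in config.variants:
            report["variants"][v]["per_fold"].append({})
        for i in range(n_subj):
            B_full = dataset.subjects[i].B
            C_tr = extract_shared_subject(
                shared, i, B_full[:, train_idx], mode=config.extraction_mode)
            H_tr = extract_individual(
                individuals[i], B_full[:, train_idx], mode=config.extraction_mode)
            C_va = extract_shared_subject(
                shared, i, B_full[:, val_idx], mode=config.extraction_mode)
            H_va = extract_individual(
                individuals[i], B_full[:, val_idx], mode=config.extraction_mode)
            C_te = extract_shared_subject(
                shared, i, B_full[:, test_idx], mode=config.extraction_mode)
            H_te = extract_individual(
                individuals[i], B_full[:, test_idx], mode=config.extraction_mode)
            for variant in config.variants:
                C_v, H_v = _variant_features(variant, C_tr, H_tr)
                Cv_va, Hv_va = _variant_features(variant, C_va, H_va)
                Cv_te, Hv_te = _variant_features(variant, C_te, H_te)
                best = None
                for lc, li in _grid_for(variant, config.lambda_grid):
                    dec = fit_decoder(V_train, C_v, H_v, lambda_com=lc, lambda_ind=li)
                    v_val = predict_visual(dec, Cv_va, Hv_va)
                    s_val = evaluate_testset(
                        v_val, list(labels[val_idx]), cand, ties=config.ties
                    ).mean_score
                    if best is None or s_val > best[0]:
                        best = (s_val, lc, li, dec)
                s_val, lc, li, dec = best
                v_te = predict_visual(dec, Cv_te, Hv_te)
                summary = evaluate_testset(
                    v_te, list(labels[test_idx]), cand, ties=config.ties)
                subj_id = dataset.subjects[i].subject_id
                report["variants"][variant]["per_fold"][fold_no][subj_id] = {
                    "mean_score": summary.mean_score,
                    "mean_rank": summary.mean_rank,
                    "lambda_com": lc,
                    "lambda_ind": li,
                    "val_score": s_val,
                }
                fold_entry["selected_lambdas"].setdefault(variant, {})[subj_id] = (
                    lc, li)
        report["folds"].append(fold_entry)
    # aggregate: subject means over folds, grand mean
    for variant in config.variants:
        per_fold = report["variants"][variant]["per_fold"]
        subj_ids = [s.subject_id for s in dataset.subjects]
        per_subject = {
            sid: float(np.mean([f[sid]["mean_score"] for f in per_fold]))
            for sid in subj_ids
        }
        report["variants"][variant]["per_subject_mean"] = per_subject
        report["variants"][variant]["mean_score"] = float(
            np.mean(list(per_subject.values()))
        )
    return report
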