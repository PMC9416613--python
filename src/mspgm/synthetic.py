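"""Synthetic multi-subject datasets with the exact structure the model assumes.

Every generator forward-samples the generative equations the models are built
on: a shared Gaussian latent observed by all subjects through per-subject
orthonormal loadings, subject-specific Gaussian latents through loadings
whose span is orthogonal to the shared one within each subject, isotropic
voxel noise, and visual features linear in the latents plus noise.  Ground
truth (latents, loadings, decoder maps) is returned so that recovery can be
measured, and every generator is a pure function of its seed.

The within-subject orthogonality of shared and individual loading spans is a
generator convenience that makes "shared vs individual" identifiable in
tests; the fitted models never assume it.

:func:`gen_decoding_benchmark` builds the desk-scale end-to-end benchmark:
categories are given latent prototypes (both shared and, per subject,
individual), samples scatter around their category prototype, and candidate
visual features are per-category means of an independently drawn image pool —
mirroring how real identification benchmarks average image features per
category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import CandidateSet, build_candidates
from .shared import SubjectData

__all__ = [
    "SyntheticGroundTruth",
    "BenchmarkDataset",
    "gen_multisubject",
    "gen_visual",
    "gen_benchmark",
    "gen_decoding_benchmark",
]


def _cov_matrix(spec, dim: int) -> np.ndarray:
    """Expand a covariance spec (scalar variance, diagonal, or full) to a matrix."""
    arr = np.asarray(spec, dtype=float)
    if arr.ndim == 0:
        return float(arr) * np.eye(dim)
    if arr.ndim == 1:
        if arr.shape[0] != dim:
            raise ValueError("diagonal covariance spec has wrong length")
        return np.diag(arr)
    if arr.shape != (dim, dim):
        raise ValueError("covariance matrix has wrong shape")
    return arr


def _orthonormal_pair(
    rng: np.random.Generator, d: int, d_com: int, d_ind: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw loadings (d x d_com, d x d_ind) with mutually orthogonal spans."""
    Q, _ = np.linalg.qr(rng.standard_normal((d, d_com + d_ind)))
    return Q[:, :d_com], Q[:, d_com : d_com + d_ind]


def _sample_gaussian(
    rng: np.random.Generator, cov: np.ndarray, n: int
) -> np.ndarray:
    """Columns ~ N(0, cov) via the symmetric PSD square root."""
    w, U = np.linalg.eigh(0.5 * (cov + cov.T))
    root = U * np.sqrt(np.maximum(w, 0.0))
    return root @ rng.standard_normal((cov.shape[0], n))


@dataclass
class SyntheticGroundTruth:
    """Everything the generator knew: latents, loadings, noise, decoder maps."""

    C: np.ndarray                      # d_com x N shared latents
    H: list[np.ndarray]                # per subject, d_ind x N individual latents
    loadings_shared: list[np.ndarray]  # P_i, orthonormal columns
    loadings_individual: list[np.ndarray]  # P'_i, orthonormal columns
    means: list[np.ndarray]
    noise_vars: list[float]
    latent_cov: np.ndarray
    individual_cov: np.ndarray
    seed: int | None
    # visual-feature pieces, set by gen_visual / gen_decoding_benchmark
    P_com: np.ndarray | None = None
    P_ind: np.ndarray | None = None
    visual_noise: float | None = None
    designated_subject: int = 0
    labels: list | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.H)


def gen_multisubject(
    J: int,
    d_list: list[int] | int,
    d_com: int,
    d_ind: int,
    N: int,
    sigma_c=1.0,
    sigma_h=1.0,
    noise_vars=0.1,
    mean_scale: float = 1.0,
    seed: int | None = 0,
    latents: tuple[np.ndarray, list[np.ndarray]] | None = None,
) -> tuple[list[SubjectData], SyntheticGroundTruth]:
    """Sample ``B_i = P_i C + P'_i H_i + mu_i + noise`` for ``J`` subjects.

    ``sigma_c`` / ``sigma_h`` give the shared and individual latent
    covariances (scalar variance, diagonal, or full matrix); ``noise_vars``
    may be a scalar or one variance per subject (0 allowed for noiseless
    data).  ``latents`` optionally supplies pre-built ``(C, [H_i])`` columns,
    e.g. with category structure, instead of i.i.d. Gaussian draws.
    """
    if np.isscalar(d_list):
        d_list = [int(d_list)] * J
    if len(d_list) != J:
        raise ValueError("d_list must have one entry per subject")
    if N < 2:
        raise ValueError("need at least 2 samples")
    if d_com + d_ind > min(d_list):
        raise ValueError(
            f"d_com + d_ind = {d_com + d_ind} exceeds the smallest data "
            f"dimension {min(d_list)}"
        )
    if np.isscalar(noise_vars):
        noise_vars = [float(noise_vars)] * J
    noise_vars = [float(v) for v in noise_vars]
    if any(v < 0 for v in noise_vars):
        raise ValueError("noise variances must be nonnegative")
    rng = np.random.default_rng(seed)
    Sigma_c = _cov_matrix(sigma_c, d_com)
    Sigma_h = _cov_matrix(sigma_h, d_ind)
    if latents is None:
        C = _sample_gaussian(rng, Sigma_c, N)
        H = [_sample_gaussian(rng, Sigma_h, N) for _ in range(J)]
    else:
        C = np.asarray(latents[0], dtype=float)
        H = [np.asarray(h, dtype=float) for h in latents[1]]
        if C.shape != (d_com, N) or any(h.shape != (d_ind, N) for h in H):
            raise ValueError("supplied latents have wrong shapes")
    subjects: list[SubjectData] = []
    P_list, Pp_list, mu_list = [], [], []
    for i, d in enumerate(d_list):
        P, Pp = _orthonormal_pair(rng, d, d_com, d_ind)
        mu = mean_scale * rng.standard_normal(d)
        B = P @ C + mu[:, None]
        if d_ind:
            B = B + Pp @ H[i]
        if noise_vars[i] > 0:
            B = B + np.sqrt(noise_vars[i]) * rng.standard_normal((d, N))
        subjects.append(SubjectData(subject_id=f"S{i + 1}", B=B))
        P_list.append(P)
        Pp_list.append(Pp)
        mu_list.append(mu)
    gt = SyntheticGroundTruth(
        C=C,
        H=H,
        loadings_shared=P_list,
        loadings_individual=Pp_list,
        means=mu_list,
        noise_vars=noise_vars,
        latent_cov=Sigma_c,
        individual_cov=Sigma_h,
        seed=seed,
    )
    return subjects, gt


def gen_visual(
    gt: SyntheticGroundTruth,
    d_v: int,
    visual_noise: float = 0.0,
    seed: int | None = 0,
    designated_subject: int = 0,
) -> np.ndarray:
    """Visual features linear in the latents: ``V = P_com C + P_ind H_i* + noise``.

    One visual-feature matrix exists per dataset (all subjects see the same
    stimuli), so the individual contribution comes from one designated
    subject's latents.  The drawn decoder maps are stored on ``gt``.
    """
    rng = np.random.default_rng(seed)
    d_com = gt.C.shape[0]
    d_ind = gt.H[designated_subject].shape[0] if gt.H else 0
    P_com = rng.standard_normal((d_v, d_com))
    P_ind = rng.standard_normal((d_v, d_ind))
    V = P_com @ gt.C
    if d_ind:
        V = V + P_ind @ gt.H[designated_subject]
    if visual_noise > 0:
        V = V + np.sqrt(visual_noise) * rng.standard_normal(V.shape)
    gt.P_com, gt.P_ind = P_com, P_ind
    gt.visual_noise = float(visual_noise)
    gt.designated_subject = designated_subject
    return V


def gen_benchmark(
    n_categories: int,
    d_v: int = 30,
    imgs_per_category: tuple[int, int] = (5, 10),
    separation: float = 1.0,
    est_noise: float = 0.0,
    signal: float = 1.0,
    n_test: int | None = None,
    seed: int | None = 0,
) -> tuple[CandidateSet, np.ndarray, list[int]]:
    """Ranking benchmark with controllable difficulty.

    Each category gets a prototype feature vector (scale ``separation``);
    candidate features average 5-10 unit-jittered images per category.  Test
    estimates are ``signal * prototype + est_noise * noise`` — ``signal=0``
    makes them independent of the candidates (uniform-rank null, expected
    score 0.5), ``est_noise=0`` with ``signal=1`` makes identification exact.
    """
    if n_categories < 2:
        raise ValueError("need at least 2 categories")
    rng = np.random.default_rng(seed)
    protos = separation * rng.standard_normal((d_v, n_categories))
    lo, hi = imgs_per_category
    pools = {}
    for m in range(n_categories):
        k = int(rng.integers(lo, hi + 1))
        pools[m] = protos[:, [m]] + rng.standard_normal((d_v, k))
    candidates = build_candidates(pools)
    if n_test is None:
        n_test = n_categories
    labels = [int(rng.integers(0, n_categories)) for _ in range(n_test)]
    estimates = signal * protos[:, labels] + est_noise * rng.standard_normal(
        (d_v, n_test)
    )
    return candidates, estimates, labels


@dataclass
class BenchmarkDataset:
    """End-to-end decoding benchmark: brain data, visual features, candidates."""

    subjects: list[SubjectData]
    V: np.ndarray                 # d_v x N visual features, sample-aligned
    labels: list                  # per-sample category
    candidates: CandidateSet      # per-category mean features from an image pool
    ground_truth: SyntheticGroundTruth | None = None
    params: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.labels)


def gen_decoding_benchmark(
    J: int = 3,
    d_i: int = 60,
    d_com: int = 8,
    d_ind: int = 8,
    n_categories: int = 50,
    imgs_per_category: int = 8,
    d_v: int = 60,
    proto_scale: float = 1.0,
    jitter: float = 0.4,
    noise_var: float = 0.2,
    visual_noise: float = 0.1,
    n_distractors: int = 40,
    distractor_scale: float = 0.4,
    pool_imgs: tuple[int, int] = (5, 10),
    seed: int | None = 0,
) -> BenchmarkDataset:
    """Desk-scale category-decoding benchmark with known ground truth.

    Category ``m`` has a shared latent prototype and, per subject, an
    individual latent prototype; sample latents scatter around their
    category's prototypes with standard deviation ``jitter``.  Visual
    features are linear in the shared latents plus the designated (first)
    subject's individual latents, and additionally carry per-image
    *distractor* latents — image content that no brain latent encodes,
    emulating the large non-decodable variance of CNN features.  The
    pipeline's PCA step then operates in its intended regime: the weak
    distractor spectrum, not the decodable structure, is what falls below
    the cumulative-variance threshold.  Candidates are per-category means
    of a separate image pool drawn from the same visual model.
    """
    rng = np.random.default_rng(seed)
    N = n_categories * imgs_per_category
    labels = list(np.repeat(np.arange(n_categories), imgs_per_category))
    gamma = proto_scale * rng.standard_normal((d_com, n_categories))  # shared protos
    etas = [
        proto_scale * rng.standard_normal((d_ind, n_categories)) for _ in range(J)
    ]
    C = gamma[:, labels] + jitter * rng.standard_normal((d_com, N))
    H = [
        etas[i][:, labels] + jitter * rng.standard_normal((d_ind, N))
        for i in range(J)
    ]
    subjects, gt = gen_multisubject(
        J=J,
        d_list=d_i,
        d_com=d_com,
        d_ind=d_ind,
        N=N,
        noise_vars=noise_var,
        seed=int(rng.integers(0, 2**31)),
        latents=(C, H),
    )
    gt.labels = labels
    V = gen_visual(
        gt, d_v=d_v, visual_noise=visual_noise, seed=int(rng.integers(0, 2**31))
    )
    # non-decodable image content, present in every image's features
    E_dist = rng.standard_normal((d_v, n_distractors))
    V = V + E_dist @ (distractor_scale * rng.standard_normal((n_distractors, N)))
    # candidate pool: fresh images per category through the same visual model
    lo, hi = pool_imgs
    pools = {}
    for m in range(n_categories):
        k = int(rng.integers(lo, hi + 1))
        c_pool = gamma[:, [m]] + jitter * rng.standard_normal((d_com, k))
        h_pool = etas[0][:, [m]] + jitter * rng.standard_normal((d_ind, k))
        V_pool = gt.P_com @ c_pool + gt.P_ind @ h_pool
        V_pool = V_pool + E_dist @ (
            distractor_scale * rng.standard_normal((n_distractors, k))
        )
        if visual_noise > 0:
            V_pool = V_pool + np.sqrt(visual_noise) * rng.standard_normal(V_pool.shape)
        pools[m] = V_pool
    candidates = build_candidates(pools)
    params = dict(
        J=J, d_i=d_i, d_com=d_com, d_ind=d_ind, n_categories=n_categories,
        imgs_per_category=imgs_per_category, d_v=d_v, proto_scale=proto_scale,
        jitter=jitter, noise_var=noise_var, visual_noise=visual_noise,
        n_distractors=n_distractors, distractor_scale=distractor_scale, seed=seed,
    )
    return BenchmarkDataset(
        subjects=subjects, V=V, labels=labels, candidates=candidates,
        ground_truth=gt, params=params,
    )
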