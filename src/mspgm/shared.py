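"""Multi-subject shared-feature model fitted by expectation-maximization.

All subjects view the same stimuli; stimulus ``n`` evokes a shared latent
response ``c_n ~ N(0, Sigma_c)`` that each subject expresses through their own
orthonormal loading ``P_i`` plus isotropic noise:

    b_{i,n} = P_i c_n + mu_i + eps_i,   eps_i ~ N(0, rho_i^2 I).

The E-step conditions the shared latent on the stacked multi-subject data; the
M-step updates each ``P_i`` by an orthogonal-Procrustes (polar) step, the
noise variances in closed form, and ``Sigma_c`` as the mean posterior second
moment.  Shared features are extracted with the pseudo-inverse of the stacked
loading, which for orthonormal blocks is the average of per-subject
projections; the posterior mean is available as an alternative extractor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    LatentGaussianSpec,
    RankDeficiencyError,
    marginal_loglik,
    polar_orthonormalize,
    woodbury_solve,
)

__all__ = [
    "SubjectData",
    "FitInfo",
    "SharedPGMModel",
    "EStepStats",
    "EMMonotonicityError",
    "init_shared",
    "e_step",
    "m_step",
    "fit_shared",
    "extract_shared_combined",
    "extract_shared_subject",
]


class EMMonotonicityError(RuntimeError):
    """Raised when the marginal log-likelihood decreases beyond slack."""


@dataclass
class SubjectData:
    """One subject's response matrix (``d_i`` voxels x ``N`` stimuli).

    ``mu`` is the row-wise (per-voxel) mean over stimuli; if omitted it is
    computed from ``B``.  A supplied ``mu`` must match the row means to 1e-10.
    """

    subject_id: str
    B: np.ndarray
    mu: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        if self.B.ndim != 2:
            raise ValueError("B must be a 2-d (voxels x samples) matrix")
        row_means = self.B.mean(axis=1)
        if self.mu is None:
            self.mu = row_means
        else:
            self.mu = np.asarray(self.mu, dtype=float).ravel()
            if self.mu.shape != row_means.shape:
                raise ValueError("mu length does not match the number of rows of B")
            scale = max(1.0, np.abs(self.B).max())
            if np.abs(self.mu - row_means).max() > 1e-10 * scale:
                raise ValueError("mu must equal the row-wise mean of B")

    @property
    def n_voxels(self) -> int:
        return self.B.shape[0]

    @property
    def n_samples(self) -> int:
        return self.B.shape[1]

    def centered(self) -> np.ndarray:
        return self.B - self.mu[:, None]


@dataclass
class FitInfo:
    """Bookkeeping for one EM run."""

    iterations: int
    loglik_trace: list[float]
    seed: int | None
    max_iter: int
    early_stop_tol: float | None = None
    converged_early: bool = False


@dataclass
class SharedPGMModel:
    """Fitted shared-feature model: a latent Gaussian spec plus fit metadata."""

    spec: LatentGaussianSpec
    fit_info: FitInfo
    model_kind: str = "shared"

    @property
    def d_com(self) -> int:
        return self.spec.latent_dim

    @property
    def n_subjects(self) -> int:
        return self.spec.n_subjects


@dataclass
class EStepStats:
    """Posterior statistics of the shared latent given stacked data.

    ``cond_var`` (``Var[c|b]``) does not depend on ``n``; the per-sample second
    moments ``E[c_n c_n^T | b_n] = Var[c|b] + E[c_n]E[c_n]^T`` are exposed both
    summed (what the M-step needs) and as an explicit list.
    """

    expectations: np.ndarray  # d_com x N
    cond_var: np.ndarray      # d_com x d_com
    _second: list[np.ndarray] | None = field(default=None, repr=False)

    @property
    def n_samples(self) -> int:
        return self.expectations.shape[1]

    @property
    def second_moments(self) -> list[np.ndarray]:
        if self._second is None:
            E = self.expectations
            self._second = [
                self.cond_var + np.outer(E[:, n], E[:, n])
                for n in range(self.n_samples)
            ]
        return self._second

    def sum_second_moments(self) -> np.ndarray:
        E = self.expectations
        return self.n_samples * self.cond_var + E @ E.T


def _check_subjects(subjects: list[SubjectData]) -> int:
    if not subjects:
        raise ValueError("at least one subject is required")
    n = subjects[0].n_samples
    for s in subjects:
        if s.n_samples != n:
            raise ValueError(
                "all subjects must have the same number of samples "
                f"({s.subject_id} has {s.n_samples}, expected {n})"
            )
    return n


def init_shared(
    subjects: list[SubjectData], d_com: int, seed: int | None = 0
) -> SharedPGMModel:
    """Neutral seeded initialization: random orthonormal ``P_i``, unit noise,
    identity latent covariance, per-subject row means."""
    n = _check_subjects(subjects)
    if n < 2:
        raise ValueError("need at least 2 samples; mean removal absorbs a single one")
    d_min = min(s.n_voxels for s in subjects)
    if d_com > d_min:
        raise ValueError(f"d_com={d_com} exceeds the smallest data dimension {d_min}")
    if d_com < 1:
        raise ValueError("d_com must be >= 1")
    rng = np.random.default_rng(seed)
    loadings = [
        polar_orthonormalize(rng.standard_normal((s.n_voxels, d_com)))
        for s in subjects
    ]
    spec = LatentGaussianSpec(
        loadings=loadings,
        means=[s.mu.copy() for s in subjects],
        noise_vars=[1.0] * len(subjects),
        latent_cov=np.eye(d_com),
    )
    info = FitInfo(iterations=0, loglik_trace=[], seed=seed, max_iter=0)
    return SharedPGMModel(spec=spec, fit_info=info)


def e_step(model: SharedPGMModel, subjects: list[SubjectData]) -> EStepStats:
    """Posterior mean and variance of the shared latent given stacked data.

    ``E[c_n|b_n] = (P Sigma_c)^T (P Sigma_c P^T + Psi)^{-1} (b_n - mu)`` and
    ``Var[c|b] = Sigma_c - Sigma_c P^T (P Sigma_c P^T + Psi)^{-1} P Sigma_c``,
    both through the Woodbury solve.
    """
    spec = model.spec
    _check_subjects(subjects)
    if [s.n_voxels for s in subjects] != spec.dims:
        raise ValueError("subject dimensions do not match the model")
    centered = np.vstack([s.B for s in subjects]) - spec.stacked_mean[:, None]
    M = spec.stacked_loading @ spec.latent_cov  # d_all x d_com
    sol = woodbury_solve(spec, np.hstack([centered, M]))
    n = centered.shape[1]
    expectations = M.T @ sol[:, :n]
    cond_var = spec.latent_cov - M.T @ sol[:, n:]
    cond_var = 0.5 * (cond_var + cond_var.T)
    return EStepStats(expectations=expectations, cond_var=cond_var)


def m_step(
    stats: EStepStats, subjects: list[SubjectData], model: SharedPGMModel
) -> SharedPGMModel:
    """Closed-form parameter updates from posterior statistics.

    ``P_i`` is the polar factor of ``A_i = 1/2 sum_n (b_{i,n}-mu_i) E[c_n]^T``
    (the 1/2 does not affect the polar factor); ``rho_i^2`` and ``Sigma_c``
    follow in closed form.  Means are untouched.
    """
    spec = model.spec
    E = stats.expectations
    n = stats.n_samples
    if n != _check_subjects(subjects):
        raise ValueError("stats and subjects disagree on the number of samples")
    sum_cc = stats.sum_second_moments()
    tr_sum_cc = float(np.trace(sum_cc))
    new_loadings: list[np.ndarray] = []
    new_noise: list[float] = []
    for i, s in enumerate(subjects):
        Bc = s.centered()
        A_i = 0.5 * (Bc @ E.T)
        try:
            P_new = polar_orthonormalize(A_i)
        except RankDeficiencyError as exc:
            raise RankDeficiencyError(
                f"M-step update for subject '{s.subject_id}': {exc}"
            ) from exc
        rho2 = (
            float(np.sum(Bc * Bc))
            - 2.0 * float(np.sum((P_new.T @ Bc) * E))
            + tr_sum_cc
        ) / (n * s.n_voxels)
        new_loadings.append(P_new)
        new_noise.append(rho2)
    sigma_new = sum_cc / n
    sigma_new = 0.5 * (sigma_new + sigma_new.T)
    # floor tiny negative eigenvalues introduced by floating point
    w, U = np.linalg.eigh(sigma_new)
    if w.min() < 0:
        sigma_new = (U * np.maximum(w, 0.0)) @ U.T
        sigma_new = 0.5 * (sigma_new + sigma_new.T)
    new_spec = LatentGaussianSpec(
        loadings=new_loadings,
        means=[m.copy() for m in spec.means],
        noise_vars=new_noise,
        latent_cov=sigma_new,
    )
    return SharedPGMModel(spec=new_spec, fit_info=model.fit_info,
                          model_kind=model.model_kind)


def fit_shared(
    subjects: list[SubjectData],
    d_com: int,
    max_iter: int = 10,
    seed: int | None = 0,
    early_stop_tol: float | None = None,
    check_monotone: bool = True,
) -> SharedPGMModel:
    """Fit the shared model by EM.

    Runs a fixed number of E/M alternations (default 10) and records the
    marginal log-likelihood after initialization and after every iteration.
    The trace must be non-decreasing; a decrease beyond slack raises
    :class:`EMMonotonicityError`, which indicates a broken update.  An
    optional relative-change early stop can terminate sooner.
    """
    model = init_shared(subjects, d_com, seed=seed)
    B = np.vstack([s.B for s in subjects])
    trace = [marginal_loglik(model.spec, B)]
    iterations = 0
    converged = False
    for _ in range(max_iter):
        stats = e_step(model, subjects)
        model = m_step(stats, subjects, model)
        ll = marginal_loglik(model.spec, B)
        if check_monotone and ll < trace[-1] - 1e-8 * max(1.0, abs(trace[-1])):
            raise EMMonotonicityError(
                f"log-likelihood decreased from {trace[-1]:.10g} to {ll:.10g} "
                f"at iteration {iterations + 1}"
            )
        trace.append(ll)
        iterations += 1
        if early_stop_tol is not None and len(trace) >= 2:
            if abs(trace[-1] - trace[-2]) < early_stop_tol * abs(trace[-1]):
                converged = True
                break
    info = FitInfo(
        iterations=iterations,
        loglik_trace=trace,
        seed=seed,
        max_iter=max_iter,
        early_stop_tol=early_stop_tol,
        converged_early=converged,
    )
    return SharedPGMModel(spec=model.spec, fit_info=info, model_kind=model.model_kind)


def _posterior_mean(spec: LatentGaussianSpec, centered: np.ndarray) -> np.ndarray:
    M = spec.stacked_loading @ spec.latent_cov
    return M.T @ woodbury_solve(spec, centered)


def extract_shared_combined(
    model: SharedPGMModel, B_stacked: np.ndarray, mode: str = "pinv"
) -> np.ndarray:
    """Shared features from stacked multi-subject data, ``c_n = P^+ (b_n - mu)``.

    With orthonormal per-subject blocks the pseudo-inverse reduces to the
    average of per-subject projections ``(1/J) sum_i P_i^T (b_{i,n}-mu_i)``.
    ``mode='posterior'`` returns the posterior mean ``E[c_n|b_n]`` instead.
    """
    spec = model.spec
    B_stacked = np.asarray(B_stacked, dtype=float)
    squeeze = B_stacked.ndim == 1
    B = B_stacked[:, None] if squeeze else B_stacked
    if B.shape[0] != spec.d_all:
        raise ValueError(f"stacked data has {B.shape[0]} rows, expected {spec.d_all}")
    centered = B - spec.stacked_mean[:, None]
    if mode == "pinv":
        P = spec.stacked_loading
        C = np.linalg.solve(P.T @ P, P.T @ centered)
    elif mode == "posterior":
        C = _posterior_mean(spec, centered)
    else:
        raise ValueError(f"unknown extraction mode {mode!r}")
    return C[:, 0] if squeeze else C


def extract_shared_subject(
    model: SharedPGMModel, subject_index: int, B_i: np.ndarray, mode: str = "pinv"
) -> np.ndarray:
    """Per-subject shared features ``c_{i,n} = P_i^+ (b_{i,n} - mu_i)``.

    This is the test-phase extractor: it uses only subject ``i``'s data, and
    for orthonormal ``P_i`` the pseudo-inverse is simply the transpose.
    ``mode='posterior'`` conditions the latent on this subject's data alone.
    """
    spec = model.spec
    if not 0 <= subject_index < spec.n_subjects:
        raise IndexError(f"subject_index {subject_index} out of range")
    B_i = np.asarray(B_i, dtype=float)
    squeeze = B_i.ndim == 1
    B = B_i[:, None] if squeeze else B_i
    d_i = spec.dims[subject_index]
    if B.shape[0] != d_i:
        raise ValueError(f"data has {B.shape[0]} rows, expected d_i={d_i}")
    P_i = spec.loadings[subject_index]
    centered = B - spec.means[subject_index][:, None]
    if mode == "pinv":
        C = np.linalg.solve(P_i.T @ P_i, P_i.T @ centered)
    elif mode == "posterior":
        sub_spec = LatentGaussianSpec(
            loadings=[P_i],
            means=[spec.means[subject_index]],
            noise_vars=[spec.noise_vars[subject_index]],
            latent_cov=spec.latent_cov,
            validate=False,
        )
        C = _posterior_mean(sub_spec, centered)
    else:
        raise ValueError(f"unknown extraction mode {mode!r}")
    return C[:, 0] if squeeze else C
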