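"""Gaussian latent-factor kernel shared by the shared- and individual-feature models.

The generative model is, per stimulus ``n``,

    b_n = P c_n + mu + eps,   c_n ~ N(0, Sigma_c),   eps ~ N(0, Psi),

where ``P`` stacks per-subject loading matrices ``P_i`` with orthonormal
columns and ``Psi = diag(rho_1^2 I, ..., rho_J^2 I)`` is isotropic within each
subject.  This module provides the block-structured Gaussian algebra every
model needs: the marginal of ``b_n``, a Woodbury-form solve against the
marginal covariance that scales with the latent dimension instead of the voxel
count, the marginal log-likelihood used to monitor EM, and the polar
(orthogonal-Procrustes) orthonormalization used by the M-step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

__all__ = [
    "LatentGaussianSpec",
    "RankDeficiencyError",
    "polar_orthonormalize",
    "marginal_gaussian",
    "woodbury_solve",
    "marginal_loglik",
]

# Eigenvalues of A^T A below this fraction of the largest are treated as rank
# deficiency (equivalently singular values below sqrt of this fraction).
_RANK_RTOL = 1e-12


class RankDeficiencyError(np.linalg.LinAlgError):
    """Raised when a matrix expected to have full column rank does not."""


def polar_orthonormalize(A: np.ndarray) -> np.ndarray:
    """Orthonormal polar factor ``A (A^T A)^{-1/2}`` of a full-column-rank matrix.

    The result is the closest matrix with orthonormal columns to ``A`` in
    Frobenius norm and the maximizer of ``tr(Q^T A)`` over such matrices
    (orthogonal Procrustes).  Computed through the thin SVD ``A = U S V^T``,
    for which the polar factor is ``U V^T``.

    Raises
    ------
    RankDeficiencyError
        If ``A`` is column-rank deficient.  The M-step formula this serves
        assumes full rank, so deficiency is reported, never regularized away.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2:
        raise ValueError(f"expected a 2-d array, got shape {A.shape}")
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    # s**2 are the eigenvalues of A^T A
    if s.size == 0 or s[0] == 0.0 or (s[-1] / s[0]) ** 2 <= _RANK_RTOL:
        rank = int(np.sum(s**2 > _RANK_RTOL * (s[0] ** 2 if s.size else 0.0)))
        raise RankDeficiencyError(
            f"matrix of shape {A.shape} has column rank {rank} < {A.shape[1]}; "
            "the polar factor (A^T A)^{-1/2} is undefined"
        )
    return U @ Vt


@dataclass
class LatentGaussianSpec:
    """Parameters of the block latent Gaussian model.

    Parameters
    ----------
    loadings
        Per-subject ``d_i x k`` matrices with orthonormal columns (``P_i``).
    means
        Per-subject ``d_i`` mean vectors (``mu_i``).
    noise_vars
        Per-subject isotropic noise variances ``rho_i^2`` (strictly positive).
    latent_cov
        ``k x k`` symmetric positive-semidefinite latent covariance
        ``Sigma_c``.
    """

    loadings: list[np.ndarray]
    means: list[np.ndarray]
    noise_vars: list[float]
    latent_cov: np.ndarray
    validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.loadings = [np.ascontiguousarray(P, dtype=float) for P in self.loadings]
        self.means = [np.asarray(m, dtype=float).ravel() for m in self.means]
        self.noise_vars = [float(v) for v in self.noise_vars]
        self.latent_cov = np.asarray(self.latent_cov, dtype=float)
        if self.validate:
            self._check()

    # -- derived structure ------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.loadings)

    @property
    def dims(self) -> list[int]:
        return [P.shape[0] for P in self.loadings]

    @property
    def latent_dim(self) -> int:
        return self.latent_cov.shape[0]

    @property
    def d_all(self) -> int:
        return int(sum(self.dims))

    @property
    def stacked_loading(self) -> np.ndarray:
        """``P = [P_1; ...; P_J]`` of shape ``(d_all, k)``."""
        return np.vstack(self.loadings)

    @property
    def stacked_mean(self) -> np.ndarray:
        return np.concatenate(self.means)

    @property
    def psi_diag(self) -> np.ndarray:
        """Diagonal of ``Psi`` as a length-``d_all`` vector."""
        return np.repeat(self.noise_vars, self.dims)

    # ---------------------------------------------------------------------
    def _check(self) -> None:
        if not (len(self.loadings) == len(self.means) == len(self.noise_vars)):
            raise ValueError("loadings, means and noise_vars must have equal length")
        if self.n_subjects == 0:
            raise ValueError("at least one subject is required")
        k = self.latent_cov.shape[0]
        if self.latent_cov.shape != (k, k):
            raise ValueError("latent_cov must be square")
        for i, (P, m) in enumerate(zip(self.loadings, self.means)):
            if P.ndim != 2 or P.shape[1] != k:
                raise ValueError(
                    f"loading {i} has shape {P.shape}, expected (d_{i}, {k})"
                )
            if m.shape[0] != P.shape[0]:
                raise ValueError(f"mean {i} length {m.shape[0]} != d_{i}={P.shape[0]}")
            dev = np.abs(P.T @ P - np.eye(k)).max()
            if dev > 1e-8:
                raise ValueError(
                    f"loading {i} columns not orthonormal (max deviation {dev:.2e})"
                )
        if any(v <= 0 for v in self.noise_vars):
            raise ValueError("noise variances must be strictly positive")
        asym = np.abs(self.latent_cov - self.latent_cov.T).max()
        scale = max(1.0, np.abs(self.latent_cov).max())
        if asym > 1e-10 * scale:
            raise ValueError(f"latent_cov not symmetric (max asymmetry {asym:.2e})")
        w = np.linalg.eigvalsh(0.5 * (self.latent_cov + self.latent_cov.T))
        if w.min() < -1e-10 * scale:
            raise ValueError(
                f"latent_cov has negative eigenvalue {w.min():.2e}; "
                "add explicit jitter if a PSD approximation is intended"
            )

    def latent_factor(self) -> np.ndarray:
        """Symmetric PSD factor ``L`` with ``Sigma_c = L L^T`` (rank columns).

        Zero eigenvalues are dropped, so a singular (even zero) latent
        covariance is handled exactly.
        """
        S = 0.5 * (self.latent_cov + self.latent_cov.T)
        w, U = np.linalg.eigh(S)
        scale = max(1.0, np.abs(w).max()) if w.size else 1.0
        if w.size and w.min() < -1e-10 * scale:
            raise ValueError(
                "latent covariance is not positive semidefinite; "
                "add explicit jitter before factorizing"
            )
        keep = w > 1e-14 * scale
        return U[:, keep] * np.sqrt(w[keep])


def marginal_gaussian(spec: LatentGaussianSpec) -> tuple[np.ndarray, np.ndarray]:
    """Mean and covariance of the marginal ``p(b) = N(mu, P Sigma_c P^T + Psi)``."""
    P = spec.stacked_loading
    cov = P @ spec.latent_cov @ P.T
    cov[np.diag_indices_from(cov)] += spec.psi_diag
    cov = 0.5 * (cov + cov.T)
    return spec.stacked_mean, cov


def _capacitance(spec: LatentGaussianSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pieces of the Woodbury identity for ``(P Sigma_c P^T + Psi)^{-1}``.

    Returns ``(G, psi_inv, cho)`` where ``G = P L`` for the PSD factor ``L``,
    ``psi_inv`` is the elementwise inverse noise diagonal, and ``cho`` is the
    Cholesky factorization of the capacitance ``I + G^T Psi^{-1} G``.
    """
    L = spec.latent_factor()
    G = spec.stacked_loading @ L
    psi_inv = 1.0 / spec.psi_diag
    r = G.shape[1]
    M = np.eye(r) + G.T @ (G * psi_inv[:, None])
    M = 0.5 * (M + M.T)
    cho = linalg.cho_factor(M, lower=True)
    return G, psi_inv, cho


def woodbury_solve(
    spec: LatentGaussianSpec, rhs: np.ndarray, *, dense: bool = False
) -> np.ndarray:
    """Solve ``(P Sigma_c P^T + Psi) X = rhs``.

    The default path uses the Woodbury identity through the latent-rank factor
    of ``Sigma_c``, costing O(latent_dim^3) instead of O(d_all^3).  ``dense``
    switches to an explicit dense solve (oracle/testing path).
    """
    rhs = np.asarray(rhs, dtype=float)
    squeeze = rhs.ndim == 1
    R = rhs[:, None] if squeeze else rhs
    if R.shape[0] != spec.d_all:
        raise ValueError(f"rhs has {R.shape[0]} rows, expected d_all={spec.d_all}")
    if dense:
        _, cov = marginal_gaussian(spec)
        X = linalg.solve(cov, R, assume_a="pos")
    else:
        G, psi_inv, cho = _capacitance(spec)
        X0 = R * psi_inv[:, None]
        if G.shape[1] == 0:
            X = X0
        else:
            X = X0 - psi_inv[:, None] * (G @ linalg.cho_solve(cho, G.T @ X0))
    return X[:, 0] if squeeze else X


def marginal_loglik(
    spec: LatentGaussianSpec, B: np.ndarray, *, dense: bool = False
) -> float:
    """Total marginal log-likelihood ``sum_n log N(b_n; mu, P Sigma_c P^T + Psi)``.

    Computed with the matrix-determinant lemma and the Woodbury solve, so the
    cost is linear in ``d_all``.  ``dense`` evaluates the naive dense Gaussian
    density instead.
    """
    B = np.asarray(B, dtype=float)
    if B.ndim == 1:
        B = B[:, None]
    if B.shape[0] != spec.d_all:
        raise ValueError(f"data has {B.shape[0]} rows, expected d_all={spec.d_all}")
    n = B.shape[1]
    centered = B - spec.stacked_mean[:, None]
    if dense:
        _, cov = marginal_gaussian(spec)
        cho = linalg.cho_factor(cov, lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
        quad = float(np.sum(centered * linalg.cho_solve(cho, centered)))
    else:
        G, psi_inv, cho = _capacitance(spec)
        # det(Psi + G G^T) = det(Psi) det(I + G^T Psi^{-1} G)
        logdet = float(-np.sum(np.log(psi_inv)) + 2.0 * np.sum(np.log(np.diag(cho[0]))))
        X0 = centered * psi_inv[:, None]
        quad = float(np.sum(centered * X0))
        if G.shape[1]:
            GtX = G.T @ X0
            quad -= float(np.sum(GtX * linalg.cho_solve(cho, GtX)))
    return -0.5 * (n * spec.d_all * np.log(2.0 * np.pi) + n * logdet + quad)
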