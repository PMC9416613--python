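"""Independent dense linear-algebra oracles used by the test suite.

Everything here is deliberately naive: dense covariance assembly, explicit
inverses, brute-force joint-Gaussian conditioning, and the stacked
closed-form ridge solution.  None of it shares code paths with the package
implementation it checks.
"""

from __future__ import annotations

import numpy as np


def dense_marginal_cov(loadings, noise_vars, latent_cov):
    """Assemble ``P Sigma_c P^T + Psi`` explicitly."""
    P = np.vstack(loadings)
    psi = np.concatenate(
        [np.full(L.shape[0], v) for L, v in zip(loadings, noise_vars)]
    )
    return P @ latent_cov @ P.T + np.diag(psi)


def dense_loglik(loadings, means, noise_vars, latent_cov, B):
    """Naive multivariate-normal log-density summed over columns."""
    cov = dense_marginal_cov(loadings, noise_vars, latent_cov)
    mu = np.concatenate(means)
    d = cov.shape[0]
    sign, logdet = np.linalg.slogdet(cov)
    assert sign > 0
    inv = np.linalg.inv(cov)
    total = 0.0
    for n in range(B.shape[1]):
        x = B[:, n] - mu
        total += -0.5 * (d * np.log(2 * np.pi) + logdet + x @ inv @ x)
    return total


def condition_joint_gaussian(loadings, means, noise_vars, latent_cov, b):
    """Posterior of the latent by explicit joint-Gaussian conditioning.

    Builds the full ``(k + d_all)``-dimensional joint covariance of
    ``(c, b)`` and conditions directly; returns ``(E[c|b], Var[c|b])``.
    """
    P = np.vstack(loadings)
    mu = np.concatenate(means)
    k = latent_cov.shape[0]
    cov_bb = dense_marginal_cov(loadings, noise_vars, latent_cov)
    cov_cb = latent_cov @ P.T
    gain = cov_cb @ np.linalg.inv(cov_bb)
    mean = gain @ (b - mu)
    var = latent_cov - gain @ cov_cb.T
    assert var.shape == (k, k)
    return mean, var


def polar_factor_svd(A):
    """Orthogonal-Procrustes polar factor via the thin SVD, ``U V^T``."""
    U, _, Vt = np.linalg.svd(A, full_matrices=False)
    return U @ Vt


def joint_block_ridge(V, C, H, lam_c, lam_h):
    """Stacked closed-form minimizer of the two-block ridge objective.

    ``[P_com P_ind] = V Z^T (Z Z^T + Lambda)^{-1}`` with ``Z = [C; H]`` and
    ``Lambda = diag(lam_c I, lam_h I)``.
    """
    Z = np.vstack([C, H])
    lam = np.concatenate([np.full(C.shape[0], lam_c), np.full(H.shape[0], lam_h)])
    G = Z @ Z.T + np.diag(lam)
    P = V @ Z.T @ np.linalg.inv(G)
    return P[:, : C.shape[0]], P[:, C.shape[0]:]


def procrustes_r2(C_hat, C_true):
    """R^2 between latents after orthogonal alignment with optimal scale."""
    from scipy.linalg import orthogonal_procrustes

    R, _ = orthogonal_procrustes(C_hat.T, C_true.T)
    A = R.T @ C_hat
    s = float(np.sum(A * C_true) / np.sum(A * A))
    resid = C_true - s * A
    return 1.0 - float(np.sum(resid**2) / np.sum((C_true - C_true.mean()) ** 2))


def random_spec_arrays(rng, J=None, d_max=10, k_max=4):
    """Random valid model parameters (loadings orthonormal via QR)."""
    if J is None:
        J = int(rng.integers(1, 4))
    k = int(rng.integers(1, k_max + 1))
    dims = [int(rng.integers(k, d_max + 1)) for _ in range(J)]
    loadings = []
    for d in dims:
        Q, _ = np.linalg.qr(rng.standard_normal((d, k)))
        loadings.append(Q)
    means = [rng.standard_normal(d) for d in dims]
    noise_vars = [float(rng.uniform(0.1, 2.0)) for _ in range(J)]
    W = rng.standard_normal((k, k + 2))
    latent_cov = W @ W.T / (k + 2)
    return loadings, means, noise_vars, latent_cov
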