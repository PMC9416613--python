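"""Regularized visual decoder.

Maps a subject's shared features ``C`` (d_com x N) and individual features
``H`` (d_ind x N) to visual features ``V`` (d_v x N) through two projection
matrices, by minimizing

    || V - (P_com C + P_ind H) ||_F^2
        + lambda_com ||P_com||_F^2 + lambda_ind ||P_ind||_F^2.

The objective is jointly convex (strictly for positive penalties), so the
alternating closed-form ridge updates

    P_com <- (V - P_ind H) C^T (C C^T + lambda_com I)^{-1}
    P_ind <- (V - P_com C) H^T (H H^T + lambda_ind I)^{-1}

converge to the unique joint minimizer.  Prediction is linear:
``v_est = P_com c + P_ind h``.

Either feature block may be empty (zero rows), which yields the single-block
ridge decoder — this is how the shared-only and individual-only ablations are
run without special casing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

__all__ = [
    "VisualDecoder",
    "decoder_objective",
    "fit_decoder",
    "predict_visual",
]


@dataclass
class VisualDecoder:
    """Fitted per-subject decoder: projections, penalties and fit metadata."""

    P_com: np.ndarray  # d_v x d_com
    P_ind: np.ndarray  # d_v x d_ind
    lambda_com: float
    lambda_ind: float
    fit_info: dict = field(default_factory=dict)


def _as_feature_matrix(X: np.ndarray | None, n: int | None, name: str) -> np.ndarray:
    if X is None:
        X = np.zeros((0, 0 if n is None else n))
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"{name} must be a 2-d matrix, got shape {X.shape}")
    return X


def decoder_objective(
    dec: VisualDecoder, V: np.ndarray, C: np.ndarray, H: np.ndarray
) -> float:
    """Value of the penalized reconstruction objective at ``dec``."""
    V = np.asarray(V, dtype=float)
    C = _as_feature_matrix(C, V.shape[1], "C")
    H = _as_feature_matrix(H, V.shape[1], "H")
    if C.shape[1] != V.shape[1] or H.shape[1] != V.shape[1]:
        raise ValueError("V, C and H must have the same number of columns")
    resid = V - (dec.P_com @ C + dec.P_ind @ H)
    return (
        float(np.sum(resid * resid))
        + dec.lambda_com * float(np.sum(dec.P_com**2))
        + dec.lambda_ind * float(np.sum(dec.P_ind**2))
    )


def _gram_factor(X: np.ndarray, lam: float, name: str):
    """Cholesky factor of ``X X^T + lam I`` (constant across sweeps)."""
    k = X.shape[0]
    if k == 0:
        return None
    G = X @ X.T + lam * np.eye(k)
    try:
        cho = linalg.cho_factor(0.5 * (G + G.T), lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"Gram matrix for {name} is singular; use a positive penalty"
        ) from exc
    # guard against semidefinite-but-factorizable near-singularity at lam=0
    diag = np.diag(cho[0])
    if lam == 0.0 and diag.min() <= 1e-10 * max(diag.max(), 1.0):
        raise ValueError(
            f"Gram matrix for {name} is numerically singular; use a positive penalty"
        )
    return cho


def _ridge_update(numerator: np.ndarray, cho) -> np.ndarray:
    """Solve ``P (X X^T + lam I) = numerator`` with a prefactored Gram matrix."""
    if cho is None:
        return np.zeros((numerator.shape[0], 0))
    return linalg.cho_solve(cho, numerator.T).T


def fit_decoder(
    V: np.ndarray,
    C: np.ndarray,
    H: np.ndarray,
    lambda_com: float = 0.1,
    lambda_ind: float = 0.1,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> VisualDecoder:
    """Fit the decoder by alternating closed-form ridge updates.

    Starts from ``P_ind = 0``; records the objective after every half-update
    and stops when the relative parameter change over a full sweep drops
    below ``tol`` or after ``max_iter`` sweeps.  Because the objective
    flattens quadratically near the optimum, the stop is on the projection
    matrices themselves, which keeps the end point at the unique joint
    minimizer (for any positive penalty) to the tolerance of the solve.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("V must be a 2-d (features x samples) matrix")
    C = _as_feature_matrix(C, V.shape[1], "C")
    H = _as_feature_matrix(H, V.shape[1], "H")
    if C.shape[1] != V.shape[1] or H.shape[1] != V.shape[1]:
        raise ValueError("V, C and H must have the same number of columns")
    if lambda_com < 0 or lambda_ind < 0:
        raise ValueError("penalties must be nonnegative")
    dec = VisualDecoder(
        P_com=np.zeros((V.shape[0], C.shape[0])),
        P_ind=np.zeros((V.shape[0], H.shape[0])),
        lambda_com=float(lambda_com),
        lambda_ind=float(lambda_ind),
    )
    cho_c = _gram_factor(C, dec.lambda_com, "C")
    cho_h = _gram_factor(H, dec.lambda_ind, "H")
    VCt, VHt, HCt = V @ C.T, V @ H.T, H @ C.T
    trace = [decoder_objective(dec, V, C, H)]
    n_iter = 0
    for _ in range(max_iter):
        P_com_old, P_ind_old = dec.P_com, dec.P_ind
        dec.P_com = _ridge_update(VCt - dec.P_ind @ HCt, cho_c)
        trace.append(decoder_objective(dec, V, C, H))
        dec.P_ind = _ridge_update(VHt - dec.P_com @ HCt.T, cho_h)
        trace.append(decoder_objective(dec, V, C, H))
        n_iter += 1
        for a, b in ((trace[-3], trace[-2]), (trace[-2], trace[-1])):
            if b > a + 1e-10 * max(1.0, abs(a)):
                raise RuntimeError(
                    f"decoder objective increased from {a:.12g} to {b:.12g}"
                )
        delta = max(
            np.abs(dec.P_com - P_com_old).max(initial=0.0),
            np.abs(dec.P_ind - P_ind_old).max(initial=0.0),
        )
        scale = max(
            1.0,
            np.abs(dec.P_com).max(initial=0.0),
            np.abs(dec.P_ind).max(initial=0.0),
        )
        if delta < tol * scale:
            break
    dec.fit_info = {"iterations": n_iter, "objective_trace": trace, "tol": tol}
    return dec


def predict_visual(
    dec: VisualDecoder, c_test: np.ndarray, h_test: np.ndarray
) -> np.ndarray:
    """Predict visual features, ``v_est = P_com c + P_ind h`` (linear in both)."""
    c = np.asarray(c_test, dtype=float)
    h = np.asarray(h_test, dtype=float)
    squeeze = c.ndim == 1 and h.ndim == 1
    C = c[:, None] if c.ndim == 1 else c
    H = h[:, None] if h.ndim == 1 else h
    if C.shape[0] != dec.P_com.shape[1]:
        raise ValueError(
            f"shared features have {C.shape[0]} rows, expected {dec.P_com.shape[1]}"
        )
    if H.shape[0] != dec.P_ind.shape[1]:
        raise ValueError(
            f"individual features have {H.shape[0]} rows, expected {dec.P_ind.shape[1]}"
        )
    if C.shape[0] and H.shape[0] and C.shape[1] != H.shape[1]:
        raise ValueError("c_test and h_test must have the same number of columns")
    n = C.shape[1] if C.shape[0] else H.shape[1]
    out = np.zeros((dec.P_com.shape[0], n))
    if C.shape[0]:
        out += dec.P_com @ C
    if H.shape[0]:
        out += dec.P_ind @ H
    return out[:, 0] if squeeze else out
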