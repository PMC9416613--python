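"""Single-subject individual-feature model.

Each subject additionally carries latent features ``h_{i,n}`` not assumed to
be shared across subjects:

    b_{i,n} = P'_i h_{i,n} + mu_i + eps'_i,  h_{i,n} ~ N(0, Sigma'_{h_i}).

The model is exactly the shared model restricted to one subject — the EM
steps and extraction are identical, no cross-subject parameter pooling — so
fitting delegates to :func:`mspgm.shared.fit_shared` with ``J=1``.  This
keeps the two implementations from drifting apart.
"""

from __future__ import annotations

import numpy as np

from .shared import (
    SharedPGMModel,
    SubjectData,
    extract_shared_subject,
    fit_shared,
)

__all__ = ["IndividualPGMModel", "fit_individual", "extract_individual"]


class IndividualPGMModel(SharedPGMModel):
    """Fitted individual-feature model (a one-subject latent Gaussian model)."""

    @property
    def d_ind(self) -> int:
        return self.spec.latent_dim


def fit_individual(
    subject: SubjectData,
    d_ind: int,
    max_iter: int = 10,
    seed: int | None = 0,
    early_stop_tol: float | None = None,
    check_monotone: bool = True,
) -> IndividualPGMModel:
    """Fit the individual model by the same EM as the shared model at ``J=1``."""
    model = fit_shared(
        [subject],
        d_ind,
        max_iter=max_iter,
        seed=seed,
        early_stop_tol=early_stop_tol,
        check_monotone=check_monotone,
    )
    return IndividualPGMModel(
        spec=model.spec, fit_info=model.fit_info, model_kind="individual"
    )


def extract_individual(
    model: IndividualPGMModel | SharedPGMModel, B_i: np.ndarray, mode: str = "pinv"
) -> np.ndarray:
    """Individual features ``h_{i,n} = P'^+ (b_{i,n} - mu_i) = P'^T (b_{i,n} - mu_i)``."""
    if model.spec.n_subjects != 1:
        raise ValueError("an individual model must have exactly one subject")
    return extract_shared_subject(model, 0, B_i, mode=mode)
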