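import numpy as np
import pytest

from mspgm import LatentGaussianSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def scalar_spec():
    """J=1, d=1, P=[1], Sigma_c=[1], rho2=1, mu=0: marginal N(0, 2)."""
    return LatentGaussianSpec(
        loadings=[np.array([[1.0]])],
        means=[np.zeros(1)],
        noise_vars=[1.0],
        latent_cov=np.array([[1.0]]),
    )


@pytest.fixture
def two_subject_scalar_spec():
    """J=2, d_i=1, P_i=[1], Sigma_c=[1], rho_i2=1: covariance [[2,1],[1,2]]."""
    return LatentGaussianSpec(
        loadings=[np.array([[1.0]]), np.array([[1.0]])],
        means=[np.zeros(1), np.zeros(1)],
        noise_vars=[1.0, 1.0],
        latent_cov=np.array([[1.0]]),
    )


def make_spec(rng, J=None, d_max=10, k_max=4):
    from oracles import random_spec_arrays

    loadings, means, noise_vars, latent_cov = random_spec_arrays(
        rng, J=J, d_max=d_max, k_max=k_max
    )
    return LatentGaussianSpec(
        loadings=loadings, means=means, noise_vars=noise_vars, latent_cov=latent_cov
    )
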