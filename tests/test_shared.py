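"""Shared-feature EM: E/M steps against conditioning oracles, fitting, extraction."""

import numpy as np
import pytest
from scipy.linalg import subspace_angles

from oracles import condition_joint_gaussian, procrustes_r2

import mspgm
from mspgm import (
    EStepStats,
    SubjectData,
    e_step,
    extract_shared_combined,
    extract_shared_subject,
    fit_shared,
    init_shared,
    m_step,
)


def _subjects_from(B_list):
    return [SubjectData(subject_id=f"S{i}", B=B) for i, B in enumerate(B_list)]


class TestSubjectData:
    def test_mean_computed_and_validated(self, rng):
        B = rng.standard_normal((4, 6))
        s = SubjectData(subject_id="a", B=B)
        np.testing.assert_allclose(s.mu, B.mean(axis=1))
        with pytest.raises(ValueError, match="mean"):
            SubjectData(subject_id="a", B=B, mu=B.mean(axis=1) + 0.1)


class TestInitShared:
    def test_orthonormal_and_deterministic(self, rng):
        subs = _subjects_from([rng.standard_normal((7, 10)) for _ in range(2)])
        m1 = init_shared(subs, 3, seed=42)
        m2 = init_shared(subs, 3, seed=42)
        for P, Q in zip(m1.spec.loadings, m2.spec.loadings):
            np.testing.assert_allclose(P.T @ P, np.eye(3), atol=1e-10)
            assert np.array_equal(P, Q)  # bit-identical

    def test_boundary_and_errors(self, rng):
        subs = _subjects_from([rng.standard_normal((5, 8)), rng.standard_normal((4, 8))])
        init_shared(subs, 4, seed=0)  # d_com == min d_i accepted
        with pytest.raises(ValueError, match="exceeds"):
            init_shared(subs, 5, seed=0)
        one = _subjects_from([rng.standard_normal((5, 1))])
        with pytest.raises(ValueError, match="2 samples"):
            init_shared(one, 2, seed=0)


class TestEStep:
    def test_scalar_single_subject_conditioning(self, scalar_spec):
        model = mspgm.SharedPGMModel(
            spec=scalar_spec, fit_info=mspgm.FitInfo(0, [], 0, 0)
        )
        subs = _subjects_from([np.array([[2.0, -2.0]])])  # zero mean
        stats = e_step(model, subs)
        np.testing.assert_allclose(stats.expectations, [[1.0, -1.0]])
        np.testing.assert_allclose(stats.cond_var, [[0.5]])

    def test_two_subject_scalar_conditioning(self, two_subject_scalar_spec):
        model = mspgm.SharedPGMModel(
            spec=two_subject_scalar_spec, fit_info=mspgm.FitInfo(0, [], 0, 0)
        )
        subs = _subjects_from([np.array([[3.0, -3.0]]), np.array([[3.0, -3.0]])])
        stats = e_step(model, subs)
        np.testing.assert_allclose(stats.expectations[:, 0], [2.0])
        np.testing.assert_allclose(stats.cond_var, [[1.0 / 3.0]])

    def test_centered_input_gives_zero_expectations(self, rng):
        subs = _subjects_from([rng.standard_normal((6, 5))])
        model = init_shared(subs, 2, seed=0)
        mu_only = _subjects_from([np.tile(subs[0].mu[:, None], (1, 5))])
        stats = e_step(model, mu_only)
        np.testing.assert_allclose(stats.expectations, 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_joint_gaussian_conditioning_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        from conftest import make_spec

        base = make_spec(rng, d_max=10, k_max=4)
        N = 4
        B = rng.standard_normal((base.d_all, N)) + base.stacked_mean[:, None]
        subs, pos = [], 0
        for i, d in enumerate(base.dims):
            subs.append(SubjectData(subject_id=f"S{i}", B=B[pos : pos + d]))
            pos += d
        # model means are the data row means, as the EM construction has them
        spec = mspgm.LatentGaussianSpec(
            loadings=base.loadings,
            means=[s.mu for s in subs],
            noise_vars=base.noise_vars,
            latent_cov=base.latent_cov,
        )
        model = mspgm.SharedPGMModel(spec=spec, fit_info=mspgm.FitInfo(0, [], 0, 0))
        stats = e_step(model, subs)
        for n in range(N):
            mean, var = condition_joint_gaussian(
                spec.loadings, [s.mu for s in subs], spec.noise_vars,
                spec.latent_cov, B[:, n],
            )
            np.testing.assert_allclose(stats.expectations[:, n], mean, atol=1e-8)
            np.testing.assert_allclose(stats.cond_var, var, atol=1e-8)
            np.testing.assert_allclose(
                stats.second_moments[n],
                var + np.outer(mean, mean),
                atol=1e-8,
            )

    def test_second_moment_invariant(self, rng):
        E = rng.standard_normal((3, 5))
        V = np.eye(3) * 0.3
        stats = EStepStats(expectations=E, cond_var=V)
        for n in range(5):
            np.testing.assert_allclose(
                stats.second_moments[n] - np.outer(E[:, n], E[:, n]), V, atol=1e-10
            )


class TestMStep:
    def test_hand_worked_update(self):
        # d=2, d_com=1, N=2, centered columns (1,0) and (-1,0)
        B = np.array([[1.0, -1.0], [0.0, 0.0]])
        subs = _subjects_from([B])
        model = init_shared(subs, 1, seed=0)
        stats = EStepStats(
            expectations=np.array([[1.0, -1.0]]), cond_var=np.array([[0.5]])
        )  # E[c^2] = 1.5 for both samples
        new = m_step(stats, subs, model)
        np.testing.assert_allclose(new.spec.loadings[0], [[1.0], [0.0]], atol=1e-12)
        assert new.spec.noise_vars[0] == pytest.approx(0.25)
        np.testing.assert_allclose(new.spec.latent_cov, [[1.5]])

    def test_zero_expectations_average_identity(self, rng):
        subs = _subjects_from([rng.standard_normal((5, 4))])
        model = init_shared(subs, 2, seed=1)
        stats = EStepStats(
            expectations=np.zeros((2, 4)), cond_var=np.eye(2)
        )
        with pytest.raises(Exception):
            # A_i = 0 is rank deficient: loud failure, not silent regularization
            m_step(stats, subs, model)
        # with tiny nonzero expectations the Sigma_c update is dominated by I
        stats2 = EStepStats(
            expectations=1e-8 * rng.standard_normal((2, 4)), cond_var=np.eye(2)
        )
        new = m_step(stats2, subs, model)
        np.testing.assert_allclose(new.spec.latent_cov, np.eye(2), atol=1e-12)

    def test_updated_loadings_orthonormal(self, rng):
        subs = _subjects_from([rng.standard_normal((8, 12)) for _ in range(2)])
        model = init_shared(subs, 3, seed=3)
        stats = e_step(model, subs)
        new = m_step(stats, subs, model)
        for P in new.spec.loadings:
            assert np.abs(P.T @ P - np.eye(3)).max() <= 1e-10


class TestFitShared:
    def test_loglik_trace_monotone(self, rng):
        subs, _ = mspgm.gen_multisubject(
            J=2, d_list=12, d_com=3, d_ind=0, N=60, noise_vars=0.3, seed=5
        )
        model = fit_shared(subs, 3, seed=6)
        diffs = np.diff(model.fit_info.loglik_trace)
        assert diffs.min() >= -1e-8
        assert model.fit_info.iterations == 10

    def test_subspace_recovery_on_model_data(self):
        subs, gt = mspgm.gen_multisubject(
            J=3, d_list=30, d_com=4, d_ind=0, N=200, noise_vars=0.05, seed=7
        )
        model = fit_shared(subs, 4, seed=8)
        angles = [
            np.degrees(subspace_angles(gt.loadings_shared[i], model.spec.loadings[i])).mean()
            for i in range(3)
        ]
        assert np.mean(angles) < 10.0

    def test_noiseless_reconstruction(self):
        subs, gt = mspgm.gen_multisubject(
            J=2, d_list=20, d_com=3, d_ind=0, N=120, noise_vars=1e-6, seed=9
        )
        model = fit_shared(subs, 3, seed=10)
        for i, s in enumerate(subs):
            C_i = extract_shared_subject(model, i, s.B)
            recon = model.spec.loadings[i] @ C_i + model.spec.means[i][:, None]
            rel = np.linalg.norm(s.B - recon) / np.linalg.norm(s.centered())
            assert rel < 0.05

    def test_early_stop_recorded(self, rng):
        subs, _ = mspgm.gen_multisubject(
            J=1, d_list=10, d_com=2, d_ind=0, N=40, noise_vars=0.2, seed=11
        )
        model = fit_shared(subs, 2, max_iter=50, seed=12, early_stop_tol=1e-9)
        assert model.fit_info.converged_early
        assert model.fit_info.iterations < 50

    def test_permuting_subjects_invariant(self, rng):
        subs, _ = mspgm.gen_multisubject(
            J=3, d_list=[8, 9, 10], d_com=2, d_ind=0, N=30, noise_vars=0.4, seed=13
        )
        model = fit_shared(subs, 2, seed=14)
        B = np.vstack([s.B for s in subs])
        ll = mspgm.marginal_loglik(model.spec, B)
        C = extract_shared_combined(model, B)
        perm = [2, 0, 1]
        spec_p = mspgm.LatentGaussianSpec(
            loadings=[model.spec.loadings[i] for i in perm],
            means=[model.spec.means[i] for i in perm],
            noise_vars=[model.spec.noise_vars[i] for i in perm],
            latent_cov=model.spec.latent_cov,
        )
        model_p = mspgm.SharedPGMModel(spec=spec_p, fit_info=model.fit_info)
        B_p = np.vstack([subs[i].B for i in perm])
        assert mspgm.marginal_loglik(spec_p, B_p) == pytest.approx(ll, abs=1e-7)
        np.testing.assert_allclose(
            extract_shared_combined(model_p, B_p), C, atol=1e-9
        )


class TestExtraction:
    def test_mean_input_gives_zero(self, rng):
        subs, _ = mspgm.gen_multisubject(
            J=2, d_list=10, d_com=2, d_ind=0, N=20, noise_vars=0.2, seed=15
        )
        model = fit_shared(subs, 2, seed=16)
        mu = model.spec.stacked_mean
        np.testing.assert_allclose(extract_shared_combined(model, mu), 0.0, atol=1e-10)
        np.testing.assert_allclose(
            extract_shared_subject(model, 0, model.spec.means[0]), 0.0, atol=1e-10
        )

    def test_combined_equals_pinv_oracle(self, rng):
        subs, _ = mspgm.gen_multisubject(
            J=3, d_list=[8, 12, 9], d_com=3, d_ind=0, N=25, noise_vars=0.3, seed=17
        )
        model = fit_shared(subs, 3, seed=18)
        B = np.vstack([s.B for s in subs])
        centered = B - model.spec.stacked_mean[:, None]
        expected = np.linalg.pinv(model.spec.stacked_loading) @ centered
        np.testing.assert_allclose(
            extract_shared_combined(model, B), expected, atol=1e-9
        )

    def test_subject_average_reproduces_combined(self, rng):
        subs, _ = mspgm.gen_multisubject(
            J=3, d_list=10, d_com=2, d_ind=0, N=30, noise_vars=0.2, seed=19
        )
        model = fit_shared(subs, 2, seed=20)
        B = np.vstack([s.B for s in subs])
        per_subject = np.mean(
            [extract_shared_subject(model, i, subs[i].B) for i in range(3)], axis=0
        )
        np.testing.assert_allclose(
            extract_shared_combined(model, B), per_subject, atol=1e-9
        )

    def test_posterior_mode_matches_e_step(self, rng):
        subs, _ = mspgm.gen_multisubject(
            J=2, d_list=9, d_com=2, d_ind=0, N=15, noise_vars=0.3, seed=21
        )
        model = fit_shared(subs, 2, seed=22)
        B = np.vstack([s.B for s in subs])
        stats = e_step(model, subs)
        np.testing.assert_allclose(
            extract_shared_combined(model, B, mode="posterior"),
            stats.expectations,
            atol=1e-9,
        )

    def test_identifiability_up_to_rotation_high_snr(self):
        subs, gt = mspgm.gen_multisubject(
            J=3, d_list=25, d_com=3, d_ind=0, N=500,
            noise_vars=0.01 * 3 / 25, seed=23,
        )
        model = fit_shared(subs, 3, seed=24)
        C_hat = extract_shared_combined(model, np.vstack([s.B for s in subs]))
        assert procrustes_r2(C_hat, gt.C) >= 0.95
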