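"""Penalty evaluation, ADMM update steps, and the full solver."""

import numpy as np
import pytest

from rcfgl import (ChainSignal, CovariancePanel, PenaltyConfig,
                   fused_lasso_prox_1d, objective_value, penalty_value,
                   rcfgl_fit, theta_update, u_update, z_update)

from conftest import random_binary_weights, random_covariance_panel
from oracles import exact_fused_objective, fused_logdet_oracle


def _random_sym_panel(rng, K, p):
    th = rng.normal(0, 1, (K, p, p))
    return (th + np.transpose(th, (0, 2, 1))) / 2


class TestPenaltyValue:
    def test_k2_pairwise_equals_sequential(self, rng):
        th = _random_sym_panel(rng, 2, 5)
        fgl = penalty_value(th, PenaltyConfig(0.3, 0.7, "FGL"))
        fmgl = penalty_value(th, PenaltyConfig(0.3, 0.7, "FMGL"))
        assert fgl == pytest.approx(fmgl, rel=1e-12)

    def test_k3_hand_case(self):
        # p=2, off-diagonal chain (0, 1, 2), lambda1=0, lambda2=1:
        # pairwise differences |0-1|+|1-2|+|0-2| = 4, sequential = 2;
        # ordered-pair sums double them.
        th = np.zeros((3, 2, 2))
        for k, v in enumerate((0.0, 1.0, 2.0)):
            th[k, 0, 1] = th[k, 1, 0] = v
        assert penalty_value(th, PenaltyConfig(0.0, 1.0, "FGL")) == 8.0
        assert penalty_value(th, PenaltyConfig(0.0, 1.0, "FMGL")) == 4.0

    def test_zero_theta_all_flavors(self):
        th = np.zeros((3, 4, 4))
        Wd = {(a, b): np.ones((4, 4)) for a in range(3) for b in range(a + 1, 3)}
        Ws = [np.ones((4, 4))] * 2
        for flavor, w in (("FGL", None), ("FMGL", None),
                          ("CFGL", Wd), ("RCFGL", Ws)):
            assert penalty_value(th, PenaltyConfig(0.5, 0.5, flavor, w)) == 0.0

    def test_all_ones_weights_match_fmgl(self, rng):
        th = _random_sym_panel(rng, 4, 6)
        ones = [np.ones((6, 6))] * 3
        rc = penalty_value(th, PenaltyConfig(0.2, 0.9, "RCFGL", ones))
        fm = penalty_value(th, PenaltyConfig(0.2, 0.9, "FMGL"))
        assert rc == pytest.approx(fm, rel=1e-12)

    def test_cfgl_requires_weight_dict(self, rng):
        th = _random_sym_panel(rng, 3, 4)
        with pytest.raises(ValueError):
            penalty_value(th, PenaltyConfig(0.1, 0.1, "CFGL",
                                            [np.ones((4, 4))] * 2))


class TestObjectiveValue:
    def test_identity_hand_case(self):
        # Theta=I, S=I: logdet=0, trace=p, objective = n*p = 15
        cov = CovariancePanel(conditions=["a"], S=np.eye(3)[None],
                              n=np.array([5]), gene_ids=["g1", "g2", "g3"])
        val = objective_value(np.eye(3)[None], cov, PenaltyConfig(0.0, 0.0, "FMGL"))
        assert val == pytest.approx(15.0)

    def test_lambda1_with_diagonal_theta_no_effect(self):
        cov = CovariancePanel(conditions=["a"], S=np.eye(3)[None],
                              n=np.array([5]), gene_ids=["g1", "g2", "g3"])
        th = np.diag([1.0, 2.0, 3.0])[None]
        v0 = objective_value(th, cov, PenaltyConfig(0.0, 0.0, "FMGL"))
        v1 = objective_value(th, cov, PenaltyConfig(7.0, 0.0, "FMGL"))
        assert v0 == pytest.approx(v1)

    def test_mle_beats_identity(self, rng):
        cov = random_covariance_panel(rng, 1, 4, 50)
        cfg = PenaltyConfig(0.0, 0.0, "FMGL")
        mle = np.linalg.inv(cov.S[0])[None]
        assert (objective_value(mle, cov, cfg)
                < objective_value(np.eye(4)[None], cov, cfg))

    def test_non_pd_rejected(self, rng):
        cov = random_covariance_panel(rng, 1, 3, 20)
        with pytest.raises(ValueError):
            objective_value(-np.eye(3)[None], cov, PenaltyConfig(0.0, 0.0, "FMGL"))


class TestThetaUpdate:
    def test_scalar_closed_form(self):
        # p=1, n=2, rho=1, S=1, Z=U=0: theta solves -2(1/t - 1) + t = 0
        th = theta_update(np.array([[1.0]]), 2, np.zeros((1, 1)),
                          np.zeros((1, 1)), 1.0)
        assert th[0, 0] == pytest.approx(np.sqrt(3) - 1, abs=1e-12)

    def test_always_positive_definite(self, rng):
        for _ in range(10):
            p = int(rng.integers(2, 9))
            S = _random_sym_panel(rng, 1, p)[0]
            Z = _random_sym_panel(rng, 1, p)[0]
            U = _random_sym_panel(rng, 1, p)[0]
            th = theta_update(S, 5, Z, U, 1.5)
            assert np.linalg.eigvalsh(th)[0] > 0

    def test_stationarity_certificate(self, rng):
        for _ in range(20):
            p = int(rng.integers(1, 9))
            n_k = int(rng.integers(1, 20))
            rho = float(rng.uniform(0.5, 2.0))
            S = _random_sym_panel(rng, 1, p)[0]
            Z = _random_sym_panel(rng, 1, p)[0]
            U = _random_sym_panel(rng, 1, p)[0]
            th = theta_update(S, n_k, Z, U, rho)
            resid = -n_k * (np.linalg.inv(th) - S) + rho * (th - Z + U)
            assert np.abs(resid).max() < 1e-8


class TestZUpdate:
    def test_no_penalty_identity(self, rng):
        A = _random_sym_panel(rng, 3, 4)
        Z = z_update(A, PenaltyConfig(0.0, 0.0, "RCFGL"), rho=1.0)
        np.testing.assert_allclose(Z, A, atol=1e-14)

    def test_diagonal_untouched(self, rng):
        A = _random_sym_panel(rng, 3, 5)
        Z = z_update(A, PenaltyConfig(2.0, 3.0, "RCFGL"), rho=0.7)
        for k in range(3):
            np.testing.assert_allclose(np.diag(Z[k]), np.diag(A[k]))

    def test_separability_matches_chain_prox(self, rng):
        K, p = 4, 6
        A = _random_sym_panel(rng, K, p)
        W = random_binary_weights(rng, K, p)
        cfg = PenaltyConfig(0.4, 0.6, "RCFGL", W)
        Z = z_update(A, cfg, rho=2.0)
        i, j = 1, 4
        sig = ChainSignal(a=A[:, i, j], w=[W[k][i, j] for k in range(K - 1)],
                          t1=0.2, t2=0.3)
        np.testing.assert_allclose(Z[:, i, j], fused_lasso_prox_1d(sig),
                                   atol=1e-14)


def test_u_update_accumulates(rng):
    U = _random_sym_panel(rng, 2, 3)
    Th = _random_sym_panel(rng, 2, 3)
    Z = _random_sym_panel(rng, 2, 3)
    U1 = u_update(U, Th, Z)
    np.testing.assert_allclose(U1, U + Th - Z)
    np.testing.assert_allclose(u_update(U1, Th, Z), U + 2 * (Th - Z))
    np.testing.assert_allclose(u_update(U, Th, Th), U)


class TestRcfglFit:
    def test_large_lambda1_diagonal_limit(self, rng):
        cov = random_covariance_panel(rng, 2, 5, 30)
        lam_huge = 10 * max(cov.n[k] * np.abs(cov.S[k] - np.diag(np.diag(cov.S[k]))).max()
                            for k in range(2))
        est = rcfgl_fit(cov, lambda1=lam_huge, lambda2=0.0,
                        lambda_scale="absolute", tol=1e-8, max_iter=10000)
        for k in range(2):
            off = est.Z[k] - np.diag(np.diag(est.Z[k]))
            assert np.all(off == 0.0)
            np.testing.assert_allclose(np.diag(est.Theta[k]),
                                       1.0 / np.diag(cov.S[k]), atol=1e-4)

    def test_k1_matches_convex_oracle(self, rng):
        cov = random_covariance_panel(rng, 1, 3, 40)
        l1 = 1.5
        est = rcfgl_fit(cov, lambda1=l1, lambda2=0.0, lambda_scale="absolute",
                        tol=1e-10, max_iter=20000)
        obj = exact_fused_objective(est.Z, list(cov.S), list(cov.n), l1, 0.0)
        _, obj_o = fused_logdet_oracle(list(cov.S), list(cov.n), l1, 0.0)
        assert obj <= obj_o + 1e-4 * abs(obj_o)

    def test_k2_equals_pairwise_adaptive_oracle(self, rng):
        """At K=2 the sequential and pairwise condition-adaptive penalties
        coincide, so the fit must match a pairwise-penalty solver."""
        cov = random_covariance_panel(rng, 2, 4, 40)
        W = random_binary_weights(rng, 2, 4)
        l1, l2 = 1.0, 0.8
        est = rcfgl_fit(cov, weights=W, lambda1=l1, lambda2=l2,
                        lambda_scale="absolute", tol=1e-10, max_iter=20000)
        obj = exact_fused_objective(est.Z, list(cov.S), list(cov.n), l1, l2,
                                    W_seq=W)
        _, obj_o = fused_logdet_oracle(list(cov.S), list(cov.n), l1, l2,
                                       pairwise=True, W_pair={(0, 1): W[0]})
        assert obj <= obj_o + 1e-4 * abs(obj_o)

    def test_rfgl_mode_is_all_ones_weights(self, rng):
        cov = random_covariance_panel(rng, 3, 4, 30)
        e1 = rcfgl_fit(cov, lambda1=0.2, lambda2=0.1, mode="rfgl")
        ones = [np.ones((4, 4))] * 2
        e2 = rcfgl_fit(cov, weights=ones, lambda1=0.2, lambda2=0.1)
        np.testing.assert_allclose(e1.Theta, e2.Theta, atol=1e-12)

    def test_permutation_invariance_no_fusion(self, rng):
        cov = random_covariance_panel(rng, 3, 4, 30)
        est = rcfgl_fit(cov, lambda1=0.2, lambda2=0.0, tol=1e-8)
        perm = [2, 0, 1]
        est_p = rcfgl_fit(cov.reorder_conditions(perm), lambda1=0.2,
                          lambda2=0.0, tol=1e-8)
        for k, orig in enumerate(perm):
            np.testing.assert_allclose(est_p.Theta[k], est.Theta[orig],
                                       atol=1e-12)

    def test_large_lambda2_fuses_all_conditions(self, rng):
        cov = random_covariance_panel(rng, 3, 4, 30)
        est = rcfgl_fit(cov, lambda1=0.05, lambda2=50.0, mode="rfgl",
                        tol=1e-8, max_iter=20000)
        iu = np.triu_indices(4, k=1)
        spread = max(np.abs(est.Z[a][iu] - est.Z[b][iu]).max()
                     for a in range(3) for b in range(a + 1, 3))
        assert spread < 1e-6

    def test_weight_monotonicity(self, rng):
        """Activating one fusion weight never increases that pair's gap."""
        cov = random_covariance_panel(rng, 2, 3, 25)
        i, j = 0, 2
        gaps = []
        for wij in (0.0, 1.0):
            w = np.ones((3, 3))
            w[i, j] = w[j, i] = wij
            est = rcfgl_fit(cov, weights=[w], lambda1=0.1, lambda2=0.3,
                            tol=1e-9, max_iter=20000)
            gaps.append(abs(est.Z[0][i, j] - est.Z[1][i, j]))
        assert gaps[1] <= gaps[0] + 1e-8

    def test_nonconvergence_warns_not_raises(self, rng):
        cov = random_covariance_panel(rng, 2, 4, 30)
        est = rcfgl_fit(cov, lambda1=0.2, lambda2=0.1, max_iter=1)
        assert est.converged is False
        assert est.n_iter == 1

    def test_feasibility_at_convergence(self, rng):
        cov = random_covariance_panel(rng, 3, 5, 40)
        est = rcfgl_fit(cov, lambda1=0.2, lambda2=0.1, tol=1e-6,
                        max_iter=10000)
        assert est.converged
        for k in range(3):
            rel = (np.linalg.norm(est.Theta[k] - est.Z[k])
                   / max(1.0, np.linalg.norm(est.Z[k])))
            assert rel < 1e-6
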