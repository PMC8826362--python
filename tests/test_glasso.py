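"""Graphical lasso, EBIC and path selection."""

import numpy as np
import pytest

from qolnet.glasso import (
    ebic,
    ebicglasso_path,
    graphical_lasso,
    kkt_residuals,
    pcor_from_precision,
)


class TestGraphicalLasso:
    def test_identity_input_gives_identity_precision(self):
        Theta, W = graphical_lasso(np.eye(4), 0.2)
        np.testing.assert_allclose(Theta, np.eye(4), atol=1e-8)

    def test_bivariate_soft_threshold_kills_edge(self):
        """p=2: the off-diagonal survives only when |s12| > lambda."""
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        Theta, _ = graphical_lasso(S, 0.6)
        assert Theta[0, 1] == 0.0

    def test_bivariate_closed_form(self):
        """p=2, s12=0.5, lam=0.2: W12 = s12 - lam = 0.3; invert the 2x2."""
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        Theta, W = graphical_lasso(S, 0.2, tol=1e-10)
        assert W[0, 1] == pytest.approx(0.3, abs=1e-6)
        ref = np.linalg.inv(np.array([[1.0, 0.3], [0.3, 1.0]]))
        np.testing.assert_allclose(Theta, ref, atol=1e-6)
        assert pcor_from_precision(Theta)[0, 1] > 0

    @pytest.mark.parametrize("seed", range(5))
    def test_kkt_conditions_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.integers(3, 7)
        X = rng.normal(size=(150, p))
        S = np.corrcoef(X.T)
        lam = rng.uniform(0.05, 0.3)
        Theta, _ = graphical_lasso(S, lam, tol=1e-9)
        r_zero, r_nz = kkt_residuals(Theta, S, lam)
        assert r_zero <= 1e-4
        assert r_nz <= 1e-4

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_independent_solver(self, seed):
        """Cross-check against scikit-learn's independent implementation."""
        from sklearn.covariance import graphical_lasso as sk_glasso

        rng = np.random.default_rng(100 + seed)
        X = rng.normal(size=(300, 5))
        S = np.corrcoef(X.T)
        Theta, _ = graphical_lasso(S, 0.1, tol=1e-10)
        _, prec = sk_glasso(S, alpha=0.1, tol=1e-9, max_iter=2000)
        np.testing.assert_allclose(Theta, prec, atol=5e-4)

    def test_negative_lambda_raises(self):
        with pytest.raises(ValueError):
            graphical_lasso(np.eye(3), -0.1)


class TestEbic:
    def test_gamma_zero_reduces_to_bic(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 3))
        S = np.corrcoef(X.T)
        Theta = np.linalg.inv(S)
        n = 100
        p = 3
        E = 3
        loglik = np.linalg.slogdet(Theta)[1] - np.sum(S * Theta)
        bic = -n * loglik + E * np.log(n)
        assert ebic(Theta, S, n, gamma=0.0) == pytest.approx(bic)

    def test_empty_beats_saturated_on_identity(self):
        S = np.eye(4)
        empty = np.eye(4)
        sat = np.eye(4) + 1e-6 * (np.ones((4, 4)) - np.eye(4))
        for n in (2, 50, 1000):
            assert ebic(empty, S, n, 0.5) < ebic(sat, S, n, 0.5)

    def test_hand_computed_instance(self):
        """p=3 with one edge: assemble the three terms by hand."""
        S = np.array([
            [1.0, 0.4, 0.0],
            [0.4, 1.0, 0.0],
            [0.0, 0.0, 1.0],
        ])
        Theta = np.array([
            [1.2, -0.3, 0.0],
            [-0.3, 1.2, 0.0],
            [0.0, 0.0, 1.0],
        ])
        n, gamma = 100, 0.5
        logdet = np.log(1.2 * 1.2 - 0.09)
        trace = 1.2 + 1.2 + 1.0 + 2 * 0.4 * (-0.3)
        expected = -n * (logdet - trace) + 1 * np.log(n) + 4 * 1 * gamma * np.log(3)
        assert ebic(Theta, S, n, gamma) == pytest.approx(expected, abs=1e-10)

    def test_non_spd_precision_raises(self):
        S = np.eye(2)
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            ebic(bad, S, 100, 0.5)


class TestEbicglassoPath:
    def test_identity_selects_empty_network(self):
        net = ebicglasso_path(np.eye(6) + 0.0, n=500)
        assert net.edge_count == 0

    def test_heavier_gamma_never_denser(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 8))
        X[:, 1] += 0.5 * X[:, 0]
        X[:, 2] += 0.4 * X[:, 1]
        S = np.corrcoef(X.T)
        e_heavy = ebicglasso_path(S, n=200, gamma=0.5).edge_count
        e_light = ebicglasso_path(S, n=200, gamma=0.0).edge_count
        assert e_heavy <= e_light

    def test_edge_count_monotone_along_path(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(300, 6))
        X[:, 1] += 0.6 * X[:, 0]
        S = np.corrcoef(X.T)
        net = ebicglasso_path(S, n=300, n_lambda=40)
        edges = net.ebic_path["edges"].to_numpy()
        # lambda descends along the path, so E must not decrease
        assert np.all(np.diff(edges) >= 0)

    def test_small_lambda_limit_matches_inversion(self):
        """Well-conditioned p=4: pcor at tiny lambda ~ closed form."""
        Sigma = np.array([
            [1.0, 0.5, 0.2, 0.1],
            [0.5, 1.0, 0.3, 0.2],
            [0.2, 0.3, 1.0, 0.4],
            [0.1, 0.2, 0.4, 1.0],
        ])
        Theta_true = np.linalg.inv(Sigma)
        pcor_true = pcor_from_precision(Theta_true)
        from qolnet._fast import glasso

        Theta, _, _ = glasso(Sigma, 1e-6, 1e-12, 2000)
        np.testing.assert_allclose(
            pcor_from_precision(Theta), pcor_true, atol=1e-3
        )

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(250, 6))
        X[:, 3] += 0.7 * X[:, 0]
        S = np.corrcoef(X.T)
        net = ebicglasso_path(S, n=250)
        perm = np.array([3, 1, 4, 0, 5, 2])
        net_p = ebicglasso_path(S[np.ix_(perm, perm)], n=250)
        np.testing.assert_allclose(
            net_p.weights, net.weights[np.ix_(perm, perm)], atol=1e-8
        )

    def test_selected_lambda_attains_path_minimum(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(200, 5))
        S = np.corrcoef(X.T)
        net = ebicglasso_path(S, n=200)
        path = net.ebic_path[net.ebic_path["converged"]]
        best = path.loc[path["ebic"].idxmin()]
        assert net.lambda_selected == pytest.approx(best["lambda"])

    def test_warns_when_n_not_above_p(self):
        with pytest.warns(UserWarning, match="regularized"):
            ebicglasso_path(np.eye(5), n=4)

    def test_support_recovery_from_generator_truth(self, continuous_defs_15):
        """EBIC-glasso finds the strong true edges and few spurious ones."""
        from qolnet.correlation import mixed_matrix
        from qolnet.simulate import generate_cohort, make_precision_spec

        sens, spec_ = [], []
        for seed in range(3):
            ps = make_precision_spec(15, 0.15, seed=seed)
            tab = generate_cohort(ps, continuous_defs_15, n=487, seed=seed + 50)
            cm = mixed_matrix(tab, timepoint="M0")
            net = ebicglasso_path(cm, gamma=0.5)
            iu = np.triu_indices(15, 1)
            true = np.abs(ps.true_pcor[iu]) > 1e-12
            strong = np.abs(ps.true_pcor[iu]) >= 0.15
            est = net.weights[iu] != 0
            sens.append((est & true & strong).sum() / max((true & strong).sum(), 1))
            spec_.append((~est & ~true).sum() / max((~true).sum(), 1))
        assert np.mean(sens) >= 0.8
        assert np.mean(spec_) >= 0.75  # deeper 20-seed check in acceptance suite
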