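"""RBF Gram matrices, kernel fusion, dual SVM contracts, grid search."""

import numpy as np
import pytest
from scipy.optimize import minimize

import mycospec as ms
from mycospec.fusion_svm import (
    KernelConfig,
    KernelPSDError,
    grid_search,
    resolve_gamma,
    train_fused,
)


class TestRBFGram:
    def test_zero_distance_gives_one(self, rng):
        A = rng.random((4, 3))
        K = ms.rbf_gram(A, A, gamma=0.7)
        assert np.allclose(np.diag(K), 1.0)

    def test_small_gamma_limit(self, rng):
        A = rng.random((3, 2))
        K = ms.rbf_gram(A, A, gamma=1e-12)
        assert np.allclose(K, 1.0, atol=1e-9)

    def test_hand_computed_entries(self):
        A = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
        B = np.array([[1.0, 1.0], [0.0, 0.0]])
        gamma = 0.5
        expected = np.array(
            [
                [np.exp(-0.5 * 2.0), 1.0],
                [np.exp(-0.5 * 1.0), np.exp(-0.5 * 1.0)],
                [np.exp(-0.5 * 2.0), np.exp(-0.5 * 4.0)],
            ]
        )
        assert np.allclose(ms.rbf_gram(A, B, gamma), expected, atol=1e-12)

    def test_invalid_inputs(self, rng):
        with pytest.raises(ValueError):
            ms.rbf_gram(rng.random((2, 3)), rng.random((2, 4)), 0.5)
        with pytest.raises(ValueError):
            ms.rbf_gram(rng.random((2, 3)), rng.random((2, 3)), -1.0)
        bad = rng.random((2, 3))
        bad[0, 0] = np.inf
        with pytest.raises(ValueError):
            ms.rbf_gram(bad, bad, 0.5)


class TestFuse:
    def test_endpoints_are_bitwise_exact(self, rng):
        Ks, Kw = rng.random((4, 4)), rng.random((4, 4))
        assert np.array_equal(ms.fuse(Ks, Kw, 1.0), Ks)
        assert np.array_equal(ms.fuse(Ks, Kw, 0.0), Kw)

    def test_halfway_is_elementwise_average(self):
        Ks = np.array([[1.0, 0.2], [0.2, 1.0]])
        Kw = np.array([[1.0, 0.8], [0.8, 1.0]])
        assert np.allclose(ms.fuse(Ks, Kw, 0.5), (Ks + Kw) / 2)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ms.fuse(np.eye(3), np.eye(4), 0.5)

    @pytest.mark.parametrize("mu", [0.0, 0.3, 0.7, 1.0])
    def test_fusion_preserves_psd(self, mu, rng):
        X1, X2 = rng.random((8, 3)), rng.random((8, 5))
        K = ms.fuse(ms.rbf_gram(X1, X1, 0.5), ms.rbf_gram(X2, X2, 0.2), mu)
        assert np.linalg.eigvalsh(K).min() >= -1e-8


class TestFit:
    def test_separable_clouds_reach_training_accuracy_one(self, rng):
        X = np.vstack([rng.normal(0, 0.2, (10, 2)), rng.normal(5, 0.2, (10, 2))])
        y = np.repeat([0, 1], 10)
        K = ms.rbf_gram(X, X, 0.5)
        svc = ms.fit(K, y, C=100.0)
        assert (svc.predict(K) == y).mean() == 1.0

    def test_dual_feasibility_holds_on_multiclass_fit(self, rng):
        X = rng.normal(size=(40, 4)) + np.repeat(np.arange(4), 10)[:, None]
        y = np.repeat(np.arange(4), 10)
        svc = ms.fit(ms.rbf_gram(X, X, 0.3), y, C=10.0)
        ok, report = ms.dual_feasibility(svc)
        assert ok, report

    def test_non_psd_kernel_rejected_with_hint(self):
        K = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(KernelPSDError, match="clip"):
            ms.fit(K, np.array([0, 1]), C=1.0)

    def test_six_point_toy_matches_qp_oracle(self):
        """Dual coefficients, support set, and margin vs an explicit QP."""
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [3.0, 3.0], [4.0, 3.0], [3.0, 4.0]])
        y = np.array([-1, -1, -1, 1, 1, 1])
        K = X @ X.T
        C = 10.0
        svc = ms.fit(K, y, C=C, tol=1e-10)

        def neg_dual(a):
            return -(a.sum() - 0.5 * (a * y) @ K @ (a * y))

        res = minimize(
            neg_dual,
            np.zeros(6),
            bounds=[(0, C)] * 6,
            constraints=({"type": "eq", "fun": lambda a: a @ y},),
            method="SLSQP",
            options={"ftol": 1e-14, "maxiter": 1000},
        )
        alpha = res.x
        alpha_svc = np.zeros(6)
        alpha_svc[svc.support_] = np.abs(svc.dual_coef_.ravel())
        assert np.allclose(alpha_svc, alpha, atol=1e-6)
        assert set(svc.support_) == set(np.flatnonzero(alpha > 1e-6))
        w = ((alpha * y)[:, None] * X).sum(axis=0)
        margin_oracle = 2.0 / np.linalg.norm(w)
        margin_svc = 2.0 / np.sqrt((alpha_svc * y) @ K @ (alpha_svc * y))
        assert margin_svc == pytest.approx(margin_oracle, abs=1e-6)


class TestPredict:
    @pytest.fixture()
    def toy_model(self, rng):
        Xs = np.vstack([rng.normal(0, 0.3, (12, 3)), rng.normal(4, 0.3, (12, 3))])
        Xw = rng.normal(size=(24, 5))
        y = np.repeat([0, 1], 12)
        cfg = KernelConfig(mu=1.0, gamma_s=0.5, gamma_w=0.5, C=100.0)
        return train_fused(Xs, Xw, y, cfg), Xs, Xw, y

    def test_training_set_reproduced_for_separable_fit(self, toy_model):
        model, Xs, Xw, y = toy_model
        assert np.array_equal(ms.predict(model, Xs, Xw), y)

    def test_single_sample(self, toy_model):
        model, Xs, Xw, _ = toy_model
        out = ms.predict(model, Xs[:1], Xw[:1])
        assert out.shape == (1,)

    def test_rowwise_independence_under_duplication(self, toy_model, rng):
        model, Xs, Xw, _ = toy_model
        new_s = rng.normal(2, 1, (3, 3))
        new_w = rng.normal(size=(3, 5))
        base = ms.predict(model, new_s, new_w)
        dup = ms.predict(model, np.vstack([new_s, new_s[1:2]]), np.vstack([new_w, new_w[1:2]]))
        assert np.array_equal(dup[:3], base)
        assert dup[3] == base[1]

    def test_width_mismatch_rejected(self, toy_model, rng):
        model, Xs, Xw, _ = toy_model
        with pytest.raises(ValueError):
            ms.predict(model, rng.random((2, 4)), rng.random((2, 5)))


class TestGridSearch:
    def test_mu_grid_of_one_reduces_to_spectral_selection(self, rng):
        Xs = np.vstack([rng.normal(0, 0.4, (10, 3)), rng.normal(3, 0.4, (10, 3))])
        Xw = rng.normal(size=(20, 4))  # uninformative
        y = np.repeat([0, 1], 10)
        best, table = grid_search(
            Xs, Xw, y, mu_grid=(1.0,), C_grid=(1.0, 10.0),
            gamma_s_grid=(0.1, 1.0), gamma_w_grid=(0.1,), cv_folds=2, seed=0,
        )
        assert best.mu == 1.0
        assert len(table) == 4  # 1 mu x 2 C x 2 gamma_s x 1 gamma_w

    def test_informative_spectra_drive_mu_toward_one(self):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            y = np.repeat([0, 1, 2, 3], 8)
            Xs = y[:, None] + r.normal(0, 0.15, (32, 3))  # clean class signal
            Xw = r.normal(size=(32, 6))  # pure noise
            best, _ = grid_search(
                Xs, Xw, y, mu_grid=(0.0, 0.25, 0.5, 0.75, 1.0),
                C_grid=(1.0, 10.0), gamma_s_grid=("scale",),
                gamma_w_grid=("scale",), cv_folds=2, seed=seed,
            )
            hits += best.mu >= 0.8
        assert hits >= 8

    def test_fold_short_of_a_class_rejected(self, rng):
        Xs = rng.random((5, 2))
        y = np.array([0, 0, 0, 0, 1])
        with pytest.raises(ValueError, match="folds"):
            grid_search(Xs, Xs, y, cv_folds=3)

    def test_resolve_gamma(self, rng):
        X = rng.random((10, 4))
        assert resolve_gamma(0.3, X) == 0.3
        assert resolve_gamma("scale", X) == pytest.approx(1.0 / (4 * X.var()))
        with pytest.raises(ValueError):
            resolve_gamma("auto", X)


def test_kernel_config_validation():
    with pytest.raises(ValueError):
        KernelConfig(mu=1.2)
    with pytest.raises(ValueError):
        KernelConfig(gamma_s=0.0)
    with pytest.raises(ValueError):
        KernelConfig(C=-1.0)
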