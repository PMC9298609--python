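import numpy as np
import pytest

from nircal import (
    LSSVM, MLR, PLS, load_model, select_lv_loocv, tune_lssvm,
)
from nircal.models import fit_lssvm
from nircal._pls_fast import pls1_coefficients


@pytest.fixture()
def linear_problem(rng):
    X = rng.normal(size=(50, 8))
    beta = rng.normal(size=8)
    y = X @ beta + 3.0
    return X, y


class TestPLS:
    def test_exact_fit_limit(self, linear_problem):
        X, y = linear_problem
        res = PLS(X, y).fit(n_lv=8)
        assert np.allclose(res.predict(X), y, atol=1e-8)

    def test_single_variable_equals_simple_regression(self, rng):
        x = rng.normal(size=(30, 1))
        y = 1.7 * x[:, 0] + 0.4 + rng.normal(scale=0.2, size=30)
        res = PLS(x, y).fit(n_lv=1)
        slope = np.cov(x[:, 0], y, ddof=1)[0, 1] / np.var(x[:, 0], ddof=1)
        intercept = y.mean() - slope * x.mean()
        assert np.allclose(res.predict(x), slope * x[:, 0] + intercept, atol=1e-10)

    def test_full_rank_matches_ols_oracle(self, rng):
        X = rng.normal(size=(40, 6))
        y = X @ rng.normal(size=6) + rng.normal(scale=0.5, size=40)
        res = PLS(X, y).fit(n_lv=6)
        A = np.column_stack([np.ones(40), X])
        ols_pred = A @ np.linalg.lstsq(A, y, rcond=None)[0]
        assert np.allclose(res.predict(X), ols_pred, atol=1e-8)

    def test_training_rmse_nonincreasing_in_lv(self, rng):
        X = rng.normal(size=(40, 10))
        y = X @ rng.normal(size=10) + rng.normal(size=40)
        rmse = []
        for a in range(1, 10):
            res = PLS(X, y).fit(n_lv=a)
            rmse.append(np.sqrt(np.mean((res.predict(X) - y) ** 2)))
        assert all(b <= a + 1e-12 for a, b in zip(rmse, rmse[1:]))

    def test_scores_orthogonal(self, rng):
        X = rng.normal(size=(30, 12))
        y = rng.normal(size=30)
        res = PLS(X, y).fit(n_lv=6)
        G = res.x_scores.T @ res.x_scores
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(G))

    def test_rank_exceeded_rejected(self, rng):
        base = rng.normal(size=(20, 2))
        X = np.column_stack([base, base @ np.array([[1.0], [2.0]])])  # rank 2
        y = rng.normal(size=20)
        with pytest.raises(ValueError, match="rank"):
            PLS(X, y).fit(n_lv=3)

    def test_matches_compiled_kernel(self, rng):
        X = rng.normal(size=(35, 20))
        y = rng.normal(size=35)
        B = pls1_coefficients(X, y, 7)
        for a in (1, 4, 7):
            res = PLS(X, y).fit(n_lv=a)
            assert np.allclose(res.coef, B[:, a - 1], atol=1e-8)

    def test_matches_sklearn_cross_check(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(40, 12))
        y = X @ rng.normal(size=12) + rng.normal(scale=0.3, size=40)
        for a in (2, 5):
            ours = PLS(X, y).fit(n_lv=a).predict(X)
            sk = sklearn.PLSRegression(n_components=a, scale=False)
            theirs = sk.fit(X, y[:, None]).predict(X).ravel()
            assert np.allclose(ours, theirs, atol=1e-8)


class TestLvSelection:
    def test_noiseless_rank_one_selects_single_lv(self, rng):
        t = rng.normal(size=40)
        X = np.outer(t, rng.normal(size=15))
        y = 2.0 * t + 1.0
        n_lv, _ = select_lv_loocv(X, y, max_lv=5)
        assert n_lv == 1

    def test_recovers_known_factor_count(self):
        hits = 0
        k = 3
        for seed in range(10):
            r = np.random.default_rng(seed)
            T = r.normal(size=(60, k))
            X = T @ r.normal(size=(k, 20)) + r.normal(scale=0.02, size=(60, 20))
            y = T @ r.normal(size=k) + r.normal(scale=0.05, size=60)
            n_lv, _ = select_lv_loocv(X, y, max_lv=8)
            hits += n_lv in (k - 1, k, k + 1)
        assert hits >= 9

    def test_rmsecv_vector_length_contract(self, rng):
        X = rng.normal(size=(30, 10))
        y = rng.normal(size=30)
        _, rmsecv = select_lv_loocv(X, y, max_lv=7)
        assert rmsecv.shape == (7,)


class TestLSSVM:
    def test_single_sample_analytic_case(self):
        res = fit_lssvm(np.array([[1.0, 2.0]]), np.array([3.5]), 10.0, 1.0)
        assert res.b == pytest.approx(3.5)
        assert res.alpha[0] == pytest.approx(0.0, abs=1e-12)
        assert res.predict([[9.0, 9.0]])[0] == pytest.approx(3.5)

    def test_kernel_at_zero_distance_is_one(self, rng):
        X = rng.normal(size=(5, 3))
        res = fit_lssvm(X, rng.normal(size=5), 1.0, 2.0)
        from nircal.models import _rbf_kernel
        assert np.allclose(np.diag(_rbf_kernel(X, X, 2.0)), 1.0)

    def test_interpolation_limit_large_gamma(self, rng):
        X = rng.normal(size=(12, 2))
        y = rng.normal(size=12)
        res = fit_lssvm(X, y, gamma=1e7, sigma2=1.0)
        assert np.allclose(res.predict(X), y, atol=1e-3)

    def test_dual_residual_small_on_random_problems(self, rng):
        for _ in range(5):
            X = rng.normal(size=(60, 8))
            y = rng.normal(size=60)
            res = fit_lssvm(X, y, gamma=100.0, sigma2=5.0)
            assert res.dual_residual() <= 1e-8

    def test_positive_hyperparameters_required(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(ValueError):
            fit_lssvm(X, rng.normal(size=5), -1.0, 1.0)


class TestLssvmTuning:
    def test_single_point_grid_returned(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        g, s2, surface = tune_lssvm(X, y, gamma_grid=[7.0], sigma2_grid=[3.0],
                                    n_folds=4)
        assert (g, s2) == (7.0, 3.0)
        assert surface.shape == (1, 1)

    def test_choice_is_surface_argmin(self, rng):
        X = rng.normal(size=(30, 4))
        y = X @ rng.normal(size=4) + rng.normal(scale=0.1, size=30)
        g, s2, surface = tune_lssvm(X, y, gamma_grid=[1.0, 100.0],
                                    sigma2_grid=[0.5, 5.0, 50.0], n_folds=5)
        gi = [1.0, 100.0].index(g)
        si = [0.5, 5.0, 50.0].index(s2)
        assert surface[gi, si] == surface.min()

    def test_seeded_fold_determinism(self, rng):
        X = rng.normal(size=(25, 3))
        y = rng.normal(size=25)
        a = tune_lssvm(X, y, gamma_grid=[1.0, 10.0], sigma2_grid=[1.0, 10.0],
                       seed=5)
        b = tune_lssvm(X, y, gamma_grid=[1.0, 10.0], sigma2_grid=[1.0, 10.0],
                       seed=5)
        assert a[:2] == b[:2]
        assert np.array_equal(a[2], b[2])


class TestMLR:
    def test_exact_recovery(self):
        x = np.linspace(0, 1, 12)[:, None]
        y = 2.0 * x[:, 0] + 3.0
        res = MLR(x, y).fit()
        assert res.coef[0] == pytest.approx(2.0, abs=1e-10)
        assert res.intercept == pytest.approx(3.0, abs=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        res = MLR(X, y).fit()
        resid = y - res.predict(X)
        assert np.allclose(X.T @ resid, 0.0, atol=1e-9)
        assert resid.sum() == pytest.approx(0.0, abs=1e-9)

    def test_more_variables_than_samples_rejected(self, rng):
        X = rng.normal(size=(10, 12))
        with pytest.raises(ValueError, match="more samples than variables"):
            MLR(X, rng.normal(size=10)).fit()

    def test_rank_deficiency_rejected(self, rng):
        x = rng.normal(size=(20, 1))
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="rank"):
            MLR(X, rng.normal(size=20)).fit()


class TestSerialization:
    def test_round_trip_preserves_predictions(self, rng, tmp_path):
        X = rng.normal(size=(25, 5))
        y = X @ rng.normal(size=5) + rng.normal(size=25)
        Xnew = rng.normal(size=(7, 5))
        fitted = {
            "pls": PLS(X, y).fit(n_lv=3),
            "lssvm": LSSVM(X, y).fit(gamma=50.0, sigma2=4.0),
            "mlr": MLR(X, y).fit(),
        }
        for name, res in fitted.items():
            path = tmp_path / f"{name}.json"
            res.to_json(path)
            back = load_model(path)
            assert np.allclose(back.predict(Xnew), res.predict(Xnew), atol=1e-12)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            load_model('{"kind": "mystery"}')
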