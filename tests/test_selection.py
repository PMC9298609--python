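import numpy as np
import pytest

from nircal import BossConfig, boss, boss_spa, spa
from nircal.selection import spa_chain


def _planted_small(seed=0, n=60, p=30, k=4, noise=0.2):
    """Tiny planted regression: k informative columns, the rest pure noise."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    informative = np.arange(k)
    beta = np.zeros(p)
    beta[informative] = rng.uniform(1.0, 2.0, size=k)
    y = 12.0 + X @ beta + rng.normal(scale=noise, size=n)
    return X, y, informative


def _gram_schmidt_residual_norms(X, selected):
    """Oracle: residual norm of every column after orthogonalising against
    the selected columns by explicit Gram-Schmidt."""
    basis = []
    for j in selected:
        v = X[:, j].astype(float).copy()
        for b in basis:
            v -= (b @ v) * b
        nv = np.linalg.norm(v)
        if nv > 1e-12:
            basis.append(v / nv)
    norms = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        v = X[:, j].astype(float).copy()
        for b in basis:
            v -= (b @ v) * b
        norms[j] = np.linalg.norm(v)
    return norms


@pytest.fixture(scope="module")
def small_run():
    X, y, informative = _planted_small()
    cfg = BossConfig(n_submodels=150, seed=1)
    return boss(X, y, cfg), informative


@pytest.fixture(scope="module")
def chain_run():
    X, y, informative = _planted_small(seed=3, n=80, p=30, k=4)
    Xv, yv, _ = _planted_small(seed=33, n=25, p=30, k=4)
    cfg = BossConfig(n_submodels=150, seed=3)
    res = boss_spa(X, y, Xv, yv, cfg, max_vars=10)
    return res, informative


class TestBoss:
    def test_nvar_trace_nonincreasing_and_ends_at_one(self, small_run):
        res, _ = small_run
        trace = res.nvar_trace
        assert all(b <= a for a, b in zip(trace, trace[1:]))
        assert trace[-1] == 1
        assert trace[0] == 30

    def test_selected_set_is_global_rmsecv_argmin(self, small_run):
        res, _ = small_run
        best = int(np.argmin(res.rmsecv_trace))
        assert res.nvar_trace[best] == res.n_selected
        assert res.best_rmsecv == res.rmsecv_trace[best]

    def test_weights_normalised_and_nonnegative(self, small_run):
        res, _ = small_run
        for w in res.weight_history:
            assert np.all(w >= 0)
            assert w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_weight_support_never_grows(self, small_run):
        res, _ = small_run
        supports = [set(np.nonzero(w)[0].tolist()) for w in res.weight_history]
        for a, b in zip(supports, supports[1:]):
            assert b <= a

    def test_recovers_planted_columns(self, small_run):
        res, informative = small_run
        assert set(informative.tolist()) <= set(res.selected_indices.tolist())

    def test_seeded_determinism(self):
        X, y, _ = _planted_small(seed=5)
        cfg = BossConfig(n_submodels=80, seed=9)
        a = boss(X, y, cfg)
        b = boss(X, y, cfg)
        assert np.array_equal(a.selected_indices, b.selected_indices)
        assert a.rmsecv_trace == b.rmsecv_trace

    def test_too_few_variables_rejected(self, rng):
        with pytest.raises(ValueError, match="2 variables"):
            boss(rng.normal(size=(10, 1)), rng.normal(size=10))

    @pytest.mark.parametrize("bad", [
        dict(best_fraction=0.0), dict(best_fraction=1.5),
        dict(n_submodels=5), dict(cv_folds=1),
    ])
    def test_config_validation(self, bad):
        with pytest.raises(ValueError):
            BossConfig(**bad).validate()


class TestSpa:
    def test_duplicate_column_never_selected_twice(self, rng):
        x = rng.normal(size=(20, 1))
        X = np.column_stack([x, x, rng.normal(size=(20, 3))])
        y = x[:, 0] * 2.0 + rng.normal(scale=0.1, size=20) + 12.0
        Xv = np.column_stack([x[:5], x[:5], rng.normal(size=(5, 3))])
        res = spa(X, y, Xv, y[:5], max_vars=4)
        assert not {0, 1} <= set(res.selected_indices.tolist())

    def test_orthogonal_columns_selected_by_descending_norm(self):
        # orthogonal design: each chain step must take the largest remaining norm
        Q = np.eye(5)
        scales = np.array([4.0, 9.0, 1.0, 6.0])
        X = Q[:, :4] * scales
        chain = spa_chain(X, start=1, max_vars=4)
        assert chain == [1, 3, 0, 2]  # 9, then 6, 4, 1

    def test_chain_matches_gram_schmidt_oracle(self, rng):
        for _ in range(20):
            n, p = int(rng.integers(6, 13)), int(rng.integers(4, 11))
            X = rng.normal(size=(n, p))
            start = int(rng.integers(p))
            chain = spa_chain(X, start, max_vars=min(p, n - 2))
            for step in range(1, len(chain)):
                norms = _gram_schmidt_residual_norms(X, chain[:step])
                norms[chain[:step]] = -1.0
                assert chain[step] == int(np.argmax(norms))

    def test_collinear_input_truncates_chain(self, rng):
        x = rng.normal(size=(10, 1))
        X = np.column_stack([x, 2 * x, -x])
        chain = spa_chain(X, 0, max_vars=3)
        assert chain == [0]

    def test_max_vars_limited_by_samples(self, rng):
        X = rng.normal(size=(10, 20))
        y = rng.normal(size=10)
        with pytest.raises(ValueError, match="max_vars"):
            spa(X, y, X, y, max_vars=15)

    def test_selected_minimises_validation_rmsep(self, rng):
        X, y, informative = _planted_small(seed=2, n=40, p=10, k=2)
        Xv, yv, _ = _planted_small(seed=22, n=15, p=10, k=2)
        res = spa(X, y, Xv, yv, max_vars=6)
        assert res.n_selected <= 6
        assert min(res.rmsecv_trace) == pytest.approx(
            res.rmsecv_trace[res.nvar_trace.index(res.n_selected)])


class TestBossSpa:
    def test_subset_of_boss_selection(self, chain_run):
        res, _ = chain_run
        boss_sel = set(res.stages["boss"].selected_indices.tolist())
        assert set(res.selected_indices.tolist()) <= boss_sel
        assert res.n_selected <= len(boss_sel)

    def test_keeps_planted_columns(self, chain_run):
        res, informative = chain_run
        kept_by_boss = set(res.stages["boss"].selected_indices) & set(informative)
        kept = set(res.selected_indices.tolist()) & set(informative.tolist())
        assert len(kept) >= 0.75 * len(kept_by_boss)

    def test_single_variable_boss_short_circuits(self, rng):
        X, y, _ = _planted_small(seed=4, n=30, p=5, k=1, noise=0.05)
        pre = boss(X, y, BossConfig(n_submodels=80, seed=4))
        single = pre
        single.selected_indices = np.array([2])
        res = boss_spa(X, y, X, y, max_vars=3, boss_result=single)
        assert np.array_equal(res.selected_indices, [2])
        assert "spa" not in res.stages

    def test_deterministic_given_boss_output(self, chain_run):
        res, _ = chain_run
        X, y, _ = _planted_small(seed=3, n=80, p=30, k=4)
        Xv, yv, _ = _planted_small(seed=33, n=25, p=30, k=4)
        again = boss_spa(X, y, Xv, yv, max_vars=10,
                         boss_result=res.stages["boss"])
        assert np.array_equal(again.selected_indices, res.selected_indices)
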