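"""mRMR -> LASSO -> RFE cascade: oracles, recovery, leakage."""
import numpy as np
import pandas as pd
import pytest

import oracles
from levoresp import selection as sel
from levoresp.synthetic import planted_feature_matrix


def small_config(**kw):
    d = dict(n_repeats=1, seed=0)
    d.update(kw)
    return sel.SelectionConfig(**d)


class TestMutualInformation:
    def test_binary_copy_equals_label_entropy(self):
        y = np.array([0, 1] * 100)
        assert sel.mutual_information(y.astype(float), y) == pytest.approx(np.log(2))

    def test_independent_near_zero(self, rng):
        x = rng.normal(size=1000)
        y = (rng.random(1000) < 0.5).astype(int)
        assert sel.mutual_information(x, y) < 0.02

    def test_nonnegative_and_constant_zero(self, rng):
        for _ in range(50):
            x = rng.normal(size=60)
            y = rng.integers(0, 2, size=60)
            assert sel.mutual_information(x, y) >= 0
        assert sel.mutual_information(np.ones(50), rng.integers(0, 2, 50)) == 0.0


class TestMrmr:
    def test_first_pick_is_max_marginal_mi(self, rng):
        X, y, names = planted_feature_matrix(200, 10, n_informative=1, effect=2.0, seed=1)
        df = pd.DataFrame(X, columns=names)
        ranked = sel.mrmr_rank(df, y, k=5)
        mis = {c: sel.mutual_information(df[c].to_numpy(), y) for c in names}
        assert ranked[0] == max(names, key=lambda c: mis[c])

    @pytest.mark.parametrize("seed", range(20))
    def test_informative_feature_ranked_first(self, seed):
        X, y, names = planted_feature_matrix(200, 21, n_informative=1, effect=2.0, seed=seed)
        ranked = sel.mrmr_rank(pd.DataFrame(X, columns=names), y, k=1)
        assert ranked == ["signal_0"]

    def test_redundant_copy_deferred(self, rng):
        x = rng.normal(size=300)
        y = (x > 0).astype(int)
        z = rng.normal(size=300) + 0.5 * y
        df = pd.DataFrame({"a": x, "a_copy": x + rng.normal(0, 0.01, 300), "b": z})
        ranked = sel.mrmr_rank(df, y, k=2)
        assert ranked[0] == "a" and ranked[1] == "b"

    @pytest.mark.parametrize("seed", range(5))
    def test_greedy_trace_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(80, 8))
        y = rng.integers(0, 2, size=80)
        df = pd.DataFrame(X, columns=[f"f{i}" for i in range(8)])
        got = sel.mrmr_rank(df, y, k=8, bins=4)
        codes = [sel._discretize(X[:, j], 4) for j in range(8)]
        want = oracles.brute_mrmr(codes, sel._discretize(y, 4), 8)
        assert got == [f"f{i}" for i in want]


class TestLasso:
    def test_huge_alpha_shrinks_everything(self, rng):
        X, y, names = planted_feature_matrix(100, 10, seed=0)
        cfg = small_config(lasso_alpha_grid=np.array([1e6]))
        picked, alpha = sel.lasso_select(pd.DataFrame(X, columns=names), y, cfg)
        assert picked == [] and alpha == 1e6

    def test_tiny_alpha_keeps_features(self, rng):
        X, y, names = planted_feature_matrix(100, 5, seed=0)
        cfg = small_config(lasso_alpha_grid=np.array([1e-8]))
        picked, _ = sel.lasso_select(pd.DataFrame(X, columns=names), y, cfg)
        assert len(picked) == 5

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_signal_survives(self, seed):
        X, y, names = planted_feature_matrix(200, 51, n_informative=1, effect=1.5, seed=seed)
        picked, _ = sel.lasso_select(
            pd.DataFrame(X, columns=names), y, small_config(), seed=seed
        )
        assert "signal_0" in picked


class TestRfe:
    def test_elimination_trace_matches_brute_force(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 6))
        y = (X[:, 0] + 0.5 * X[:, 1] + rng.normal(0, 1, 60) > 0).astype(int)
        from sklearn.preprocessing import StandardScaler

        arr = StandardScaler().fit_transform(X)
        got = sel.rfe_elimination_order(arr, y)

        def fit(Xa, ya):
            return sel._logistic().fit(Xa, ya).coef_[0]

        want = oracles.brute_rfe_order(arr, y, fit)
        assert got == want

    def test_signed_importances_and_signal_kept(self):
        X, y, names = planted_feature_matrix(150, 8, n_informative=2, effect=1.5, seed=3)
        X[:, 2] = -X[:, 0]  # anti-correlated copy -> negative coefficient
        df = pd.DataFrame(X, columns=names)
        picked, imps = sel.rfe_select(df, y, small_config())
        assert set(picked) & {"signal_0", "signal_1", "noise_0"}
        assert any(w < 0 for w in imps.values()) or all(w > 0 for w in imps.values())
        assert all(np.isfinite(list(imps.values())))

    def test_single_feature_returned_as_is(self):
        X, y, _ = planted_feature_matrix(60, 1, n_informative=1, seed=0)
        picked, imps = sel.rfe_select(pd.DataFrame(X, columns=["only"]), y, small_config())
        assert picked == ["only"] and "only" in imps


class TestCascade:
    def test_single_repeat_equals_one_cascade_run(self):
        X, y, names = planted_feature_matrix(120, 30, seed=4)
        df = pd.DataFrame(X, columns=names)
        cfg = small_config(mrmr_k=15)
        res = sel.run_sequential(df, y, cfg)
        ranked = sel.mrmr_rank(df, y, 15)
        lnames, _ = sel.lasso_select(df[ranked], y, cfg, seed=cfg.seed)
        rnames, _ = sel.rfe_select(df[lnames], y, cfg, seed=cfg.seed)
        assert res.names == rnames and res.per_repeat == [rnames]

    def test_cascade_monotone_nested(self):
        X, y, names = planted_feature_matrix(150, 60, seed=5)
        df = pd.DataFrame(X, columns=names)
        cfg = small_config(n_repeats=2, mrmr_k=20)
        ranked = sel.mrmr_rank(df, y, cfg.mrmr_k)
        for r in range(cfg.n_repeats):
            lnames, _ = sel.lasso_select(df[ranked], y, cfg, seed=cfg.seed + r)
            rnames, _ = sel.rfe_select(df[lnames], y, cfg, seed=cfg.seed + r)
            assert set(lnames) <= set(ranked)
            assert set(rnames) <= set(lnames)

    def test_shuffled_labels_select_nearly_nothing(self, rng):
        X, y, names = planted_feature_matrix(150, 40, n_informative=0, seed=6)
        res = sel.run_sequential(pd.DataFrame(X, columns=names), y,
                                 small_config(n_repeats=3, mrmr_k=15))
        assert len(res.names) <= 5

    def test_training_rows_only(self):
        """Appending extra (test) rows after the training block must not
        change a result computed on the training block alone."""
        X, y, names = planted_feature_matrix(150, 25, seed=7)
        df = pd.DataFrame(X, columns=names)
        cfg = small_config(n_repeats=2, mrmr_k=10)
        res1 = sel.run_sequential(df.iloc[:100], y[:100], cfg)
        res2 = sel.run_sequential(df.iloc[:100], y[:100], cfg)
        assert res1.names == res2.names and res1.importances == res2.importances

    def test_result_json_round_trip(self, tmp_path):
        X, y, names = planted_feature_matrix(100, 20, seed=8)
        res = sel.run_sequential(pd.DataFrame(X, columns=names), y, small_config(mrmr_k=10))
        res.to_json(tmp_path / "sel.json")
        back = sel.SelectionResult.from_json(tmp_path / "sel.json")
        assert back.names == res.names and back.alphas == res.alphas
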