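import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from adipolipid.diffstats import (group_anova, paired_test,
                                  paired_test_values, pls_on_fcs,
                                  storey_qvalues, twin_log_ratio,
                                  twin_log_ratio_matrix)


class TestTwinLogRatio:
    def test_known_ratios(self, small_table):
        lr = twin_log_ratio(small_table, "PC(16:0/18:1)")
        assert np.allclose(lr, 1.0)  # heavy = 2x lean
        lr0 = twin_log_ratio(small_table, "PE(P-16:0/20:4)")
        assert np.allclose(lr0, 0.0)  # heavy = lean

    def test_metadata_variable(self, small_table):
        lr = twin_log_ratio(small_table, "fcs")
        assert lr["p1"] == pytest.approx(math.log2(100 / 85))

    def test_antisymmetric_under_role_swap(self, small_table):
        lr = twin_log_ratio(small_table, "SM(d18:1/16:0)")
        meta = small_table.metadata.copy()
        meta["role"] = meta["role"].map({"heavy": "lean", "lean": "heavy"})
        swapped = small_table.__class__(data=small_table.data.copy(),
                                        metadata=meta)
        lr_swapped = twin_log_ratio(swapped, "SM(d18:1/16:0)")
        assert np.allclose(lr.values, -lr_swapped.values)

    def test_nonpositive_value_names_pair(self, small_table):
        data = small_table.data.copy()
        data.loc["PC(16:0/18:1)", "p2_lean"] = 0.0
        table = small_table.__class__(data=data,
                                      metadata=small_table.metadata.copy())
        with pytest.raises(ValueError, match="p2"):
            twin_log_ratio(table, "PC(16:0/18:1)")

    def test_matrix_matches_per_variable(self, small_table):
        mat = twin_log_ratio_matrix(small_table.data, small_table.metadata)
        for sp in small_table.data.index:
            assert np.allclose(mat[sp].values,
                               twin_log_ratio(small_table, sp).values)


class TestPairedTest:
    def test_hand_formula_t(self):
        # within-pair differences (1, 2, 3): t = mean/(sd/sqrt(n)) = 2/(1/sqrt(3))
        heavy, lean = np.array([2.0, 3.0, 4.0]), np.array([1.0, 1.0, 1.0])
        t, p = paired_test_values(heavy, lean, log_transform=False)
        assert t == pytest.approx(2.0 / (1.0 / math.sqrt(3)), abs=1e-9)
        assert t == pytest.approx(3.4641016, abs=1e-6)

    def test_degenerate_all_zero_differences(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="zero"):
            t, p = paired_test_values(x, x.copy(), log_transform=False)
        assert p == 1.0

    def test_pair_order_permutation_invariant(self):
        rng = np.random.default_rng(0)
        heavy, lean = rng.lognormal(size=8), rng.lognormal(size=8)
        _, p1 = paired_test_values(heavy, lean)
        perm = rng.permutation(8)
        _, p2 = paired_test_values(heavy[perm], lean[perm])
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_wilcoxon_and_table_interface(self, small_table):
        t, p = paired_test(small_table, "PC(16:0/18:1)")
        assert p < 0.05  # exact 2x effect in all three pairs
        _, pw = paired_test(small_table, "PC(16:0/18:1)", method="wilcoxon")
        assert 0 < pw <= 1

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="3"):
            paired_test_values([1.0, 2.0], [1.0, 1.0])


def _bh(p):
    """Independent Benjamini-Hochberg oracle (direct step-up formula)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestStoreyQvalues:
    def test_single_pvalue(self):
        assert storey_qvalues([0.04], pi0=1.0)[0] == pytest.approx(0.04)

    def test_brute_force_example(self):
        q = storey_qvalues([0.01, 0.02, 0.9], pi0=1.0)
        assert np.allclose(q, [0.03, 0.03, 0.9])

    def test_equals_bh_when_pi0_is_one(self, rng):
        for _ in range(100):
            p = rng.random(rng.integers(5, 200))
            assert np.allclose(storey_qvalues(p, pi0=1.0), _bh(p), atol=1e-12)

    def test_matches_statsmodels_bh(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.random(500)
        q = storey_qvalues(p, pi0=1.0)
        expected = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, expected, atol=1e-12)

    def test_uniform_null_rarely_significant(self, rng):
        p = rng.random(10_000)
        assert (storey_qvalues(p) < 0.05).mean() < 0.005

    def test_monotone_in_pvalue_rank(self, rng):
        p = rng.random(300)
        q = storey_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q <= 1.0).all()

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalues([0.1, 1.5])
        with pytest.raises(ValueError):
            storey_qvalues([-0.1])

    def test_pi0_estimator_reduces_qvalues_under_signal(self, rng):
        p = np.concatenate([rng.random(500) * 1e-4, rng.random(500)])
        q_est = storey_qvalues(p)
        q_one = storey_qvalues(p, pi0=1.0)
        assert (q_est <= q_one + 1e-12).all()


class TestGroupAnova:
    def test_hand_formula(self):
        values = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        groups = np.array(["a"] * 3 + ["b"] * 3)
        f, p = group_anova(values, groups)
        # SSB = 2*3*(1.5)^2 = 13.5, MSW = 1 -> F = 13.5 on (1, 4) df
        assert f == pytest.approx(13.5, abs=1e-9)
        from scipy import stats
        assert p == pytest.approx(float(stats.f.sf(13.5, 1, 4)), abs=1e-12)

    def test_three_groups_shifted_matches_two_group_reduction(self):
        base = np.array([1.0, 2.0, 3.0, 2.0])
        values = np.concatenate([base, base + 1, base + 2])
        groups = np.repeat(["a", "b", "c"], 4)
        f3, _ = group_anova(values, groups)
        f2, _ = group_anova(values[:8], groups[:8])
        # equally spaced shifts: between-group MS scales by factor 2 vs the
        # a-b pair (variance of {0,1,2} vs {0,1} group means)
        assert f3 == pytest.approx(2 * f2, rel=1e-9)

    def test_degenerate_branches(self):
        with pytest.warns(UserWarning):
            f, p = group_anova([1.0, 1.0, 1.0, 1.0], ["a", "a", "b", "b"])
        assert (f, p) == (0.0, 1.0)
        f, p = group_anova([1.0, 1.0, 2.0, 2.0], ["a", "a", "b", "b"])
        assert math.isinf(f) and p == 0.0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            group_anova([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestPls:
    def test_single_collinear_column(self, rng):
        # centered orthogonal design so the informative column is a pure
        # direction that centering inside the fit does not mix
        A = rng.normal(size=(12, 6))
        A -= A.mean(axis=0)
        X, _ = np.linalg.qr(A)
        y = 3.0 * X[:, 2]
        model = pls_on_fcs(X, y, n_components=1)
        assert model.explained_variance[0] > 1 - 1e-9
        assert np.allclose(model.predict(X), y, atol=1e-8)

    def test_two_orthogonal_informative_columns(self):
        n = 16
        a = np.tile([1.0, -1.0], n // 2)
        b = np.repeat([1.0, -1.0], n // 2)
        X = np.column_stack([a, b])
        y = 2.0 * a + 0.5 * b
        model = pls_on_fcs(X, y, n_components=2)
        assert model.explained_variance.sum() >= 0.99

    def test_row_permutation_equivariance(self, rng):
        X = rng.normal(size=(10, 5))
        y = rng.normal(size=10)
        m1 = pls_on_fcs(X, y, 2)
        perm = rng.permutation(10)
        m2 = pls_on_fcs(X[perm], y[perm], 2)
        assert np.allclose(m1.regression_coefficients,
                           m2.regression_coefficients, atol=1e-10)

    def test_scores_orthogonal_and_variance_bounded(self, rng):
        X = rng.normal(size=(15, 8))
        y = X @ rng.normal(size=8) + rng.normal(size=15)
        model = pls_on_fcs(X, y, 3)
        gram = model.scores.T @ model.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8
        assert model.explained_variance.sum() <= 1 + 1e-9

    def test_matches_sklearn(self, rng):
        from sklearn.cross_decomposition import PLSRegression
        X = rng.normal(size=(20, 7))
        y = X @ rng.normal(size=7) + 0.3 * rng.normal(size=20)
        model = pls_on_fcs(X, y, 3)
        ref = PLSRegression(n_components=3, scale=False).fit(X, y)
        assert np.allclose(model.regression_coefficients,
                           ref.coef_.ravel(), atol=1e-8)

    def test_rank_guard(self, rng):
        X = rng.normal(size=(5, 10))
        y = rng.normal(size=5)
        with pytest.raises(ValueError, match="rank"):
            pls_on_fcs(X, y, n_components=5)
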