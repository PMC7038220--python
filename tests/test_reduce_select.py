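"""LSDA projection behaviour and Welch t-test ranking/selection."""

import numpy as np
import pytest
from scipy import stats

from bispeeg import (
    lsda_fit,
    lsda_transform,
    select_features,
    ttest_rank,
    welch_t_from_summary,
)


def _two_clouds(rng, n=100, dim=5, sep=6.0):
    X = rng.standard_normal((2 * n, dim))
    X[n:, 0] += sep
    y = np.array(["a"] * n + ["b"] * n)
    return X, y


class TestLSDA:
    def test_recovers_separating_axis(self, rng):
        """Clouds separated only along axis 0: top direction aligns with it."""
        X, y = _two_clouds(rng)
        model = lsda_fit(X, y, k=5, alpha=0.5, d=2)
        a = model.projection[:, 0]
        assert abs(a[0]) / np.linalg.norm(a) > 0.95

    def test_one_dimensional_data_preserves_order(self, rng):
        x = np.sort(rng.standard_normal(30))[:, None]
        y = np.array(["a"] * 15 + ["b"] * 15)
        model = lsda_fit(x, y, k=3, d=1)
        z = lsda_transform(model, x).to_numpy()[:, 0]
        assert np.all(np.diff(z) > 0) or np.all(np.diff(z) < 0)

    def test_d_larger_than_feature_count_rejected(self, rng):
        X, y = _two_clouds(rng, n=20, dim=3)
        with pytest.raises(ValueError, match="exceeds"):
            lsda_fit(X, y, d=10)

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(ValueError, match="both classes"):
            lsda_fit(X, np.zeros(10), d=2)

    def test_feature_permutation_leaves_spectrum(self, rng):
        """Permuting feature columns permutes loadings, not eigenvalues."""
        X, y = _two_clouds(rng, n=40, dim=4)
        perm = np.array([2, 0, 3, 1])
        m1 = lsda_fit(X, y, d=3)
        m2 = lsda_fit(X[:, perm], y, d=3)
        np.testing.assert_allclose(m1.eigenvalues, m2.eigenvalues, atol=1e-8 * abs(m1.eigenvalues[0]))

    def test_transform_columns_and_affine_consistency(self, rng):
        X, y = _two_clouds(rng, n=30, dim=4)
        model = lsda_fit(X, y, d=3)
        Z = lsda_transform(model, X)
        assert list(Z.columns) == ["LSDA1", "LSDA2", "LSDA3"]
        shift = lsda_transform(model, X + 2.5).to_numpy() - Z.to_numpy()
        np.testing.assert_allclose(shift, np.broadcast_to(shift[0], shift.shape),
                                   atol=1e-6 * np.abs(shift).max())

    def test_dimension_mismatch(self, rng):
        X, y = _two_clouds(rng, n=20, dim=4)
        model = lsda_fit(X, y, d=2)
        with pytest.raises(ValueError, match="features"):
            lsda_transform(model, rng.standard_normal((5, 7)))

    def test_determinism(self, rng):
        X, y = _two_clouds(rng, n=30, dim=5)
        m1 = lsda_fit(X, y, d=4)
        m2 = lsda_fit(X, y, d=4)
        np.testing.assert_array_equal(m1.projection, m2.projection)


class TestWelchT:
    def test_symmetric_in_group_order(self):
        t1, p1, _ = welch_t_from_summary(1.0, 2.0, 30, 3.0, 1.5, 25)
        t2, p2, _ = welch_t_from_summary(3.0, 1.5, 25, 1.0, 2.0, 30)
        assert t1 == t2 and p1 == p2

    def test_equal_groups_give_zero(self):
        t, p, _ = welch_t_from_summary(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert t == 0.0 and p == 1.0

    def test_degenerate_zero_variance(self):
        t, p, _ = welch_t_from_summary(5.0, 0.0, 10, 5.0, 0.0, 12)
        assert t == 0.0 and p == 1.0

    def test_matches_scipy_on_raw_samples(self, rng):
        a = rng.standard_normal(14) + 0.8
        b = rng.standard_normal(19)
        t, p, df = welch_t_from_summary(a.mean(), a.std(ddof=1), len(a),
                                        b.mean(), b.std(ddof=1), len(b))
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(abs(ref.statistic), rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            welch_t_from_summary(0, -1.0, 10, 0, 1.0, 10)
        with pytest.raises(ValueError):
            welch_t_from_summary(0, 1.0, 1, 0, 1.0, 10)


class TestTTestRank:
    def test_agrees_with_summary_path_bitwise(self, rng):
        X = rng.standard_normal((40, 6))
        y = np.array(["n"] * 18 + ["a"] * 22)
        res = ttest_rank(X, y)
        for j in range(6):
            t, p, df = welch_t_from_summary(
                X[y == "n", j].mean(), X[y == "n", j].std(ddof=1), 18,
                X[y == "a", j].mean(), X[y == "a", j].std(ddof=1), 22,
            )
            assert res.t[j] == t and res.p[j] == p and res.df[j] == df

    def test_perfect_separator_ranks_first(self, rng):
        y01 = np.array([0] * 20 + [1] * 20)
        X = rng.standard_normal((40, 5))
        X[:, 3] = y01 + 0.001 * rng.standard_normal(40)
        res = ttest_rank(X, np.where(y01, "a", "n"))
        assert res.rank[0] == 3

    def test_duplicated_column_identical_stats(self, rng):
        X = rng.standard_normal((30, 2))
        X[:, 1] = X[:, 0]
        res = ttest_rank(X, np.array(["a"] * 15 + ["b"] * 15))
        assert res.t[0] == res.t[1] and res.p[0] == res.p[1]

    def test_constant_column_flagged(self, rng):
        X = rng.standard_normal((20, 2))
        X[:, 1] = 3.14
        res = ttest_rank(X, np.array(["a"] * 10 + ["b"] * 10))
        assert res.t[1] == 0.0 and res.p[1] == 1.0
        assert res.feature_names[1] in res.constant_features

    def test_null_p_values_approximately_uniform(self, rng):
        """Label permutations give uniform p (KS test not rejecting at 0.01)."""
        x = rng.standard_normal((24, 1))
        base = np.array(["a"] * 12 + ["b"] * 12)
        pvals = []
        for _ in range(200):
            perm = rng.permutation(base)
            pvals.append(ttest_rank(x, perm).p[0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestNullCalibration:
    def test_selection_retains_five_percent_under_null(self):
        """Zero class contrast: LSDA components pass the p < 0.05 filter at
        ~5% rate (binomial band over 50 null cohorts x 18 components)."""
        rng = np.random.default_rng(42)
        y = np.array(["n"] * 37 + ["a"] * 40)
        fractions = []
        for _ in range(50):
            X = rng.standard_normal((77, 18))
            model = lsda_fit(X, y, k=5, alpha=0.5, d=18)
            res = ttest_rank(lsda_transform(model, X), y)
            fractions.append(np.mean(res.p < 0.05))
        mean_frac = np.mean(fractions)
        half_band = 1.96 * np.sqrt(0.05 * 0.95 / (50 * 18))
        assert 0.05 - half_band <= mean_frac <= 0.05 + half_band


class TestSelection:
    def test_threshold_zero_selects_nothing(self, rng):
        res = ttest_rank(rng.standard_normal((20, 4)), np.array(["a"] * 10 + ["b"] * 10))
        assert select_features(res, p_threshold=0.0) == []

    def test_all_below_threshold_is_sorted_permutation(self, rng):
        res = ttest_rank(rng.standard_normal((20, 5)), np.array(["a"] * 10 + ["b"] * 10))
        sel = select_features(res, p_threshold=1.01)
        assert sorted(sel) == [0, 1, 2, 3, 4]
        assert all(res.p[a] <= res.p[b] for a, b in zip(sel, sel[1:]))
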