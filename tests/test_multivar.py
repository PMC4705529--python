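import numpy as np
import pandas as pd
import pytest

from cocompart.multivar import (
    ScoreGate,
    cluster_summary,
    condition_summary_and_test,
    gate_scores,
    run_pca,
)


def make_table(rng, n=60, n_attr=6, treatments=("n.t.", "LPS")):
    cols = [f"a{i}" for i in range(n_attr)]
    df = pd.DataFrame(rng.normal(size=(n, n_attr)), columns=cols)
    df.insert(0, "treatment", [treatments[i % len(treatments)] for i in range(n)])
    df.insert(0, "cls", ["NALP3" if i % 3 else "LC3" for i in range(n)])
    return df, tuple(cols)


class TestRunPca:
    def test_collinear_data_single_component(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        df = pd.DataFrame({"cls": "A", "treatment": "n.t.",
                           "a1": x, "a2": 3 * x + 1})
        res = run_pca(df, attributes=("a1", "a2"))
        assert res.variance_fractions[0] == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        df, attrs = make_table(rng)
        res = run_pca(df, attributes=attrs)
        assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_eigenvalues_match_direct_covariance_eigendecomposition(self):
        rng = np.random.default_rng(2)
        df, attrs = make_table(rng, n=50)
        res = run_pca(df, attributes=attrs)
        x = df[list(attrs)].to_numpy()
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        # independent oracle: explicit covariance, scipy eigendecomposition
        from scipy.linalg import eigvalsh

        n = z.shape[0]
        cov = z.T @ z / (n - 1)
        expected = np.sort(eigvalsh(cov))[::-1]
        assert np.allclose(res.eigenvalues, expected, atol=1e-8)

    def test_matches_sklearn(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(3)
        df, attrs = make_table(rng, n=80)
        res = run_pca(df, attributes=attrs)
        x = df[list(attrs)].to_numpy()
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        sk = PCA().fit(z)
        assert np.allclose(res.eigenvalues, sk.explained_variance_, atol=1e-8)

    def test_reconstruction_recovers_standardized_data(self):
        rng = np.random.default_rng(4)
        df, attrs = make_table(rng)
        res = run_pca(df, attributes=attrs)
        z = res.scores @ res.loadings.T
        x = df[list(attrs)].to_numpy()
        z_true = (x - res.mean) / res.sd
        assert np.abs(z - z_true).max() < 1e-8

    def test_total_variance_equals_attribute_count(self):
        rng = np.random.default_rng(5)
        df, attrs = make_table(rng)
        res = run_pca(df, attributes=attrs)
        assert res.eigenvalues.sum() == pytest.approx(len(attrs), abs=1e-8)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(6)
        df, attrs = make_table(rng)
        res = run_pca(df, attributes=attrs)
        assert np.allclose(res.loadings.T @ res.loadings,
                           np.eye(len(attrs)), atol=1e-10)

    def test_constant_attribute_named_in_error(self):
        df = pd.DataFrame({"cls": "A", "treatment": "n.t.",
                           "a1": [1.0, 2.0, 3.0], "a2": 5.0})
        with pytest.raises(ValueError, match="a2"):
            run_pca(df, attributes=("a1", "a2"))

    def test_sentinel_rows_dropped(self):
        rng = np.random.default_rng(7)
        df, attrs = make_table(rng, n=20)
        df.loc[df.index[:3], "a0"] = np.nan
        res = run_pca(df, attributes=attrs)
        assert res.n_dropped == 3 and res.scores.shape[0] == 17

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(8)
        df, attrs = make_table(rng)
        a = run_pca(df, attributes=attrs)
        b = run_pca(df.copy(), attributes=attrs)
        assert np.array_equal(a.loadings, b.loadings)
        for j in range(a.loadings.shape[1]):
            assert a.loadings[np.abs(a.loadings[:, j]).argmax(), j] > 0


class TestGating:
    def test_full_range_gate_selects_all(self):
        rng = np.random.default_rng(0)
        df, attrs = make_table(rng)
        res = run_pca(df, attributes=attrs)
        gate = ScoreGate(1, 2, (-1e6, 1e6), (-1e6, 1e6))
        assert len(gate_scores(res, gate)) == len(df)

    def test_degenerate_gate_rejected(self):
        with pytest.raises(ValueError, match="lower < upper"):
            ScoreGate(1, 2, (0.0, 0.0), (-1.0, 1.0))

    def test_unknown_component_rejected(self):
        rng = np.random.default_rng(1)
        df, attrs = make_table(rng)
        res = run_pca(df, attributes=attrs)
        with pytest.raises(KeyError, match="PC99"):
            gate_scores(res, ScoreGate(1, 99, (0, 1), (0, 1)))

    def test_planted_clusters_recovered_exactly(self):
        rng = np.random.default_rng(2)
        n = 40
        centers = np.array([[0.0] * 4, [8.0] * 4])
        member = np.repeat([0, 1], n // 2)
        x = centers[member] + rng.normal(0, 0.3, size=(n, 4))
        df = pd.DataFrame(x, columns=list("abcd"))
        df.insert(0, "treatment", "n.t.")
        df.insert(0, "cls", "NALP3")
        res = run_pca(df, attributes=tuple("abcd"))
        s1 = res.scores[:, 0]
        mid = s1.mean()
        side = s1[member == 1].mean() > mid
        lo, hi = (mid, 1e6) if side else (-1e6, mid)
        sel = gate_scores(res, ScoreGate(1, 2, (lo, hi), (-1e6, 1e6)))
        assert set(sel.index) == set(df.index[member == 1])

    def test_treatment_filter(self):
        rng = np.random.default_rng(3)
        df, attrs = make_table(rng)
        res = run_pca(df, attributes=attrs)
        gate = ScoreGate(1, 2, (-1e6, 1e6), (-1e6, 1e6), treatment="LPS")
        sel = gate_scores(res, gate)
        assert (sel.treatment == "LPS").all()
        assert len(sel) == (df.treatment == "LPS").sum()


class TestSummaries:
    def _subset(self):
        df = pd.DataFrame({
            "cls": ["NALP3", "NALP3", "LC3", "LC3"],
            "treatment": "n.t.",
            "pct_voxels_coloc": [10.0, 30.0, 50.0, 50.0],
            "n_coloc_objects": [1, 3, 2, 2],
            "intensity_sum": [100.0, 300.0, 400.0, 400.0],
        }, index=list("wxyz"))
        return df

    def test_hand_means(self):
        df = self._subset()
        out = cluster_summary(df, df)
        assert out.loc["NALP3", ("pct_voxels_coloc", "mean")] == 20.0
        assert out.loc["LC3", ("intensity_sum", "std")] == 0.0

    def test_row_order_invariant(self):
        df = self._subset()
        a = cluster_summary(df, df)
        shuffled = df.iloc[[3, 1, 0, 2]]
        b = cluster_summary(shuffled, shuffled)
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())

    def test_empty_subset_rejected(self):
        df = self._subset()
        with pytest.raises(ValueError, match="empty"):
            cluster_summary(df.iloc[:0], df)


class TestGroupComparison:
    def test_identical_groups_no_signal(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=30)
        df = pd.DataFrame({"treatment": ["a"] * 30 + ["b"] * 30,
                           "y": np.concatenate([vals, vals])})
        res = condition_summary_and_test(df, "y")
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value > 0.9

    def test_large_shift_detected(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "treatment": ["a"] * 30 + ["b"] * 30,
            "y": np.concatenate([rng.normal(0, 1, 30), rng.normal(3, 1, 30)]),
        })
        res = condition_summary_and_test(df, "y")
        assert res.p_value < 0.01
        assert res.pairwise.significant.all()

    def test_anova_matches_hand_sum_of_squares(self):
        # 3 groups x 5 observations, textbook one-way ANOVA arithmetic
        data = {
            "a": [4.0, 5.0, 6.0, 5.0, 4.0],
            "b": [6.0, 7.0, 8.0, 7.0, 6.0],
            "c": [9.0, 9.0, 10.0, 11.0, 9.0],
        }
        rows = [(g, v) for g, vs in data.items() for v in vs]
        df = pd.DataFrame(rows, columns=["treatment", "y"])
        grand = df.y.mean()
        ssb = sum(5 * (np.mean(v) - grand) ** 2 for v in data.values())
        ssw = sum(((np.array(v) - np.mean(v)) ** 2).sum() for v in data.values())
        f_hand = (ssb / 2) / (ssw / 12)
        from scipy.stats import f as fdist

        res = condition_summary_and_test(df, "y")
        assert res.f_statistic == pytest.approx(f_hand)
        assert res.p_value == pytest.approx(fdist.sf(f_hand, 2, 12))

    def test_holm_sidak_adjustment_matches_manual(self):
        from scipy import stats as ss

        rng = np.random.default_rng(2)
        groups = {g: rng.normal(m, 1, 10)
                  for g, m in (("a", 0.0), ("b", 0.6), ("c", 2.0))}
        rows = [(g, v) for g, vs in groups.items() for v in vs]
        df = pd.DataFrame(rows, columns=["treatment", "y"])
        res = condition_summary_and_test(df, "y")
        p_raw = np.array(res.pairwise.p_raw)
        order = np.argsort(p_raw)
        m = len(p_raw)
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            val = 1 - (1 - p_raw[i]) ** (m - rank)
            running = max(running, val)
            adj[i] = min(running, 1.0)
        assert np.allclose(res.pairwise.p_adjusted, adj, atol=1e-12)

    def test_tukey_available(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "treatment": ["a"] * 10 + ["b"] * 10 + ["c"] * 10,
            "y": rng.normal(size=30),
        })
        res = condition_summary_and_test(df, "y", method="tukey")
        assert len(res.pairwise) == 3
        assert ((res.pairwise.p_adjusted >= 0)
                & (res.pairwise.p_adjusted <= 1)).all()

    def test_small_group_rejected(self):
        df = pd.DataFrame({"treatment": ["a", "a", "b"], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="<2 observations"):
            condition_summary_and_test(df, "y")
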