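import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from cucurgrow import compare_slopes, component_correlations, tukey_letters


class TestTukeyLetters:
    def test_identical_groups_share_a_letter(self):
        rng = np.random.default_rng(0)
        base = rng.normal(10, 1, 6)
        res = tukey_letters({g: base for g in "abcd"})
        assert len(set(res.letters.values())) == 1

    def test_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(1)
        res = tukey_letters(
            {"lo": rng.normal(0, 1, 6), "hi": rng.normal(100, 1, 6),
             "mid": rng.normal(50, 1, 6)}
        )
        letters = res.letters
        assert len({letters["lo"], letters["mid"], letters["hi"]}) == 3

    def test_two_groups_reduce_to_t_test(self):
        """With two groups the Tukey p-value equals the pooled t-test's."""
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 8)
        res = tukey_letters({"a": a, "b": b})
        t_p = sps.ttest_ind(a, b).pvalue
        assert res.pairwise["p_adj"].iloc[0] == pytest.approx(t_p, abs=1e-9)

    def test_pvalues_match_studentized_range_oracle(self):
        """Fixed 4x6 table: p-values recomputed independently from the
        studentized-range distribution."""
        rng = np.random.default_rng(3)
        data = {g: rng.normal(mu, 2.0, 6) for g, mu in
                zip("abcd", (0.0, 1.0, 3.5, 4.0))}
        res = tukey_letters(data)
        groups = sorted(data)
        n, k = 6, 4
        mse = np.mean([np.var(data[g], ddof=1) for g in groups])
        dfree = k * (n - 1)
        for row in res.pairwise.itertuples():
            diff = abs(np.mean(data[row.group2]) - np.mean(data[row.group1]))
            q = diff / np.sqrt(mse / n)
            expected = sps.studentized_range.sf(q, k, dfree)
            assert row.p_adj == pytest.approx(expected, abs=1e-6)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            tukey_letters({"a": [1.0], "b": [1.0, 2.0]})


class TestCompareSlopes:
    def test_identical_groups_nonsignificant(self):
        rng = np.random.default_rng(4)
        x = np.tile(np.linspace(0, 10, 8), 2)
        y = 2.0 * x + rng.normal(0, 0.5, 16)
        g = np.repeat(["a", "b"], 8)
        out = compare_slopes(x, y, g)
        assert abs(out["diff"].iloc[0]) < 0.5
        assert out["p_adj"].iloc[0] > 0.2

    def test_lue_sized_contrast_detected(self):
        """Slopes 4.26 vs 3.86 with small noise, n=6 each: significant."""
        rng = np.random.default_rng(5)
        x = np.tile(np.linspace(50, 350, 6), 2)
        y = np.concatenate([4.26 * x[:6], 3.86 * x[6:]]) + rng.normal(0, 5.0, 12)
        out = compare_slopes(x, y, np.repeat(["s30", "yusho"], 6))
        assert out["p_adj"].iloc[0] < 0.01
        assert out["diff"].iloc[0] == pytest.approx(0.40, abs=0.05)

    def test_two_group_case_equals_slope_t_test(self):
        """Closed-form oracle: two independent regressions, slope-difference
        t statistic from the pooled residual variance."""
        rng = np.random.default_rng(6)
        x1, x2 = np.linspace(0, 10, 7), np.linspace(0, 12, 9)
        y1 = 1.5 * x1 + rng.normal(0, 1, 7)
        y2 = 2.5 * x2 + rng.normal(0, 1, 9)
        out = compare_slopes(
            np.concatenate([x1, x2]),
            np.concatenate([y1, y2]),
            np.repeat(["a", "b"], [7, 9]),
        )
        # hand computation
        def fit(x, y):
            X = np.column_stack([np.ones_like(x), x])
            beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
            return beta[1], float(res[0]), x
        b1, rss1, _ = fit(x1, y1)
        b2, rss2, _ = fit(x2, y2)
        dfree = (7 - 2) + (9 - 2)
        s2 = (rss1 + rss2) / dfree
        var = s2 * (1 / np.sum((x1 - x1.mean()) ** 2) + 1 / np.sum((x2 - x2.mean()) ** 2))
        t = (b1 - b2) / np.sqrt(var)
        assert out["t"].iloc[0] == pytest.approx(t, rel=1e-9)
        assert out["diff"].iloc[0] == pytest.approx(b1 - b2, rel=1e-9)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            compare_slopes([1, 1, 2, 3], [1, 2, 3, 4], ["a", "a", "b", "b"])


class TestComponentCorrelations:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(7)
        v = rng.normal(0, 1, 20)
        out = component_correlations(pd.DataFrame({"x": v, "y": v + 0.0}))
        assert out["r"].loc["x", "y"] == pytest.approx(1.0)

    def test_bh_equals_step_up_hand_computation(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(size=(12, 3)), columns=list("abc"))
        df["b"] += 2.0 * df["a"]
        out = component_correlations(df)
        raw = [out["p_raw"].loc[i, j] for i, j in (("a", "b"), ("a", "c"), ("b", "c"))]
        m = len(raw)
        order = np.argsort(raw)
        adj = np.empty(m)
        prev = 1.0
        for rank, idx in list(enumerate(order))[::-1]:
            prev = min(prev, raw[idx] * m / (rank + 1))
            adj[idx] = prev
        got = [out["p_adj"].loc[i, j] for i, j in (("a", "b"), ("a", "c"), ("b", "c"))]
        assert np.allclose(got, adj)

    def test_bh_monotone_and_not_below_raw(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.normal(size=(15, 5)), columns=list("abcde"))
        out = component_correlations(df)
        iu = np.triu_indices(5, 1)
        raw = out["p_raw"].to_numpy()[iu]
        adj = out["p_adj"].to_numpy()[iu]
        assert (adj >= raw - 1e-12).all()
        order = np.argsort(raw)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_matrix_structure(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(rng.normal(size=(25, 4)), columns=list("wxyz"))
        r = component_correlations(df)["r"].to_numpy()
        assert np.allclose(r, r.T)
        assert np.allclose(np.diag(r), 1.0)
        assert (np.abs(r) <= 1.0 + 1e-12).all()

    def test_constant_column_reported_missing(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [5.0] * 4,
                           "c": [2.0, 1.0, 4.0, 3.0]})
        out = component_correlations(df)
        assert np.isnan(out["r"].loc["a", "b"])
        assert not np.isnan(out["r"].loc["a", "c"])

    def test_null_type_one_error_rate(self):
        """Independent columns: ~5% raw rejections at alpha = 0.05 over
        1000 null simulations."""
        rng = np.random.default_rng(12)
        n_sims, n, hits, total = 1000, 40, 0, 0
        for _ in range(n_sims):
            x, y = rng.normal(size=(2, n))
            p = sps.pearsonr(x, y).pvalue
            hits += p < 0.05
            total += 1
        rate = hits / total
        assert rate == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / n_sims))

    def test_bh_controls_fdr_in_spiked_simulation(self):
        """Half the columns correlate with a driver; BH-adjusted discoveries
        keep the false-discovery proportion near or below 5%."""
        rng = np.random.default_rng(13)
        fdp = []
        for _ in range(200):
            n = 40
            driver = rng.normal(size=n)
            df = pd.DataFrame({"driver": driver})
            for i in range(4):
                df[f"sig{i}"] = driver + rng.normal(0, 0.7, n)
            for i in range(4):
                df[f"null{i}"] = rng.normal(size=n)
            out = component_correlations(df)
            adj = out["p_adj"]
            false = sum(
                adj.loc[f"null{i}", c] < 0.05
                for i in range(4)
                for c in adj.columns
                if c != f"null{i}"
            ) / 2.0  # symmetric pairs counted once
            disc = (adj.to_numpy()[np.triu_indices(9, 1)] < 0.05).sum()
            fdp.append(false / max(disc, 1))
        assert np.mean(fdp) < 0.08

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            component_correlations(pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]}))
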