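"""Statistical layer: PCA, ANOVAs, assumption checks, matched-filter report."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from spectune.stats import (
    assumption_checks,
    compact_letter_display,
    matched_filter_report,
    one_way_anova,
    pca_metrics,
    two_way_anova,
)


class TestPCA:
    def test_rank_one_case(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": 3 * x + 1})
        res = pca_metrics(df, feature_cols=["a", "b"])
        assert res.variance_pct[0] == pytest.approx(100.0, abs=1e-9)

    def test_variance_percentages_sum_to_100(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 4)),
                          columns=["peak_nm", "fwhm_nm", "auc_pct_nm", "avg_pct"])
        res = pca_metrics(df)
        assert res.variance_pct.sum() == pytest.approx(100.0, abs=1e-9)

    def test_zero_variance_variable_named_in_error(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=10), "b": np.ones(10)})
        with pytest.raises(ValueError, match="'b'"):
            pca_metrics(df, feature_cols=["a", "b"])

    def test_scores_centered_and_sign_convention(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        res = pca_metrics(df, feature_cols=list("abc"))
        assert np.allclose(res.scores[["PC1", "PC2", "PC3"]].mean(), 0.0, atol=1e-12)
        for pc in ("PC1", "PC2", "PC3"):
            loading = res.loadings[pc]
            assert loading.iloc[np.argmax(np.abs(loading))] > 0

    def test_score_variances_proportional_to_variance_pct(self, rng):
        df = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        res = pca_metrics(df, feature_cols=list("abc"))
        var = res.scores[["PC1", "PC2", "PC3"]].var(ddof=1).to_numpy()
        assert np.allclose(var / var.sum() * 100, res.variance_pct, atol=1e-9)

    def test_group_hulls_present(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        df["morph"] = np.repeat(["X", "Y"], 10)
        res = pca_metrics(df, feature_cols=list("abc"), group_col="morph")
        assert set(res.hulls) == {"X", "Y"}
        assert res.hulls["X"].shape[1] == 2


class TestOneWayAnova:
    def test_hand_computed_table(self):
        res = one_way_anova([1, 2, 3, 2, 3, 4, 3, 4, 5],
                            ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert res.table.loc["group", "sum_sq"] == pytest.approx(6.0)
        assert res.table.loc["Residual", "sum_sq"] == pytest.approx(6.0)
        assert res.table.loc["group", "df"] == 2
        assert res.table.loc["Residual", "df"] == 6
        assert res.table.loc["group", "F"] == pytest.approx(3.0)

    def test_matches_scipy_f_oneway(self, rng):
        groups = [rng.normal(loc=i, size=12) for i in range(3)]
        y = np.concatenate(groups)
        g = np.repeat(list("abc"), 12)
        res = one_way_anova(y, g, pairwise=False)
        F, p = sps.f_oneway(*groups)
        assert res.table.loc["group", "F"] == pytest.approx(F, rel=1e-12)
        assert res.table.loc["group", "p"] == pytest.approx(p, rel=1e-12)

    def test_decomposition_conserves_total_ss(self, rng):
        y = rng.normal(size=40)
        g = rng.choice(list("abcd"), size=40)
        res = one_way_anova(y, g, pairwise=False)
        sst = float(((y - y.mean()) ** 2).sum())
        assert res.table["sum_sq"].sum() == pytest.approx(sst, abs=1e-10)

    def test_identical_observations_flagged(self):
        res = one_way_anova([5.0] * 6, ["a"] * 3 + ["b"] * 3)
        assert res.f_undefined
        assert np.isnan(res.table.loc["group", "F"])

    def test_separated_tight_groups_tukey(self, rng):
        y = np.concatenate([rng.normal(0, 0.1, 10), rng.normal(10, 0.1, 10),
                            rng.normal(20, 0.1, 10)])
        g = np.repeat(list("abc"), 10)
        res = one_way_anova(y, g)
        assert (res.pairwise["adj_p"] < 0.001).all()
        # independent oracle: studentized-range tail probability
        parts = [y[g == lv] for lv in "abc"]
        msw = np.mean([p.var(ddof=1) for p in parts])
        for (a, b) in itertools.combinations(range(3), 2):
            q = abs(parts[a].mean() - parts[b].mean()) / np.sqrt(msw / 10)
            p_oracle = sps.studentized_range.sf(q, 3, 27)
            assert p_oracle < 0.001
        # all groups differ -> all letters distinct
        assert len(set(res.letters.values())) == 3

    def test_tukey_adjusted_p_bounded_by_raw(self, rng):
        y = rng.normal(size=30)
        g = np.repeat(list("abc"), 10)
        res = one_way_anova(y, g)
        assert (res.pairwise["adj_p"] >= res.pairwise["raw_p"] - 1e-12).all()
        assert (res.pairwise["adj_p"] <= 1.0).all()


def _type2_oracle(y, A, B):
    """Brute-force model-comparison sums of squares via explicit regressions."""
    df = pd.DataFrame({"y": y, "A": A, "B": B})

    def rss(terms):
        X = [np.ones(len(df))]
        if "A" in terms:
            X.append(pd.get_dummies(df["A"], drop_first=True).to_numpy(float))
        if "B" in terms:
            X.append(pd.get_dummies(df["B"], drop_first=True).to_numpy(float))
        if "AB" in terms:
            a = pd.get_dummies(df["A"], drop_first=True).to_numpy(float)
            b = pd.get_dummies(df["B"], drop_first=True).to_numpy(float)
            X.append(np.stack([a[:, i] * b[:, j]
                               for i in range(a.shape[1])
                               for j in range(b.shape[1])], axis=1))
        M = np.column_stack(X)
        resid = df["y"] - M @ np.linalg.lstsq(M, df["y"], rcond=None)[0]
        return float((resid**2).sum()), M.shape[1]

    rss_full, p_full = rss(["A", "B", "AB"])
    rss_ab, _ = rss(["A", "B"])
    ss = {
        "A": rss(["B"])[0] - rss_ab,
        "B": rss(["A"])[0] - rss_ab,
        "A:B": rss_ab - rss_full,
    }
    n_a, n_b = df["A"].nunique(), df["B"].nunique()
    dfs = {"A": n_a - 1, "B": n_b - 1, "A:B": (n_a - 1) * (n_b - 1)}
    df_resid = len(df) - p_full
    mse = rss_full / df_resid
    return {k: (ss[k] / dfs[k]) / mse for k in ss}


class TestTwoWayAnova:
    def balanced(self, rng, n=4, shift=0.0):
        levels_a, levels_b = ["g1", "g2"], ["w1", "w2", "w3"]
        rows = []
        for a in levels_a:
            for b in levels_b:
                mu = (1.0 if a == "g2" else 0.0) + {"w1": 0, "w2": 1, "w3": 2}[b]
                if a == "g2" and b == "w2":
                    mu += shift
                for _ in range(n):
                    rows.append((rng.normal(mu, 1.0), a, b))
        return map(np.array, zip(*rows))

    def test_additive_design_zero_interaction(self):
        # noiseless, purely additive cell means
        y, a, b = [], [], []
        for ai, av in enumerate(["g1", "g2"]):
            for bi, bv in enumerate(["w1", "w2"]):
                for _ in range(3):
                    y.append(ai * 2.0 + bi * 5.0)
                    a.append(av)
                    b.append(bv)
        res = two_way_anova(y, a, b)
        assert res.table.loc["A:B", "sum_sq"] == pytest.approx(0.0, abs=1e-10)

    def test_matches_regression_oracle(self, rng):
        y, a, b = self.balanced(rng, shift=1.5)
        res = two_way_anova(y, a, b)
        oracle = _type2_oracle(y, a, b)
        for term in ("A", "B", "A:B"):
            assert res.table.loc[term, "F"] == pytest.approx(oracle[term], abs=1e-8)

    def test_matches_oracle_unbalanced(self, rng):
        y, a, b = self.balanced(rng, shift=1.0)
        keep = np.ones(len(y), bool)
        keep[[0, 7, 13]] = False  # unbalance the cells without emptying any
        res = two_way_anova(y[keep], a[keep], b[keep])
        oracle = _type2_oracle(y[keep], a[keep], b[keep])
        for term in ("A", "B", "A:B"):
            assert res.table.loc[term, "F"] == pytest.approx(oracle[term], abs=1e-8)

    def test_type2_equals_sequential_on_balanced_data(self, rng):
        y, a, b = self.balanced(rng)
        t2 = two_way_anova(y, a, b, ss_type=2).table
        t1 = two_way_anova(y, a, b, ss_type=1).table
        for term in ("A", "B", "A:B"):
            assert t2.loc[term, "sum_sq"] == pytest.approx(t1.loc[term, "sum_sq"], abs=1e-8)

    def test_bonferroni_multiplies_and_caps(self, rng):
        y, a, b = self.balanced(rng, n=6, shift=4.0)
        res = two_way_anova(y, a, b)
        pw = res.pairwise
        for scope, fam in pw.groupby(pw["scope"] == "marginal"):
            m = len(fam)
            assert np.allclose(fam["adj_p"], np.minimum(fam["raw_p"] * m, 1.0))

    def test_missing_cell_drops_level_with_warning(self, rng):
        y, a, b = self.balanced(rng)
        keep = ~((a == "g2") & (b == "w3"))  # empty one cell entirely
        with pytest.warns(UserWarning, match="dropping"):
            res = two_way_anova(y[keep], a[keep], b[keep])
        assert "w3" in res.notes[0]

    def test_fewer_than_two_levels_rejected(self):
        with pytest.raises(ValueError, match="2 levels"):
            two_way_anova([1.0, 2.0, 3.0, 4.0], ["a"] * 4, ["x", "x", "y", "y"])


class TestAssumptionChecks:
    def test_levene_and_normality_on_gaussian_data(self, rng):
        y = rng.normal(size=100)
        g = np.repeat(["a", "b"], 50)
        out = assumption_checks(y, g)
        assert out["levene"]["p"] > 0.001
        assert not out["normality"]["skipped"].any()

    def test_levene_matches_scipy(self, rng):
        x, z = rng.normal(size=40), rng.normal(scale=3.0, size=40)
        out = assumption_checks(np.concatenate([x, z]), np.repeat(["a", "b"], 40))
        stat, p = sps.levene(x, z, center="mean")
        assert out["levene"]["statistic"] == pytest.approx(stat)
        assert out["levene"]["p"] == pytest.approx(p)

    def test_degenerate_group_flagged_and_skipped(self, rng):
        y = np.concatenate([np.full(10, 3.0), rng.normal(size=10)])
        g = np.repeat(["const", "ok"], 10)
        out = assumption_checks(y, g)
        assert out["degenerate_groups"] == ["const"]
        assert out["normality"].set_index("group").loc["const", "skipped"]

    def test_uniform_data_fails_normality(self, rng):
        # Lilliefors power against uniform(0,1) at n=200 is ~95% at the
        # 0.05 level (and distinctly lower at 0.01)
        rejections = 0
        for _ in range(200):
            y = np.concatenate([rng.uniform(0, 1, 200), rng.normal(size=50)])
            g = np.array(["u"] * 200 + ["n"] * 50)
            out = assumption_checks(y, g)
            p = out["normality"].set_index("group").loc["u", "p"]
            rejections += p < 0.05
        assert rejections >= 0.90 * 200

    def test_naive_ks_mode_exposed(self, rng):
        y = rng.normal(size=60)
        g = np.repeat(["a", "b"], 30)
        out = assumption_checks(y, g, normality="ks")
        assert out["normality_method"] == "ks"
        assert (out["normality"]["p"] > 0).all()


class TestMatchedFilterReport:
    @staticmethod
    def tuning(group, best_wl, wavelengths=(400, 450, 500, 550, 600, 650)):
        thr = [(-3.5 if wl == best_wl else -3.0) for wl in wavelengths]
        return pd.DataFrame({"group": group, "wavelength_nm": wavelengths,
                             "mean_threshold": thr})

    @staticmethod
    def reflectance(group, peak_wl):
        wl = np.arange(300.0, 701.0)
        r = 50.0 * np.exp(-((wl - peak_wl) ** 2) / (2 * 60.0**2))
        return pd.DataFrame({"group": group, "wavelength_nm": wl, "mean_pct": r})

    def test_identical_optima_give_zero_mismatch(self):
        rep = matched_filter_report(self.tuning("g", 550), self.reflectance("g", 550))
        assert rep.loc[0, "mismatch_nm"] == 0.0

    def test_reported_wavelengths_inside_measured_ranges(self):
        rep = matched_filter_report(self.tuning("g", 450), self.reflectance("g", 480))
        assert 400 <= rep.loc[0, "min_threshold_wavelength_nm"] <= 650
        assert 300 <= rep.loc[0, "peak_reflectance_wavelength_nm"] <= 700
        assert rep.loc[0, "mismatch_nm"] == 30.0

    def test_too_few_wavelengths_rejected(self):
        t = self.tuning("g", 450, wavelengths=(450, 500))
        with pytest.raises(ValueError, match="< 3"):
            matched_filter_report(t, self.reflectance("g", 480))

    def test_non_overlapping_ranges_rejected(self):
        refl = pd.DataFrame({"group": "g", "wavelength_nm": np.arange(900.0, 1000.0),
                             "mean_pct": 1.0})
        with pytest.raises(ValueError, match="overlap"):
            matched_filter_report(self.tuning("g", 450), refl)


def test_compact_letter_display_shares_letters_iff_not_different():
    letters = compact_letter_display(["a", "b", "c"], {("a", "c")})
    assert set(letters["a"]) & set(letters["b"])
    assert set(letters["b"]) & set(letters["c"])
    assert not set(letters["a"]) & set(letters["c"])
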