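"""The study's statistical layer.

Covers four jobs: PCA of the spectral curve metrics (peak, FWHM, AUC,
average reflectance) on standardized variables; one-way ANOVA with Tukey
HSD and a compact-letter display for the photographic scaled-reflectance
comparison; two-way factorial ANOVA (group x wavelength, Type II sums of
squares for unbalanced data) with Bonferroni-corrected pairwise and
simple-effects contrasts for retinal thresholds; Levene and
Kolmogorov-Smirnov (Lilliefors) assumption checks; and the matched-filter
report comparing each group's most sensitive stimulus wavelength with the
peak of its dorsal reflectance curve.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.diagnostic import kstest_normal
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "PCAResult",
    "AnovaResult",
    "pca_metrics",
    "one_way_anova",
    "two_way_anova",
    "assumption_checks",
    "matched_filter_report",
    "compact_letter_display",
]

DEFAULT_ALPHA = 0.05


@dataclass
class PCAResult:
    variance_pct: np.ndarray          # per component, sums to 100
    scores: pd.DataFrame              # observations x components (+ group column)
    loadings: pd.DataFrame            # variables x components
    hulls: dict = field(default_factory=dict)  # group -> (m, 2) PC1/PC2 hull vertices


@dataclass
class AnovaResult:
    table: pd.DataFrame               # per term: df, sum_sq, mean_sq, F, p
    pairwise: pd.DataFrame            # contrast, raw_p, adj_p, method (+ scope)
    letters: dict | None = None       # compact-letter display
    alpha: float = DEFAULT_ALPHA
    f_undefined: bool = False
    notes: list = field(default_factory=list)


def pca_metrics(
    table: pd.DataFrame,
    feature_cols: list[str] | tuple[str, ...] = ("peak_nm", "fwhm_nm", "auc_pct_nm", "avg_pct"),
    group_col: str | None = None,
) -> PCAResult:
    """PCA of curve metrics on centered, unit-variance variables.

    Components are ordered by explained variance; the sign of each
    component is fixed so its largest-magnitude loading is positive.
    Convex hulls of (PC1, PC2) scores are returned per group when a
    grouping column is given.
    """
    feature_cols = list(feature_cols)
    X = table[feature_cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values among the metric columns")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 variables")
    sd = X.std(axis=0, ddof=0)
    for name, s in zip(feature_cols, sd):
        if s == 0:
            raise ValueError(f"variable {name!r} has zero variance")
    Z = (X - X.mean(axis=0)) / sd

    pca = PCA()
    scores = pca.fit_transform(Z)
    loadings = pca.components_          # (n_components, n_features)
    for k in range(loadings.shape[0]):  # sign convention
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] *= -1.0
            scores[:, k] *= -1.0

    comp_names = [f"PC{i + 1}" for i in range(loadings.shape[0])]
    scores_df = pd.DataFrame(scores, columns=comp_names, index=table.index)
    if group_col is not None:
        scores_df[group_col] = table[group_col].to_numpy()
    loadings_df = pd.DataFrame(loadings.T, index=feature_cols, columns=comp_names)
    variance_pct = pca.explained_variance_ratio_ * 100.0

    hulls: dict = {}
    if group_col is not None and scores.shape[1] >= 2:
        from scipy.spatial import ConvexHull, QhullError
        for label, grp in scores_df.groupby(group_col):
            pts = grp[["PC1", "PC2"]].to_numpy()
            if len(pts) >= 3:
                try:
                    hull = ConvexHull(pts)
                    hulls[label] = pts[hull.vertices]
                except QhullError:  # collinear points
                    hulls[label] = pts
            else:
                hulls[label] = pts
    return PCAResult(variance_pct, scores_df, loadings_df, hulls)


def compact_letter_display(
    levels: list[str],
    significant_pairs: set[tuple[str, str]],
) -> dict[str, str]:
    """Letters such that two levels share a letter iff not significantly different.

    Insert-and-absorb construction; letter assignment order (and hence
    ties) is alphabetical in the level names.
    """
    levels = sorted(levels)
    groups: list[set[str]] = [set(levels)]
    for a, b in sorted(significant_pairs):
        new_groups = []
        for g in groups:
            if a in g and b in g:
                new_groups.extend([g - {a}, g - {b}])
            else:
                new_groups.append(g)
        # absorb subsets
        groups = []
        for g in sorted(new_groups, key=len, reverse=True):
            if g and not any(g <= h for h in groups):
                groups.append(g)
    groups.sort(key=lambda g: min(g))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lv: "" for lv in levels}
    for letter, g in zip(alphabet, groups):
        for lv in sorted(g):
            out[lv] += letter
    return out


def one_way_anova(
    values, groups, alpha: float = DEFAULT_ALPHA, pairwise: bool = True
) -> AnovaResult:
    """Classical one-way ANOVA with Tukey HSD pairwise comparisons.

    The between/within decomposition is computed directly; Tukey adjusted
    p-values come from the studentized-range distribution, and raw
    pairwise p-values from pooled-variance t tests.  A compact-letter
    display marks groups not significantly different at ``alpha``.
    ``pairwise=False`` skips the post-hoc layer (useful in simulations
    that only need the omnibus F).
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if len(y) != len(g):
        raise ValueError("values and groups differ in length")
    labels = sorted(pd.unique(g).tolist())
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    parts = [y[g == lv] for lv in labels]
    ns = np.array([len(p) for p in parts])
    if not (ns >= 1).all() or not (ns >= 2).any():
        raise ValueError("need at least 2 observations in some group")

    grand = y.mean()
    ssb = float(sum(n * (p.mean() - grand) ** 2 for n, p in zip(ns, parts)))
    ssw = float(sum(((p - p.mean()) ** 2).sum() for p in parts))
    df_b = len(labels) - 1
    df_w = len(y) - len(labels)
    msb = ssb / df_b
    f_undefined = ssw == 0.0
    if f_undefined:
        msw, F, p = np.nan, np.nan, np.nan
    else:
        msw = ssw / df_w
        F = msb / msw
        p = float(sps.f.sf(F, df_b, df_w))
    table = pd.DataFrame(
        {"df": [df_b, df_w], "sum_sq": [ssb, ssw],
         "mean_sq": [msb, msw], "F": [F, np.nan], "p": [p, np.nan]},
        index=["group", "Residual"])

    pair_rows = []
    sig_pairs: set[tuple[str, str]] = set()
    if not f_undefined and pairwise:
        tukey = pairwise_tukeyhsd(y, g, alpha=alpha)
        tukey_df = pd.DataFrame(tukey.summary().data[1:],
                                columns=tukey.summary().data[0])
        adj = {}
        for _, row in tukey_df.iterrows():
            adj[(str(row["group1"]), str(row["group2"]))] = float(row["p-adj"])
        for (i, a), (j, b) in itertools.combinations(enumerate(labels), 2):
            diff = parts[i].mean() - parts[j].mean()
            se = np.sqrt(msw * (1 / ns[i] + 1 / ns[j]))
            t = diff / se
            raw_p = float(2 * sps.t.sf(abs(t), df_w))
            adj_p = adj[(str(a), str(b))] if (str(a), str(b)) in adj else adj[(str(b), str(a))]
            adj_p = float(min(max(adj_p, raw_p), 1.0))
            pair_rows.append({"contrast": f"{a} - {b}", "group1": a, "group2": b,
                              "raw_p": raw_p, "adj_p": adj_p, "method": "tukey_hsd"})
            if adj_p < alpha:
                sig_pairs.add((str(a), str(b)))
    pairwise_df = pd.DataFrame(pair_rows)
    letters = compact_letter_display([str(lv) for lv in labels], sig_pairs) \
        if (not f_undefined and pairwise) else None
    return AnovaResult(table, pairwise_df, letters, alpha, f_undefined,
                       ["all groups have zero within-group variance; F undefined"]
                       if f_undefined else [])


def _drop_empty_cells(df: pd.DataFrame, notes: list) -> pd.DataFrame:
    """Drop factor-B levels (e.g. 350 nm) missing from any factor-A group."""
    counts = df.groupby(["A", "B"], observed=True).size().unstack(fill_value=0)
    bad_b = [b for b in counts.columns if (counts[b] == 0).any()]
    if bad_b:
        msg = (f"dropping factor-B level(s) {bad_b} absent from some "
               "factor-A group (incomplete factorial)")
        warnings.warn(msg, UserWarning, stacklevel=3)
        notes.append(msg)
        df = df[~df["B"].isin(bad_b)]
    if df["A"].nunique() < 2 or df["B"].nunique() < 2:
        raise ValueError("fewer than 2 levels per factor after dropping empty cells")
    return df


def two_way_anova(
    response, factor_a, factor_b,
    alpha: float = DEFAULT_ALPHA,
    ss_type: int = 2,
) -> AnovaResult:
    """Factorial two-way ANOVA with interaction and Bonferroni contrasts.

    Type II sums of squares by default (robust to unbalance; identical to
    sequential SS on balanced data).  Factor A is the grouping factor of
    interest (species / morph / sex / strategy); factor B is typically the
    stimulus wavelength.  Incomplete cells are handled by dropping the
    factor-B level with a warning.  Pairwise factor-A contrasts are
    Welch t tests on the marginal data, Bonferroni-adjusted; when the
    interaction is significant at ``alpha``, simple-effects contrasts of
    factor A within each factor-B level are added (Bonferroni-adjusted
    over all simple-effect contrasts).
    """
    notes: list = []
    df = pd.DataFrame({
        "y": np.asarray(response, dtype=float),
        "A": np.asarray(factor_a).astype(str),
        "B": np.asarray(factor_b).astype(str),
    })
    if df["A"].nunique() < 2 or df["B"].nunique() < 2:
        raise ValueError("need at least 2 levels per factor")
    df = _drop_empty_cells(df, notes)

    model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=ss_type)
    aov = aov.rename(index={"C(A)": "A", "C(B)": "B", "C(A):C(B)": "A:B"})
    table = pd.DataFrame({
        "df": aov["df"],
        "sum_sq": aov["sum_sq"],
        "mean_sq": aov["sum_sq"] / aov["df"],
        "F": aov.get("F"),
        "p": aov.get("PR(>F)"),
    })

    def _pairs(sub: pd.DataFrame, scope: str) -> list[dict]:
        rows = []
        for a1, a2 in itertools.combinations(sorted(sub["A"].unique()), 2):
            y1 = sub.loc[sub["A"] == a1, "y"]
            y2 = sub.loc[sub["A"] == a2, "y"]
            if len(y1) < 2 or len(y2) < 2:
                continue
            _, raw_p = sps.ttest_ind(y1, y2, equal_var=False)
            rows.append({"contrast": f"{a1} - {a2}", "scope": scope,
                         "raw_p": float(raw_p)})
        return rows

    pair_rows = _pairs(df, "marginal")
    interaction_p = float(table.loc["A:B", "p"]) if "A:B" in table.index else np.nan
    if np.isfinite(interaction_p) and interaction_p < alpha:
        for b_level in sorted(df["B"].unique()):
            pair_rows += _pairs(df[df["B"] == b_level], f"B={b_level}")
    pairwise = pd.DataFrame(pair_rows)
    if not pairwise.empty:
        # Bonferroni within each family (marginal vs simple effects)
        for fam, idx in pairwise.groupby(pairwise["scope"] == "marginal").groups.items():
            m = len(idx)
            pairwise.loc[idx, "adj_p"] = np.minimum(pairwise.loc[idx, "raw_p"] * m, 1.0)
        pairwise["method"] = "bonferroni"
    return AnovaResult(table, pairwise, None, alpha, False, notes)


def assumption_checks(
    values, groups,
    normality: str = "lilliefors",
    min_n_normality: int = 4,
) -> dict:
    """Homogeneity-of-variance and normality diagnostics.

    Levene's test on absolute deviations from group means (``center=
    'mean'``); per-group normality via a Kolmogorov-Smirnov statistic
    against a normal with moments estimated from the sample — by default
    using the Lilliefors-corrected null distribution, or ``normality=
    "ks"`` for the naive KS p-value.  Groups with zero deviation are
    flagged and skipped.
    """
    if normality not in {"lilliefors", "ks"}:
        raise ValueError(f"unknown normality method {normality!r}")
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels = sorted(pd.unique(g).tolist())
    if len(labels) < 2:
        raise ValueError("Levene needs at least 2 groups")
    parts = {lv: y[g == lv] for lv in labels}

    degenerate = [lv for lv, p in parts.items() if np.ptp(p) == 0]
    out: dict = {"degenerate_groups": degenerate}
    usable = [p for lv, p in parts.items() if lv not in degenerate]
    if len(usable) >= 2:
        stat, p = sps.levene(*usable, center="mean")
        out["levene"] = {"statistic": float(stat), "p": float(p)}
    else:
        out["levene"] = None

    rows = []
    for lv in labels:
        p_ = parts[lv]
        if lv in degenerate or len(p_) < min_n_normality:
            rows.append({"group": lv, "n": len(p_), "statistic": np.nan,
                         "p": np.nan, "skipped": True})
            continue
        if normality == "lilliefors":
            stat, pval = kstest_normal(p_, dist="norm")
        else:
            stat, pval = sps.kstest(p_, "norm", args=(p_.mean(), p_.std(ddof=1)))
        rows.append({"group": lv, "n": len(p_), "statistic": float(stat),
                     "p": float(pval), "skipped": False})
    out["normality"] = pd.DataFrame(rows)
    out["normality_method"] = normality
    return out


def matched_filter_report(
    tuning: pd.DataFrame,
    dorsal_summary: pd.DataFrame,
) -> pd.DataFrame:
    """Compare each group's sensitivity optimum with its reflectance peak.

    ``tuning`` is a tuning-curve table (``group, wavelength_nm,
    mean_threshold``); ``dorsal_summary`` a group mean reflectance table
    (``group, wavelength_nm, mean_pct``).  For every group present in
    both, reports the tested wavelength of minimum mean threshold, the
    wavelength of peak mean dorsal reflectance, and their absolute
    difference in nm.  No significance claim is attached.
    """
    for col in ("group", "wavelength_nm", "mean_threshold"):
        if col not in tuning.columns:
            raise ValueError(f"tuning table missing column {col!r}")
    for col in ("group", "wavelength_nm", "mean_pct"):
        if col not in dorsal_summary.columns:
            raise ValueError(f"reflectance summary missing column {col!r}")
    rows = []
    for label in sorted(set(tuning["group"]) & set(dorsal_summary["group"]), key=str):
        tun = tuning[tuning["group"] == label]
        refl = dorsal_summary[dorsal_summary["group"] == label]
        if tun["wavelength_nm"].nunique() < 3:
            raise ValueError(f"group {label!r}: tuning curve has < 3 wavelengths")
        t_lo, t_hi = tun["wavelength_nm"].min(), tun["wavelength_nm"].max()
        r_lo, r_hi = refl["wavelength_nm"].min(), refl["wavelength_nm"].max()
        if t_hi < r_lo or r_hi < t_lo:
            raise ValueError(f"group {label!r}: tuning and reflectance ranges do not overlap")
        best_stim = float(tun.loc[tun["mean_threshold"].idxmin(), "wavelength_nm"])
        refl_peak = float(refl.loc[refl["mean_pct"].idxmax(), "wavelength_nm"])
        rows.append({
            "group": label,
            "min_threshold_wavelength_nm": best_stim,
            "peak_reflectance_wavelength_nm": refl_peak,
            "mismatch_nm": abs(refl_peak - best_stim),
        })
    if not rows:
        raise ValueError("no group appears in both tables")
    return pd.DataFrame(rows)
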