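"""Group comparisons and the yield-component correlation analysis.

Tukey HSD with a compact letter display, pairwise regression-slope
contrasts (Tukey-adjusted via the studentized range), and a Pearson (or
Spearman) correlation matrix with Benjamini-Hochberg adjustment over the
upper triangle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests


@dataclass
class ComparisonResult:
    groups: list
    means: pd.Series
    pooled_se: float
    pairwise: pd.DataFrame  # group1, group2, diff, p_adj
    letters: dict = field(default_factory=dict)
    alpha: float = 0.05


def _compact_letters(groups: list, pairwise: pd.DataFrame, alpha: float) -> dict:
    """Compact letter display by the insert-and-absorb algorithm.

    Groups sharing a letter are not significantly different; each
    significant pair is separated in every letter set.
    """
    sets: list[set] = [set(groups)]
    sig_pairs = [
        (r.group1, r.group2) for r in pairwise.itertuples() if r.p_adj < alpha
    ]
    for a, b in sig_pairs:
        for s in list(sets):
            if a in s and b in s:
                sets.remove(s)
                for drop in (a, b):
                    new = s - {drop}
                    # absorb: keep only maximal sets
                    if not any(new <= other for other in sets):
                        sets = [o for o in sets if not o <= new]
                        sets.append(new)
    # order letter sets by the first group they contain
    order = {g: i for i, g in enumerate(groups)}
    sets.sort(key=lambda s: min(order[g] for g in s) if s else len(order))
    letters = {g: "" for g in groups}
    for letter, s in zip("abcdefghijklmnopqrstuvwxyz", sets):
        for g in s:
            letters[g] += letter
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def tukey_letters(
    values: pd.Series | dict, groups: pd.Series | None = None, alpha: float = 0.05
) -> ComparisonResult:
    """One-way Tukey HSD with a compact letter display.

    ``values`` may be a mapping {group: array-like} or a value series
    paired with a ``groups`` label series.
    """
    if isinstance(values, dict):
        data = pd.concat(
            [pd.DataFrame({"value": v, "group": k}) for k, v in values.items()],
            ignore_index=True,
        )
    else:
        data = pd.DataFrame({"value": np.asarray(values), "group": np.asarray(groups)})
    counts = data.groupby("group")["value"].size()
    if len(counts) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"groups with < 2 values: {small}")

    res = pairwise_tukeyhsd(data["value"], data["group"], alpha=alpha)
    tbl = pd.DataFrame(
        res._results_table.data[1:], columns=res._results_table.data[0]
    )
    pairwise = tbl.rename(columns={"p-adj": "p_adj", "meandiff": "diff"})[
        ["group1", "group2", "diff", "p_adj"]
    ]
    # pairwise_tukeyhsd rounds p to 4 dp in the table; recover full precision
    pairwise["p_adj"] = res.pvalues

    group_order = list(res.groupsunique)
    means = data.groupby("group")["value"].mean().loc[group_order]
    df_resid = len(data) - len(group_order)
    mse = (
        data.groupby("group")["value"]
        .apply(lambda v: ((v - v.mean()) ** 2).sum())
        .sum()
        / df_resid
    )
    pooled_se = float(np.sqrt(mse / counts.loc[group_order]).mean())
    letters = _compact_letters(group_order, pairwise, alpha)
    return ComparisonResult(
        groups=group_order,
        means=means,
        pooled_se=pooled_se,
        pairwise=pairwise,
        letters=letters,
        alpha=alpha,
    )


def compare_slopes(x, y, groups) -> pd.DataFrame:
    """Pairwise contrasts of per-group regression slopes.

    Fits a common linear model with group-specific intercepts and slopes
    (full interaction) and tests every pairwise slope difference with a
    Tukey adjustment based on the studentized range over the number of
    groups.  Returns ``group1, group2, slope1, slope2, diff, se, t, p_adj``.
    """
    df = pd.DataFrame({"x": np.asarray(x, float), "y": np.asarray(y, float),
                       "group": np.asarray(groups)})
    labels = sorted(df["group"].unique())
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    for g, grp in df.groupby("group"):
        if len(grp) < 2 or np.ptp(grp["x"].to_numpy()) == 0:
            raise ValueError(f"group {g!r} has degenerate x values")

    # design: per-group intercept and per-group slope
    X = np.zeros((len(df), 2 * len(labels)))
    for j, g in enumerate(labels):
        mask = (df["group"] == g).to_numpy()
        X[mask, j] = 1.0
        X[mask, len(labels) + j] = df.loc[mask, "x"]
    fit = sm.OLS(df["y"].to_numpy(), X).fit()
    k = len(labels)
    dfree = fit.df_resid
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            c = np.zeros(2 * k)
            c[k + i], c[k + j] = 1.0, -1.0
            diff = float(c @ fit.params)
            se = float(np.sqrt(c @ fit.cov_params() @ c))
            t = diff / se if se > 0 else np.inf
            p = float(stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, dfree))
            rows.append(
                {
                    "group1": labels[i],
                    "group2": labels[j],
                    "slope1": float(fit.params[k + i]),
                    "slope2": float(fit.params[k + j]),
                    "diff": diff,
                    "se": se,
                    "t": t,
                    "p_adj": min(p, 1.0),
                }
            )
    return pd.DataFrame(rows)


def component_correlations(
    components: pd.DataFrame,
    method: str = "pearson",
    alpha: float = 0.05,
) -> dict:
    """Correlation matrix over yield-component columns with BH adjustment.

    Non-numeric columns are ignored.  Constant columns yield undefined
    correlations, reported as missing.  Returns a dict with ``r`` (matrix),
    ``p_raw``, ``p_adj`` (BH over the upper-triangle tests) and ``marks``
    ('**' for adjusted p < 0.01, '*' for < 0.05).
    """
    num = components.select_dtypes(include=[np.number])
    cols = list(num.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 numeric components")
    if len(num) < 3:
        raise ValueError("need at least 3 pooled observations")
    corr_fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")

    m = len(cols)
    r = np.full((m, m), np.nan)
    p = np.full((m, m), np.nan)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    pairs, pvals = [], []
    for i in range(m):
        for j in range(i + 1, m):
            xi, xj = num.iloc[:, i], num.iloc[:, j]
            if xi.nunique() < 2 or xj.nunique() < 2:
                continue  # constant column: undefined, left missing
            res = corr_fn(xi, xj)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
            pairs.append((i, j))
            pvals.append(res.pvalue)
    p_adj = np.full((m, m), np.nan)
    np.fill_diagonal(p_adj, 0.0)
    if pvals:
        adj = multipletests(pvals, method="fdr_bh")[1]
        for (i, j), q in zip(pairs, adj):
            p_adj[i, j] = p_adj[j, i] = q
    marks = np.full((m, m), "", dtype=object)
    marks[p_adj < alpha] = "*"
    marks[p_adj < 0.01] = "**"
    np.fill_diagonal(marks, "")
    as_df = lambda a: pd.DataFrame(a, index=cols, columns=cols)
    return {
        "r": as_df(r),
        "p_raw": as_df(p),
        "p_adj": as_df(p_adj),
        "marks": as_df(marks),
        "method": method,
    }
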