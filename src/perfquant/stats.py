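"""Two-group cohort statistics: normality-gated comparisons, exact
categorical tests, covariate-adjusted group means, and descriptive tables.

Continuous variables are gated through the Shapiro-Wilk test in each
group: if both groups look normal (p >= alpha) the comparison is a
two-sided pooled-variance t-test summarized as mean +/- SD, otherwise an
exact Wilcoxon-Mann-Whitney test summarized as median [Q1, Q3].
Categorical flags use Fisher's exact test.  Adjusted group means come from
an OLS model of the outcome on a group indicator plus covariates,
evaluated at the covariate grand means.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "TestResult",
    "AdjustedMeans",
    "exact_wilcoxon",
    "compare_continuous",
    "compare_categorical",
    "adjusted_group_means",
    "build_tables",
]

#: combined-sample cutoff below which the no-tie exact null (shift
#: algorithm) is used; above it a continuity-corrected normal approximation.
EXACT_WILCOXON_MAX_N = 50
#: combined-sample cutoff for the brute tie-aware permutation enumeration.
TIE_ENUMERATION_MAX_N = 16


@dataclass
class TestResult:
    variable: str
    test_name: str
    statistic: float
    p_value: float
    group_summaries: dict
    n_per_group: dict
    normal: bool | None = None
    warnings: list[str] = field(default_factory=list)


@dataclass
class AdjustedMeans:
    outcome: str
    covariates: list[str]
    adjusted_means: dict
    group_p: float
    covariate_p: dict
    group_difference: float
    n_used: int
    n_dropped: int
    pairwise: list | None = None  # Tukey-adjusted comparisons when > 2 groups


def _rank_sum_enumeration(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Tie-aware exact two-sided WMW p by full enumeration of group splits.

    Uses mid-ranks of the pooled sample; p = min(1, 2 * min(lower tail,
    upper tail)) of the rank-sum of the first group over all C(n, nx)
    equally likely assignments.
    """
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    nx = len(x)
    w_obs = ranks[:nx].sum()
    n_lo = n_hi = total = 0
    for combo in itertools.combinations(range(len(pooled)), nx):
        w = ranks[list(combo)].sum()
        total += 1
        if w <= w_obs + 1e-9:
            n_lo += 1
        if w >= w_obs - 1e-9:
            n_hi += 1
    p = min(1.0, 2.0 * min(n_lo, n_hi) / total)
    return float(w_obs), p


def exact_wilcoxon(x, y) -> tuple[float, float, str]:
    """Two-sided Wilcoxon-Mann-Whitney test.

    Exact null distribution (shift algorithm) for tie-free samples with
    combined n <= EXACT_WILCOXON_MAX_N; tie-aware full enumeration for
    small tied samples; otherwise a continuity-corrected, tie-corrected
    normal approximation.  Returns (statistic, p, method).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size + y.size
    has_ties = np.unique(np.concatenate([x, y])).size < n
    if not has_ties and n <= EXACT_WILCOXON_MAX_N:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue), "exact-shift"
    if has_ties and n <= TIE_ENUMERATION_MAX_N:
        stat, p = _rank_sum_enumeration(x, y)
        return stat, p, "exact-enumeration"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue), "normal-approximation"


def _summaries(groups: dict, normal: bool) -> dict:
    out = {}
    for name, v in groups.items():
        v = np.asarray(v, dtype=float)
        if normal:
            out[name] = {"n": v.size, "mean": float(v.mean()),
                         "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                         "text": f"{v.mean():.2f} ± {v.std(ddof=1):.2f}"}
        else:
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            out[name] = {"n": v.size, "median": float(med), "q1": float(q1),
                         "q3": float(q3),
                         "text": f"{med:.2f} [{q1:.2f}, {q3:.2f}]"}
    return out


def compare_continuous(table: pd.DataFrame, variable: str,
                       group_col: str = "group",
                       alpha_normality: float = 0.05,
                       welch: bool = False) -> TestResult:
    """Normality-gated two-group comparison of a continuous variable.

    Both groups must pass Shapiro-Wilk at ``alpha_normality`` for the
    pooled-variance t-test (Welch by flag); otherwise the exact
    Wilcoxon-Mann-Whitney path is taken.  A constant variable, for which
    Shapiro-Wilk is undefined, falls to the Wilcoxon path with a warning.
    """
    levels = [lv for lv in table[group_col].dropna().unique()]
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, found {levels}")
    groups = {}
    for lv in levels:
        v = pd.to_numeric(table.loc[table[group_col] == lv, variable],
                          errors="coerce").dropna().to_numpy()
        if v.size < 3:
            raise ValueError(f"group {lv!r} has < 3 non-missing values "
                             f"for {variable!r}")
        groups[lv] = v

    warns: list[str] = []
    normal = True
    for lv, v in groups.items():
        if np.allclose(v, v[0]):
            warns.append(f"constant values in group {lv!r}; "
                         "Shapiro-Wilk undefined, using Wilcoxon")
            normal = False
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if sps.shapiro(v).pvalue < alpha_normality:
                normal = False

    a, b = (groups[lv] for lv in levels)
    if normal:
        res = sps.ttest_ind(a, b, equal_var=not welch)
        name = "welch-t" if welch else "t-test"
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        stat, p, method = exact_wilcoxon(a, b)
        name = f"wilcoxon ({method})"
    return TestResult(variable=variable, test_name=name, statistic=stat,
                      p_value=p, group_summaries=_summaries(groups, normal),
                      n_per_group={lv: int(groups[lv].size) for lv in levels},
                      normal=normal, warnings=warns)


def compare_categorical(table: pd.DataFrame, flag: str,
                        group_col: str = "group") -> TestResult:
    """Two-sided Fisher exact test of a binary flag across two groups."""
    sub = table[[group_col, flag]].dropna()
    ct = pd.crosstab(sub[group_col], sub[flag].astype(bool))
    if ct.shape[0] != 2:
        raise ValueError(f"need exactly 2 groups, crosstab shape {ct.shape}")
    # pad absent flag levels with zero columns (reindex: a boolean list
    # would be taken as a row mask)
    ct = ct.reindex(columns=[False, True], fill_value=0)
    counts = ct.to_numpy()
    if counts.sum(axis=1).min() == 0:
        raise ValueError("a group has no observations for the flag")
    odds, p = sps.fisher_exact(counts, alternative="two-sided")
    summaries = {}
    for lv in ct.index:
        n = int(ct.loc[lv].sum())
        k = int(ct.loc[lv].get(True, 0))
        summaries[lv] = {"n": n, "count": k, "pct": 100.0 * k / n,
                         "text": f"{k} ({100.0 * k / n:.0f}%)"}
    return TestResult(variable=flag, test_name="fisher-exact",
                      statistic=float(odds), p_value=float(p),
                      group_summaries=summaries,
                      n_per_group={lv: int(ct.loc[lv].sum()) for lv in ct.index})


def _check_full_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        culprits = []
        cols = list(X.columns)
        for i in range(len(cols)):
            sub = X.drop(columns=cols[i])
            if np.linalg.matrix_rank(sub.to_numpy()) == rank:
                culprits.append(cols[i])
        raise ValueError(f"rank-deficient design; collinear columns: {culprits}")


def adjusted_group_means(table: pd.DataFrame, outcome: str,
                         covariates: list[str] | None = None,
                         group_col: str = "group") -> AdjustedMeans:
    """Covariate-adjusted group means for a perfusion outcome.

    Fits OLS of the outcome on a group indicator plus covariates on
    complete cases; adjusted means are model predictions at the covariate
    grand means for each group.  With two groups the group p-value is the
    two-sided t-test of the group coefficient; with more groups, all
    pairwise differences are reported with Tukey-adjusted p-values from
    the studentized-range distribution.
    """
    if covariates is None:
        covariates = ["age", "lv_mass", "bmi", "female"]
    cols = [outcome, group_col] + covariates
    sub = table[cols].copy()
    for c in [outcome] + covariates:
        sub[c] = pd.to_numeric(sub[c].astype(float) if sub[c].dtype == bool
                               else sub[c], errors="coerce")
    n_before = len(sub)
    sub = sub.dropna()
    n_used, n_dropped = len(sub), n_before - len(sub)

    levels = sorted(sub[group_col].unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    X = pd.DataFrame(index=sub.index)
    for lv in levels[1:]:
        X[f"group[{lv}]"] = (sub[group_col] == lv).astype(float)
    for c in covariates:
        X[c] = sub[c]
    X = sm.add_constant(X)
    _check_full_rank(X)
    model = sm.OLS(sub[outcome].astype(float), X).fit()

    grand = {c: float(sub[c].mean()) for c in covariates}
    adj = {}
    for lv in levels:
        row = {"const": 1.0, **grand}
        for other in levels[1:]:
            row[f"group[{other}]"] = 1.0 if other == lv else 0.0
        adj[lv] = float(model.predict(pd.DataFrame([row])[X.columns])[0])

    cov_p = {c: float(model.pvalues[c]) for c in covariates}
    pairwise = None
    if len(levels) == 2:
        coef_name = f"group[{levels[1]}]"
        group_p = float(model.pvalues[coef_name])
        group_diff = float(model.params[coef_name])
    else:
        # Tukey HSD over all pairwise group-coefficient contrasts
        pairwise = []
        k = len(levels)
        df = model.df_resid
        best_p = 1.0
        for i, j in itertools.combinations(range(k), 2):
            contrast = pd.Series(0.0, index=X.columns)
            if i > 0:
                contrast[f"group[{levels[i]}]"] = -1.0
            if j > 0:
                contrast[f"group[{levels[j]}]"] = 1.0
            diff = float(contrast @ model.params)
            se = float(np.sqrt(contrast @ model.cov_params() @ contrast))
            q = abs(diff) / se * np.sqrt(2.0)
            p = float(sps.studentized_range.sf(q, k, df))
            pairwise.append({"pair": (levels[i], levels[j]), "difference": diff,
                             "p_tukey": p})
            best_p = min(best_p, p)
        group_p = best_p
        group_diff = adj[levels[1]] - adj[levels[0]]
    return AdjustedMeans(outcome=outcome, covariates=list(covariates),
                         adjusted_means=adj, group_p=group_p,
                         covariate_p=cov_p, group_difference=group_diff,
                         n_used=n_used, n_dropped=n_dropped, pairwise=pairwise)


TABLE1_CONTINUOUS = ["age", "bmi"]
TABLE1_FLAGS = ["female", "diabetes", "smoking", "htn", "hld"]
TABLE2_VARIABLES = ["rest_mbf", "stress_mbf", "mpr", "lvef", "lv_mass",
                    "ecv", "native_t1"]


def _result_row(r: TestResult) -> dict:
    row = {"variable": r.variable, "test": r.test_name,
           "p_value": r.p_value}
    for lv, s in r.group_summaries.items():
        row[str(lv)] = s["text"]
    return row


def build_tables(table: pd.DataFrame, group_col: str = "group"
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Descriptive characteristics and imaging-outcome tables with p-values."""
    counts = table[group_col].value_counts()
    if len(counts) != 2 or counts.min() == 0:
        raise ValueError("both groups must be nonempty")
    t1_rows = []
    for var in TABLE1_CONTINUOUS:
        if var in table.columns:
            t1_rows.append(_result_row(compare_continuous(table, var, group_col)))
    for flag in TABLE1_FLAGS:
        if flag in table.columns:
            t1_rows.append(_result_row(compare_categorical(table, flag, group_col)))
    t2_rows = []
    for var in TABLE2_VARIABLES:
        if var in table.columns and table[var].notna().sum() > 0:
            t2_rows.append(_result_row(compare_continuous(table, var, group_col)))
    return pd.DataFrame(t1_rows), pd.DataFrame(t2_rows)
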