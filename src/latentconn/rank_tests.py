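"""Rank-based manipulation checks and the registration-variable screen.

The battery mirrors the study's non-parametric analysis plan: Kendall tau-b
correlation tests for the two-group agency checks, Kruskal-Wallis +
pairwise Wilcoxon rank-sum (BH-adjusted) for the three viewing conditions,
a Wilcoxon rank-sum test for Zoom vs YouTube, and a Kendall correlation
matrix across the numeric registration/experience variables with BH
adjustment over the upper triangle.

Conventions (the study report leaves them implicit, so they are fixed and
documented here): the Kendall variant is tau-b (tie corrections in both
variables, needed for a binary-vs-ordinal comparison); the Wilcoxon W
statistic is the Mann-Whitney U of the *first* sample; p-values are exact
by enumeration for small tie-free samples and use the tie-corrected normal
approximation with continuity correction otherwise.  Effect sizes:
rank-biserial r = 1 - 2W/(n_a n_b) for two groups, epsilon-squared
H/((N^2-1)/(N+1)) for k groups.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class TestResult:
    """One rank-based test: statistic, p-values, effect size, group sizes."""

    test: str
    statistic_name: str
    statistic: float
    p_value: float
    effect_size_name: str
    effect_size: float
    n: tuple
    df: int | None = None
    p_adjusted: float | None = None
    adjust_method: str | None = None
    note: str = ""

    def as_dict(self) -> dict:
        return {"test": self.test, "statistic": self.statistic_name,
                "value": self.statistic, "df": self.df, "p": self.p_value,
                "p_adj": self.p_adjusted, "adjust": self.adjust_method,
                "effect": self.effect_size_name, "effect_size": self.effect_size,
                "n": "/".join(str(k) for k in self.n), "note": self.note}


def _clean(x) -> np.ndarray:
    x = np.asarray(pd.to_numeric(pd.Series(x), errors="coerce"), dtype=float)
    return x[~np.isnan(x)]


def kendall_tau_test(x, y) -> TestResult:
    """Kendall tau-b with tie-adjusted normal-approximation p (two-sided)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroDivisionError("tau undefined: a variable has zero variance")
    res = stats.kendalltau(x, y, variant="b", method="asymptotic")
    return TestResult(test="kendall", statistic_name="tau_b",
                      statistic=float(res.statistic), p_value=float(res.pvalue),
                      effect_size_name="tau_b", effect_size=float(res.statistic),
                      n=(len(x),))


def kruskal_wallis(groups) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with chi-square p and epsilon-squared."""
    groups = [_clean(g) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    N = sum(len(g) for g in groups)
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        warnings.warn("all observations identical: H defined as 0")
        return TestResult(test="kruskal_wallis", statistic_name="H", statistic=0.0,
                          p_value=1.0, effect_size_name="epsilon2", effect_size=0.0,
                          n=tuple(len(g) for g in groups), df=len(groups) - 1,
                          note="degenerate: zero variance")
    H, p = stats.kruskal(*groups)
    eps2 = float(H / ((N**2 - 1) / (N + 1)))
    return TestResult(test="kruskal_wallis", statistic_name="H", statistic=float(H),
                      p_value=float(p), effect_size_name="epsilon2",
                      effect_size=eps2, n=tuple(len(g) for g in groups),
                      df=len(groups) - 1)


def wilcoxon_rank_sum(a, b, continuity: bool = True,
                      exact_limit: int = 400) -> TestResult:
    """Wilcoxon rank-sum with W = Mann-Whitney U of the first sample.

    Exact enumeration when both samples are tie-free and
    ``n_a * n_b <= exact_limit``; otherwise the tie-corrected normal
    approximation (continuity correction switchable).  Rank-biserial effect
    size r = 1 - 2W/(n_a n_b).
    """
    a, b = _clean(a), _clean(b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (not has_ties and len(a) * len(b) <= exact_limit) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=continuity)
    W = float(res.statistic)
    r = 1.0 - 2.0 * W / (len(a) * len(b))
    return TestResult(test="wilcoxon_rank_sum", statistic_name="W", statistic=W,
                      p_value=float(res.pvalue), effect_size_name="rank_biserial",
                      effect_size=r, n=(len(a), len(b)), note=f"p: {method}")


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-D vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pairwise_wilcoxon(groups, labels=None, continuity: bool = True) -> list[TestResult]:
    """All unordered pairwise rank-sum tests with BH adjustment over the
    family of pairs."""
    groups = list(groups)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    labels = labels or [f"group{i + 1}" for i in range(len(groups))]
    results = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        r = wilcoxon_rank_sum(groups[i], groups[j], continuity=continuity)
        r.test = f"wilcoxon[{labels[i]} vs {labels[j]}]"
        results.append(r)
    adj = bh_adjust([r.p_value for r in results])
    for r, pa in zip(results, adj):
        r.p_adjusted = float(pa)
        r.adjust_method = "BH"
    return results


def kendall_matrix(table: pd.DataFrame, variables: list[str],
                   alpha: float = 0.05):
    """Kendall tau-b correlation matrix with BH-adjusted p over the upper
    triangle, pairwise-complete observations.

    Returns ``(tau, p_adj, significant)`` DataFrames.  Zero-variance
    variables are excluded with a warning.
    """
    if len(variables) < 2:
        raise ValueError("need >= 2 variables")
    keep = []
    for v in variables:
        vals = _clean(table[v])
        if len(vals) < 3 or np.ptp(vals) == 0:
            warnings.warn(f"excluding zero-variance or empty variable {v!r}")
        else:
            keep.append(v)
    k = len(keep)
    tau = np.eye(k)
    praw = np.full((k, k), np.nan)
    for i, j in itertools.combinations(range(k), 2):
        sub = table[[keep[i], keep[j]]].apply(pd.to_numeric, errors="coerce").dropna()
        res = stats.kendalltau(sub.iloc[:, 0], sub.iloc[:, 1], variant="b",
                               method="asymptotic")
        tau[i, j] = tau[j, i] = float(res.statistic)
        praw[i, j] = praw[j, i] = float(res.pvalue)
    iu = np.triu_indices(k, 1)
    padj = np.full((k, k), np.nan)
    if iu[0].size:
        adj = bh_adjust(praw[iu])
        padj[iu] = adj
        padj[(iu[1], iu[0])] = adj
    tau_df = pd.DataFrame(tau, index=keep, columns=keep)
    p_df = pd.DataFrame(padj, index=keep, columns=keep)
    sig = p_df < alpha
    np.fill_diagonal(sig.values, False)
    return tau_df, p_df, sig


# ---------------------------------------------------------------------------
# the study's manipulation-check battery
# ---------------------------------------------------------------------------

#: variables screened in the registration/experience correlation analysis
CORRELATION_VARIABLES = ["agency_self", "agency_shared", "social_presence",
                         "physical_presence", "conn_artist", "conn_audience",
                         "covid_loneliness", "covid_lack_companionship",
                         "covid_isolation", "covid_worry_self", "covid_worry_others",
                         "emo_loneliness", "emo_lack_companionship",
                         "emo_isolation", "emo_anxiety", "forget_covid",
                         "empathic_concern", "age_years"]


def manipulation_checks(table, concert: int, subscale_columns=None) -> list[TestResult]:
    """Run the concert's manipulation-check battery on a response table.

    Concert 1: Kendall tests of voting ability (and preference played)
    against self/shared agency.  Concert 2: Kruskal-Wallis across the three
    viewing groups on presence scales and subscales, with BH-adjusted
    pairwise rank-sum comparisons.  Concert 3: rank-sum tests Zoom vs
    YouTube on the presence scale and its subscales.
    """
    from .data_model import (DEFAULT_IPQ_MAPPING, DEFAULT_MPS_MAPPING, IPQ_ITEMS,
                             MPS_ITEMS, ResponseTable, _subscale_frame)
    df = table.df if isinstance(table, ResponseTable) else table
    df = df[df["concert"] == concert].reset_index(drop=True)
    mps = _subscale_frame(df, MPS_ITEMS, DEFAULT_MPS_MAPPING, "mps")
    mps["mps_mean"] = df[MPS_ITEMS].mean(axis=1, skipna=False)
    out: list[TestResult] = []
    if concert == 1:
        voted = (df["condition"] == "voted").astype(float)
        pref = pd.to_numeric(df["preference_played"], errors="coerce")
        for pred_name, pred in (("allowed_vote", voted), ("preference_played", pref)):
            for outcome in ("agency_self", "agency_shared"):
                sub = pd.DataFrame({"x": pred, "y": df[outcome]}).dropna()
                r = kendall_tau_test(sub["x"], sub["y"])
                r.test = f"kendall[{pred_name} vs {outcome}]"
                out.append(r)
    elif concert == 2:
        ipq = _subscale_frame(df, IPQ_ITEMS, DEFAULT_IPQ_MAPPING, "ipq")
        ipq["ipq_mean"] = df[IPQ_ITEMS].mean(axis=1, skipna=False)
        scores = pd.concat([mps, ipq], axis=1)
        order = ["youtube", "youtube360", "vr"]
        for col in ["mps_mean", "mps_social", "mps_physical",
                    "ipq_mean", "ipq_spatial", "ipq_involvement", "ipq_realism"]:
            groups = [scores.loc[df["condition"] == g, col] for g in order]
            kw = kruskal_wallis(groups)
            kw.test = f"kruskal_wallis[{col}]"
            out.append(kw)
            out.extend(pairwise_wilcoxon(groups, labels=order))
            for r in out[-3:]:
                r.test = f"{col} {r.test}"
    elif concert == 3:
        for col in ["mps_mean", "mps_social", "mps_physical"]:
            a = mps.loc[df["condition"] == "zoom", col]
            b = mps.loc[df["condition"] == "youtube", col]
            r = wilcoxon_rank_sum(a, b)
            r.test = f"wilcoxon[{col}: zoom vs youtube]"
            out.append(r)
    else:
        raise ValueError("concert must be 1, 2 or 3")
    return out


def correlation_screen(table, variables=None, alpha: float = 0.05):
    """The registration/experience Kendall screen across all concerts."""
    from .data_model import (DEFAULT_MPS_MAPPING, MPS_ITEMS, ResponseTable,
                             _subscale_frame)
    df = (table.df if isinstance(table, ResponseTable) else table).copy()
    mps = _subscale_frame(df, MPS_ITEMS, DEFAULT_MPS_MAPPING, "mps")
    df["social_presence"] = mps["mps_social"]
    df["physical_presence"] = mps["mps_physical"]
    variables = variables or [v for v in CORRELATION_VARIABLES if v in df.columns]
    return kendall_matrix(df, variables, alpha=alpha)
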