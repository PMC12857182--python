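"""Statistical layer: ANOVA, Tukey HSD, chi-squared, regression,
Bonferroni t-tests, weighted clone means and 2^-ddCT fold changes.

One-way ANOVA and Tukey HSD are computed from first principles (sums of
squares and the studentized-range distribution); two-way ANOVA delegates
to statsmodels with type-II sums of squares; the remaining tests wrap
scipy.stats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "AnovaResult",
    "PairwiseResult",
    "QpcrRecord",
    "one_way_anova",
    "tukey_hsd",
    "two_way_anova",
    "chi_squared_contingency",
    "linear_fit",
    "t_test_bonferroni",
    "weighted_clone_mean",
    "delta_delta_ct",
]


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    mean_diff: float
    p_adjusted: float
    reject: bool


@dataclass
class QpcrRecord:
    sample: str
    group: str
    ct_target: float
    ct_reference: float


def _as_groups(table) -> dict:
    """Accept a {label: values} mapping or a long DataFrame with
    'condition'/'value' columns."""
    if isinstance(table, pd.DataFrame):
        return {
            str(cond): sub["value"].to_numpy(dtype=float)
            for cond, sub in table.groupby("condition", sort=True)
        }
    return {str(k): np.asarray(v, dtype=float) for k, v in table.items()}


def one_way_anova(table) -> AnovaResult:
    """Classical one-way ANOVA from the sum-of-squares decomposition."""
    groups = _as_groups(table)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    values = list(groups.values())
    n_total = sum(len(v) for v in values)
    k = len(values)
    df_between = k - 1
    df_within = n_total - k
    if df_within < 1:
        raise ValueError("insufficient residual degrees of freedom")
    grand = np.concatenate(values).mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in values)
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in values)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        # identical groups give F = 0; distinct means with zero noise diverge
        F = 0.0 if ms_between == 0 else float("inf")
    else:
        F = float(ms_between / ms_within)
    p = float(sps.f.sf(F, df_between, df_within)) if np.isfinite(F) else 0.0
    return AnovaResult(F=F, df_between=df_between, df_within=df_within, p=p)


def tukey_hsd(table, alpha: float = 0.05) -> list[PairwiseResult]:
    """All-pairs comparisons via the studentized-range distribution
    (Tukey-Kramer standard errors for unequal group sizes)."""
    groups = _as_groups(table)
    anova = one_way_anova(groups)
    names = sorted(groups)
    values = [groups[n] for n in names]
    ms_within = sum(((v - v.mean()) ** 2).sum() for v in values) / anova.df_within
    k = len(names)
    out: list[PairwiseResult] = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = values[i], values[j]
            diff = float(a.mean() - b.mean())
            se = np.sqrt(ms_within / 2 * (1 / len(a) + 1 / len(b)))
            if se == 0:
                p_adj = 1.0 if diff == 0 else 0.0
            else:
                q = abs(diff) / se
                p_adj = float(sps.studentized_range.sf(q, k, anova.df_within))
                p_adj = min(1.0, max(0.0, p_adj))
            out.append(
                PairwiseResult(
                    group_a=names[i],
                    group_b=names[j],
                    mean_diff=diff,
                    p_adjusted=p_adj,
                    reject=p_adj < alpha,
                )
            )
    return out


def two_way_anova(table: pd.DataFrame, factors: tuple[str, str] = ("condition", "factor2")) -> dict:
    """Two-way ANOVA with interaction, type-II sums of squares.

    Returns ``{term: (F, p)}`` for both main effects and the interaction.
    Every design cell must be nonempty.
    """
    fa, fb = factors
    counts = table.groupby([fa, fb], sort=True).size()
    levels_a = table[fa].unique()
    levels_b = table[fb].unique()
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError("both factors need >= 2 levels")
    for la in levels_a:
        for lb in levels_b:
            if (la, lb) not in counts.index:
                raise ValueError(f"empty design cell ({la!r}, {lb!r})")
    data = table.rename(columns={fa: "_fa", fb: "_fb"})
    model = smf.ols("value ~ C(_fa) * C(_fb)", data=data).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    key_map = {
        "C(_fa)": fa,
        "C(_fb)": fb,
        "C(_fa):C(_fb)": f"{fa}:{fb}",
    }
    return {
        key_map[idx]: (float(row["F"]), float(row["PR(>F)"]))
        for idx, row in anova.iterrows()
        if idx in key_map
    }


def chi_squared_contingency(table, yates: bool = True) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence.

    Yates continuity correction applies to 2x2 tables when enabled.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (arr < 0).any() or arr.sum() == 0:
        raise ValueError("counts must be nonnegative with positive total")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    res = sps.chi2_contingency(arr, correction=yates)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def linear_fit(x, y) -> tuple[float, float, float, float]:
    """Least-squares line: (slope, intercept, Pearson r, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x must not be constant")
    if np.ptp(y) == 0:  # flat response: r defined as 0 rather than NaN
        return 0.0, float(y[0]), 0.0, 1.0
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue), float(res.pvalue)


def t_test_bonferroni(pairs, m: int) -> list[tuple[float, float, float]]:
    """Pooled-variance two-sample t-tests with Bonferroni adjustment.

    ``pairs`` is a list of (treatment values, control values); ``m`` is
    the total number of comparisons in the family. Returns
    ``(t, raw p, adjusted p)`` per pair with adjusted p = min(1, m * p).
    """
    if m < len(pairs):
        raise ValueError("m must be >= number of comparisons")
    out = []
    for treated, control in pairs:
        a = np.asarray(treated, dtype=float)
        b = np.asarray(control, dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError("each group needs >= 2 values")
        res = sps.ttest_ind(a, b, equal_var=True)
        t, p = float(res.statistic), float(res.pvalue)
        if np.isnan(t):  # zero pooled variance with equal means
            t, p = 0.0, 1.0
        out.append((t, p, min(1.0, m * p)))
    return out


def weighted_clone_mean(values, weights) -> float:
    """Weighted average (e.g. per-clone mean weighted by cells measured)."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0 or values.size != weights.size:
        raise ValueError("values and weights must be nonempty and equal length")
    if (weights <= 0).any():
        raise ValueError("weights must be positive")
    return float(np.average(values, weights=weights))


def delta_delta_ct(records: list[QpcrRecord], control_group: str) -> dict[str, float]:
    """Per-sample fold change by the 2^-ddCT method.

    dCT = ct_target - ct_reference per sample; ddCT subtracts the mean
    control dCT; fold = 2^-ddCT.
    """
    control = [r for r in records if r.group == control_group]
    if not control:
        raise ValueError(f"no samples in control group {control_group!r}")
    control_mean = float(np.mean([r.ct_target - r.ct_reference for r in control]))
    folds = {}
    for r in records:
        ddct = (r.ct_target - r.ct_reference) - control_mean
        folds[r.sample] = float(2.0 ** (-ddct))
    return folds
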