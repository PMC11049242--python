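"""Group-comparison statistics.

Test selection follows the common practice for larva-level metrics:
Shapiro–Wilk normality on each group; when both pass, Student's unpaired
t-test (with Welch's correction when Levene's test rejects equal
variances), otherwise the Mann–Whitney U test. Factorial designs get a
two-way ANOVA with a Tukey HSD post-hoc table. All tests are delegated to
scipy.stats / statsmodels; this module owns only the selection logic and
the tidy result container.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class GroupComparison:
    metric: str
    group_labels: list[str]
    group_n: list[int]
    group_mean: list[float]
    group_sem: list[float]
    test_name: str
    statistic: float
    p_value: float
    posthoc: pd.DataFrame | None = None
    anova: pd.DataFrame | None = None

    def as_row(self) -> dict:
        row = {"metric": self.metric, "test": self.test_name,
               "statistic": self.statistic, "p_value": self.p_value}
        for lbl, n, m, s in zip(self.group_labels, self.group_n, self.group_mean, self.group_sem):
            row[f"n_{lbl}"] = n
            row[f"mean_{lbl}"] = m
            row[f"sem_{lbl}"] = s
        return row


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0


def compare_two_groups(
    values_a,
    values_b,
    normality_alpha: float = 0.05,
    variance_alpha: float = 0.05,
    metric: str = "metric",
    labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Auto-selected two-group test (t, Welch t, or Mann–Whitney)."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 values per group")

    if np.ptp(np.concatenate([a, b])) == 0:
        test, stat, p = "degenerate (all values equal)", 0.0, 1.0
    else:
        def _normal(x: np.ndarray) -> bool:
            if np.ptp(x) == 0:
                return False  # constant group: normality undecidable, be robust
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return sps.shapiro(x).pvalue > normality_alpha

        if _normal(a) and _normal(b):
            equal_var = sps.levene(a, b).pvalue > variance_alpha
            res = sps.ttest_ind(a, b, equal_var=equal_var)
            test = "t-test" if equal_var else "Welch t-test"
        else:
            res = sps.mannwhitneyu(a, b, alternative="two-sided")
            test = "Mann-Whitney U"
        stat, p = float(res.statistic), float(res.pvalue)

    return GroupComparison(
        metric=metric,
        group_labels=list(labels),
        group_n=[a.size, b.size],
        group_mean=[float(a.mean()), float(b.mean())],
        group_sem=[_sem(a), _sem(b)],
        test_name=test,
        statistic=stat,
        p_value=p,
    )


def compare_factorial(
    table: pd.DataFrame,
    value: str = "value",
    factor_a: str = "genotype",
    factor_b: str = "microglia",
    metric: str | None = None,
) -> GroupComparison:
    """Two-way ANOVA with interaction plus a Tukey HSD pairwise table.

    ``table`` holds one row per larva with the metric column and two
    categorical factor columns; every design cell must be populated with
    at least 3 values.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    for col in (value, factor_a, factor_b):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    cells = table.groupby([factor_a, factor_b], observed=True)[value].count()
    levels_a = table[factor_a].nunique()
    levels_b = table[factor_b].nunique()
    if levels_a < 2 or levels_b < 2:
        raise ValueError("need ≥ 2 levels per factor")
    if len(cells) < levels_a * levels_b or (cells < 3).any():
        raise ValueError("every design cell needs at least 3 values")

    df = table.rename(columns={value: "_y", factor_a: "_fa", factor_b: "_fb"})
    model = ols("_y ~ C(_fa) * C(_fb)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)

    combined = (table[factor_a].astype(str) + ":" + table[factor_b].astype(str)).to_numpy()
    if np.ptp(table[value].to_numpy()) == 0:
        posthoc = None
        p_inter = 1.0
        f_inter = 0.0
    else:
        tk = pairwise_tukeyhsd(table[value].to_numpy(), combined)
        posthoc = pd.DataFrame(
            tk.summary().data[1:], columns=tk.summary().data[0]
        )
        p_inter = float(anova.loc["C(_fa):C(_fb)", "PR(>F)"])
        f_inter = float(anova.loc["C(_fa):C(_fb)", "F"])

    groups = table.groupby([factor_a, factor_b], observed=True)[value]
    labels = [f"{a}:{b}" for (a, b) in groups.groups]
    return GroupComparison(
        metric=metric or value,
        group_labels=labels,
        group_n=[int(g.size) for _, g in groups],
        group_mean=[float(g.mean()) for _, g in groups],
        group_sem=[_sem(g.to_numpy()) for _, g in groups],
        test_name="two-way ANOVA + Tukey",
        statistic=f_inter,
        p_value=p_inter,
        posthoc=posthoc,
        anova=anova.rename(index={"C(_fa)": factor_a, "C(_fb)": factor_b,
                                  "C(_fa):C(_fb)": f"{factor_a}:{factor_b}"}),
    )
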