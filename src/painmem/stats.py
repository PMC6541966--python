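"""Repeated-measures ANOVA from explicit sums of squares.

Two designs are implemented directly from their variance decompositions:

* One-way repeated measures (every subject observed in every condition):
  ``F = MS_condition / MS_(condition x subject)`` with df ``(k-1)`` and
  ``(k-1)(n-1)``. With two conditions this F equals the squared paired-t
  statistic.
* Two-way mixed design (group between subjects, time within): the
  between-subject error is subjects-within-groups, the within-subject
  error is time x subjects-within-groups, giving the three classical F
  tests for group, time, and group x time.

No sphericity correction is applied by default; a Greenhouse-Geisser
epsilon adjustment of the within-subject df is available behind
``correction="gg"``. Post hoc contrasts are Bonferroni-adjusted
(``p_adj = min(1, m * p)``) and flagged significant at strict ``p < alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "PosthocContrast",
    "DesignError",
    "rm_anova_oneway",
    "rm_anova_mixed",
    "bonferroni",
    "significance_report",
]


class DesignError(ValueError):
    """The supplied table violates the design's completeness requirements."""


@dataclass(frozen=True)
class PosthocContrast:
    contrast: str
    mean_diff: float
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df_num: float
    df_den: float
    p: float
    posthoc: tuple[PosthocContrast, ...] = field(default_factory=tuple)

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p < alpha


def bonferroni(p_values, m: int) -> np.ndarray:
    """Bonferroni-adjusted p-values: ``min(1, m * p)`` elementwise."""
    p = np.asarray(p_values, dtype=float)
    if m < 1:
        raise ValueError(f"number of comparisons m must be >= 1, got {m}")
    if m < p.size:
        raise ValueError(f"m = {m} smaller than the {p.size} comparisons supplied")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, m * p)


def _pivot_complete(
    table: pd.DataFrame, index: str, columns: str, value: str
) -> pd.DataFrame:
    wide = table.pivot_table(
        index=index, columns=columns, values=value, aggfunc="mean", sort=False
    )
    if wide.isna().any().any():
        missing = [
            f"({idx}, {col})"
            for idx in wide.index
            for col in wide.columns
            if pd.isna(wide.loc[idx, col])
        ]
        raise DesignError(f"incomplete design; missing cells: {', '.join(missing)}")
    return wide


def _gg_epsilon(wide: np.ndarray) -> float:
    # Greenhouse-Geisser epsilon from the double-centered covariance of the
    # condition columns; 1/(k-1) <= epsilon <= 1.
    k = wide.shape[1]
    if k < 3:
        return 1.0
    cov = np.cov(wide, rowvar=False)
    dc = (
        cov
        - cov.mean(axis=0, keepdims=True)
        - cov.mean(axis=1, keepdims=True)
        + cov.mean()
    )
    eps = np.trace(dc) ** 2 / ((k - 1) * np.sum(dc**2))
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def rm_anova_oneway(
    table: pd.DataFrame,
    subject: str = "subject",
    condition: str = "condition",
    value: str = "value",
    correction: str = "none",
) -> AnovaResult:
    """One-way repeated-measures ANOVA on a long-format complete table.

    Post hoc: all pairwise paired t-tests between conditions, Bonferroni
    over the number of pairs.
    """
    wide = _pivot_complete(table, subject, condition, value)
    n, k = wide.shape
    if n < 2 or k < 2:
        raise DesignError(f"need >= 2 subjects and >= 2 conditions, got {n} x {k}")
    x = wide.to_numpy(float)
    grand = x.mean()
    ss_cond = n * float(((x.mean(axis=0) - grand) ** 2).sum())
    ss_subj = k * float(((x.mean(axis=1) - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_err = ss_total - ss_cond - ss_subj
    df_num, df_den = float(k - 1), float((k - 1) * (n - 1))
    ms_err = ss_err / df_den
    f_stat = (ss_cond / df_num) / ms_err if ms_err > 0 else (
        0.0 if ss_cond == 0 else np.inf
    )
    if correction == "gg":
        eps = _gg_epsilon(x)
        df_num, df_den = df_num * eps, df_den * eps
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    p = float(sps.f.sf(f_stat, df_num, df_den))

    pairs = list(combinations(wide.columns, 2))
    raws, diffs = [], []
    for a, b in pairs:
        diff = x[:, wide.columns.get_loc(a)] - x[:, wide.columns.get_loc(b)]
        t_res = sps.ttest_rel(
            x[:, wide.columns.get_loc(a)], x[:, wide.columns.get_loc(b)]
        )
        raws.append(float(t_res.pvalue))
        diffs.append(float(diff.mean()))
    adjusted = bonferroni(raws, len(pairs)) if pairs else np.array([])
    posthoc = tuple(
        PosthocContrast(f"{a} vs {b}", d, r, float(adj))
        for (a, b), d, r, adj in zip(pairs, diffs, raws, adjusted)
    )
    return AnovaResult("condition", float(f_stat), df_num, df_den, p, posthoc)


def rm_anova_mixed(
    table: pd.DataFrame,
    subject: str = "subject",
    group: str = "group",
    time: str = "timepoint",
    value: str = "value",
    correction: str = "none",
) -> list[AnovaResult]:
    """Two-way mixed-design ANOVA (group between, time within).

    Returns results for the three effects (group, time, group x time).
    Post hoc (attached to the interaction): pairwise group differences at
    each timepoint, tested against the pooled error term, with Bonferroni
    m = number of contrasts performed.
    """
    grp_of = table.groupby(subject)[group].nunique()
    if (grp_of > 1).any():
        bad = grp_of[grp_of > 1].index[0]
        raise DesignError(f"subject {bad!r} appears in more than one group")

    wide = _pivot_complete(table, subject, time, value)
    subject_group = table.groupby(subject)[group].first().loc[wide.index]
    groups = list(dict.fromkeys(table[group]))
    times = list(wide.columns)
    x = wide.to_numpy(float)
    n_total, k = x.shape
    g = len(groups)
    if g < 2 or k < 2:
        raise DesignError(f"need >= 2 groups and >= 2 timepoints, got {g} x {k}")

    grand = x.mean()
    subj_means = x.mean(axis=1)
    time_means = x.mean(axis=0)
    group_sizes = {gr: int((subject_group == gr).sum()) for gr in groups}

    ss_between = k * float(((subj_means - grand) ** 2).sum())
    ss_group = k * sum(
        group_sizes[gr] * (subj_means[(subject_group == gr).to_numpy()].mean() - grand) ** 2
        for gr in groups
    )
    ss_subj_within = ss_between - ss_group

    ss_time = n_total * float(((time_means - grand) ** 2).sum())
    ss_cells = sum(
        group_sizes[gr]
        * float(((x[(subject_group == gr).to_numpy()].mean(axis=0) - grand) ** 2).sum())
        for gr in groups
    )
    ss_int = ss_cells - ss_group - ss_time
    ss_total = float(((x - grand) ** 2).sum())
    ss_err_within = ss_total - ss_between - ss_time - ss_int

    df_group, df_sw = float(g - 1), float(n_total - g)
    df_time, df_int = float(k - 1), float((g - 1) * (k - 1))
    df_ew = float((n_total - g) * (k - 1))
    ms_sw, ms_ew = ss_subj_within / df_sw, ss_err_within / df_ew

    eps = 1.0
    if correction == "gg":
        eps = _gg_epsilon(x)
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")

    def f_of(ss: float, df_n: float, ms_e: float, df_e: float) -> tuple[float, float]:
        f_stat = (ss / df_n) / ms_e if ms_e > 0 else (0.0 if ss == 0 else np.inf)
        return f_stat, float(sps.f.sf(f_stat, df_n, df_e))

    f_group, p_group = f_of(ss_group, df_group, ms_sw, df_sw)
    f_time, _ = f_of(ss_time, df_time, ms_ew, df_ew)
    p_time = float(sps.f.sf(f_time, df_time * eps, df_ew * eps))
    f_int, _ = f_of(ss_int, df_int, ms_ew, df_ew)
    p_int = float(sps.f.sf(f_int, df_int * eps, df_ew * eps))

    # Pairwise group contrasts per timepoint against the pooled error term.
    ms_pooled = (ss_subj_within + ss_err_within) / (df_sw + df_ew)
    df_pooled = df_sw + df_ew
    contrasts, raws, diffs = [], [], []
    for t_label in times:
        col = x[:, times.index(t_label)]
        for a, b in combinations(groups, 2):
            mask_a = (subject_group == a).to_numpy()
            mask_b = (subject_group == b).to_numpy()
            diff = float(col[mask_a].mean() - col[mask_b].mean())
            se = np.sqrt(ms_pooled * (1 / group_sizes[a] + 1 / group_sizes[b]))
            t_stat = diff / se if se > 0 else 0.0
            raws.append(2 * float(sps.t.sf(abs(t_stat), df_pooled)))
            diffs.append(diff)
            contrasts.append(f"{a} vs {b} @ {t_label}")
    adjusted = bonferroni(raws, len(raws)) if raws else np.array([])
    posthoc = tuple(
        PosthocContrast(c, d, r, float(adj))
        for c, d, r, adj in zip(contrasts, diffs, raws, adjusted)
    )

    return [
        AnovaResult("group", f_group, df_group, df_sw, p_group),
        AnovaResult("time", f_time, df_time * eps, df_ew * eps, p_time),
        AnovaResult("group x time", f_int, df_int * eps, df_ew * eps, p_int, posthoc),
    ]


def significance_report(
    results: list[AnovaResult], alpha: float = 0.05
) -> pd.DataFrame:
    """Tabulate effects and post hoc contrasts flagged at strict p < alpha."""
    rows = []
    for res in results:
        rows.append(
            ("effect", res.effect, res.F, res.df_num, res.df_den, res.p,
             res.p < alpha)
        )
        for ph in res.posthoc:
            rows.append(
                ("posthoc", f"{res.effect}: {ph.contrast}", np.nan, np.nan,
                 np.nan, ph.p_adjusted, ph.p_adjusted < alpha)
            )
    return pd.DataFrame(
        rows, columns=["kind", "name", "F", "df_num", "df_den", "p", "significant"]
    )
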