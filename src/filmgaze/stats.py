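"""Comprehension-measure statistics.

Pearson chi-square on labelled frequency tables with a small-cell guard,
Cohen's kappa for coder agreement, a classic split-plot (mixed
between x within) ANOVA with partial eta-squared, and Bonferroni-corrected
pairwise t-tests with Cohen's d.

The chi-square is the uncorrected Pearson statistic (no Yates continuity
correction) by default; the guard refuses tables with any *observed* cell at
or below a threshold (default 5), reporting them as not computable instead of
producing a fragile statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score

__all__ = [
    "ContingencyTable",
    "StatResult",
    "GuardResult",
    "NotComputableError",
    "pearson_chi2",
    "cell_count_guard",
    "cohen_kappa",
    "mixed_anova",
    "posthoc_pairwise",
    "cohens_d",
]


class NotComputableError(ValueError):
    """A statistic was refused (e.g. small-cell guard) rather than computed."""


@dataclass
class ContingencyTable:
    """An r x c table of non-negative counts with row/column labels."""

    counts: np.ndarray
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] < 2 or c.shape[1] < 2:
            raise ValueError("contingency table must be at least 2 x 2")
        if (c < 0).any() or not np.issubdtype(c.dtype, np.number):
            raise ValueError("counts must be non-negative numbers")
        self.counts = c.astype(np.int64)
        if not self.row_labels:
            self.row_labels = [f"row{i+1}" for i in range(c.shape[0])]
        if not self.col_labels:
            self.col_labels = [f"col{j+1}" for j in range(c.shape[1])]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)


@dataclass
class StatResult:
    """A test statistic with df, p value and (optionally) an effect size."""

    effect_label: str
    statistic: float
    df: int | tuple[int, int]
    p_value: float
    effect_size: float | None = None
    effect_name: str = ""
    note: str = ""


@dataclass
class GuardResult:
    passed: bool
    reason: str = ""

    def __bool__(self) -> bool:
        return self.passed


def cell_count_guard(t: ContingencyTable, threshold: int = 5) -> GuardResult:
    """Refuse tables with any observed cell count at or below ``threshold``.

    Sparse observed cells make the chi-square approximation unreliable; such
    tables are reported as not computable rather than tested.
    """
    small = np.argwhere(t.counts <= threshold)
    if len(small):
        i, j = small[0]
        return GuardResult(
            False,
            f"cell ({t.row_labels[i]!r}, {t.col_labels[j]!r}) has "
            f"{t.counts[i, j]} <= {threshold} observations",
        )
    return GuardResult(True)


def pearson_chi2(
    t: ContingencyTable,
    correction: bool = False,
    guard_threshold: int | None = None,
) -> StatResult:
    """Pearson chi-square test of independence on a contingency table.

    No continuity correction by default.  When ``guard_threshold`` is given,
    the small-cell guard is applied first and failing tables raise
    :class:`NotComputableError`.
    """
    if guard_threshold is not None:
        guard = cell_count_guard(t, guard_threshold)
        if not guard:
            raise NotComputableError(f"chi-square not computable: {guard.reason}")
    if (t.counts.sum(axis=0) == 0).any() or (t.counts.sum(axis=1) == 0).any():
        raise ValueError("zero row/column margin: expected counts undefined")
    res = sps.chi2_contingency(t.counts, correction=correction)
    return StatResult(
        effect_label="independence",
        statistic=float(res.statistic),
        df=int(res.dof),
        p_value=float(res.pvalue),
    )


def cohen_kappa(codes_a: Sequence, codes_b: Sequence) -> float:
    """Cohen's kappa: chance-corrected agreement between two categorical coders.

    kappa = (p_o - p_e) / (1 - p_e), with chance agreement p_e from the
    coders' marginal label frequencies.  When both coders are constant and
    identical (p_e = 1) agreement is perfect by convention and 1.0 is
    returned with a warning.
    """
    a = np.asarray(codes_a)
    b = np.asarray(codes_b)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 1:
        raise ValueError("coders must supply equal-length non-empty vectors")
    if len(np.unique(a)) == 1 and np.array_equal(a, b):
        warnings.warn(
            "both coders constant and identical (chance agreement = 1); "
            "kappa defined as 1 by convention",
            stacklevel=2,
        )
        return 1.0
    return float(cohen_kappa_score(a, b))


# ---------------------------------------------------------------------------
# mixed (split-plot) ANOVA


def mixed_anova(
    data: pd.DataFrame,
    dv: str = "value",
    between: str = "group",
    within: str = "shot",
    subject: str = "participant",
) -> pd.DataFrame:
    """Mixed group x repeated-measure ANOVA (classic split-plot SS partition).

    Requires a complete within design: every subject observed exactly once at
    every level of ``within``, each subject in exactly one group.  Group sizes
    may differ.  Sums of squares follow the sequential (group, subjects within
    groups, within-factor, interaction, residual) partition, which is exactly
    additive for this design; effect sizes are partial eta-squared
    SS_effect / (SS_effect + SS_error), with the subjects-within-groups error
    for the between effect and the subject x within residual otherwise.

    Returns a DataFrame with one row per effect (between, within,
    interaction) and columns ``effect, ss, df1, df2, ms, F, p, partial_eta_sq,
    note``; the full partition (including subject and residual SS) is in
    ``result.attrs["ss_partition"]``.  Degenerate data (zero total variance)
    yields NaN F values with a note; a zero error term under a non-zero
    effect yields an infinite F sentinel.
    """
    df = data[[subject, between, within, dv]].copy()
    if df[dv].isna().any():
        raise ValueError("missing values in the dependent variable (no imputation)")
    levels_w = sorted(df[within].unique())
    b = len(levels_w)
    groups_of = df.groupby(subject)[between].nunique()
    if (groups_of > 1).any():
        raise ValueError("each subject must belong to exactly one group")
    counts = df.groupby([subject, within]).size()
    if (counts != 1).any() or df.groupby(subject)[within].nunique().ne(b).any():
        raise ValueError(
            "unbalanced within-factor: every subject must be observed exactly "
            "once at every within level (no imputation)"
        )
    g_levels = sorted(df[between].unique())
    a = len(g_levels)
    if a < 2:
        raise ValueError("need at least 2 groups")

    # cube y[i][j, k]: group i, subject j, within level k
    wide = df.pivot_table(index=[between, subject], columns=within, values=dv)
    wide = wide.reindex(columns=levels_w)
    y_by_group = [wide.loc[g].to_numpy() for g in g_levels]
    n_i = np.array([y.shape[0] for y in y_by_group])
    N = int(n_i.sum())

    gm = float(np.concatenate(y_by_group).mean())
    subj_means = [y.mean(axis=1) for y in y_by_group]
    grp_means = np.array([y.mean() for y in y_by_group])
    # within-level means weighted by observed subjects (sequential/Type I)
    col_means = np.vstack([y.mean(axis=0) for y in y_by_group])  # (a, b) cell means
    w_means = (n_i[:, None] * col_means).sum(axis=0) / N

    ss_total = float(sum(((y - gm) ** 2).sum() for y in y_by_group))
    ss_group = float(b * (n_i * (grp_means - gm) ** 2).sum())
    ss_subj = float(b * sum(((sm - m) ** 2).sum() for sm, m in zip(subj_means, grp_means)))
    ss_within = float(N * ((w_means - gm) ** 2).sum())
    inter_dev = col_means - grp_means[:, None] - w_means[None, :] + gm
    ss_inter = float((n_i[:, None] * inter_dev**2).sum())
    ss_error = float(
        sum(
            ((y - cm[None, :] - sm[:, None] + m) ** 2).sum()
            for y, cm, sm, m in zip(y_by_group, col_means, subj_means, grp_means)
        )
    )

    df_group, df_subj = a - 1, N - a
    df_w, df_inter = b - 1, (a - 1) * (b - 1)
    df_err = (N - a) * (b - 1)

    degenerate = ss_total <= 1e-12 * max(1.0, gm**2) * N * b

    def _row(label, ss_eff, df_eff, ss_err, df_err_):
        note = ""
        if degenerate:
            return (label, ss_eff, df_eff, df_err_, np.nan, np.nan, np.nan, np.nan,
                    "degenerate: zero total variance")
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err_
        if ms_err == 0.0:
            f = np.inf if ms_eff > 0 else np.nan
            p = 0.0 if ms_eff > 0 else np.nan
            note = "zero error variance"
        else:
            f = ms_eff / ms_err
            p = float(sps.f.sf(f, df_eff, df_err_))
        pes = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else np.nan
        return (label, ss_eff, df_eff, df_err_, ms_eff, f, p, pes, note)

    rows = [
        _row(between, ss_group, df_group, ss_subj, df_subj),
        _row(within, ss_within, df_w, ss_error, df_err),
        _row(f"{between} x {within}", ss_inter, df_inter, ss_error, df_err),
    ]
    out = pd.DataFrame(
        rows, columns=["effect", "ss", "df1", "df2", "ms", "F", "p", "partial_eta_sq", "note"]
    )
    out.attrs["ss_partition"] = {
        "ss_between_groups": ss_group,
        "ss_subjects_within_groups": ss_subj,
        "ss_within_factor": ss_within,
        "ss_interaction": ss_inter,
        "ss_error": ss_error,
        "ss_total": ss_total,
        "df": {
            "between": df_group,
            "subjects": df_subj,
            "within": df_w,
            "interaction": df_inter,
            "error": df_err,
        },
    }
    out.attrs["degenerate"] = bool(degenerate)
    return out


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d with pooled SD: (mean_x - mean_y) / s_pooled."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 == 0.0:
        return 0.0 if x.mean() == y.mean() else np.inf * np.sign(x.mean() - y.mean())
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


def posthoc_pairwise(
    data: pd.DataFrame,
    dv: str = "value",
    between: str = "group",
    stratify: str | None = None,
    correction: str = "bonferroni",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Pairwise two-sample t-tests between groups with Bonferroni correction.

    Pooled-variance t by default (``equal_var=False`` gives Welch).  When
    ``stratify`` names a column, tests are run within each stratum; the
    Bonferroni family is all comparisons performed: p_adj = min(1, p * m).
    Cohen's d (pooled SD) accompanies each test.  Comparisons in which a
    group has fewer than 2 observations are reported with a reason and no
    statistic.
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    strata = [None] if stratify is None else sorted(data[stratify].unique())
    groups = sorted(data[between].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for stratum in strata:
        d = data if stratum is None else data[data[stratify] == stratum]
        for i, g1 in enumerate(groups):
            for g2 in groups[i + 1 :]:
                x = d.loc[d[between] == g1, dv].dropna().to_numpy()
                y = d.loc[d[between] == g2, dv].dropna().to_numpy()
                if len(x) < 2 or len(y) < 2:
                    rows.append((stratum, g1, g2, np.nan, np.nan, np.nan, np.nan,
                                 "skipped: group with < 2 observations"))
                    continue
                t = sps.ttest_ind(x, y, equal_var=equal_var)
                rows.append((stratum, g1, g2, float(t.statistic), float(t.df),
                             float(t.pvalue), cohens_d(x, y), ""))
    out = pd.DataFrame(
        rows, columns=["stratum", "group1", "group2", "t", "df", "p", "cohen_d", "note"]
    )
    m = int(out["p"].notna().sum())
    if correction == "bonferroni" and m:
        out["p_adj"] = np.minimum(1.0, out["p"] * m)
    else:
        out["p_adj"] = out["p"]
    return out
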