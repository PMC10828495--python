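"""Multi-arm cohort statistics.

The comparison layer used throughout the study design: one-way ANOVA with a
Holm-Sidak step-down post hoc within each timepoint, two-way
repeated-measures (mixed) ANOVA across the two follow-up timepoints with
Holm-Sidak-adjusted within-group contrasts, unpaired t-tests for two-group
questions, and Fisher's exact test (Freeman-Halton r x c extension) for
ordinal renal damage scores.  Significance level alpha = 0.05, two-sided
throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "OneWayAnovaResult",
    "RMAnovaResult",
    "FisherExactResult",
    "holm_sidak_adjust",
    "one_way_anova_posthoc",
    "rm_two_way_anova",
    "fisher_exact_rxc",
    "unpaired_t",
    "summarize_table",
]

ALPHA = 0.05


@dataclass(frozen=True)
class ComparisonResult:
    """A single named contrast with raw and family-adjusted p-values."""

    name: str
    statistic: float
    df: float
    p_raw: float
    p_adjusted: float
    family: str = ""
    flag: str = ""

    @property
    def significant(self) -> bool:
        return self.p_adjusted < ALPHA


def holm_sidak_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values, in input order.

    Sort ascending; the i-th smallest raw p becomes
    max_{j<=i} [1 - (1 - p_(j))^(m - j + 1)], clipped at 1.  Equals the raw
    p when m = 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    with np.errstate(divide="ignore"):  # log1p(-1) at p = 1 is benign
        return multipletests(p, method="holm-sidak")[1]


@dataclass(frozen=True)
class OneWayAnovaResult:
    """Omnibus one-way ANOVA plus Holm-Sidak-adjusted pairwise contrasts."""

    f_statistic: float
    p_omnibus: float
    df_between: int
    df_within: int
    mse: float
    comparisons: tuple[ComparisonResult, ...]

    def summary(self) -> str:
        lines = [
            f"One-way ANOVA: F({self.df_between}, {self.df_within}) = "
            f"{self.f_statistic:.4g}, p = {self.p_omnibus:.4g}",
            "Holm-Sidak pairwise contrasts:",
        ]
        for c in self.comparisons:
            star = " *" if c.significant else ""
            lines.append(f"  {c.name}: t = {c.statistic:.4g}, "
                         f"p_raw = {c.p_raw:.4g}, p_adj = {c.p_adjusted:.4g}{star}")
        return "\n".join(lines)


def one_way_anova_posthoc(
    groups: Mapping[str, Sequence[float]],
    family: str = "all-pairs",
    control: Optional[str] = None,
) -> OneWayAnovaResult:
    """One-way ANOVA with pooled-variance pairwise t post hoc.

    ``family`` is "all-pairs" or "vs-control" (requires ``control``); the
    Holm-Sidak correction is applied over the chosen comparison family.
    Pairwise t-statistics use the ANOVA pooled error (MSE, df = N - k).
    """
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if len(arrays) < 2:
        raise ValueError("need at least 2 arms")
    for n, a in zip(names, arrays):
        if a.size < 2:
            raise ValueError(f"arm {n!r} has n < 2")
    k = len(arrays)
    ns = np.array([a.size for a in arrays])
    total_n = int(ns.sum())
    means = np.array([a.mean() for a in arrays])
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df_within = total_n - k
    mse = ss_within / df_within

    f_stat, p_omni = sps.f_oneway(*arrays)
    if not np.isfinite(f_stat):  # all groups identical & constant
        f_stat, p_omni = 0.0, 1.0

    if family == "all-pairs":
        pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    elif family == "vs-control":
        if control is None or control not in names:
            raise ValueError("family='vs-control' requires a valid control arm")
        ci = names.index(control)
        pairs = [(ci, j) for j in range(k) if j != ci]
    else:
        raise ValueError("family must be 'all-pairs' or 'vs-control'")

    tstats, praws, labels = [], [], []
    for i, j in pairs:
        se = math.sqrt(mse * (1.0 / ns[i] + 1.0 / ns[j]))
        if se == 0:
            t = 0.0 if means[i] == means[j] else math.inf
        else:
            t = (means[i] - means[j]) / se
        p = 1.0 if t == 0 else float(2 * sps.t.sf(abs(t), df_within))
        tstats.append(t)
        praws.append(p)
        labels.append(f"{names[i]} vs {names[j]}")
    p_adj = holm_sidak_adjust(praws) if praws else np.array([])

    comparisons = tuple(
        ComparisonResult(name=lab, statistic=t, df=df_within, p_raw=p,
                         p_adjusted=pa, family=family)
        for lab, t, p, pa in zip(labels, tstats, praws, p_adj)
    )
    return OneWayAnovaResult(
        f_statistic=float(f_stat), p_omnibus=float(p_omni),
        df_between=k - 1, df_within=df_within, mse=mse,
        comparisons=comparisons,
    )


@dataclass(frozen=True)
class RMAnovaResult:
    """Mixed (split-plot) ANOVA effects plus within-arm time contrasts."""

    effects: pd.DataFrame  # rows: group, time, interaction
    contrasts: tuple[ComparisonResult, ...]
    n_excluded_animals: int = 0

    def effect_p(self, which: str) -> float:
        """p-value for 'group', 'time' or 'interaction'."""
        return float(self.effects.loc[which, "p"])

    def summary(self) -> str:
        lines = ["Two-way repeated-measures ANOVA:"]
        for name, row in self.effects.iterrows():
            lines.append(f"  {name}: F({row['df1']:.0f}, {row['df2']:.0f}) = "
                         f"{row['F']:.4g}, p = {row['p']:.4g}")
        lines.append("Holm-Sidak within-arm time contrasts:")
        for c in self.contrasts:
            star = " $" if c.significant else ""
            lines.append(f"  {c.name}: t = {c.statistic:.4g}, "
                         f"p_adj = {c.p_adjusted:.4g}{star}")
        if self.n_excluded_animals:
            lines.append(f"({self.n_excluded_animals} incomplete animal(s) excluded)")
        return "\n".join(lines)


def rm_two_way_anova(
    table: pd.DataFrame,
    parameter: Optional[str] = None,
    subject: str = "animal",
    group: str = "arm",
    within: str = "timepoint",
    value: str = "value",
) -> RMAnovaResult:
    """Group x time mixed ANOVA on a tidy cohort table.

    ``table`` is long format with one row per animal x timepoint (columns
    ``animal``, ``arm``, ``timepoint``, ``value``, and optionally
    ``parameter`` filtered by the ``parameter`` argument).  Animals missing
    a timepoint are excluded with a warning (complete-case analysis, as when
    one animal dies mid-study); an arm reduced below n = 2 is an error.
    """
    df = table.copy()
    if parameter is not None:
        if "parameter" not in df.columns:
            raise ValueError("table has no 'parameter' column to filter")
        df = df[df["parameter"] == parameter]
        if df.empty:
            raise ValueError(f"no rows for parameter {parameter!r}")
    if df.duplicated([subject, within]).any():
        raise ValueError("duplicated animal x timepoint rows")
    timepoints = sorted(df[within].unique())
    if len(timepoints) != 2:
        raise ValueError(f"expected exactly 2 timepoints, found {timepoints}")

    counts = df.groupby(subject)[within].nunique()
    incomplete = counts[counts < 2].index
    if len(incomplete):
        warnings.warn(f"excluding {len(incomplete)} animal(s) missing a timepoint: "
                      f"{sorted(map(str, incomplete))}")
        df = df[~df[subject].isin(incomplete)]
    arm_sizes = df.groupby(group)[subject].nunique()
    if (arm_sizes < 2).any():
        raise ValueError(f"arm(s) below n=2 after exclusion: "
                         f"{arm_sizes[arm_sizes < 2].index.tolist()}")

    aov = pg.mixed_anova(data=df, dv=value, within=within,
                         subject=subject, between=group)
    aov = aov.set_index("Source")
    src_group, src_time = group, within
    effects = pd.DataFrame(
        {
            "F": [aov.loc[src_group, "F"], aov.loc[src_time, "F"],
                  aov.loc["Interaction", "F"]],
            "df1": [aov.loc[src_group, "DF1"], aov.loc[src_time, "DF1"],
                    aov.loc["Interaction", "DF1"]],
            "df2": [aov.loc[src_group, "DF2"], aov.loc[src_time, "DF2"],
                    aov.loc["Interaction", "DF2"]],
            "p": [aov.loc[src_group, "p_unc"], aov.loc[src_time, "p_unc"],
                  aov.loc["Interaction", "p_unc"]],
        },
        index=["group", "time", "interaction"],
    )

    # within-arm paired contrasts between the two timepoints
    tstats, praws, labels, dfs = [], [], [], []
    wide = df.pivot_table(index=[group, subject], columns=within,
                          values=value, aggfunc="first")
    for arm_name, sub in wide.groupby(level=0):
        a = sub[timepoints[0]].to_numpy()
        b = sub[timepoints[1]].to_numpy()
        t, p = sps.ttest_rel(b, a)
        if not np.isfinite(t):
            t, p = 0.0, 1.0
        tstats.append(float(t))
        praws.append(float(p))
        dfs.append(len(a) - 1)
        labels.append(f"{arm_name}: {timepoints[1]} vs {timepoints[0]}")
    p_adj = holm_sidak_adjust(praws)
    contrasts = tuple(
        ComparisonResult(name=lab, statistic=t, df=d, p_raw=p, p_adjusted=pa,
                         family="within-arm time")
        for lab, t, d, p, pa in zip(labels, tstats, dfs, praws, p_adj)
    )
    return RMAnovaResult(effects=effects, contrasts=contrasts,
                         n_excluded_animals=len(incomplete))


# ---------------------------------------------------------------------------
# Fisher's exact test, r x c (Freeman-Halton)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FisherExactResult:
    """Two-sided exact (or Monte-Carlo) p for an r x c contingency table."""

    p: float
    method: str  # "exact" | "monte-carlo"
    n_tables: int = 0  # tables enumerated (exact) or sampled (MC)
    se: Optional[float] = None  # Monte-Carlo standard error

    def __float__(self) -> float:
        return self.p


def _log_table_prob(cells: np.ndarray, log_margin_const: float) -> float:
    return log_margin_const - sum(math.lgamma(v + 1.0) for v in cells.ravel())


def fisher_exact_rxc(
    table,
    max_tables: int = 10_000_000,
    method: str = "auto",
    n_permutations: int = 100_000,
    rng: Optional[np.random.Generator] = None,
) -> FisherExactResult:
    """Fisher's exact test for an r x c table of counts, two-sided.

    The two-sided p sums, over all tables sharing the observed margins, the
    probabilities of tables no more probable than the observed one
    (probability ordering; Freeman-Halton extension of the 2 x 2 test).
    All-zero rows/columns are dropped first (they do not affect the margins).

    When the fixed-margin space exceeds ``max_tables``, the exact route
    raises unless ``method="monte-carlo"`` is chosen, which estimates p from
    ``n_permutations`` random tables with the observed margins and reports
    the Monte-Carlo standard error.
    """
    obs = np.asarray(table, dtype=np.int64)
    if obs.ndim != 2:
        raise ValueError("table must be 2-D")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative integers")
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        return FisherExactResult(p=1.0, method="exact", n_tables=1)

    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    n = int(obs.sum())
    log_margin_const = (
        sum(math.lgamma(v + 1.0) for v in row_sums)
        + sum(math.lgamma(v + 1.0) for v in col_sums)
        - math.lgamma(n + 1.0)
    )
    logp_obs = _log_table_prob(obs, log_margin_const)
    tol = 1e-9 * abs(logp_obs)

    if method not in ("auto", "exact", "monte-carlo"):
        raise ValueError("method must be 'auto', 'exact' or 'monte-carlo'")

    if method in ("auto", "exact"):
        r, c = obs.shape
        p_sum = 0.0
        count = 0
        cells = np.zeros((r, c), dtype=np.int64)
        overflow = False

        def recurse(i: int, j: int, row_rem: np.ndarray, col_rem: np.ndarray,
                    lg_acc: float) -> None:
            nonlocal p_sum, count, overflow
            if overflow:
                return
            if i == r - 1:
                # last row fully determined by column remainders
                lg = lg_acc - sum(math.lgamma(v + 1.0) for v in col_rem)
                cells[r - 1, :] = col_rem
                count += 1
                if count > max_tables:
                    overflow = True
                    return
                logp = log_margin_const + lg
                if logp <= logp_obs + tol:
                    p_sum += math.exp(logp)
                return
            if j == c - 1:
                v = row_rem[i]
                if v > col_rem[j]:
                    return
                recurse(i + 1, 0, row_rem, _dec(col_rem, j, v),
                        lg_acc - math.lgamma(v + 1.0))
                return
            hi = min(row_rem[i], col_rem[j])
            for v in range(hi + 1):
                new_row = row_rem.copy()
                new_row[i] -= v
                recurse(i, j + 1, new_row, _dec(col_rem, j, v),
                        lg_acc - math.lgamma(v + 1.0))

        def _dec(arr: np.ndarray, idx: int, v: int) -> np.ndarray:
            out = arr.copy()
            out[idx] -= v
            return out

        row_rem0 = row_sums.copy()
        # recursion fills rows 0..r-2 cell by cell; row i's remainder is
        # consumed as cells are chosen, column remainders likewise
        recurse(0, 0, row_rem0, col_sums.copy(), 0.0)
        if not overflow:
            return FisherExactResult(p=min(p_sum, 1.0), method="exact",
                                     n_tables=count)
        if method == "exact":
            raise ValueError(
                f"more than {max_tables} tables share these margins; "
                "use method='monte-carlo'"
            )

    rng = rng or np.random.default_rng()
    # permutation sampling: shuffle column labels against row labels
    row_labels = np.repeat(np.arange(obs.shape[0]), row_sums)
    col_labels = np.repeat(np.arange(obs.shape[1]), col_sums)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(col_labels)
        sampled = np.zeros_like(obs)
        np.add.at(sampled, (row_labels, perm), 1)
        if _log_table_prob(sampled, log_margin_const) <= logp_obs + tol:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    se = math.sqrt(p * (1 - p) / n_permutations)
    return FisherExactResult(p=p, method="monte-carlo",
                             n_tables=n_permutations, se=se)


def unpaired_t(a: Sequence[float], b: Sequence[float],
               welch: bool = False) -> ComparisonResult:
    """Two-sided unpaired t-test (Student by default, Welch optional)."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    flag = ""
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            t, p, df = 0.0, 1.0, x.size + y.size - 2
            flag = "zero-variance"
            return ComparisonResult(name="a vs b", statistic=t, df=df,
                                    p_raw=p, p_adjusted=p, family="t-test",
                                    flag=flag)
        flag = "zero-variance"
    res = sps.ttest_ind(x, y, equal_var=not welch)
    df = float(res.df) if hasattr(res, "df") else x.size + y.size - 2
    t, p = float(res.statistic), float(res.pvalue)
    if not np.isfinite(t):
        t, p = math.inf if x.mean() > y.mean() else -math.inf, 0.0
    return ComparisonResult(name="a vs b", statistic=t, df=df,
                            p_raw=p, p_adjusted=p, family="t-test", flag=flag)


def summarize_table(
    table: pd.DataFrame,
    group: str = "arm",
    within: str = "timepoint",
    parameter: str = "parameter",
    value: str = "value",
) -> pd.DataFrame:
    """Mean +/- SEM grid per arm x timepoint, one row per parameter cell.

    Matches the layout of a cohort results table: for every parameter and
    every arm x timepoint cell, the arithmetic mean, SEM (sample SD /
    sqrt(n)) and the cell n.
    """
    required = {group, parameter, value}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    keys = [parameter, group] + ([within] if within in table.columns else [])
    g = table.groupby(keys)[value]
    out = g.agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)),
                n="count").reset_index()
    return out
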