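"""Condition-comparison statistics.

The averaging hierarchy reduces per-cycle values to one number per
participant and condition: mean over cycles within a trial, then mean over
trials within a condition (unweighted at each level). Condition means are
compared with a one-way ANOVA treating each (participant, condition) mean
as an independent cell — with 16 participants and 4 conditions this gives
df = (3, 60) — followed by Tukey's HSD post-hoc test. Effect sizes are
partial eta squared, SS_effect / (SS_effect + SS_error), labelled small
(>= 0.02), medium (>= 0.13) or large (>= 0.26). A repeated-measures variant
is available behind a flag but is not the default, so reported degrees of
freedom match the between-cells convention. Normality is checked with a
one-sample Kolmogorov-Smirnov test against a normal distribution with the
sample's own mean and SD (advisory; estimated parameters make the nominal
p-values conservative in the Lilliefors sense).

Comfort ratings for the three assisted conditions are compared with paired
t-tests at a Bonferroni-adjusted significance level (default 0.03).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .exceptions import DomainError, MissingDataError

__all__ = [
    "NormalityResult",
    "TukeyPair",
    "AnovaResult",
    "PairedTResult",
    "average_hierarchy",
    "ks_normality",
    "oneway_anova_tukey",
    "paired_t_bonferroni",
    "effect_label",
]

#: Partial eta-squared cutoffs for small/medium/large effects.
ETA_SQ_CUTOFFS = {"small": 0.02, "medium": 0.13, "large": 0.26}


def effect_label(partial_eta_sq: float) -> str:
    if partial_eta_sq >= ETA_SQ_CUTOFFS["large"]:
        return "large"
    if partial_eta_sq >= ETA_SQ_CUTOFFS["medium"]:
        return "medium"
    if partial_eta_sq >= ETA_SQ_CUTOFFS["small"]:
        return "small"
    return "negligible"


def average_hierarchy(
    per_cycle: pd.DataFrame, conditions: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Cycle -> trial -> condition averaging.

    ``per_cycle`` is tidy: columns participant, condition, trial, cycle,
    metric, value. Returns a table with one row per (participant, condition)
    and one column per metric. When ``conditions`` is given, every
    participant must have every condition.
    """
    required = {"participant", "condition", "trial", "metric", "value"}
    missing = required - set(per_cycle.columns)
    if missing:
        raise DomainError(f"per-cycle table missing columns: {sorted(missing)}")
    trial_means = (
        per_cycle.groupby(["participant", "condition", "trial", "metric"], sort=False)["value"]
        .mean()
        .reset_index()
    )
    cond_means = (
        trial_means.groupby(["participant", "condition", "metric"], sort=False)["value"]
        .mean()
        .reset_index()
    )
    table = cond_means.pivot_table(
        index=["participant", "condition"], columns="metric", values="value", sort=False
    ).reset_index()
    table.columns.name = None
    if conditions is not None:
        for pid, grp in table.groupby("participant"):
            absent = set(conditions) - set(grp["condition"])
            if absent:
                raise MissingDataError(
                    f"participant {pid}: no trials for condition(s) {sorted(absent)}"
                )
    return table


@dataclass
class NormalityResult:
    statistic: float
    p: float
    degenerate: bool = False


def ks_normality(values) -> NormalityResult:
    """One-sample KS test against N(sample mean, sample SD). Advisory only."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 3:
        raise DomainError(f"need at least 3 values for the KS normality check, got {arr.size}")
    sd = float(np.std(arr, ddof=1))
    if sd == 0.0:
        return NormalityResult(float("nan"), float("nan"), degenerate=True)
    stat, p = sp_stats.kstest(arr, "norm", args=(float(np.mean(arr)), sd))
    return NormalityResult(float(stat), float(p))


@dataclass
class TukeyPair:
    pair: tuple[str, str]
    mean_diff: float
    p_adj: float
    significant: bool


@dataclass
class AnovaResult:
    metric: str
    F: float
    df_effect: int
    df_error: int
    p: float
    partial_eta_sq: float
    effect_label: str
    tukey: list[TukeyPair] = field(default_factory=list)
    alpha: float = 0.05
    normality: NormalityResult | None = None

    def to_dict(self) -> dict:
        out = {
            "metric": self.metric,
            "F": self.F,
            "df_effect": self.df_effect,
            "df_error": self.df_error,
            "p": self.p,
            "partial_eta_sq": self.partial_eta_sq,
            "effect_label": self.effect_label,
            "alpha": self.alpha,
            "tukey": [
                {
                    "pair": list(t.pair),
                    "mean_diff": t.mean_diff,
                    "p_adj": t.p_adj,
                    "significant": t.significant,
                }
                for t in self.tukey
            ],
        }
        if self.normality is not None:
            out["ks_normality"] = {
                "statistic": self.normality.statistic,
                "p": self.normality.p,
                "degenerate": self.normality.degenerate,
            }
        return out


def oneway_anova_tukey(
    table: pd.DataFrame,
    metric: str,
    alpha: float = 0.05,
    conditions: tuple[str, ...] | None = None,
    repeated_measures: bool = False,
    include_tukey: bool = True,
) -> AnovaResult:
    """One-way ANOVA over conditions with Tukey HSD and partial eta squared.

    ``table`` is the cohort table from :func:`average_hierarchy`. The design
    must be complete (every participant in every condition).
    """
    if metric not in table.columns:
        raise DomainError(f"metric {metric!r} not in cohort table")
    conds = tuple(conditions) if conditions else tuple(dict.fromkeys(table["condition"]))
    if len(conds) < 2:
        raise DomainError(f"need at least 2 conditions, got {conds}")
    groups = []
    sizes = set()
    for cond in conds:
        vals = table.loc[table["condition"] == cond, metric].to_numpy(dtype=float)
        if len(vals) == 0 or np.isnan(vals).any():
            raise MissingDataError(f"condition {cond!r} has missing values for {metric!r}")
        groups.append(vals)
        sizes.add(len(vals))
    if len(sizes) != 1:
        raise MissingDataError(f"unbalanced design for {metric!r}: group sizes {sorted(sizes)}")

    values = np.concatenate(groups)
    normality = ks_normality(values) if len(values) >= 3 and np.std(values) > 0 else None

    if repeated_measures:
        from statsmodels.stats.anova import AnovaRM

        long = table[["participant", "condition", metric]].rename(columns={metric: "value"})
        rm = AnovaRM(long, depvar="value", subject="participant", within=["condition"]).fit()
        row = rm.anova_table.iloc[0]
        f_stat = float(row["F Value"])
        df_effect, df_error = int(row["Num DF"]), int(row["Den DF"])
        p_val = float(row["Pr > F"])
        eta = f_stat * df_effect / (f_stat * df_effect + df_error)
    else:
        grand = values.mean()
        n_per = len(groups[0])
        ss_effect = float(sum(n_per * (g.mean() - grand) ** 2 for g in groups))
        ss_error = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
        df_effect = len(groups) - 1
        df_error = len(values) - len(groups)
        if ss_error == 0.0:
            f_stat = 0.0 if ss_effect == 0.0 else float("inf")
            p_val = 1.0 if ss_effect == 0.0 else 0.0
        else:
            f_stat = (ss_effect / df_effect) / (ss_error / df_error)
            p_val = float(sp_stats.f.sf(f_stat, df_effect, df_error))
        denom = ss_effect + ss_error
        eta = ss_effect / denom if denom > 0 else 0.0

    result = AnovaResult(
        metric=metric,
        F=float(f_stat),
        df_effect=df_effect,
        df_error=df_error,
        p=float(p_val),
        partial_eta_sq=float(eta),
        effect_label=effect_label(float(eta)),
        alpha=alpha,
        normality=normality,
    )

    if not include_tukey:
        return result
    if np.std(values) > 0:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        labels = np.concatenate([[c] * len(g) for c, g in zip(conds, groups)])
        hsd = pairwise_tukeyhsd(values, labels, alpha=alpha)
        res = hsd.summary().data[1:]
        for row in res:
            g1, g2, meandiff, p_adj, _, _, reject = row
            result.tukey.append(
                TukeyPair(
                    pair=(str(g1), str(g2)),
                    mean_diff=float(meandiff),
                    p_adj=float(p_adj),
                    significant=bool(reject),
                )
            )
    else:
        for g1, g2 in combinations(conds, 2):
            result.tukey.append(TukeyPair((g1, g2), 0.0, 1.0, False))
    return result


@dataclass
class PairedTResult:
    pair: tuple[str, str]
    t: float
    p: float
    mean_diff: float
    significant: bool
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "t": self.t,
            "p": self.p,
            "mean_diff": self.mean_diff,
            "significant": self.significant,
            "degenerate": self.degenerate,
        }


def paired_t_bonferroni(scores: pd.DataFrame, alpha_adjusted: float = 0.03) -> list[PairedTResult]:
    """Paired t-tests between all column pairs of ``scores``.

    ``scores`` holds one row per participant and one column per condition
    (e.g. the three assisted-walking comfort ratings). Significance is
    declared at the Bonferroni-adjusted level ``alpha_adjusted``.
    """
    if scores.shape[1] < 2:
        raise DomainError("need at least two conditions to compare")
    out = []
    for a, b in combinations(scores.columns, 2):
        paired = scores[[a, b]].dropna()
        if len(paired) < 2:
            raise MissingDataError(f"fewer than 2 complete pairs for {a!r} vs {b!r}")
        diff = paired[a].to_numpy(dtype=float) - paired[b].to_numpy(dtype=float)
        mean_diff = float(diff.mean())
        if np.std(diff, ddof=1) == 0.0:
            if mean_diff == 0.0:
                out.append(PairedTResult((a, b), 0.0, 1.0, 0.0, False, degenerate=True))
            else:
                out.append(
                    PairedTResult(
                        (a, b), float(np.inf) if mean_diff > 0 else float(-np.inf),
                        0.0, mean_diff, True, degenerate=True,
                    )
                )
            continue
        t, p = sp_stats.ttest_rel(paired[a], paired[b])
        out.append(PairedTResult((a, b), float(t), float(p), mean_diff, bool(p < alpha_adjusted)))
    return out
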