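"""Contingency-table tests for predation frequency and prey survival.

Groups of predators are scored for whether each individual consumed any
prey (successes out of totals); frequencies are compared with Pearson
chi-square tests — Yates-corrected by default only for 2x2 tables — and
with Fisher's exact test for pairwise survival comparisons against
controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "ChiSquareResult",
    "chi_square_test",
    "fisher_exact_2x2",
    "survival_summary",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Successes out of totals for each group (k x 2 layout)."""

    groups: tuple
    successes: tuple
    totals: tuple

    def __post_init__(self):
        if not (len(self.groups) == len(self.successes) == len(self.totals)):
            raise ValueError("groups, successes and totals must have equal length")
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        for s, t in zip(self.successes, self.totals):
            if not 0 <= s <= t:
                raise ValueError("successes must lie in [0, totals] per group")

    @classmethod
    def from_counts(cls, groups, successes, totals) -> "ContingencyTable":
        return cls(tuple(groups), tuple(int(s) for s in successes), tuple(int(t) for t in totals))

    def as_array(self) -> np.ndarray:
        s = np.asarray(self.successes)
        t = np.asarray(self.totals)
        return np.column_stack([s, t - s])


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    pvalue: float
    continuity_corrected: bool


def chi_square_test(table: ContingencyTable, continuity_correction=None) -> ChiSquareResult:
    """Pearson chi-square test on the groups x (success, failure) table.

    ``continuity_correction=None`` applies the conventional default:
    Yates correction for 2x2 tables only.  Explicit True requests the
    correction (honoured only for 2x2); False disables it.
    """
    arr = table.as_array()
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("chi-square test undefined with a zero marginal total")
    is_2x2 = arr.shape == (2, 2)
    correct = is_2x2 if continuity_correction is None else (continuity_correction and is_2x2)
    stat, p, df, _ = stats.chi2_contingency(arr, correction=correct)
    return ChiSquareResult(float(stat), int(df), float(p), bool(correct))


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Accepts a :class:`ContingencyTable` with two groups or a 2x2 array.
    Two-sided p sums hypergeometric probabilities no larger than the
    observed table's probability (the conventional definition).
    """
    arr = table.as_array() if isinstance(table, ContingencyTable) else np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("Fisher exact test requires a 2x2 table")
    if np.any(arr < 0):
        raise ValueError("table entries must be non-negative")
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    return float(p)


def survival_summary(
    trials: pd.DataFrame, control_label="control", alpha=0.05
) -> pd.DataFrame:
    """Per-group prey survival with mortality attribution against control.

    Survival is ``1 - (consumed + dead_unconsumed) / offered`` aggregated
    over trials.  A group's mortality is attributed to predation when its
    survival differs from the control group's by a Fisher exact test at
    level ``alpha``.  Requires a control group (no predator) in the table.
    """
    df = trials
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    groups = df.groupby("predator_group", sort=False).agg(
        offered=("density_offered", "sum"),
        consumed=("consumed", "sum"),
        dead_unconsumed=("dead_unconsumed", "sum"),
    )
    if control_label not in groups.index:
        raise ValueError("trial table has no control group %r" % control_label)
    groups["died"] = groups["consumed"] + groups["dead_unconsumed"]
    groups["survival"] = 1.0 - groups["died"] / groups["offered"]
    ctrl = groups.loc[control_label]
    pvals, attributed = [], []
    for g, row in groups.iterrows():
        if g == control_label:
            pvals.append(np.nan)
            attributed.append(False)
            continue
        tab = np.array(
            [
                [row["offered"] - row["died"], row["died"]],
                [ctrl["offered"] - ctrl["died"], ctrl["died"]],
            ],
            dtype=int,
        )
        p = fisher_exact_2x2(tab)
        pvals.append(p)
        attributed.append(p < alpha and row["survival"] < ctrl["survival"])
    out = groups.reset_index()
    out["fisher_p_vs_control"] = pvals
    out["mortality_attributed_to_predation"] = attributed
    return out
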