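"""Contingency-table tests against brute-force oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from frip.counts import (
    ChiSquareResult,
    ContingencyTable,
    chi_square_test,
    fisher_exact_2x2,
    survival_summary,
)

# -- oracles -------------------------------------------------------------


def pearson_chi2(arr):
    """Brute-force sum of (O - E)^2 / E."""
    arr = np.asarray(arr, dtype=float)
    rows = arr.sum(axis=1, keepdims=True)
    cols = arr.sum(axis=0, keepdims=True)
    expected = rows * cols / arr.sum()
    return float(((arr - expected) ** 2 / expected).sum())


def fisher_enumeration(arr):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    a, b = arr[0]
    c, d = arr[1]
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


# -- chi-square ----------------------------------------------------------


def test_chi_square_matches_brute_force_and_is_order_invariant():
    t = ContingencyTable.from_counts(["a", "b", "c"], [5, 44, 44], [45, 45, 45])
    r = chi_square_test(t)
    assert isinstance(r, ChiSquareResult)
    assert r.statistic == pytest.approx(pearson_chi2(t.as_array()), rel=1e-12)
    assert r.df == 2 and not r.continuity_corrected
    shuffled = ContingencyTable.from_counts(["c", "a", "b"], [44, 5, 44], [45, 45, 45])
    assert chi_square_test(shuffled).statistic == pytest.approx(r.statistic, rel=1e-12)


def test_chi_square_default_corrections():
    """Yates by default only on 2x2; k x 2 stays uncorrected."""
    t22 = ContingencyTable.from_counts(["x", "y"], [53, 31], [77, 77])
    assert chi_square_test(t22).continuity_corrected
    assert not chi_square_test(t22, continuity_correction=False).continuity_corrected
    t32 = ContingencyTable.from_counts(["x", "y", "z"], [5, 10, 20], [30, 30, 30])
    assert not chi_square_test(t32).continuity_corrected


def test_chi_square_identical_proportions_and_zero_marginal():
    t = ContingencyTable.from_counts(["a", "b", "c"], [12, 12, 12], [40, 40, 40])
    assert chi_square_test(t).statistic == pytest.approx(0.0, abs=1e-12)
    empty = ContingencyTable.from_counts(["a", "b"], [0, 0], [10, 10])
    with pytest.raises(ValueError):
        chi_square_test(empty)


# -- Fisher --------------------------------------------------------------


@pytest.mark.parametrize(
    "table",
    [
        [[167, 8], [175, 0]],
        [[5, 40], [44, 1]],
        [[16, 60], [31, 46]],
        [[3, 7], [6, 4]],
    ],
)
def test_fisher_matches_enumeration_oracle(table):
    arr = np.asarray(table)
    assert fisher_exact_2x2(arr) == pytest.approx(fisher_enumeration(arr), rel=1e-9)


def test_fisher_properties():
    assert fisher_exact_2x2([[20, 5], [20, 5]]) == pytest.approx(1.0)
    assert fisher_exact_2x2([[0, 45], [45, 0]]) < 1e-20
    arr = np.array([[12, 30], [25, 9]])
    p = fisher_exact_2x2(arr)
    assert fisher_exact_2x2(arr[::-1]) == pytest.approx(p, rel=1e-12)
    assert fisher_exact_2x2(arr[:, ::-1]) == pytest.approx(p, rel=1e-12)
    with pytest.raises(ValueError):
        fisher_exact_2x2(np.ones((3, 2)))


# -- survival summary ----------------------------------------------------


def _survival_table():
    rows = []
    for grp, consumed, dead in [
        ("control", 0, 0),
        ("invader", 5, 0),  # eats a quarter of what is offered
        ("sham", 0, 0),
    ]:
        for i in range(10):
            rows.append(
                dict(
                    predator_group=grp,
                    prey_type="larva",
                    density_offered=2,
                    consumed=consumed and (1 if i < 5 else 0),
                    dead_unconsumed=dead,
                    duration_days=2.0,
                    replicate_id=f"{grp}-{i}",
                    excluded=False,
                )
            )
    return pd.DataFrame(rows)


def test_survival_summary_attribution():
    out = survival_summary(_survival_table()).set_index("predator_group")
    assert out.loc["control", "survival"] == 1.0
    assert out.loc["sham", "survival"] == 1.0
    assert not out.loc["sham", "mortality_attributed_to_predation"]
    assert out.loc["invader", "survival"] == pytest.approx(0.75)
    assert out.loc["invader", "mortality_attributed_to_predation"]


def test_survival_summary_requires_control():
    df = _survival_table()
    with pytest.raises(ValueError):
        survival_summary(df[df["predator_group"] != "control"])
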