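"""Quadrat-density summaries and quasi-Poisson group comparison."""

import numpy as np
import pandas as pd
import pytest

import frip
from frip.abundance import (
    allocate_published_abundance,
    compare_abundance,
    density_from_quadrat,
    summarize_abundance,
)


def test_density_arithmetic():
    assert density_from_quadrat(37, 0.25) == 148.0
    assert density_from_quadrat(0, 0.25) == 0.0
    assert density_from_quadrat(21, 0.25) == 84.0
    with pytest.raises(ValueError):
        density_from_quadrat(5, 0.0)
    with pytest.raises(ValueError):
        density_from_quadrat(-1, 0.25)


def test_allocation_conserves_total():
    props = {"small": 0.2, "mid": 0.5, "large": 0.3}
    alloc = allocate_published_abundance(100.0, props)
    assert alloc == {"small": 20.0, "mid": 50.0, "large": 30.0}
    assert sum(alloc.values()) == pytest.approx(100.0)
    assert all(v == 0 for v in allocate_published_abundance(0.0, props).values())
    with pytest.raises(ValueError):
        allocate_published_abundance(10.0, {"a": 0.5, "b": 0.6})


def test_summary_moments_and_invariances(mixed_survey):
    s = {x.group: x for x in summarize_abundance(mixed_survey)}
    assert set(s) == {"intermediate_invader", "native"}
    assert all(x.mean_density >= 0 and x.se_density >= 0 for x in s.values())
    # order invariance
    shuffled = mixed_survey.sample(frac=1.0, random_state=1)
    s2 = {x.group: x for x in summarize_abundance(shuffled)}
    for g in s:
        assert s2[g].mean_density == pytest.approx(s[g].mean_density)
        assert s2[g].se_density == pytest.approx(s[g].se_density)
    # densities scale linearly with counts
    doubled = mixed_survey.assign(count=mixed_survey["count"] * 2)
    s3 = {x.group: x for x in summarize_abundance(doubled)}
    for g in s:
        assert s3[g].mean_density == pytest.approx(2 * s[g].mean_density)


def test_summary_recovers_generating_density():
    """Survey simulated at 870 ind/m^2 recovers the mean within 2 SE."""
    q = frip.generate_quadrat_survey(870.0, 1.5, 40, seed=21, group="invader")
    (s,) = summarize_abundance(q)
    assert abs(s.mean_density - 870.0) <= 2 * s.se_density


def test_single_and_identical_samples():
    one = pd.DataFrame(
        [dict(site="s1", group="g", count=10, area_m2=0.25, source="field")]
    )
    with pytest.warns(UserWarning):
        (s,) = summarize_abundance(one)
    assert s.se_density == 0.0
    same = pd.concat([one] * 4, ignore_index=True)
    (s4,) = summarize_abundance(same)
    assert s4.se_density == 0.0


def test_literature_pseudo_samples_pool_with_field():
    field = frip.generate_quadrat_survey(80.0, 2.0, 10, seed=22, group="g")
    lit = pd.DataFrame(
        [
            dict(site=f"pub-{i}", group="g", count=c, area_m2=1.0, source="literature")
            for i, c in enumerate([60, 90, 120])
        ]
    )
    (s,) = summarize_abundance(pd.concat([field, lit], ignore_index=True))
    assert s.n_samples == 13
    assert s.n_field == 10 and s.n_literature == 3


def test_dispersion_near_one_under_poisson():
    """Quasi-dispersion calibrates to ~1 when counts are truly Poisson."""
    q1 = frip.generate_quadrat_survey(
        30.0, np.inf, 300, area_m2=1.0, seed=23, group="a"
    )
    q2 = frip.generate_quadrat_survey(
        45.0, np.inf, 300, area_m2=1.0, seed=24, group="b"
    )
    cmp_ = compare_abundance(pd.concat([q1, q2], ignore_index=True))
    assert cmp_.dispersion == pytest.approx(1.0, abs=0.2)


def test_contrast_detected_at_survey_scale(mixed_survey):
    cmp_ = compare_abundance(mixed_survey)
    assert cmp_.f_statistic > 0 and cmp_.pvalue < 0.01
    assert len(cmp_.pairwise) == 1
    row = cmp_.pairwise.iloc[0]
    assert row["p_holm"] >= row["p"] - 1e-15


def test_power_and_size_at_field_contrast():
    """83 vs 17 ind/m^2 with 30 quadrats: rejection is near-certain;
    permuting labels destroys it."""
    rng = np.random.default_rng(31)
    hits = 0
    runs = 40
    for i in range(runs):
        q1 = frip.generate_quadrat_survey(
            83.0, 2.0, 30, rng=rng, group="invader"
        )
        q2 = frip.generate_quadrat_survey(17.0, 2.0, 30, rng=rng, group="native")
        df = pd.concat([q1, q2], ignore_index=True)
        hits += compare_abundance(df).pvalue < 0.01
    assert hits / runs >= 0.95

    # permutation: same pooled counts, random labels
    q1 = frip.generate_quadrat_survey(83.0, 2.0, 30, rng=rng, group="invader")
    q2 = frip.generate_quadrat_survey(17.0, 2.0, 30, rng=rng, group="native")
    df = pd.concat([q1, q2], ignore_index=True)
    pvals = []
    for i in range(25):
        perm = df.assign(group=rng.permutation(df["group"].to_numpy()))
        pvals.append(compare_abundance(perm).pvalue)
    assert np.median(pvals) > 0.2


def test_type_i_error_near_alpha_under_equal_means():
    """Equal-mean groups: rejection rate compatible with alpha = 0.05."""
    rng = np.random.default_rng(32)
    rej = 0
    runs = 200
    for _ in range(runs):
        q1 = frip.generate_quadrat_survey(40.0, 2.0, 30, rng=rng, group="a")
        q2 = frip.generate_quadrat_survey(40.0, 2.0, 30, rng=rng, group="b")
        rej += compare_abundance(pd.concat([q1, q2], ignore_index=True)).pvalue < 0.05
    # binomial(200, 0.05): central 99.9% range roughly [1, 21]
    assert 1 <= rej <= 21


def test_all_zero_counts_error():
    q = frip.generate_quadrat_survey(0.0, 2.0, 10, seed=25, group="a")
    q2 = frip.generate_quadrat_survey(0.0, 2.0, 10, seed=26, group="b")
    with pytest.raises(ValueError):
        compare_abundance(pd.concat([q, q2], ignore_index=True))
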