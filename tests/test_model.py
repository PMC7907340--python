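"""Fitting, comparison, classification and bootstrap of the Rogers model."""

import numpy as np
import pandas as pd
import pytest

import frip
from frip.model import RogersModel, classify_fr_type, compare_fits, fit_rogers
from frip.rogers import rogers_expected_consumption


def _trials_frame(densities, consumed, duration, group="g", excluded=None):
    n = len(densities)
    return pd.DataFrame(
        {
            "predator_group": group,
            "prey_type": "prey",
            "density_offered": densities,
            "consumed": consumed,
            "dead_unconsumed": 0,
            "duration_days": duration,
            "replicate_id": [f"r{i}" for i in range(n)],
            "excluded": excluded if excluded is not None else [False] * n,
        }
    )


# -- fitting -------------------------------------------------------------


def test_self_consistency_on_noise_free_data():
    """Refitting rounded noise-free expectations recovers (a, h) within 5%.

    A dense density design (every integer 1..70) is used so that the
    deterministic rounding errors average out across densities; sparse
    designs concentrate rounding error at the low densities that anchor
    the attack coefficient.
    """
    a, h, T = 0.85, 0.258, 1.0
    densities = np.arange(1, 71)
    consumed = np.round(rogers_expected_consumption(a, h, T, densities)).astype(int)
    res = fit_rogers(_trials_frame(densities, consumed, T))
    assert res.converged
    assert res.a == pytest.approx(a, rel=0.05)
    assert res.h == pytest.approx(h, rel=0.05)
    assert res.max_feeding_rate == pytest.approx(1.0 / (T * res.h), rel=1e-12)
    assert res.max_feeding_rate_per_day == pytest.approx(1.0 / res.h, rel=1e-12)


def test_parameter_recovery_at_published_scale(embryo_trials):
    res = fit_rogers(embryo_trials)
    assert res.converged and res.a > 0 and res.h > 0
    assert abs(res.a - 0.85) <= 2 * res.bse["a"]
    assert abs(res.h - 0.258) <= 2 * res.bse["h"]


def test_local_optimality_of_reported_optimum(larva_trials):
    """Likelihood at the optimum beats 100 perturbed parameter pairs."""
    res = fit_rogers(larva_trials)
    model = RogersModel.from_dataframe(larva_trials)
    ll_hat = model.loglike((res.a, res.h))
    rng = np.random.default_rng(12)
    for _ in range(100):
        a = res.a * np.exp(rng.normal(0, 0.3))
        h = res.h * np.exp(rng.normal(0, 0.3))
        assert model.loglike((a, h)) <= ll_hat + 1e-8


def test_excluded_trials_never_enter_fits(embryo_trials):
    flagged = embryo_trials.copy()
    flagged.loc[flagged.index[:30], "excluded"] = True
    res = fit_rogers(flagged)
    assert res.nobs == len(embryo_trials) - 30


def test_unfittable_inputs_raise():
    with pytest.raises(ValueError):  # < 3 distinct densities
        fit_rogers(_trials_frame([5, 5, 10, 10], [1, 2, 3, 4], 1.0))
    with pytest.raises(ValueError):  # nothing consumed
        fit_rogers(_trials_frame([2, 5, 10, 20], [0, 0, 0, 0], 1.0))
    with pytest.raises(ValueError):  # all-or-nothing boundary
        fit_rogers(_trials_frame([2, 5, 10], [2, 5, 10], 1.0))


# -- comparison ----------------------------------------------------------


def test_identical_datasets_give_zero_differences(embryo_trials):
    cmp_ = compare_fits(embryo_trials, embryo_trials)
    assert cmp_.Da == pytest.approx(0.0, abs=1e-8)
    assert cmp_.Dh == pytest.approx(0.0, abs=1e-8)
    assert cmp_.p_Da > 0.9 and cmp_.p_Dh > 0.9


def test_handling_time_difference_direction():
    """Faster feeder as base: Dh = h_base - h_comparator is negative."""
    common = dict(attack_coefficient=0.5, duration=2.0,
                  densities=frip.LARVA_DENSITIES, replicates_per_density=50)
    fast = frip.generate_trials(
        frip.SimulationConfig(handling_time=0.988, seed=31, **common)
    )
    slow = frip.generate_trials(
        frip.SimulationConfig(handling_time=2.803, seed=32, **common)
    )
    cmp_ = compare_fits(fast, slow)
    assert cmp_.Dh < 0
    assert cmp_.p_Dh < 0.05
    assert cmp_.z_Dh == pytest.approx(cmp_.Dh / cmp_.se_Dh)


def test_unfittable_side_is_named():
    good = frip.generate_trials(frip.SimulationConfig(0.85, 0.258, seed=33))
    bad = _trials_frame([2, 5, 10, 20], [0, 0, 0, 0], 1.0)
    with pytest.raises(ValueError, match="comparator"):
        compare_fits(good, bad)
    with pytest.raises(ValueError, match="base"):
        compare_fits(bad, good)


# -- bootstrap -----------------------------------------------------------

def test_bootstrap_bands_and_determinism(embryo_trials):
    res = fit_rogers(embryo_trials)
    e1 = res.bootstrap(n_boot=60, seed=77)
    e2 = res.bootstrap(n_boot=60, seed=77)
    np.testing.assert_array_equal(e1.params, e2.params)
    # point fit inside the 95% band on (at least) 95% of the grid
    inside = (e1.band_lower <= e1.point_prediction + 1e-9) & (
        e1.point_prediction <= e1.band_upper + 1e-9
    )
    assert inside.mean() >= 0.95
    obs = np.isin(e1.grid, np.unique(embryo_trials["density_offered"]))
    assert inside[obs].all()


def test_small_bootstrap_reports_feeding_rate_moments(embryo_trials):
    """The n = 30 ensemble yields mean +/- SE in both conventions."""
    res = fit_rogers(embryo_trials)
    ens = res.bootstrap(n_boot=30, seed=13)
    assert ens.n_converged + ens.n_failed == 30
    assert ens.max_feeding_rate_per_day_mean == pytest.approx(1 / res.h, rel=0.15)
    assert ens.max_feeding_rate_se >= 0
    assert ens.max_feeding_rate_mean == pytest.approx(
        ens.max_feeding_rate_per_day_mean / res.duration, rel=1e-9
    )


def test_stratified_bootstrap_preserves_design(embryo_trials):
    res = fit_rogers(embryo_trials)
    ens = res.bootstrap(n_boot=25, seed=14, stratify_by_density=True)
    assert ens.n_converged > 0


# -- classification ------------------------------------------------------


def test_type_ii_classification(embryo_trials):
    r = classify_fr_type(embryo_trials)
    assert r.classified_type == "II"
    assert r.first_order_coef < 0 and r.first_order_p < 0.05
    assert r.dispersion > 0


def test_constant_proportion_is_indeterminate():
    """Flat proportion consumed: first-order term not significant."""
    rng = np.random.default_rng(55)
    densities = np.repeat([5, 10, 20, 40], 30)
    consumed = rng.binomial(densities, 0.4)
    r = classify_fr_type(_trials_frame(densities, consumed, 1.0))
    assert r.classified_type == "indeterminate"


def test_sigmoid_consumption_is_type_iii():
    """Proportion rising then falling with density classifies as III."""
    rng = np.random.default_rng(56)
    densities = np.repeat([2, 5, 10, 20, 40, 70], 40)
    # logistic in density with positive linear, negative quadratic term
    eta = -2.0 + 0.16 * densities - 0.0022 * densities**2
    p = 1 / (1 + np.exp(-eta))
    consumed = rng.binomial(densities, p)
    r = classify_fr_type(
        _trials_frame(densities, consumed, 1.0), include_quadratic=True
    )
    assert r.classified_type == "III"
    assert r.second_order_coef < 0 and r.second_order_p < 0.05


def test_classification_edge_cases():
    with pytest.raises(ValueError):  # single density
        classify_fr_type(_trials_frame([10, 10, 10], [1, 2, 3], 1.0))
    with pytest.warns(UserWarning):
        r = classify_fr_type(_trials_frame([2, 5, 10, 20], [0, 0, 0, 0], 1.0))
    assert r.classified_type == "indeterminate"
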