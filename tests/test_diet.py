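"""Diet-scenario tests: intake arithmetic, target substitution,
under-reporting correction, survey-weighted summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saltimpact.diet import (
    age_group_label,
    apply_targets,
    baseline_salt,
    correction_factors,
    stratified_means,
    summarize_change,
)

from conftest import make_records

TARGETS = pd.DataFrame(
    {
        "category_id": ["G001", "G002", "O001"],
        "sector": ["grocery", "grocery", "out_of_home"],
        "target_type": ["per_100g", "per_100g", "per_serving"],
        "target_value": [0.9, 0.3, 1.1],
    }
)


@pytest.mark.parametrize(
    "rows, expected",
    [
        ([(1, 1, "G001", 200.0, 1.2)], {1: 2.4, 2: 0.0}),
        ([(1, 1, "G001", 100.0, 0.5), (1, 2, "G002", 50.0, 2.0)], {1: 1.5, 2: 0.0}),
        ([(1, 1, "homemade", 300.0, 2.0), (2, 2, "homemade", 100.0, 1.0)], {1: 0.0, 2: 0.0}),
        ([(2, 1, "unmatched", 500.0, 1.0)], {1: 0.0, 2: 0.0}),
    ],
)
def test_baseline_salt_arithmetic(toy_persons, rows, expected):
    out = baseline_salt(make_records(rows), toy_persons)
    for pid, val in expected.items():
        assert out.loc[pid] == pytest.approx(val)


def test_baseline_salt_rejects_negative_values(toy_persons):
    with pytest.raises(ValueError, match="negative"):
        baseline_salt(make_records([(1, 1, "G001", -5.0, 1.0)]), toy_persons)


def test_apply_targets_per_100g_substitution(toy_persons):
    recs = make_records([(1, 1, "G001", 200.0, 1.2)])
    out = apply_targets(recs, TARGETS)
    assert baseline_salt(out, toy_persons).loc[1] == pytest.approx(200 * 0.9 / 100)


def test_apply_targets_per_serving_ignores_grams(toy_persons):
    recs = make_records([(1, 1, "O001", 350.0, 1.0), (2, 2, "O001", 80.0, 1.0)])
    out = baseline_salt(apply_targets(recs, TARGETS), toy_persons)
    assert out.loc[1] == pytest.approx(1.1)
    assert out.loc[2] == pytest.approx(1.1)


def test_apply_targets_substitution_is_unconditional(toy_persons):
    # record already below the target is still set to the target
    recs = make_records([(1, 1, "G001", 100.0, 0.2)])
    out = apply_targets(recs, TARGETS)
    assert out["salt_per_100g"].iloc[0] == pytest.approx(0.9)


def test_apply_targets_leaves_excluded_records_unchanged():
    recs = make_records([(1, 1, "homemade", 100.0, 0.7), (1, 2, "unmatched", 50.0, 0.4)])
    out = apply_targets(recs, TARGETS)
    np.testing.assert_allclose(out["salt_per_100g"], recs["salt_per_100g"])


def test_apply_targets_missing_category_raises():
    recs = make_records([(1, 1, "G999", 100.0, 0.7)])
    with pytest.raises(KeyError, match="G999"):
        apply_targets(recs, TARGETS)


def test_serving_cap_switch(toy_persons):
    recs = make_records([(1, 1, "O001", 600.0, 1.0)])
    out = baseline_salt(
        apply_targets(recs, TARGETS, assumed_serving_g=300.0, max_servings=3.0), toy_persons
    )
    assert out.loc[1] == pytest.approx(2 * 1.1)


def test_age_group_nearest_assignment():
    assert age_group_label(18) == "19-34"
    assert age_group_label(40) == "35-49"
    assert age_group_label(77) == "50-64"


@pytest.mark.parametrize(
    "ref, est, expected",
    [(8.0, 6.0, 4.0 / 3.0), (5.5, 5.5, 1.0)],
)
def test_correction_factor_ratio(ref, est, expected):
    reference = pd.DataFrame({"sex": ["female"], "age_group": ["19-34"], "reference_mean": [ref]})
    estimated = pd.DataFrame({"sex": ["female"], "age_group": ["19-34"], "estimated_mean": [est]})
    out = correction_factors(reference, estimated)
    assert out["factor"].iloc[0] == pytest.approx(expected)


def test_correction_factor_zero_estimate_rejected():
    reference = pd.DataFrame({"sex": ["male"], "age_group": ["35-49"], "reference_mean": [8.0]})
    estimated = pd.DataFrame({"sex": ["male"], "age_group": ["35-49"], "estimated_mean": [0.0]})
    with pytest.raises(ZeroDivisionError):
        correction_factors(reference, estimated)


def test_recovers_true_underreporting_factor(survey):
    """Correction factors computed from generated reference intakes
    recover the generator's true factor."""
    from saltimpact.synthetic import SyntheticConfig, generate_reference_intakes

    persons, records, _ = survey
    cfg = SyntheticConfig(seed=1, n_persons=200, true_underreporting_factor=1.25)
    ref = generate_reference_intakes(persons, records, cfg)
    est = stratified_means(baseline_salt(records, persons), persons)
    fac = correction_factors(ref, est)
    np.testing.assert_allclose(fac["factor"], 1.25, rtol=1e-12)


def test_weighted_mean_hand_example(toy_persons):
    baseline = pd.Series([4.0, 8.0], index=[1, 2])
    out = summarize_change(baseline, baseline, toy_persons, None, n_boot=10, seed=0)
    row = out.table.set_index("group").loc["overall"]
    assert row["baseline_mean"] == pytest.approx(7.0)
    assert row["abs_change"] == 0.0
    assert row["abs_change_lo"] <= 0.0 <= row["abs_change_hi"]


def test_corrected_mean_scales_like_published_adjustment(toy_persons):
    """A 1.164 correction factor turns a 5.21 g/d diary mean into the
    ~6.06 g/d corrected mean."""
    persons = toy_persons.assign(age=[30, 30], sex=["female", "female"], survey_weight=1.0)
    baseline = pd.Series([5.21, 5.21], index=[1, 2])
    factors = pd.DataFrame(
        {"sex": ["female"], "age_group": ["19-34"], "factor": [1.164]}
    )
    out = summarize_change(baseline, baseline, persons, factors, n_boot=10, seed=0)
    assert out.table.set_index("group").loc["overall", "baseline_mean"] == pytest.approx(
        6.06, abs=0.01
    )


def test_relative_change_invariant_to_correction_factor(survey, intakes):
    """The correction factor scales baseline and scenario identically, so
    the percentage reduction is unchanged while the absolute reduction
    scales with the factor."""
    persons = survey[0]
    baseline, scenario = intakes
    strata = stratified_means(baseline, persons)[["sex", "age_group"]]
    f1 = strata.assign(factor=1.0)
    f2 = strata.assign(factor=1.3)
    a = summarize_change(baseline, scenario, persons, f1, n_boot=10, seed=0).table
    b = summarize_change(baseline, scenario, persons, f2, n_boot=10, seed=0).table
    np.testing.assert_allclose(a["rel_change"], b["rel_change"], rtol=1e-12)
    np.testing.assert_allclose(1.3 * a["abs_change"], b["abs_change"], rtol=1e-12)


def test_scenario_never_exceeds_baseline(intakes):
    baseline, scenario = intakes
    assert (scenario.to_numpy() <= baseline.to_numpy() + 1e-12).all()


@settings(max_examples=25, deadline=None, derandomize=True)
@given(scale=st.floats(min_value=1e-3, max_value=1e3))
def test_weighted_mean_invariant_to_weight_rescaling(scale):
    persons = pd.DataFrame(
        {
            "person_id": [1, 2, 3],
            "sex": ["female", "male", "female"],
            "age": [25, 45, 60],
            "survey_weight": [0.5, 1.5, 1.0],
        }
    )
    baseline = pd.Series([3.0, 6.0, 9.0], index=[1, 2, 3])
    scenario = baseline * 0.8
    a = summarize_change(baseline, scenario, persons, None, n_boot=5, seed=1).table
    persons2 = persons.assign(survey_weight=persons["survey_weight"] * scale)
    b = summarize_change(baseline, scenario, persons2, None, n_boot=5, seed=1).table
    np.testing.assert_allclose(a["baseline_mean"], b["baseline_mean"], rtol=1e-9)
    np.testing.assert_allclose(a["abs_change"], b["abs_change"], rtol=1e-9)
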