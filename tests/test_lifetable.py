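"""Lifetable-engine tests: Markov oracle, conservation, discounting,
null intervention, dominance, proportionality and a 200k-individual
microsimulation oracle."""

import math

import numpy as np
import pandas as pd
import pytest

from saltimpact.lifetable import (
    DiscountSpec,
    EpiValidationError,
    InterventionTimeline,
    TrendSpec,
    build_pif_result,
    discount_stream,
    life_expectancy_delta,
    run_disease_lifetable,
    run_population,
    validate_epi,
)

N_YEARS = 110 - 18 + 1


def zero_pifs(epi):
    return {
        (d, s): np.zeros((epi.terminal_age + 1, N_YEARS))
        for d in epi.diseases
        for s in epi.sexes
    }


def const_pifs(epi, values):
    return {
        (d, s): np.full((epi.terminal_age + 1, N_YEARS), values[d])
        for d in epi.diseases
        for s in epi.sexes
    }


@pytest.fixture(scope="module")
def main_run(epi):
    tl = InterventionTimeline()
    pifs = build_pif_result(epi, {"female": 0.9, "male": 1.4}, tl, N_YEARS)
    trends = TrendSpec.fit(epi.trend_history)
    return run_population(epi, pifs, tl, trends, DiscountSpec())


# --------------------------------------------------------------- discounting
@pytest.mark.parametrize(
    "values, rate, expected",
    [
        ([10.0, 20.0, 30.0], 0.0, 60.0),
        ([0.0, 100.0], 0.035, 100.0 / 1.035),
        ([0.0, 0.0, 100.0], 0.035, 100.0 / 1.035**2),
    ],
)
def test_discount_stream_closed_form(values, rate, expected):
    assert discount_stream(np.array(values), rate) == pytest.approx(expected, rel=1e-12)


# ------------------------------------------------------------ disease module
def test_three_age_markov_oracle():
    """State occupancies match hand-multiplied Markov products."""
    I, F = 0.1, 0.5
    lt = run_disease_lifetable(np.full(3, I), np.full(3, F))
    qi, qf = 1 - math.exp(-I), 1 - math.exp(-F)
    h, d, dead = 1.0, 0.0, 0.0
    for t in range(3):
        new, dd = h * qi, d * qf
        h, d, dead = h - new, d + new - dd, dead + dd
        assert abs(lt["h"][t + 1] - h) < 1e-12
        assert abs(lt["d"][t + 1] - d) < 1e-12
        assert abs(lt["dead"][t + 1] - dead) < 1e-12


def test_no_incidence_means_no_disease():
    lt = run_disease_lifetable(np.zeros(30), np.full(30, 0.2))
    assert np.all(lt["new_cases"] == 0)
    assert np.all(lt["disease_deaths"] == 0)
    assert np.all(lt["h"] == 1.0)


def test_unit_multipliers_match_no_multipliers():
    rng = np.random.default_rng(0)
    I = rng.uniform(0, 0.2, size=(25, 4))
    F = rng.uniform(0, 0.4, size=(25, 4))
    a = run_disease_lifetable(I, F)
    b = run_disease_lifetable(I, F, incidence_multiplier=np.ones_like(I))
    for k in a:
        np.testing.assert_array_equal(a[k], b[k])


def test_state_conservation():
    """healthy + diseased + dead-from-disease = 1 in every year."""
    rng = np.random.default_rng(42)
    I = rng.uniform(0, 0.5, size=(60, 10))
    F = rng.uniform(0, 0.8, size=(60, 10))
    prev0 = rng.uniform(0, 0.3, size=10)
    lt = run_disease_lifetable(I, F, init_prevalence=prev0)
    total = lt["h"] + lt["d"] + lt["dead"]
    np.testing.assert_allclose(total, 1.0, atol=1e-9)


# ---------------------------------------------------------------- validation
def test_validator_rejects_out_of_range_case_fatality(epi):
    bad = epi.disease_rates.copy()
    bad.loc[(bad["disease"] == "ihd") & (bad["sex"] == "male") & (bad["age"] == 70),
            "case_fatality"] = 1.2
    broken = type(epi)(
        population=epi.population, disease_rates=bad, sbp=epi.sbp,
        utilities=epi.utilities, costs=epi.costs, rr_slopes=epi.rr_slopes,
        trend_history=epi.trend_history,
    )
    with pytest.raises(EpiValidationError, match="ihd.*male.*70"):
        validate_epi(broken)


def test_validator_rejects_mortality_dominance_violation(epi):
    bad = epi.disease_rates.copy()
    mask = (bad["disease"] == "stroke") & (bad["sex"] == "female") & (bad["age"] == 80)
    bad.loc[mask, "cause_mortality"] = 0.99
    broken = type(epi)(
        population=epi.population, disease_rates=bad, sbp=epi.sbp,
        utilities=epi.utilities, costs=epi.costs, rr_slopes=epi.rr_slopes,
        trend_history=epi.trend_history,
    )
    with pytest.raises(EpiValidationError, match="exceeds all-cause"):
        validate_epi(broken)


# -------------------------------------------------------------------- trends
def test_trend_fit_recovers_generator_factors(epi):
    spec = TrendSpec.fit(epi.trend_history)
    assert spec.factors["ihd"][0] == pytest.approx(0.98, rel=1e-9)
    assert spec.factors["ihd"][1] == pytest.approx(0.975, rel=1e-9)
    assert spec.factors["stroke"][0] == pytest.approx(0.985, rel=1e-9)


def test_timeline_ramp_and_lag():
    tl = InterventionTimeline(phase_in_years=4, lag_years=5)
    assert [tl.exposure_fraction(t) for t in (0, 5, 6, 7, 9, 30)] == [
        0.0, 0.0, 0.25, 0.5, 1.0, 1.0,
    ]


# ---------------------------------------------------------------- population
def test_null_intervention_differences_exactly_zero(epi):
    tl = InterventionTimeline()
    res = run_population(epi, zero_pifs(epi), tl, TrendSpec(), DiscountSpec())
    diff = res.outcomes[res.outcomes["simulation"] == "difference"]["value"]
    assert (diff == 0.0).all()
    le = life_expectancy_delta(res)
    assert (le["delta_days"] == 0.0).all()


def test_zero_discount_rate_is_plain_sum(epi):
    tl = InterventionTimeline()
    pifs = build_pif_result(epi, {"female": 0.9, "male": 1.4}, tl, N_YEARS)
    res = run_population(epi, pifs, tl, TrendSpec(), DiscountSpec(rate=0.0))
    for sex in ("female", "male"):
        plain = float(
            (res.series[(sex, "scenario", "qalys")] - res.series[(sex, "baseline", "qalys")]).sum()
        )
        row = res.outcomes[
            (res.outcomes["sex"] == sex)
            & (res.outcomes["horizon"] == "lifetime")
            & (res.outcomes["measure"] == "qalys")
            & (res.outcomes["simulation"] == "difference")
        ]["value"].iloc[0]
        assert row == pytest.approx(plain, rel=1e-12)


def test_lower_incidence_never_harms(main_run):
    """Dominance: the scenario lowers disease deaths and raises QALYs,
    life-years and life expectancy at every horizon."""
    diff = main_run.outcomes[main_run.outcomes["simulation"] == "difference"]
    for measure, sign in [
        ("qalys", 1), ("life_years", 1),
        ("ihd_cases", -1), ("stroke_cases", -1),
        ("ihd_deaths", -1), ("stroke_deaths", -1),
    ]:
        vals = diff[diff["measure"] == measure]["value"]
        assert (sign * vals >= -1e-9).all(), measure
    deaths20 = diff[(diff["measure"] == "total_deaths") & (diff["horizon"] == "20y")]["value"]
    assert (deaths20 <= 1e-9).all()
    assert (life_expectancy_delta(main_run)["delta_years"] >= 0).all()
    costs = diff[diff["measure"] == "costs"]["value"]
    assert (costs <= 1e-9).all()


def test_day_conversion_consistency(main_run):
    le = life_expectancy_delta(main_run)
    np.testing.assert_allclose(le["delta_days"], le["delta_years"] * 365.0, rtol=1e-12)


def test_effect_scaling_approximately_proportional(epi):
    """Scaling the intervention effect to 80% / 60% scales the QALY and
    cost differences within 10% of proportionality."""
    trends = TrendSpec.fit(epi.trend_history)
    diffs = {}
    for scale in (1.0, 0.8, 0.6):
        tl = InterventionTimeline(effect_scale=scale)
        pifs = build_pif_result(epi, {"female": 0.9, "male": 1.4}, tl, N_YEARS)
        res = run_population(epi, pifs, tl, trends, DiscountSpec())
        d = res.outcomes[
            (res.outcomes["simulation"] == "difference") & (res.outcomes["sex"] == "both")
        ].set_index(["horizon", "measure"])["value"]
        diffs[scale] = d
    for measure in ("qalys", "costs"):
        base = diffs[1.0][("lifetime", measure)]
        for scale in (0.8, 0.6):
            ratio = diffs[scale][("lifetime", measure)] / base
            assert ratio == pytest.approx(scale, abs=0.1 * scale)


def test_horizon_beyond_terminal_age_warns(epi):
    tl = InterventionTimeline()
    with pytest.warns(UserWarning, match="truncated"):
        run_population(epi, zero_pifs(epi), tl, TrendSpec(), DiscountSpec(), horizons=(200,))


# ------------------------------------------------------- microsimulation oracle
def _microsim_cohort(epi, sex, a0, n, pif_mult, n_years, seed):
    """Individual-level Monte Carlo of the same disease/death process.

    Common random numbers across the baseline and scenario runs; returns
    per-person case indicators per disease for both runs.
    """
    diseases = epi.diseases
    rates = {}
    for dis in diseases:
        sub = epi.disease_rates[
            (epi.disease_rates["disease"] == dis) & (epi.disease_rates["sex"] == sex)
        ].set_index("age")
        rates[dis] = sub
    pop = epi.population[epi.population["sex"] == sex].set_index("age")
    cause = sum(rates[d]["cause_mortality"] for d in diseases)
    m_other = (pop["all_cause_mortality"] - cause).clip(lower=0.0)

    rng = np.random.default_rng(seed)
    u_init = {d: rng.random(n) for d in diseases}
    u_inc = {d: rng.random((n_years, n)) for d in diseases}
    u_death = rng.random((n_years, n))

    out = {}
    for run in ("baseline", "scenario"):
        alive = np.ones(n, dtype=bool)
        diseased = {d: u_init[d] < rates[d].loc[a0, "prevalence"] for d in diseases}
        cases = {d: np.zeros(n, dtype=bool) for d in diseases}
        for t in range(n_years):
            a = a0 + t
            new = {}
            for dis in diseases:
                inc = rates[dis].loc[a, "incidence"]
                if run == "scenario":
                    inc = inc * pif_mult[dis]
                qi = 1 - math.exp(-inc)
                new[dis] = alive & ~diseased[dis] & (u_inc[dis][t] < qi)
                cases[dis] |= new[dis]
            hazard = np.full(n, m_other.loc[a])
            for dis in diseases:
                hazard += np.where(diseased[dis], rates[dis].loc[a, "case_fatality"], 0.0)
            die = alive & (u_death[t] < 1 - np.exp(-hazard))
            for dis in diseases:
                diseased[dis] = diseased[dis] | new[dis]
            alive &= ~die
        out[run] = cases
    return out


def test_population_matches_microsimulation_oracle(epi):
    """Cases averted from the cohort lifetable agree with a
    200,000-individual microsimulation of the same 3-state process
    (two cohorts, 20 years) within 3 standard errors."""
    n_per_cohort = 100_000
    cohorts = [50, 60]
    pif_vals = {"ihd": 0.10, "stroke": 0.05}
    pop = epi.population.copy()
    pop["count"] = 0.0
    for a0 in cohorts:
        pop.loc[(pop["sex"] == "female") & (pop["age"] == a0), "count"] = n_per_cohort
    epi2 = type(epi)(
        population=pop, disease_rates=epi.disease_rates, sbp=epi.sbp,
        utilities=epi.utilities, costs=epi.costs, rr_slopes=epi.rr_slopes,
        trend_history=None,
    )
    res = run_population(
        epi2, const_pifs(epi2, pif_vals), InterventionTimeline(), TrendSpec(),
        DiscountSpec(), horizons=(20,),
    )
    model = {}
    for dis in epi.diseases:
        d = res.outcomes[
            (res.outcomes["sex"] == "female")
            & (res.outcomes["horizon"] == "20y")
            & (res.outcomes["measure"] == f"{dis}_cases")
        ].set_index("simulation")["value"]
        model[dis] = d

    mult = {d: 1 - pif_vals[d] for d in epi.diseases}
    sims = [
        _microsim_cohort(epi, "female", a0, n_per_cohort, mult, 20, seed=100 + a0)
        for a0 in cohorts
    ]
    for dis in epi.diseases:
        base_ind = np.concatenate([s["baseline"][dis] for s in sims]).astype(float)
        scen_ind = np.concatenate([s["scenario"][dis] for s in sims]).astype(float)
        diff = base_ind - scen_ind
        n = len(diff)
        sim_base, se_base = base_ind.sum(), base_ind.std() * math.sqrt(n)
        sim_avert, se_avert = diff.sum(), diff.std() * math.sqrt(n)
        assert abs(model[dis]["baseline"] - sim_base) < 3 * se_base, dis
        model_avert = model[dis]["baseline"] - model[dis]["scenario"]
        assert abs(model_avert - sim_avert) < 3 * se_avert, dis
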