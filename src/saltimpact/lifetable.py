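"""Proportional multistate lifetable engine.

Each disease (IHD, ischemic stroke) is modelled as a 3-state process —
no disease, disease, dead-from-disease — with incidence as the first
transition and case fatality as the second; remission is zero.  The
disease processes run as proportions alongside a main cohort lifetable:
the change each disease process induces in its cause-specific mortality
rate feeds back into the cohort's all-cause mortality, so a scenario
that lowers incidence raises survival, person-years, QALYs and lowers
healthcare costs relative to baseline.

Conventions (chosen for bit-for-bit reproducibility): annual cycles,
single-year ages, closed cohorts to a terminal age of 110 (forced death
in the terminal year), no half-cycle correction; rates are converted to
annual probabilities as q = 1 - exp(-rate); competing risks within a
cycle are resolved as independent exponentials, with deaths partitioned
across causes in proportion to their rates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .risk import RelativeRiskFunction, pif_curve

logger = logging.getLogger(__name__)

__all__ = [
    "EpiInputs",
    "EpiValidationError",
    "InterventionTimeline",
    "TrendSpec",
    "DiscountSpec",
    "PopulationResult",
    "validate_epi",
    "run_disease_lifetable",
    "build_pif_result",
    "run_population",
    "discount_stream",
    "life_expectancy_delta",
]

SEXES = ("female", "male")
TERMINAL_AGE = 110


@dataclass
class EpiInputs:
    """Epidemiological inputs for the population model.

    population: sex, age, count, all_cause_mortality (annual rate)
    disease_rates: disease, sex, age, incidence, case_fatality,
        prevalence, cause_mortality (annual rates / proportion)
    sbp: sex, age, mean_sbp, sd_sbp (mmHg)
    utilities: sex, age, baseline_utility, decrement_<disease> columns
    costs: disease, sex, age, annual_cost (currency per prevalent case-year)
    rr_slopes: disease, age_lo, age_hi, log_rr_per_mmhg, log_rr_lo, log_rr_hi
    trend_history: disease, year_offset (-10..-1), incidence_index,
        case_fatality_index (rate indices relative to 1 at year 0)
    """

    population: pd.DataFrame
    disease_rates: pd.DataFrame
    sbp: pd.DataFrame
    utilities: pd.DataFrame
    costs: pd.DataFrame
    rr_slopes: pd.DataFrame
    trend_history: pd.DataFrame | None = None
    terminal_age: int = TERMINAL_AGE

    @property
    def diseases(self) -> list[str]:
        return sorted(self.disease_rates["disease"].unique())

    @property
    def sexes(self) -> list[str]:
        return sorted(self.population["sex"].unique())


class EpiValidationError(ValueError):
    """Raised when epidemiological inputs are internally inconsistent."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        shown = "\n  ".join(violations[:20])
        more = f"\n  ... and {len(violations) - 20} more" if len(violations) > 20 else ""
        super().__init__(f"invalid epidemiological inputs:\n  {shown}{more}")


def validate_epi(epi: EpiInputs) -> EpiInputs:
    """Check rate ranges, mortality dominance and age coverage.

    Returns the inputs unchanged if valid; raises
    :class:`EpiValidationError` listing every violation with its
    age/sex/disease coordinates otherwise.
    """
    v: list[str] = []
    ages = np.arange(epi.terminal_age + 1)

    for sex in epi.sexes:
        pop = epi.population[epi.population["sex"] == sex]
        missing = set(ages) - set(pop["age"])
        if missing:
            v.append(f"population/{sex}: missing ages {sorted(missing)[:5]}...")
        bad = pop[(pop["all_cause_mortality"] < 0) | (pop["all_cause_mortality"] > 1)]
        for _, r in bad.iterrows():
            v.append(f"all_cause_mortality out of [0,1] at sex={sex} age={int(r['age'])}")
        if (pop["count"] < 0).any():
            v.append(f"negative population count for sex={sex}")

    for (dis, sex), sub in epi.disease_rates.groupby(["disease", "sex"]):
        missing = set(ages) - set(sub["age"])
        if missing:
            v.append(f"disease_rates/{dis}/{sex}: missing ages {sorted(missing)[:5]}...")
        for col in ("incidence", "case_fatality", "prevalence", "cause_mortality"):
            bad = sub[(sub[col] < 0) | (sub[col] > 1)]
            for _, r in bad.iterrows():
                v.append(f"{col} out of [0,1] at disease={dis} sex={sex} age={int(r['age'])}")

    # mortality dominance: all-cause >= sum of cause-specific at every age
    cause = (
        epi.disease_rates.groupby(["sex", "age"])["cause_mortality"].sum().rename("cause_sum")
    )
    merged = epi.population.set_index(["sex", "age"]).join(cause).fillna(0.0)
    viol = merged[merged["cause_sum"] > merged["all_cause_mortality"] + 1e-12]
    for (sex, age), r in viol.iterrows():
        v.append(
            f"cause-specific mortality sum {r['cause_sum']:.3e} exceeds all-cause "
            f"{r['all_cause_mortality']:.3e} at sex={sex} age={int(age)}"
        )

    if (epi.sbp["sd_sbp"] <= 0).any():
        v.append("nonpositive SBP standard deviation")
    if ((epi.utilities["baseline_utility"] < 0) | (epi.utilities["baseline_utility"] > 1)).any():
        v.append("baseline utility outside [0,1]")
    for col in [c for c in epi.utilities.columns if c.startswith("decrement_")]:
        if ((epi.utilities[col] < 0) | (epi.utilities[col] > 1)).any():
            v.append(f"utility {col} outside [0,1]")
    if (epi.costs["annual_cost"] < 0).any():
        v.append("negative annual healthcare cost")

    if v:
        raise EpiValidationError(v)
    return epi


@dataclass(frozen=True)
class InterventionTimeline:
    """Phase-in and lag of the salt-reduction effect.

    The salt (hence SBP) change ramps linearly over ``phase_in_years``;
    disease incidence in year t responds to the exposure of year
    ``t - lag_years`` (no effect before the lag has elapsed).
    ``effect_scale`` scales the full salt change (1.0 main analysis,
    0.8 / 0.6 shortfall sensitivity analyses).
    """

    phase_in_years: int = 4
    lag_years: int = 5
    effect_scale: float = 1.0

    def exposure_fraction(self, year: int) -> float:
        """Fraction of the full exposure change felt by incidence in ``year``."""
        u = year - self.lag_years
        if u <= 0:
            return 0.0
        return min(u / self.phase_in_years, 1.0)


@dataclass(frozen=True)
class TrendSpec:
    """Annualized multiplicative trends in incidence and case fatality.

    ``factors[disease] = (incidence_factor, case_fatality_factor)``;
    rates in simulation year t are multiplied by factor**min(t, years),
    i.e. the trend continues for ``years`` years and is constant after.
    """

    factors: dict[str, tuple[float, float]] = field(default_factory=dict)
    years: int = 10

    def __post_init__(self) -> None:
        for dis, (fi, fc) in self.factors.items():
            if fi <= 0 or fc <= 0:
                raise ValueError(f"trend factors must be positive ({dis})")

    @classmethod
    def fit(cls, trend_history: pd.DataFrame | None, years: int = 10) -> "TrendSpec":
        """Annualized factors from a log-linear fit to the 10 pre-baseline
        years of rate indices (index 1 at year 0)."""
        if trend_history is None or trend_history.empty:
            return cls(factors={}, years=years)
        factors = {}
        for dis, sub in trend_history.groupby("disease"):
            t = sub["year_offset"].to_numpy(float)
            fi = float(np.exp(np.polyfit(t, np.log(sub["incidence_index"].to_numpy(float)), 1)[0]))
            fc = float(
                np.exp(np.polyfit(t, np.log(sub["case_fatality_index"].to_numpy(float)), 1)[0])
            )
            factors[dis] = (fi, fc)
        return cls(factors=factors, years=years)

    def multiplier(self, disease: str, year: int) -> tuple[float, float]:
        fi, fc = self.factors.get(disease, (1.0, 1.0))
        k = min(year, self.years)
        return fi**k, fc**k


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discount rate for QALYs and healthcare costs (3.5% default;
    1.5% and 0% as sensitivity alternates)."""

    rate: float = 0.035

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("discount rate must be >= 0")


def discount_stream(values: np.ndarray, rate: float) -> float:
    """Present value of an annual stream; t = 0 at simulation start."""
    values = np.asarray(values, dtype=float)
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    t = np.arange(values.shape[0])
    return float(np.sum(values / (1.0 + rate) ** t))


def run_disease_lifetable(
    incidence: np.ndarray,
    case_fatality: np.ndarray,
    incidence_multiplier: np.ndarray | None = None,
    init_prevalence: np.ndarray | float = 0.0,
) -> dict[str, np.ndarray]:
    """3-state disease process (healthy / diseased / dead-from-disease).

    ``incidence`` and ``case_fatality`` are annual rates of shape (T,) or
    (T, C) for C cohorts simulated in parallel; ``incidence_multiplier``
    (same shape) rescales incidence (e.g. 1 - PIF).  The cohort starts
    with ``init_prevalence`` diseased.  Within a cycle, incident cases
    are not exposed to case fatality until the next cycle.

    Returns states ``h``, ``d``, ``dead`` of shape (T+1, ...) — which
    conserve h + d + dead = 1 exactly — and flows ``new_cases``,
    ``disease_deaths`` of shape (T, ...).
    """
    I = np.asarray(incidence, dtype=float)
    F = np.asarray(case_fatality, dtype=float)
    if I.shape != F.shape:
        raise ValueError("incidence and case_fatality must have the same shape")
    mult = np.ones_like(I) if incidence_multiplier is None else np.asarray(incidence_multiplier, float)
    T = I.shape[0]
    rest = I.shape[1:]

    h = np.empty((T + 1,) + rest)
    d = np.empty((T + 1,) + rest)
    dead = np.empty((T + 1,) + rest)
    new_cases = np.empty((T,) + rest)
    disease_deaths = np.empty((T,) + rest)

    d[0] = np.broadcast_to(np.asarray(init_prevalence, dtype=float), rest)
    h[0] = 1.0 - d[0]
    dead[0] = 0.0

    for t in range(T):
        qi = -np.expm1(-I[t] * mult[t])
        qf = -np.expm1(-F[t])
        new = h[t] * qi
        dd = d[t] * qf
        new_cases[t] = new
        disease_deaths[t] = dd
        h[t + 1] = h[t] - new
        d[t + 1] = d[t] + new - dd
        dead[t + 1] = dead[t] + dd

    return {
        "h": h,
        "d": d,
        "dead": dead,
        "new_cases": new_cases,
        "disease_deaths": disease_deaths,
    }


def build_pif_result(
    epi: EpiInputs,
    delta_sbp_by_sex: dict[str, float],
    timeline: InterventionTimeline,
    n_years: int,
    rr_z: dict[str, float] | None = None,
    bin_width: float = 1.0,
) -> dict[tuple[str, str], np.ndarray]:
    """Population impact fractions keyed by (disease, sex).

    Each value is an array of shape (terminal_age + 1, n_years):
    ``pif[age, year]`` for the intervention's lagged, phased-in SBP shift.
    ``delta_sbp_by_sex`` is the full (end-of-phase-in) SBP reduction in
    mmHg; ``rr_z`` optionally perturbs the RR slopes (Monte Carlo).
    """
    rr_z = rr_z or {}
    ages = np.arange(epi.terminal_age + 1)
    frac = np.array([timeline.exposure_fraction(t) for t in range(n_years)])
    levels = sorted(set(frac))
    out: dict[tuple[str, str], np.ndarray] = {}
    for dis in epi.diseases:
        rrf = RelativeRiskFunction.from_table(epi.rr_slopes, dis, z=rr_z.get(dis, 0.0))
        for sex in epi.sexes:
            sbp = (
                epi.sbp[epi.sbp["sex"] == sex]
                .set_index("age")
                .reindex(ages)
                .sort_index()
            )
            full_shift = delta_sbp_by_sex[sex] * timeline.effect_scale
            means = sbp["mean_sbp"].to_numpy(float)
            sds = sbp["sd_sbp"].to_numpy(float)
            slopes = np.array([rrf.slope_at(float(a)) for a in ages])
            by_level = {}
            for lev in levels:
                shift = full_shift * lev
                by_level[lev] = pif_curve(
                    means,
                    sds,
                    slopes,
                    shift,
                    tmrel=rrf.tmrel,
                    bin_width=bin_width,
                    low_pad=max(10.0, abs(shift) + 5.0),
                )
            arr = np.empty((len(ages), n_years))
            for t in range(n_years):
                arr[:, t] = by_level[frac[t]]
            out[(dis, sex)] = arr
    return out


def pif_result_to_frame(pifs: dict[tuple[str, str], np.ndarray]) -> pd.DataFrame:
    """Tidy (disease, sex, age, year, pif) export of a PIF result."""
    frames = []
    for (dis, sex), arr in pifs.items():
        n_ages, n_years = arr.shape
        idx = pd.MultiIndex.from_product(
            [range(n_ages), range(n_years)], names=["age", "year"]
        )
        frames.append(
            pd.DataFrame({"pif": arr.ravel()}, index=idx)
            .reset_index()
            .assign(disease=dis, sex=sex)
        )
    return pd.concat(frames, ignore_index=True)[["disease", "sex", "age", "year", "pif"]]


def _by_age(df: pd.DataFrame, col: str, terminal_age: int) -> np.ndarray:
    out = df.set_index("age")[col].reindex(np.arange(terminal_age + 1))
    if out.isna().any():
        raise ValueError(f"column {col} does not cover ages 0..{terminal_age}")
    return out.to_numpy(float)


@dataclass
class PopulationResult:
    """Baseline vs scenario population outcomes.

    ``outcomes``: tidy table keyed by (sex, horizon, measure, simulation)
    where simulation is baseline / scenario / difference and difference
    is scenario minus baseline.  ``series``: per (sex, run, measure)
    absolute annual streams.  ``survival``: per (sex, run) matrices
    l[t, cohort] plus cohort counts, used for life-expectancy deltas.
    """

    outcomes: pd.DataFrame
    series: dict[tuple[str, str, str], np.ndarray] = field(repr=False, default_factory=dict)
    survival: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = field(
        repr=False, default_factory=dict
    )
    horizons: dict[str, int] = field(default_factory=dict)
    discount_rate: float = 0.035


def run_population(
    epi: EpiInputs,
    pifs: dict[tuple[str, str], np.ndarray],
    timeline: InterventionTimeline,
    trends: TrendSpec,
    discount: DiscountSpec = DiscountSpec(),
    horizons: tuple[int, ...] = (20, 30),
    min_age: int = 18,
    utility_scale: float = 1.0,
    decrement_scale: dict[str, float] | None = None,
    cost_scale: dict[str, float] | None = None,
) -> PopulationResult:
    """Closed-cohort proportional multistate lifetable, baseline vs scenario.

    Every adult age/sex cohort alive at year 0 is simulated to the
    terminal age.  The scenario differs from baseline only through the
    incidence multipliers ``1 - PIF``; incidence and case-fatality trends
    apply to both runs.  Case and death counts over the year horizons are
    undiscounted; QALYs and costs are discounted at ``discount.rate``
    from year 0.  ``utility_scale`` / ``decrement_scale`` / ``cost_scale``
    support Monte Carlo perturbations.
    """
    A = epi.terminal_age
    diseases = epi.diseases
    decrement_scale = decrement_scale or {}
    cost_scale = cost_scale or {}

    n_steps = A - min_age + 1  # year indices 0..n_steps-1
    for h in horizons:
        if h > n_steps:
            warnings.warn(
                f"horizon {h}y exceeds the terminal age for the oldest cohort; truncated",
                stacklevel=2,
            )
    horizon_map = {f"{h}y": min(h, n_steps) for h in horizons}
    horizon_map["lifetime"] = n_steps

    series: dict[tuple[str, str, str], np.ndarray] = {}
    survival: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}

    for sex in epi.sexes:
        pop = epi.population[epi.population["sex"] == sex]
        m_all = _by_age(pop, "all_cause_mortality", A)
        counts = _by_age(pop, "count", A)
        util = epi.utilities[epi.utilities["sex"] == sex]
        u_base = _by_age(util, "baseline_utility", A) * utility_scale

        dis_rates = {}
        cause_sum = np.zeros(A + 1)
        for dis in diseases:
            sub = epi.disease_rates[
                (epi.disease_rates["disease"] == dis) & (epi.disease_rates["sex"] == sex)
            ]
            dis_rates[dis] = {
                "incidence": _by_age(sub, "incidence", A),
                "case_fatality": _by_age(sub, "case_fatality", A),
                "prevalence": _by_age(sub, "prevalence", A),
                "cause_mortality": _by_age(sub, "cause_mortality", A),
                "decrement": _by_age(util, f"decrement_{dis}", A)
                * decrement_scale.get(dis, 1.0),
                "cost": _by_age(
                    epi.costs[(epi.costs["disease"] == dis) & (epi.costs["sex"] == sex)],
                    "annual_cost",
                    A,
                )
                * cost_scale.get(dis, 1.0),
            }
            cause_sum += dis_rates[dis]["cause_mortality"]
        m_other = np.maximum(m_all - cause_sum, 0.0)

        a0 = np.arange(min_age, A + 1)  # cohort starting ages
        nc = len(a0)
        cohort_counts = counts[a0]
        age_idx = np.minimum(a0[None, :] + np.arange(n_steps)[:, None], A)  # (T, nc)

        for run in ("baseline", "scenario"):
            # disease submodels (proportions, vectorized over cohorts)
            m_d = {}
            prev_frac = {}
            case_frac = {}
            for dis in diseases:
                r = dis_rates[dis]
                ti = np.array([trends.multiplier(dis, t)[0] for t in range(n_steps)])
                tc = np.array([trends.multiplier(dis, t)[1] for t in range(n_steps)])
                I = r["incidence"][age_idx] * ti[:, None]
                F = r["case_fatality"][age_idx] * tc[:, None]
                if run == "scenario":
                    pif = pifs[(dis, sex)]  # (A+1, n_years)
                    mult = 1.0 - pif[age_idx, np.arange(n_steps)[:, None]]
                else:
                    mult = None
                lt = run_disease_lifetable(
                    I, F, incidence_multiplier=mult, init_prevalence=r["prevalence"][a0]
                )
                alive = lt["h"][:-1] + lt["d"][:-1]  # start-of-year alive (T, nc)
                safe = np.where(alive > 0, alive, 1.0)
                frac_dead = np.where(alive > 0, lt["disease_deaths"] / safe, 0.0)
                m_d[dis] = -np.log1p(-np.minimum(frac_dead, 1 - 1e-15))
                prev_frac[dis] = np.where(alive > 0, lt["d"][:-1] / safe, 0.0)
                case_frac[dis] = np.where(alive > 0, lt["new_cases"] / safe, 0.0)

            # main lifetable
            m_tot = m_other[age_idx] + sum(m_d[dis] for dis in diseases)
            l = np.empty((n_steps + 1, nc))
            l[0] = 1.0
            deaths = np.empty((n_steps, nc))
            terminal = age_idx == A
            for t in range(n_steps):
                q = -np.expm1(-m_tot[t])
                q = np.where(terminal[t], 1.0, q)
                deaths[t] = l[t] * q
                l[t + 1] = l[t] - deaths[t]

            py = l[:-1]  # person-years: alive at start of year, no half-cycle
            safe_m = np.where(m_tot > 0, m_tot, 1.0)
            qaly_w = np.maximum(
                u_base[age_idx] - sum(prev_frac[d_] * dis_rates[d_]["decrement"][age_idx]
                                      for d_ in diseases),
                0.0,
            )
            streams: dict[str, np.ndarray] = {
                "life_years": py,
                "total_deaths": deaths,
                "qalys": py * qaly_w,
                "costs": py * sum(
                    prev_frac[d_] * dis_rates[d_]["cost"][age_idx] for d_ in diseases
                ),
            }
            for dis in diseases:
                streams[f"{dis}_cases"] = py * case_frac[dis]
                share = np.where(m_tot > 0, m_d[dis] / safe_m, 0.0)
                streams[f"{dis}_deaths"] = deaths * share

            for name, arr in streams.items():
                series[(sex, run, name)] = arr @ cohort_counts  # absolute, per year
            survival[(sex, run)] = (l, cohort_counts)

    rows = []
    discounted = {"qalys", "costs"}
    for sex in epi.sexes:
        for hname, hyears in horizon_map.items():
            for name in sorted({k[2] for k in series if k[0] == sex}):
                vals = {}
                for run in ("baseline", "scenario"):
                    s = series[(sex, run, name)][:hyears]
                    if name in discounted:
                        vals[run] = discount_stream(s, discount.rate)
                    else:
                        vals[run] = float(s.sum())
                for run in ("baseline", "scenario"):
                    rows.append(
                        {"sex": sex, "horizon": hname, "measure": name,
                         "simulation": run, "value": vals[run]}
                    )
                rows.append(
                    {"sex": sex, "horizon": hname, "measure": name,
                     "simulation": "difference", "value": vals["scenario"] - vals["baseline"]}
                )
    outcomes = pd.DataFrame(rows)

    # pooled-sex rows
    pooled = (
        outcomes.groupby(["horizon", "measure", "simulation"], as_index=False)["value"]
        .sum()
        .assign(sex="both")
    )
    outcomes = pd.concat([outcomes, pooled], ignore_index=True)[
        ["sex", "horizon", "measure", "simulation", "value"]
    ]

    return PopulationResult(
        outcomes=outcomes,
        series=series,
        survival=survival,
        horizons=horizon_map,
        discount_rate=discount.rate,
    )


def life_expectancy_delta(result: PopulationResult) -> pd.DataFrame:
    """Population-weighted change in cohort life expectancy per sex.

    Life expectancy of a cohort is the sum over years of the start-of-year
    survival proportion (consistent with the engine's person-year
    convention); the delta is scenario minus baseline, also expressed in
    days (years x 365).
    """
    rows = []
    sexes = sorted({k[0] for k in result.survival})
    for sex in sexes:
        le = {}
        for run in ("baseline", "scenario"):
            l, counts = result.survival[(sex, run)]
            per_cohort = l[:-1].sum(axis=0)  # LE of each cohort in years
            le[run] = float(np.dot(per_cohort, counts) / counts.sum())
        dy = le["scenario"] - le["baseline"]
        rows.append(
            {"sex": sex, "delta_years": dy, "delta_days": dy * 365.0,
             "baseline_le": le["baseline"], "scenario_le": le["scenario"]}
        )
    return pd.DataFrame(rows)
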