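"""Monte Carlo propagation of parameter uncertainty.

Each uncertain parameter carries a central value and a 95% CI and is
drawn from a distribution family chosen by its support: lognormal for
positive slopes and relative risks (quantile-matched to the CI bounds),
beta for utility decrements, gamma for cost multipliers, zero-truncated
normal for the intervention effect.  Parameters are drawn independently;
each gets its own seed substream so results are reproducible and
individual parameters can be perturbed without disturbing the others'
draws.  The reported point estimate is the central-parameter run, not
the Monte Carlo mean; intervals are 2.5/97.5 percentiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .lifetable import (
    DiscountSpec,
    EpiInputs,
    InterventionTimeline,
    PopulationResult,
    TrendSpec,
    build_pif_result,
    life_expectancy_delta,
    run_population,
)
from .risk import SaltBPSlope, delta_sbp

logger = logging.getLogger(__name__)

__all__ = [
    "Param",
    "sample_parameters",
    "default_parameter_spec",
    "run_monte_carlo",
    "UncertaintySummary",
]

_Z975 = 1.959963984540054


@dataclass(frozen=True)
class Param:
    """One uncertain parameter: central value, 95% CI and family.

    Families: ``lognormal`` (CI quantile-matched on the log scale),
    ``beta`` (moment-matched on [0, 1]), ``gamma`` (moment-matched,
    positive), ``normal_trunc0`` (normal truncated at 0), ``normal``.
    A degenerate CI (low == high == central) yields a point mass.
    """

    central: float
    ci_low: float
    ci_high: float
    family: str = "normal"

    def __post_init__(self) -> None:
        if not self.ci_low <= self.central <= self.ci_high:
            raise ValueError("parameter central value must lie within its CI")


def _sample_one(p: Param, n: int, rng: np.random.Generator) -> np.ndarray:
    if p.ci_low == p.ci_high:
        return np.full(n, p.central)
    sd = (p.ci_high - p.ci_low) / (2 * _Z975)
    if p.family == "lognormal":
        if p.ci_low <= 0:
            raise ValueError("lognormal parameter requires a positive CI")
        mu = 0.5 * (np.log(p.ci_low) + np.log(p.ci_high))
        sigma = (np.log(p.ci_high) - np.log(p.ci_low)) / (2 * _Z975)
        return np.exp(mu + sigma * rng.standard_normal(n))
    if p.family == "beta":
        m = p.central
        if not 0 < m < 1:
            raise ValueError("beta parameter central value must be in (0, 1)")
        var = sd**2
        if var >= m * (1 - m):
            raise ValueError("beta parameter CI too wide for its mean")
        k = m * (1 - m) / var - 1
        return rng.beta(m * k, (1 - m) * k, size=n)
    if p.family == "gamma":
        if p.central <= 0:
            raise ValueError("gamma parameter requires a positive central value")
        shape = (p.central / sd) ** 2
        return rng.gamma(shape, sd**2 / p.central, size=n)
    if p.family == "normal_trunc0":
        a = (0.0 - p.central) / sd
        return truncnorm.rvs(a, np.inf, loc=p.central, scale=sd, size=n, random_state=rng)
    if p.family == "normal":
        return p.central + sd * rng.standard_normal(n)
    raise ValueError(f"unknown distribution family {p.family!r}")


def sample_parameters(
    spec: dict[str, Param], n_iter: int, seed: int
) -> pd.DataFrame:
    """Draw matrix of parameter values, one column per parameter.

    Each parameter receives an independent child stream of ``seed``
    (keyed by its position in name order), so the full matrix is
    reproducible and marginals do not interact.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    names = sorted(spec)
    ss = np.random.SeedSequence(seed).spawn(len(names))
    cols = {}
    for name, child in zip(names, ss):
        cols[name] = _sample_one(spec[name], n_iter, np.random.default_rng(child))
    return pd.DataFrame(cols)


def default_parameter_spec(
    epi: EpiInputs,
    delta_salt_ci: dict[str, tuple[float, float, float]],
    slope: SaltBPSlope = SaltBPSlope(),
    utility_scale_ci: tuple[float, float] = (0.96, 1.04),
    decrement_ci_frac: float = 0.25,
    cost_ci_frac: float = 0.2,
) -> dict[str, Param]:
    """Monte Carlo parameter spec for a full pipeline run.

    ``delta_salt_ci[sex] = (central, lo, hi)`` in g/day, from the diet
    stage's bootstrap.  RR slope uncertainty enters as a standard-normal
    quantile per disease, applied to the band CIs in the RR table.
    """
    spec: dict[str, Param] = {
        "salt_bp_slope": Param(slope.central, slope.ci_low, slope.ci_high, "lognormal"),
        "utility_scale": Param(1.0, *utility_scale_ci, "normal_trunc0"),
    }
    for sex, (c, lo, hi) in delta_salt_ci.items():
        spec[f"delta_salt_{sex}"] = Param(c, lo, hi, "normal_trunc0")
    diseases = epi.diseases
    dec = (
        epi.utilities.iloc[0]
        if not epi.utilities.empty
        else None
    )
    for dis in diseases:
        spec[f"rr_z_{dis}"] = Param(0.0, -_Z975, _Z975, "normal")
        d0 = float(epi.utilities[f"decrement_{dis}"].iloc[0])
        spec[f"decrement_{dis}"] = Param(
            d0, d0 * (1 - decrement_ci_frac), d0 * (1 + decrement_ci_frac), "beta"
        )
        spec[f"cost_scale_{dis}"] = Param(
            1.0, 1 - cost_ci_frac, 1 + cost_ci_frac, "gamma"
        )
    return spec


@dataclass
class UncertaintySummary:
    """Point estimates with percentile 95% uncertainty intervals.

    ``table`` columns: outcome (sex|horizon|measure), point, lo95, hi95,
    n_iter, seed.  ``point_result`` is the central-parameter population
    run the point estimates come from.
    """

    table: pd.DataFrame
    point_result: PopulationResult = field(repr=False, default=None)
    n_failed: int = 0


def _outcome_vector(
    result: PopulationResult, dsbp: dict[str, float], dsalt: dict[str, float]
) -> dict[str, float]:
    out = {}
    diff = result.outcomes[result.outcomes["simulation"] == "difference"]
    for _, r in diff.iterrows():
        out[f"{r['sex']}|{r['horizon']}|{r['measure']}"] = float(r["value"])
    for _, r in life_expectancy_delta(result).iterrows():
        out[f"{r['sex']}|lifetime|le_days"] = float(r["delta_days"])
    for sex, v in dsbp.items():
        out[f"{sex}|delta_sbp"] = v
    for sex, v in dsalt.items():
        out[f"{sex}|delta_salt"] = v
    return out


def run_monte_carlo(
    epi: EpiInputs,
    timeline: InterventionTimeline,
    trends: TrendSpec,
    discount: DiscountSpec,
    delta_salt_ci: dict[str, tuple[float, float, float]],
    n_iter: int = 500,
    seed: int = 0,
    spec: dict[str, Param] | None = None,
    slope: SaltBPSlope = SaltBPSlope(),
    horizons: tuple[int, ...] = (20, 30),
    bin_width: float = 1.0,
    min_age: int = 18,
) -> UncertaintySummary:
    """Re-run the risk and lifetable stages under parameter draws.

    Iterations whose inputs fail validation are skipped and logged;
    more than 1% failures aborts the analysis.
    """
    if spec is None:
        spec = default_parameter_spec(epi, delta_salt_ci, slope=slope)
    draws = sample_parameters(spec, n_iter, seed)
    diseases = epi.diseases
    n_years = epi.terminal_age - min_age + 1

    def one_run(
        slope_val: float,
        dsalt: dict[str, float],
        rr_z: dict[str, float],
        u_scale: float,
        dec_scale: dict[str, float],
        c_scale: dict[str, float],
    ) -> tuple[PopulationResult, dict[str, float]]:
        sl = SaltBPSlope(
            central=slope_val,
            ci_low=min(slope.ci_low, slope_val),
            ci_high=max(slope.ci_high, slope_val),
            salt_ref_g=slope.salt_ref_g,
        )
        dsbp = {sex: delta_sbp(v, sl) for sex, v in dsalt.items()}
        pifs = build_pif_result(epi, dsbp, timeline, n_years, rr_z=rr_z, bin_width=bin_width)
        result = run_population(
            epi,
            pifs,
            timeline,
            trends,
            discount,
            horizons=horizons,
            min_age=min_age,
            utility_scale=u_scale,
            decrement_scale=dec_scale,
            cost_scale=c_scale,
        )
        return result, dsbp

    central_dsalt = {sex: v[0] for sex, v in delta_salt_ci.items()}
    point_result, point_dsbp = one_run(
        slope.central,
        central_dsalt,
        {d: 0.0 for d in diseases},
        1.0,
        {d: 1.0 for d in diseases},
        {d: 1.0 for d in diseases},
    )
    point = _outcome_vector(point_result, point_dsbp, central_dsalt)

    samples: dict[str, list[float]] = {k: [] for k in point}
    n_failed = 0
    for i in range(n_iter):
        row = draws.iloc[i]
        try:
            dec0 = {
                d: float(epi.utilities[f"decrement_{d}"].iloc[0]) for d in diseases
            }
            res, dsbp = one_run(
                float(row["salt_bp_slope"]),
                {sex: float(row[f"delta_salt_{sex}"]) for sex in delta_salt_ci},
                {d: float(row[f"rr_z_{d}"]) for d in diseases},
                float(row["utility_scale"]),
                {d: float(row[f"decrement_{d}"]) / dec0[d] if dec0[d] > 0 else 1.0
                 for d in diseases},
                {d: float(row[f"cost_scale_{d}"]) for d in diseases},
            )
        except Exception as exc:  # noqa: BLE001 - iteration-level robustness
            n_failed += 1
            logger.warning("Monte Carlo iteration %d failed: %s", i, exc)
            if n_failed > max(1, 0.01 * n_iter):
                raise RuntimeError(
                    f"{n_failed} Monte Carlo iterations failed; aborting"
                ) from exc
            continue
        vec = _outcome_vector(
            res, dsbp, {sex: float(row[f"delta_salt_{sex}"]) for sex in delta_salt_ci}
        )
        for k, v in vec.items():
            samples[k].append(v)

    rows = []
    for k in sorted(point):
        arr = np.asarray(samples[k])
        lo, hi = np.percentile(arr, [2.5, 97.5]) if len(arr) else (np.nan, np.nan)
        rows.append(
            {
                "outcome": k,
                "point": point[k],
                "lo95": float(lo),
                "hi95": float(hi),
                "n_iter": n_iter - n_failed,
                "seed": seed,
            }
        )
    return UncertaintySummary(
        table=pd.DataFrame(rows), point_result=point_result, n_failed=n_failed
    )
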