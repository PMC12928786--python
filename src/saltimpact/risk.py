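"""Risk stage: salt -> systolic blood pressure -> disease incidence.

A population mean salt change is converted to a mean systolic blood
pressure (SBP) shift with a linear dose-response slope.  The SBP shift is
then propagated to ischemic heart disease (IHD) and ischemic stroke
incidence through a population impact fraction (PIF) computed on a
discretized normal exposure distribution:

    PIF = (sum_i p_i RR_i - sum_i p'_i RR_i) / sum_i p_i RR_i

where ``p_i`` / ``p'_i`` are baseline / scenario prevalences of SBP
exposure category ``i`` and ``RR_i`` the relative risk of that category.
Relative risks are 1 at or below a theoretical-minimum-risk exposure
level (TMREL, 115 mmHg) and log-linear in SBP above it, with age-specific
slopes supplied as data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

__all__ = [
    "SaltBPSlope",
    "SBPDistribution",
    "RelativeRiskFunction",
    "delta_sbp",
    "discretize_exposure",
    "compute_pif",
    "pif_for_shift",
    "scenario_incidence",
]


@dataclass(frozen=True)
class SaltBPSlope:
    """Linear salt -> SBP dose response.

    ``central`` mmHg of SBP reduction per ``salt_ref_g`` grams/day of salt
    reduction (the reference quantum is 100 mmol sodium = 2.30 g sodium =
    5.88 g salt).  The 95% CI bounds are carried for Monte Carlo draws.
    """

    central: float = 5.80
    ci_low: float = 2.45
    ci_high: float = 9.15
    salt_ref_g: float = 5.88

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.central <= self.ci_high):
            raise ValueError("central slope must lie within its CI")
        if self.salt_ref_g <= 0:
            raise ValueError("salt_ref_g must be positive")


def delta_sbp(delta_salt: float, slope: SaltBPSlope = SaltBPSlope()) -> float:
    """SBP change (mmHg) for a salt change (g/day); linear, sign-preserving."""
    return float(delta_salt) * slope.central / slope.salt_ref_g


@dataclass(frozen=True)
class SBPDistribution:
    """Normal SBP exposure distribution for one age/sex stratum.

    The discretization grid spans ``n_sd`` standard deviations either side
    of the mean, extended downward by ``low_pad`` mmHg so that baseline and
    downward-shifted distributions share identical exposure categories.
    """

    mean: float
    sd: float
    bin_width: float = 1.0
    n_sd: float = 6.0
    low_pad: float = 10.0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("SBP sd must be positive")
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")

    def edges(self) -> np.ndarray:
        lo = self.mean - self.n_sd * self.sd - self.low_pad
        hi = self.mean + self.n_sd * self.sd
        n = int(np.ceil((hi - lo) / self.bin_width))
        return lo + self.bin_width * np.arange(n + 1)


def discretize_exposure(
    dist: SBPDistribution, shift: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Category midpoints and prevalences of the (shifted) SBP distribution.

    ``shift`` reduces the mean; the grid is taken from the unshifted
    distribution so that ``p`` and ``p'`` share categories.  Prevalences
    are renormalized to sum to exactly 1.
    """
    edges = dist.edges()
    cdf = ndtr((edges - (dist.mean - shift)) / dist.sd)
    p = np.diff(cdf)
    total = p.sum()
    if total <= 0:
        raise ValueError("degenerate exposure discretization")
    mid = 0.5 * (edges[:-1] + edges[1:])
    return mid, p / total


class RelativeRiskFunction:
    """Relative risk of a disease as a function of SBP and age.

    log RR is ``slope(age) * max(SBP - tmrel, 0)``; slopes are a step
    function over age bands supplied as data (log RR per mmHg, with CI
    bounds used for Monte Carlo draws).
    """

    def __init__(
        self,
        disease: str,
        age_lo: np.ndarray,
        age_hi: np.ndarray,
        slope: np.ndarray,
        tmrel: float = 115.0,
    ) -> None:
        age_lo = np.asarray(age_lo, dtype=float)
        age_hi = np.asarray(age_hi, dtype=float)
        slope = np.asarray(slope, dtype=float)
        if not (len(age_lo) == len(age_hi) == len(slope)):
            raise ValueError("age band arrays must have equal length")
        if np.any(slope < 0):
            raise ValueError("log-RR slopes must be nonnegative")
        order = np.argsort(age_lo)
        self.disease = disease
        self.age_lo = age_lo[order]
        self.age_hi = age_hi[order]
        self.slope = slope[order]
        self.tmrel = float(tmrel)

    @classmethod
    def from_table(
        cls,
        table: pd.DataFrame,
        disease: str,
        tmrel: float = 115.0,
        z: float = 0.0,
    ) -> "RelativeRiskFunction":
        """Build from an ``rr_slopes`` table (disease, age_lo, age_hi,
        log_rr_per_mmhg, log_rr_lo, log_rr_hi).

        ``z`` is a standard-normal quantile applied on the log scale to all
        bands jointly (z=0 gives the central slopes); band CIs are treated
        as 95% intervals of a lognormal slope distribution.
        """
        sub = table[table["disease"] == disease]
        if sub.empty:
            raise KeyError(f"no RR slopes for disease {disease!r}")
        central = sub["log_rr_per_mmhg"].to_numpy(float)
        if z == 0.0:
            slope = central
        else:
            lo = sub["log_rr_lo"].to_numpy(float)
            hi = sub["log_rr_hi"].to_numpy(float)
            with np.errstate(divide="ignore"):
                sigma = np.where(hi > lo, (np.log(hi) - np.log(lo)) / (2 * 1.959963984540054), 0.0)
            slope = central * np.exp(z * sigma)
        return cls(
            disease,
            sub["age_lo"].to_numpy(float),
            sub["age_hi"].to_numpy(float),
            slope,
            tmrel=tmrel,
        )

    def slope_at(self, age: float) -> float:
        idx = np.searchsorted(self.age_lo, age, side="right") - 1
        idx = int(np.clip(idx, 0, len(self.slope) - 1))
        return float(self.slope[idx])

    def rr(self, sbp: np.ndarray, age: float) -> np.ndarray:
        """RR at SBP value(s) for a given age; 1 at or below the TMREL."""
        excess = np.maximum(np.asarray(sbp, dtype=float) - self.tmrel, 0.0)
        return np.exp(self.slope_at(age) * excess)


def compute_pif(
    p: np.ndarray, p_prime: np.ndarray, rr: np.ndarray
) -> float:
    """Population impact fraction from categorical exposure prevalences.

    Raises if the baseline risk-weighted exposure sum is zero (PIF
    undefined).
    """
    p = np.asarray(p, dtype=float)
    p_prime = np.asarray(p_prime, dtype=float)
    rr = np.asarray(rr, dtype=float)
    if p.shape != p_prime.shape or p.shape != rr.shape:
        raise ValueError("p, p_prime and rr must share categories")
    base = float(np.dot(p, rr))
    if base == 0.0:
        raise ZeroDivisionError("undefined PIF: baseline sum(p*RR) is zero")
    return (base - float(np.dot(p_prime, rr))) / base


def pif_for_shift(
    dist: SBPDistribution,
    rr_func: RelativeRiskFunction,
    age: float,
    shift: float,
) -> float:
    """PIF for a uniform downward SBP shift in one age/sex stratum."""
    if shift == 0.0:
        return 0.0
    mid, p = discretize_exposure(dist)
    _, p_prime = discretize_exposure(dist, shift=shift)
    return compute_pif(p, p_prime, rr_func.rr(mid, age))


def pif_curve(
    means: np.ndarray,
    sds: np.ndarray,
    slopes: np.ndarray,
    shift: float,
    tmrel: float = 115.0,
    bin_width: float = 1.0,
    n_sd: float = 6.0,
    low_pad: float = 10.0,
) -> np.ndarray:
    """PIF for a uniform downward shift, vectorized over age strata.

    ``means``/``sds``/``slopes`` are per-age SBP means, SDs and log-RR
    slopes.  Equivalent to calling :func:`pif_for_shift` per age (all
    strata share the widest grid, which only adds empty top bins).
    """
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    slopes = np.asarray(slopes, float)
    if shift == 0.0:
        return np.zeros_like(means)
    lo = means - n_sd * sds - low_pad
    span = 2 * n_sd * float(sds.max()) + low_pad
    k = int(np.ceil(span / bin_width))
    edges = lo[:, None] + bin_width * np.arange(k + 1)[None, :]
    z0 = (edges - means[:, None]) / sds[:, None]
    zs = (edges - (means - shift)[:, None]) / sds[:, None]
    p = np.diff(ndtr(z0), axis=1)
    p_prime = np.diff(ndtr(zs), axis=1)
    p /= p.sum(axis=1, keepdims=True)
    p_prime /= p_prime.sum(axis=1, keepdims=True)
    mid = 0.5 * (edges[:, :-1] + edges[:, 1:])
    rr = np.exp(slopes[:, None] * np.maximum(mid - tmrel, 0.0))
    base = np.einsum("ij,ij->i", p, rr)
    return (base - np.einsum("ij,ij->i", p_prime, rr)) / base


def scenario_incidence(i_baseline: float, pif: float) -> float:
    """Scenario incidence I' = I * (1 - PIF), clamped to [0, 1]."""
    if not 0.0 <= i_baseline <= 1.0:
        raise ValueError("baseline incidence must be a rate in [0, 1]")
    i_prime = i_baseline * (1.0 - pif)
    if i_prime > 1.0:
        warnings.warn("scenario incidence exceeded 1 and was clamped", stacklevel=2)
        return 1.0
    return max(i_prime, 0.0)
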