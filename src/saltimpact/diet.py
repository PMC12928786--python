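"""Diet-survey reformulation microsimulation.

Computes per-person baseline daily salt intake from food-diary records,
substitutes category-specific salt targets to obtain a full-compliance
scenario intake, rescales both by stratified under-reporting correction
factors (diary intake vs a urinary-sodium-based reference), and
summarizes survey-weighted changes with bootstrap confidence intervals.

Records flagged ``homemade`` or ``unmatched`` (foods outside the target
categories) contribute to neither baseline nor scenario intake.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AGE_GROUPS",
    "age_group_label",
    "baseline_salt",
    "apply_targets",
    "stratified_means",
    "correction_factors",
    "summarize_change",
    "SaltChangeSummary",
]

#: Calibration age groups for the under-reporting correction.
AGE_GROUPS: tuple[tuple[int, int], ...] = ((19, 34), (35, 49), (50, 64))

EXCLUDED_CATEGORIES = ("homemade", "unmatched")


def age_group_label(age: float) -> str:
    """Nearest calibration age group (persons outside 19-64 are assigned
    the closest group's factor)."""
    for lo, hi in AGE_GROUPS:
        if lo <= age <= hi:
            return f"{lo}-{hi}"
    if age < AGE_GROUPS[0][0]:
        lo, hi = AGE_GROUPS[0]
    else:
        lo, hi = AGE_GROUPS[-1]
    return f"{lo}-{hi}"


def _check_records(records: pd.DataFrame) -> None:
    bad = records[(records["grams_per_day"] < 0) | (records["salt_per_100g"] < 0)]
    if not bad.empty:
        first = bad.iloc[0]
        raise ValueError(
            "negative grams_per_day or salt_per_100g in food record "
            f"(person {first['person_id']}, food {first['food_id']})"
        )


def baseline_salt(records: pd.DataFrame, persons: pd.DataFrame) -> pd.Series:
    """Per-person daily salt intake in g/day.

    Sums ``grams_per_day * salt_per_100g / 100`` over each person's
    matched, non-homemade records; persons with no qualifying records
    get 0.  Indexed by ``person_id`` covering every person.
    """
    _check_records(records)
    unknown = set(records["person_id"]) - set(persons["person_id"])
    if unknown:
        raise ValueError(f"food records reference unknown persons: {sorted(unknown)[:5]}")
    qual = records[~records["category_id"].isin(EXCLUDED_CATEGORIES)]
    salt = qual["grams_per_day"] * qual["salt_per_100g"] / 100.0
    per_person = salt.groupby(qual["person_id"]).sum()
    return per_person.reindex(persons["person_id"], fill_value=0.0).astype(float)


def apply_targets(
    records: pd.DataFrame,
    targets: pd.DataFrame,
    assumed_serving_g: float | None = None,
    max_servings: float | None = None,
) -> pd.DataFrame:
    """Replace each matched record's salt content with its category target.

    Per-100g categories: ``salt_per_100g`` is set to the target
    (unconditionally, even if already below it).  Per-serving categories
    (out-of-home sector): the record's total daily salt is set to the
    target, treating the reported grams as exactly one serving; when
    ``assumed_serving_g`` is given the number of servings is
    ``max(1, grams / assumed_serving_g)``, optionally capped at
    ``max_servings``.  Homemade/unmatched records pass through unchanged.
    """
    _check_records(records)
    matched = records[~records["category_id"].isin(EXCLUDED_CATEGORIES)]
    missing = set(matched["category_id"]) - set(targets["category_id"])
    if missing:
        raise KeyError(f"categories missing from target table: {sorted(missing)}")

    out = records.merge(
        targets[["category_id", "target_type", "target_value"]],
        on="category_id",
        how="left",
    )
    out.index = records.index

    per100 = out["target_type"] == "per_100g"
    out.loc[per100, "salt_per_100g"] = out.loc[per100, "target_value"]

    serving = out["target_type"] == "per_serving"
    grams = out.loc[serving, "grams_per_day"]
    n_serv = pd.Series(1.0, index=grams.index)
    if assumed_serving_g is not None:
        n_serv = np.maximum(grams / assumed_serving_g, 1.0)
        if max_servings is not None:
            n_serv = np.minimum(n_serv, max_servings)
    total_salt = out.loc[serving, "target_value"] * n_serv
    # keep the g/100g representation: total = grams * salt_per_100g / 100
    with np.errstate(divide="ignore", invalid="ignore"):
        new_content = np.where(grams > 0, total_salt * 100.0 / grams, 0.0)
    out.loc[serving, "salt_per_100g"] = new_content

    return out.drop(columns=["target_type", "target_value"])


def _weighted_mean(values: np.ndarray, weights: np.ndarray) -> float:
    wsum = weights.sum()
    if wsum <= 0:
        raise ValueError("all-zero survey weights")
    return float(np.dot(values, weights) / wsum)


def stratified_means(
    intake: pd.Series, persons: pd.DataFrame
) -> pd.DataFrame:
    """Survey-weighted mean intake by calibration stratum (age-group x sex).

    Strata with no persons are omitted with a warning.
    """
    df = persons.copy()
    df["intake"] = intake.reindex(df["person_id"]).to_numpy()
    df["age_group"] = df["age"].map(age_group_label)
    rows = []
    for (sex, grp), sub in df.groupby(["sex", "age_group"], sort=True):
        rows.append(
            {
                "sex": sex,
                "age_group": grp,
                "estimated_mean": _weighted_mean(
                    sub["intake"].to_numpy(), sub["survey_weight"].to_numpy()
                ),
                "n": len(sub),
            }
        )
    present = {(r["sex"], r["age_group"]) for r in rows}
    for sex in df["sex"].unique():
        for lo, hi in AGE_GROUPS:
            if (sex, f"{lo}-{hi}") not in present:
                logger.warning("stratum %s %s-%s has no persons; omitted", sex, lo, hi)
    return pd.DataFrame(rows)


def correction_factors(
    reference: pd.DataFrame, estimated: pd.DataFrame
) -> pd.DataFrame:
    """Under-reporting correction factor per stratum.

    ``factor = reference_mean / estimated_mean``, where the reference is
    the urinary-sodium-based published mean and the estimate the
    survey-weighted diary mean.  Both inputs are keyed by (sex,
    age_group).
    """
    merged = reference.merge(estimated, on=["sex", "age_group"], how="inner")
    if len(merged) < len(reference):
        raise ValueError("estimated means do not cover all reference strata")
    if (merged["estimated_mean"] <= 0).any():
        bad = merged[merged["estimated_mean"] <= 0].iloc[0]
        raise ZeroDivisionError(
            f"undefined correction factor: zero estimated mean in stratum "
            f"({bad['sex']}, {bad['age_group']})"
        )
    merged["factor"] = merged["reference_mean"] / merged["estimated_mean"]
    return merged[["sex", "age_group", "factor"]]


def person_factors(persons: pd.DataFrame, factors: pd.DataFrame) -> pd.Series:
    """Per-person correction factor via the (nearest) calibration stratum."""
    lookup = factors.set_index(["sex", "age_group"])["factor"]
    keys = list(zip(persons["sex"], persons["age"].map(age_group_label)))
    vals = [lookup.get(k, 1.0) for k in keys]
    return pd.Series(vals, index=persons["person_id"], dtype=float)


@dataclass
class SaltChangeSummary:
    """Stratified salt-change summary with bootstrap CIs.

    ``table`` has one row per group (overall, each sex, sex x age group)
    with survey-weighted baseline/scenario means, absolute and relative
    change, and percentile-bootstrap 95% CI bounds.  ``per_person`` holds
    the corrected per-person intakes for distribution plots.
    """

    table: pd.DataFrame
    per_person: pd.DataFrame = field(repr=False, default=None)


def _boot_stats(
    b: np.ndarray, s: np.ndarray, w: np.ndarray, n_boot: int, rng: np.random.Generator
) -> dict[str, float]:
    n = len(b)
    bm = _weighted_mean(b, w)
    sm = _weighted_mean(s, w)
    row = {
        "baseline_mean": bm,
        "scenario_mean": sm,
        "abs_change": bm - sm,
        "rel_change": (bm - sm) / bm if bm > 0 else 0.0,
        "n": n,
    }
    idx = rng.integers(0, n, size=(n_boot, n))
    wb = w[idx]
    wsum = wb.sum(axis=1)
    bms = (b[idx] * wb).sum(axis=1) / wsum
    sms = (s[idx] * wb).sum(axis=1) / wsum
    abss = bms - sms
    with np.errstate(divide="ignore", invalid="ignore"):
        rels = np.where(bms > 0, abss / bms, 0.0)
    for name, arr in (
        ("baseline_mean", bms),
        ("scenario_mean", sms),
        ("abs_change", abss),
        ("rel_change", rels),
    ):
        lo, hi = np.percentile(arr, [2.5, 97.5])
        row[f"{name}_lo"] = float(lo)
        row[f"{name}_hi"] = float(hi)
    return row


def summarize_change(
    baseline: pd.Series,
    scenario: pd.Series,
    persons: pd.DataFrame,
    factors: pd.DataFrame | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> SaltChangeSummary:
    """Survey-weighted salt-change summary by sex, age group and overall.

    The under-reporting correction is applied to both baseline and
    scenario intakes (it therefore cancels from the relative change).
    CIs are percentile intervals from a survey-weighted person-level
    bootstrap (persons resampled with replacement, weights carried).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    df = persons.copy().reset_index(drop=True)
    pid = df["person_id"]
    if factors is not None:
        f = person_factors(df, factors).to_numpy()
    else:
        f = np.ones(len(df))
    b = baseline.reindex(pid).to_numpy() * f
    s = scenario.reindex(pid).to_numpy() * f
    w = df["survey_weight"].to_numpy(float)
    df["age_group"] = df["age"].map(age_group_label)

    rng = np.random.default_rng(seed)
    groups: list[tuple[str, np.ndarray]] = [("overall", np.ones(len(df), dtype=bool))]
    for sex in sorted(df["sex"].unique()):
        groups.append((sex, (df["sex"] == sex).to_numpy()))
    for sex in sorted(df["sex"].unique()):
        for lo, hi in AGE_GROUPS:
            grp = f"{lo}-{hi}"
            mask = ((df["sex"] == sex) & (df["age_group"] == grp)).to_numpy()
            if mask.any():
                groups.append((f"{sex} {grp}", mask))

    rows = []
    for name, mask in groups:
        row = _boot_stats(b[mask], s[mask], w[mask], n_boot, rng)
        row["group"] = name
        rows.append(row)
    table = pd.DataFrame(rows).set_index("group").reset_index()

    per_person = pd.DataFrame(
        {
            "person_id": pid,
            "sex": df["sex"],
            "age_group": df["age_group"],
            "survey_weight": w,
            "baseline_intake": b,
            "scenario_intake": s,
        }
    )
    return SaltChangeSummary(table=table, per_person=per_person)
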