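"""CSV schemas and read/write helpers.

All tabular I/O is plain CSV.  File schemas:

- persons.csv: person_id, sex, age, survey_weight
- food_records.csv: person_id, food_id, category_id, grams_per_day,
  salt_per_100g, takeaway_flag  (category_id may be ``homemade`` or
  ``unmatched`` for excluded records)
- targets.csv: category_id, sector, target_type, target_value
- reference_intakes.csv: sex, age_group, reference_mean
- population.csv: sex, age, count, all_cause_mortality
- disease_rates.csv: disease, sex, age, incidence, case_fatality,
  prevalence, cause_mortality
- sbp.csv: sex, age, mean_sbp, sd_sbp
- utilities.csv: sex, age, baseline_utility, decrement_<disease>...
- costs.csv: disease, sex, age, annual_cost
- rr_slopes.csv: disease, age_lo, age_hi, log_rr_per_mmhg, log_rr_lo,
  log_rr_hi
- trend_history.csv: disease, year_offset, incidence_index,
  case_fatality_index
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

from .lifetable import EpiInputs

DIET_FILES = ("persons", "food_records", "targets", "reference_intakes")
EPI_FILES = (
    "population",
    "disease_rates",
    "sbp",
    "utilities",
    "costs",
    "rr_slopes",
    "trend_history",
)

_REQUIRED_COLUMNS = {
    "persons": ["person_id", "sex", "age", "survey_weight"],
    "food_records": [
        "person_id", "food_id", "category_id", "grams_per_day",
        "salt_per_100g", "takeaway_flag",
    ],
    "targets": ["category_id", "sector", "target_type", "target_value"],
    "reference_intakes": ["sex", "age_group", "reference_mean"],
    "population": ["sex", "age", "count", "all_cause_mortality"],
    "disease_rates": [
        "disease", "sex", "age", "incidence", "case_fatality",
        "prevalence", "cause_mortality",
    ],
    "sbp": ["sex", "age", "mean_sbp", "sd_sbp"],
    "utilities": ["sex", "age", "baseline_utility"],
    "costs": ["disease", "sex", "age", "annual_cost"],
    "rr_slopes": [
        "disease", "age_lo", "age_hi", "log_rr_per_mmhg", "log_rr_lo", "log_rr_hi",
    ],
    "trend_history": [
        "disease", "year_offset", "incidence_index", "case_fatality_index",
    ],
}


def _read(path: Path, name: str) -> pd.DataFrame:
    f = path / f"{name}.csv"
    if not f.exists():
        raise FileNotFoundError(f"missing input file {f}")
    df = pd.read_csv(f)
    missing = set(_REQUIRED_COLUMNS[name]) - set(df.columns)
    if missing:
        raise ValueError(f"{f} is missing required columns: {sorted(missing)}")
    return df


def write_diet_csvs(
    outdir: str | Path,
    persons: pd.DataFrame,
    records: pd.DataFrame,
    targets: pd.DataFrame,
    reference: pd.DataFrame,
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    persons.to_csv(outdir / "persons.csv", index=False)
    records.to_csv(outdir / "food_records.csv", index=False)
    targets.to_csv(outdir / "targets.csv", index=False)
    reference.to_csv(outdir / "reference_intakes.csv", index=False)


def read_diet_csvs(
    indir: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    indir = Path(indir)
    return (
        _read(indir, "persons"),
        _read(indir, "food_records"),
        _read(indir, "targets"),
        _read(indir, "reference_intakes"),
    )


def write_epi_csvs(outdir: str | Path, epi: EpiInputs) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    epi.population.to_csv(outdir / "population.csv", index=False)
    epi.disease_rates.to_csv(outdir / "disease_rates.csv", index=False)
    epi.sbp.to_csv(outdir / "sbp.csv", index=False)
    epi.utilities.to_csv(outdir / "utilities.csv", index=False)
    epi.costs.to_csv(outdir / "costs.csv", index=False)
    epi.rr_slopes.to_csv(outdir / "rr_slopes.csv", index=False)
    if epi.trend_history is not None:
        epi.trend_history.to_csv(outdir / "trend_history.csv", index=False)


def read_epi_csvs(indir: str | Path) -> EpiInputs:
    indir = Path(indir)
    trend = None
    if (indir / "trend_history.csv").exists():
        trend = _read(indir, "trend_history")
    return EpiInputs(
        population=_read(indir, "population"),
        disease_rates=_read(indir, "disease_rates"),
        sbp=_read(indir, "sbp"),
        utilities=_read(indir, "utilities"),
        costs=_read(indir, "costs"),
        rr_slopes=_read(indir, "rr_slopes"),
        trend_history=trend,
    )


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
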