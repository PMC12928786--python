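import numpy as np
import pandas as pd
import pytest

from saltimpact.diet import apply_targets, baseline_salt
from saltimpact.synthetic import (
    SyntheticConfig,
    generate_diet_survey,
    generate_epi_inputs,
    generate_reference_intakes,
)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(seed=1, n_persons=200, n_categories=20)


@pytest.fixture(scope="session")
def survey(small_config):
    return generate_diet_survey(small_config)


@pytest.fixture(scope="session")
def reference(survey, small_config):
    persons, records, _ = survey
    return generate_reference_intakes(persons, records, small_config)


@pytest.fixture(scope="session")
def intakes(survey):
    persons, records, targets = survey
    baseline = baseline_salt(records, persons)
    scenario = baseline_salt(apply_targets(records, targets), persons)
    return baseline, scenario


@pytest.fixture(scope="session")
def epi():
    return generate_epi_inputs(SyntheticConfig(seed=1))


@pytest.fixture()
def toy_persons():
    return pd.DataFrame(
        {
            "person_id": [1, 2],
            "sex": ["female", "male"],
            "age": [30, 40],
            "survey_weight": [1.0, 3.0],
        }
    )


def make_records(rows):
    df = pd.DataFrame(
        rows,
        columns=["person_id", "food_id", "category_id", "grams_per_day", "salt_per_100g"],
    )
    df["takeaway_flag"] = df["category_id"].astype(str).str.startswith("O")
    return df
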