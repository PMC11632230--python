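import numpy as np
import pandas as pd
import pytest

from frailtyburst import CohortDesign, default_schema, simulate_cohort

BASE_ROW = {
    "person_id": "p1",
    "burst": 1,
    "wave": 1,
    "age_baseline": 75.0,
    "sex": "men",
    "education": "low",
    "living_alone": "no",
    "social_support": "low",
    "interview_mode": "personal",
    "bedrest": "no",
    "fall": "no",
    "hospital": "no",
    "dead_between_bursts": "no",
}


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def rendered_cohort():
    """Small cohort with rendered deficit items (valid DeficitPanel input)."""
    return simulate_cohort(CohortDesign(n_persons=36), seed=11)


@pytest.fixture(scope="session")
def fi_cohort():
    """Mid-size cohort carrying the latent FI directly (no deficit rendering)."""
    return simulate_cohort(CohortDesign(n_persons=80, render_deficits=False), seed=5)


def toy_panel_frame(schema, records):
    """Long panel frame from per-row overrides; deficits default to 0."""
    rows = []
    for rec in records:
        row = dict(BASE_ROW)
        row.update({name: 0.0 for name in schema.names})
        row.update(rec)
        rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def toy_frame(schema):
    def _make(records):
        return toy_panel_frame(schema, records)

    return _make
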