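"""Shared fixtures: the reference synthetic scenario and small hand-built
logs.  Expensive artifacts (the default log, its feature table, a trained
model) are session-scoped so the suite builds them once."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import alertsuppress as ap


def make_events(rows: list[dict]) -> pd.DataFrame:
    """Build a wide event frame from sparse row dicts with sane defaults."""
    defaults = {
        "encounter_id": None, "patient_id": "P1", "clinician_id": "C1",
        "timestamp": "2017-01-02T09:00:00", "service_date": "2017-01-02",
        "visit_type": "scheduled", "is_initial_primary_care": False,
        "clinician_role": "physician", "clinician_specialty": "im",
        "clinician_age_band": "35-44", "clinician_sex": "F",
        "patient_age": 65, "patient_sex": "M",
        "prior_shingles_vaccine": False, "fired": True,
        "suppressed": False, "response_action": "none",
        "order_placed": False,
    }
    out = []
    for i, row in enumerate(rows):
        rec = {**defaults, "alert_id": f"A{i}", **row}
        if rec["encounter_id"] is None:
            rec["encounter_id"] = f"E{i}"
        out.append(rec)
    return pd.DataFrame(out)


@pytest.fixture(scope="session")
def default_config() -> ap.GeneratorConfig:
    return ap.GeneratorConfig()


@pytest.fixture(scope="session")
def default_log(default_config) -> ap.AlertLog:
    return ap.generate_log(default_config)


@pytest.fixture(scope="session")
def default_table(default_log) -> ap.FeatureTable:
    return ap.build_features(default_log)


@pytest.fixture(scope="session")
def default_split(default_table):
    return ap.split_by_clinician(default_table, ap.SplitSpec(seed=0))


@pytest.fixture(scope="session")
def trained_model(default_split):
    tr, va, _ = default_split
    return ap.train(tr, va)


@pytest.fixture(scope="session")
def validation_scored(default_split, trained_model):
    _, va, _ = default_split
    scores = ap.score(trained_model, va)
    return (va, scores,
            va.frame["label_interacted"].to_numpy(bool),
            va.frame["label_ordered"].to_numpy(bool))


@pytest.fixture(scope="session")
def small_pilot():
    """A cheap 2-week on/off pilot for pipeline unit tests."""
    from datetime import date
    gen = ap.GeneratorConfig(n_clinicians=80, n_patients=1500,
                             mean_encounters_per_day=30,
                             date_range=(date(2017, 5, 1),
                                         date(2017, 6, 30)),
                             seed=11)
    pipe = ap.PipelineConfig(window_start=date(2017, 5, 1),
                             pilot_weeks=2, seed=11)
    return ap.simulate_study(gen, pipe), gen, pipe
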