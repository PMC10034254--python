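import numpy as np
import pandas as pd
import pytest

from longsynth import (AttributeDef, BaselineDef, Cohort, CohortSchema,
                       simulate_cohort, small_spec)


@pytest.fixture(scope="session")
def toy_schema() -> CohortSchema:
    """Two event tables (lab, ED) plus a terminal label; one shared timing
    attribute and per-type attributes."""
    return CohortSchema(
        event_labels=["LAB", "ED", "EOS"],
        terminal_label="EOS",
        attributes=[
            AttributeDef(name="sojourn", n_bins=6),
            AttributeDef(name="lab_result", n_bins=4),
            AttributeDef(name="triage", categories=["1", "2", "3"]),
        ],
        relevance={
            "LAB": {"sojourn", "lab_result"},
            "ED": {"sojourn", "triage"},
            "EOS": {"sojourn"},
        },
        baseline_vars=[
            BaselineDef(name="age", n_bins=4),
            BaselineDef(name="sex", categories=["M", "F"]),
        ],
        table_priority=["LAB", "ED", "EOS"],
    )


def make_toy_cohort(schema, rng=None) -> Cohort:
    """A small hand-buildable cohort in harmonized form (dates, no sojourn)."""
    rng = rng or np.random.default_rng(0)
    baseline = pd.DataFrame({
        "pid": [0, 1, 2],
        "age": [30.0, 55.0, 70.0],
        "sex": ["M", "F", "F"],
    })
    rows = [
        (0, "LAB", 5, {"lab_result": 1.0}),
        (0, "ED", 8, {"triage": "2"}),
        (0, "LAB", 20, {"lab_result": 2.5}),
        (1, "ED", 0, {"triage": "1"}),
        (1, "ED", 0, {"triage": "3"}),
        (1, "LAB", 9, {"lab_result": 0.5}),
        (1, "EOS", 30, {}),
        (2, "LAB", 2, {"lab_result": 4.0}),
    ]
    recs = []
    for pid, label, date, attrs in rows:
        rec = {"pid": pid, "label": label, "date": float(date),
               "sojourn": np.nan, "lab_result": np.nan, "triage": np.nan}
        rec.update(attrs)
        recs.append(rec)
    events = pd.DataFrame(recs)
    events["pos"] = events.groupby("pid").cumcount()
    events = events[["pid", "pos", "label", "date", "sojourn",
                     "lab_result", "triage"]]
    return Cohort(baseline=baseline, events=events, schema=schema)


@pytest.fixture()
def toy_cohort(toy_schema) -> Cohort:
    return make_toy_cohort(toy_schema)


@pytest.fixture(scope="session")
def sim_spec():
    return small_spec(n=400, max_length=40, seed=0)


@pytest.fixture(scope="session")
def sim_cohort(sim_spec) -> Cohort:
    return simulate_cohort(sim_spec, seed=7)
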