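"""Shared fixtures: a default registry, small hand-built tables, and one
session-scoped simulation of the shipped configuration reused by the
fingerprint/scoring/cognition tests to keep the suite fast."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from morphprint import (
    MorphometryTable,
    SubjectRecord,
    build_default_registry,
    default_cohort_config,
    simulate_cohorts,
)
from morphprint.io_morphometry import DATA_COLUMNS, PROV_AGE_CORRECTED, PROV_NORMALIZED
from morphprint.pipeline import derive_fingerprint
from morphprint.preprocess import fit_age_model, preprocess_pipeline


@pytest.fixture(scope="session")
def registry():
    return build_default_registry()


def make_table(rows, subjects=None, provenance=frozenset()):
    """Build a MorphometryTable from (sid, region, hemi, metric, value) rows.

    Subjects default to controls aged 50 with ICV 1.5e6; pass a dict
    sid -> kwargs to override demographic fields.
    """
    subjects = subjects or {}
    ids = list(dict.fromkeys(r[0] for r in rows)) or list(subjects)
    records = []
    for sid in ids:
        kw = {
            "group": "control",
            "age": 50.0,
            "sex": "unknown",
            "cohort_tag": "t",
            "icv": 1.5e6,
        }
        kw.update(subjects.get(sid, {}))
        records.append(SubjectRecord(subject_id=sid, **kw))
    data = pd.DataFrame(rows, columns=DATA_COLUMNS)
    return MorphometryTable.from_records(records, data, provenance=provenance)


NORMALIZED = frozenset({PROV_AGE_CORRECTED, PROV_NORMALIZED})


@pytest.fixture(scope="session")
def default_sim():
    """One default-configuration simulation shared across the suite."""
    return simulate_cohorts(default_cohort_config(), seed=7)


@pytest.fixture(scope="session")
def derived(default_sim):
    """Fingerprint derivation products for the shared simulation."""
    table = default_sim.table
    controls = table.select_group("control")
    cases = table.select_group("AD")
    fp, stats, controls_n = derive_fingerprint(controls, cases)
    model = fit_age_model(controls)
    exposed_n = preprocess_pipeline(table.select_group("exposed"), model)
    return {
        "fingerprint": fp,
        "stats": stats,
        "controls": controls,
        "controls_n": controls_n,
        "exposed_n": exposed_n,
        "model": model,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
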