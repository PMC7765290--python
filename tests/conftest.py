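import numpy as np
import pandas as pd
import pytest

from psamris import (
    CohortTable,
    ScoreSchema,
    build_full_schema,
    build_reduced_schema,
    enumerate_items,
)


@pytest.fixture(scope="session")
def full_schema() -> ScoreSchema:
    return build_full_schema()


@pytest.fixture(scope="session")
def sps_schema(full_schema) -> ScoreSchema:
    return build_reduced_schema(full_schema, ["MCP3", "MCP4", "PIP4"], name="sPsAMRIS")


def build_cohort(schema, overrides=None, raters=("R1",), patients=("P1", "P2"),
                 timepoints=("t0", "t1"), allow_fractional=False):
    """All-zero complete cohort with explicit item overrides.

    ``overrides`` maps (patient, timepoint, joint, site, feature) -> value
    (applied for every rater) or with a rater as sixth element of the key.
    """
    overrides = overrides or {}
    rows = []
    for pid in patients:
        for tp in timepoints:
            for rid in raters:
                for js, feat in enumerate_items(schema):
                    key = (pid, tp, js.joint.token, js.site, feat.name)
                    value = overrides.get(key + (rid,), overrides.get(key, 0))
                    rows.append((pid, tp, rid, js.joint.token, js.site,
                                 feat.name, value))
    frame = pd.DataFrame(rows, columns=["patient_id", "timepoint", "rater_id",
                                        "joint", "site", "feature", "value"])
    return CohortTable.from_frame(frame, schema, allow_fractional=allow_fractional)


def overall_change_cohort(schema, changes, joint="MCP2", feature="bone_erosion"):
    """Cohort of len(changes) patients whose overall change (t0 - t1) equals
    the given integers, carried on a single bone-erosion item."""
    overrides = {}
    patients = []
    for i, delta in enumerate(changes):
        pid = f"P{i + 1}"
        patients.append(pid)
        t0 = max(delta, 0)
        t1 = max(-delta, 0)
        overrides[(pid, "t0", joint, "site_A", feature)] = t0
        overrides[(pid, "t1", joint, "site_A", feature)] = t1
    return build_cohort(schema, overrides, patients=tuple(patients))


@pytest.fixture()
def make_cohort():
    return build_cohort


@pytest.fixture()
def make_change_cohort():
    return overall_change_cohort


@pytest.fixture(scope="session")
def adam_cohort():
    """One study-shaped synthetic cohort, shared across tests."""
    from psamris import adam_like_config, generate

    return generate(adam_like_config(11))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
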