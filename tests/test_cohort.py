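"""Cohort I/O, rater resolution, aggregation and descriptive summaries."""

import math

import pandas as pd
import pytest

from psamris import (
    CohortTable,
    CohortValidationError,
    aggregate,
    read_cohort,
    resolve_raters,
    summarize,
    write_cohort,
)
from psamris.cohort import COLUMNS, field_values


def _frame(rows):
    return pd.DataFrame(rows, columns=list(COLUMNS))


class TestValidation:
    def test_valid_rows(self, full_schema):
        frame = _frame([
            ("P1", "t0", "R1", "MCP2", "site_A", "synovitis", 1),
            ("P1", "t0", "R1", "MCP2", "site_B", "synovitis", 0),
            ("P1", "t0", "R1", "MCP2", "site_A", "bone_erosion", 7),
        ])
        cohort = CohortTable.from_frame(frame, full_schema)
        assert len(cohort) == 3

    def test_out_of_range_cites_bound(self, full_schema):
        frame = _frame([("P1", "t0", "R1", "MCP2", "site_A", "synovitis", 4)])
        with pytest.raises(CohortValidationError, match="0–3"):
            CohortTable.from_frame(frame, full_schema)

    def test_duplicate_key(self, full_schema):
        row = ("P1", "t0", "R1", "MCP2", "site_A", "synovitis", 1)
        with pytest.raises(CohortValidationError, match="duplicate"):
            CohortTable.from_frame(_frame([row, row]), full_schema)

    def test_unknown_tokens(self, full_schema):
        with pytest.raises(CohortValidationError, match="joint"):
            CohortTable.from_frame(
                _frame([("P1", "t0", "R1", "MCP9", "site_A", "synovitis", 1)]),
                full_schema)
        with pytest.raises(CohortValidationError, match="feature"):
            CohortTable.from_frame(
                _frame([("P1", "t0", "R1", "MCP2", "site_A", "enthesitis", 1)]),
                full_schema)

    def test_followup_only_patient_rejected(self, full_schema):
        frame = _frame([("P1", "t1", "R1", "MCP2", "site_A", "synovitis", 1)])
        with pytest.raises(CohortValidationError, match="no baseline"):
            CohortTable.from_frame(frame, full_schema)

    def test_site_aliases_canonicalized(self, full_schema):
        frame = _frame([
            ("P1", "t0", "R1", "MCP2", "proximal", "bone_erosion", 2),
            ("P1", "t0", "R1", "MCP2", "palmar", "synovitis", 1),
        ])
        cohort = CohortTable.from_frame(frame, full_schema)
        assert sorted(cohort.frame["site"]) == ["site_A", "site_B"]


class TestRoundTrip:
    def test_read_write_identity(self, tmp_path, full_schema, make_cohort):
        cohort = make_cohort(full_schema,
                             {("P1", "t0", "MCP3", "site_A", "bone_erosion"): 5})
        path = write_cohort(cohort, tmp_path / "c.csv")
        again = read_cohort(path, full_schema)
        pd.testing.assert_frame_equal(
            cohort.frame.sort_values(list(COLUMNS)).reset_index(drop=True),
            again.frame.sort_values(list(COLUMNS)).reset_index(drop=True))

    def test_canonical_bytes_under_shuffle(self, tmp_path, full_schema, make_cohort):
        cohort = make_cohort(full_schema, raters=("R1", "R2"))
        shuffled = CohortTable(
            frame=cohort.frame.sample(frac=1, random_state=5).reset_index(drop=True),
            schema=full_schema)
        a = write_cohort(cohort, tmp_path / "a.csv").read_bytes()
        b = write_cohort(shuffled, tmp_path / "b.csv").read_bytes()
        assert a == b

    def test_error_reports_csv_line(self, tmp_path, full_schema):
        path = tmp_path / "bad.csv"
        path.write_text("patient_id,timepoint,rater_id,joint,site,feature,value\n"
                        "P1,t0,R1,MCP2,site_A,synovitis,4\n")
        with pytest.raises(CohortValidationError, match="row 2"):
            read_cohort(path, full_schema)


class TestResolveRaters:
    def test_identical_raters(self, full_schema, make_cohort):
        key = ("P1", "t0", "MCP2", "site_A", "synovitis")
        cohort = make_cohort(full_schema, {key: 2}, raters=("R1", "R2"))
        for policy in ("mean", "consensus_required", "single:R2"):
            out = resolve_raters(cohort, policy)
            assert len(out.raters) == 1
            hit = out.frame.query(
                "patient_id=='P1' and timepoint=='t0' and joint=='MCP2' "
                "and site=='site_A' and feature=='synovitis'")
            assert hit["value"].item() == 2

    def test_mean_rounds_half_away_from_zero(self, full_schema, make_cohort):
        key = ("P1", "t0", "MCP2", "site_A", "synovitis")
        cohort = make_cohort(full_schema, {key + ("R1",): 1, key + ("R2",): 2},
                             raters=("R1", "R2"))
        out = resolve_raters(cohort, "mean")
        hit = out.frame.query("feature=='synovitis' and joint=='MCP2' "
                              "and site=='site_A' and patient_id=='P1' "
                              "and timepoint=='t0'")
        assert hit["value"].item() == 2  # 1.5 rounds away from zero

        fractional = resolve_raters(cohort, "mean", round_to_grid=False)
        hit = fractional.frame.query("feature=='synovitis' and joint=='MCP2' "
                                     "and site=='site_A' and patient_id=='P1' "
                                     "and timepoint=='t0'")
        assert hit["value"].item() == pytest.approx(1.5)

    def test_mean_is_idempotent(self, full_schema, make_cohort):
        key = ("P1", "t0", "MCP2", "site_A", "bone_erosion")
        cohort = make_cohort(full_schema, {key + ("R1",): 3, key + ("R2",): 6},
                             raters=("R1", "R2"))
        once = resolve_raters(cohort, "mean")
        twice = resolve_raters(once, "mean")
        pd.testing.assert_frame_equal(
            once.frame.sort_values(list(COLUMNS)).reset_index(drop=True),
            twice.frame.sort_values(list(COLUMNS)).reset_index(drop=True))

    def test_consensus_required_disagreement(self, full_schema, make_cohort):
        key = ("P1", "t0", "MCP2", "site_A", "synovitis")
        cohort = make_cohort(full_schema, {key + ("R1",): 1, key + ("R2",): 2},
                             raters=("R1", "R2"))
        with pytest.raises(CohortValidationError, match="disagreement"):
            resolve_raters(cohort, "consensus_required")

        with_consensus = make_cohort(
            full_schema,
            {key + ("R1",): 1, key + ("R2",): 2, key + ("consensus",): 2},
            raters=("R1", "R2", "consensus"))
        out = resolve_raters(with_consensus, "consensus_required")
        hit = out.frame.query("feature=='synovitis' and joint=='MCP2' "
                              "and site=='site_A' and timepoint=='t0' "
                              "and patient_id=='P1'")
        assert hit["value"].item() == 2

    def test_missing_rater_cells(self, full_schema, make_cohort):
        cohort = make_cohort(full_schema, raters=("R1", "R2"))
        broken = CohortTable(frame=cohort.frame.iloc[:-1], schema=full_schema)
        with pytest.raises(CohortValidationError):
            resolve_raters(broken, "mean")


class TestAggregate:
    def test_all_zero(self, full_schema, make_cohort):
        aggs = aggregate(make_cohort(full_schema))
        assert all(a.overall == 0 for a in aggs)
        assert all(v == 0 for a in aggs for v in a.per_feature.values())

    def test_single_item_propagates(self, full_schema, make_cohort):
        cohort = make_cohort(full_schema,
                             {("P1", "t0", "MCP3", "site_A", "bone_erosion"): 7})
        agg = {(a.patient_id, a.timepoint): a for a in aggregate(cohort)}
        hit = agg[("P1", "t0")]
        assert hit.overall == 7
        assert hit.per_joint["MCP3"] == 7
        assert hit.per_feature["bone_erosion"] == 7
        assert hit.per_joint_feature[("MCP3", "bone_erosion")] == 7
        assert agg[("P1", "t1")].overall == 0

    def test_reduced_schema_equals_restricted_sum(self, full_schema, sps_schema,
                                                  make_cohort):
        overrides = {
            ("P1", "t0", "MCP3", "site_A", "bone_erosion"): 4,
            ("P1", "t0", "DIP5", "site_B", "synovitis"): 3,
        }
        cohort = make_cohort(full_schema, overrides)
        reduced = {(a.patient_id, a.timepoint): a.overall
                   for a in aggregate(cohort, sps_schema)}
        # oracle: sum full-cohort values over the selected joints only
        df = cohort.frame
        expect = df[df.joint.isin(sps_schema.joint_tokens)].groupby(
            ["patient_id", "timepoint"])["value"].sum()
        for key, val in reduced.items():
            assert val == expect[key]

    def test_missing_item_is_error(self, full_schema, make_cohort):
        cohort = make_cohort(full_schema)
        broken = CohortTable(frame=cohort.frame.iloc[:-1], schema=full_schema)
        with pytest.raises(CohortValidationError, match="missing item"):
            aggregate(broken)
        # permissive mode imputes zero instead
        aggs = aggregate(broken, missing="zero")
        assert all(a.overall == 0 for a in aggs)

    def test_multi_rater_is_error(self, full_schema, make_cohort):
        cohort = make_cohort(full_schema, raters=("R1", "R2"))
        with pytest.raises(CohortValidationError, match="rater"):
            aggregate(cohort)

    def test_linearity(self, full_schema, make_cohort, rng):
        keys = [("P1", "t0", "MCP2", "site_A", "synovitis"),
                ("P1", "t0", "PIP3", "site_B", "bone_edema"),
                ("P2", "t1", "DIP4", "site_A", "bone_erosion")]
        a_vals = {k: int(v) for k, v in zip(keys, rng.integers(0, 2, 3))}
        b_vals = {k: int(v) for k, v in zip(keys, rng.integers(0, 2, 3))}
        sum_vals = {k: a_vals[k] + b_vals[k] for k in keys}
        get = lambda cohort: {(a.patient_id, a.timepoint): a.overall
                              for a in aggregate(cohort)}
        a = get(make_cohort(full_schema, a_vals))
        b = get(make_cohort(full_schema, b_vals))
        s = get(make_cohort(full_schema, sum_vals))
        assert all(s[k] == a[k] + b[k] for k in s)


class TestSummarize:
    def test_hand_example(self):
        s = summarize([2, 4, 4, 4, 5, 5, 7, 9])
        assert s.mean == 5.0
        assert s.median == 4.5
        assert s.min == 2 and s.max == 9

    def test_constant_and_single(self):
        assert summarize([3, 3, 3]).sd == 0
        single = summarize([4])
        assert math.isnan(single.sd)
        assert (single.mean, single.min, single.max, single.median) == (4, 4, 4, 4)

    def test_sample_sd(self):
        assert summarize([1, 2, 3]).sd == pytest.approx(1.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            summarize([])

    def test_scope_extraction(self, full_schema, make_cohort):
        cohort = make_cohort(full_schema,
                             {("P1", "t0", "MCP3", "site_A", "bone_erosion"): 7})
        aggs = [a for a in aggregate(cohort) if a.timepoint == "t0"]
        assert field_values(aggs, "MCP3") == [7, 0]
        assert field_values(aggs, ("MCP3", "bone_erosion")) == [7, 0]
        assert summarize(aggs, "overall").max == 7
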