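"""Long-format item-level cohorts: read, validate, write, aggregate.

The universal input record is one ordinal score keyed by
(patient_id, timepoint, rater_id, joint, site, feature).  Cohorts live
in a pandas DataFrame wrapped together with the instrument schema they
validate against; aggregation produces overall, per-feature, per-joint
and per-(joint, feature) sum scores for every patient x timepoint.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .schema import (
    JointId,
    ScoreSchema,
    SchemaError,
    as_joint,
    max_total_score,
)

__all__ = [
    "COLUMNS",
    "TIMEPOINTS",
    "CohortValidationError",
    "CohortTable",
    "AggregateScore",
    "Summary",
    "read_cohort",
    "write_cohort",
    "resolve_raters",
    "aggregate",
    "summarize",
    "field_values",
    "normalize_scope",
]

log = logging.getLogger(__name__)

COLUMNS = ("patient_id", "timepoint", "rater_id", "joint", "site", "feature", "value")
KEY_COLUMNS = ("patient_id", "timepoint", "rater_id", "joint", "site", "feature")
TIMEPOINTS = ("t0", "t1")


class CohortValidationError(ValueError):
    """Validation failure carrying the full list of violations."""

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        preview = "\n  ".join(self.violations[:20])
        more = "" if len(self.violations) <= 20 else f"\n  ... {len(self.violations) - 20} more"
        super().__init__(f"cohort validation failed with {len(self.violations)} "
                         f"violation(s):\n  {preview}{more}")


def _row_label(idx, offset: int) -> str:
    try:
        return f"row {int(idx) + offset}"
    except (TypeError, ValueError):  # pragma: no cover
        return f"row {idx}"


@dataclass
class CohortTable:
    """A validated long-format cohort bound to its instrument schema."""

    frame: pd.DataFrame
    schema: ScoreSchema

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        schema: ScoreSchema,
        *,
        allow_fractional: bool = False,
        row_offset: int = 0,
    ) -> "CohortTable":
        """Validate and canonicalize a raw frame (site aliases, casing).

        ``row_offset`` shifts reported row numbers so CSV errors point at
        file lines (header = line 1).
        """
        violations: list[str] = []
        missing_cols = [c for c in COLUMNS if c not in frame.columns]
        if missing_cols:
            raise CohortValidationError(
                [f"missing column(s): {', '.join(missing_cols)}; expected header "
                 + ",".join(COLUMNS)]
            )
        df = frame.loc[:, list(COLUMNS)].copy()
        df["patient_id"] = df["patient_id"].astype(str)
        df["timepoint"] = df["timepoint"].astype(str).str.strip().str.lower()
        df["rater_id"] = df["rater_id"].astype(str)

        # token columns
        joint_map = {j.token: j.token for j in schema.joints}
        raw_joint = df["joint"].astype(str).str.strip().str.upper()
        bad = ~raw_joint.isin(joint_map)
        for idx, tok in raw_joint[bad].items():
            violations.append(f"{_row_label(idx, row_offset)}: unknown joint {tok!r} "
                              f"for schema {schema.name!r}")
        df["joint"] = raw_joint

        site_norm = df["site"].astype(str).str.strip().str.lower()
        from .schema import SITE_ALIASES  # local import to avoid cycle noise
        mapped = site_norm.map(SITE_ALIASES)
        bad = mapped.isna() | ~mapped.isin(schema.sites)
        for idx, tok in df["site"][bad].items():
            violations.append(f"{_row_label(idx, row_offset)}: unknown site token {tok!r}")
        df["site"] = mapped

        feat_ok = df["feature"].isin(schema.feature_names)
        for idx, tok in df["feature"][~feat_ok].items():
            violations.append(f"{_row_label(idx, row_offset)}: unknown feature {tok!r}")

        values = pd.to_numeric(df["value"], errors="coerce")
        for idx in df.index[values.isna()]:
            violations.append(f"{_row_label(idx, row_offset)}: non-numeric value "
                              f"{df.at[idx, 'value']!r}")
        df["value"] = values

        if not allow_fractional:
            frac = values.notna() & (values != values.round())
            for idx in df.index[frac]:
                violations.append(f"{_row_label(idx, row_offset)}: non-integer value "
                                  f"{values[idx]!r} on the ordinal grid")

        # range checks per feature
        fmin = {f.name: f.score_min for f in schema.features}
        fmax = {f.name: f.score_max for f in schema.features}
        lo = df["feature"].map(fmin)
        hi = df["feature"].map(fmax)
        out = values.notna() & feat_ok & ((values < lo) | (values > hi))
        for idx in df.index[out]:
            violations.append(
                f"{_row_label(idx, row_offset)}: {df.at[idx, 'feature']} value "
                f"{values[idx]:g} out of range {int(lo[idx])}–{int(hi[idx])}"
            )

        if violations:
            raise CohortValidationError(violations)

        dup = df.duplicated(subset=list(KEY_COLUMNS), keep=False)
        if dup.any():
            for idx in df.index[dup]:
                key = tuple(df.loc[idx, list(KEY_COLUMNS)])
                violations.append(f"{_row_label(idx, row_offset)}: duplicate key {key}")
            raise CohortValidationError(violations)

        bad_tp = ~df["timepoint"].isin(TIMEPOINTS)
        for idx in df.index[bad_tp]:
            violations.append(f"{_row_label(idx, row_offset)}: timepoint must be one of "
                              f"{TIMEPOINTS}, got {df.at[idx, 'timepoint']!r}")
        if violations:
            raise CohortValidationError(violations)

        t0 = set(df.loc[df.timepoint == "t0", "patient_id"])
        t1 = set(df.loc[df.timepoint == "t1", "patient_id"])
        orphans = sorted(t1 - t0)
        if orphans:
            raise CohortValidationError(
                [f"patient {p!r} has follow-up (t1) records but no baseline (t0)"
                 for p in orphans]
            )

        if not allow_fractional:
            df["value"] = df["value"].astype(int)
        return cls(frame=df.reset_index(drop=True), schema=schema)

    # -- views ------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    @property
    def patients(self) -> tuple[str, ...]:
        return tuple(sorted(self.frame["patient_id"].unique()))

    @property
    def raters(self) -> tuple[str, ...]:
        return tuple(sorted(self.frame["rater_id"].unique()))

    def complete_cases(self) -> tuple[str, ...]:
        """Patients with records at both timepoints."""
        df = self.frame
        t1 = set(df.loc[df.timepoint == "t1", "patient_id"])
        return tuple(p for p in self.patients if p in t1)

    def restrict(self, schema: ScoreSchema) -> "CohortTable":
        """Drop records outside ``schema`` (joint subset) without re-validating."""
        keep = self.frame["joint"].isin(schema.joint_tokens) & self.frame[
            "feature"
        ].isin(schema.feature_names) & self.frame["site"].isin(schema.sites)
        return CohortTable(frame=self.frame.loc[keep].reset_index(drop=True),
                           schema=schema)


def _canonical_sort(frame: pd.DataFrame, schema: ScoreSchema) -> pd.DataFrame:
    joint_rank = {tok: i for i, tok in enumerate(schema.joint_tokens)}
    feat_rank = {name: i for i, name in enumerate(schema.feature_names)}
    keyed = frame.assign(
        _j=frame["joint"].map(joint_rank),
        _f=frame["feature"].map(feat_rank),
    )
    keyed = keyed.sort_values(
        ["patient_id", "timepoint", "rater_id", "_j", "site", "_f"],
        kind="mergesort",
    )
    return keyed.drop(columns=["_j", "_f"]).reset_index(drop=True)


def read_cohort(path: Union[str, Path], schema: ScoreSchema) -> CohortTable:
    """Read and validate a cohort CSV (header required, UTF-8, comma-separated)."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    # +2: header occupies line 1, data starts at line 2
    return CohortTable.from_frame(raw, schema, row_offset=2)


def write_cohort(cohort: CohortTable, path: Union[str, Path]) -> Path:
    """Write the cohort CSV in canonical order (round-trips to identical bytes)."""
    path = Path(path)
    out = _canonical_sort(cohort.frame, cohort.schema)
    out.to_csv(path, index=False)
    return path


# -- rater resolution -----------------------------------------------------

def _round_half_away(values: pd.Series) -> pd.Series:
    return np.sign(values) * np.floor(np.abs(values) + 0.5)


def resolve_raters(
    cohort: CohortTable,
    policy: str,
    *,
    round_to_grid: bool = True,
) -> CohortTable:
    """Collapse a multi-rater cohort onto one effective rater.

    Policies:

    ``consensus_required``
        Raters must agree item-wise; disagreements are resolved by an
        explicit ``consensus`` rater, and are an error if it is absent.
    ``mean``
        Item-wise mean across raters, rounded half away from zero back
        onto the ordinal grid (``round_to_grid=False`` keeps fractions).
    ``single:<rater_id>``
        Take one rater's records verbatim.
    """
    df = cohort.frame
    key = [c for c in KEY_COLUMNS if c != "rater_id"]
    raters = list(cohort.raters)

    counts = df.groupby("rater_id", sort=True).size()
    if counts.nunique() > 1:
        raise CohortValidationError(
            [f"raters cover different item sets: {dict(counts)}"]
        )
    per_key = df.groupby(key, sort=False)["rater_id"].count()
    if per_key.nunique() > 1:
        raise CohortValidationError(["some keys are missing for one or more raters"])

    if policy.startswith("single:"):
        rid = policy.split(":", 1)[1]
        if rid not in raters:
            raise CohortValidationError([f"rater {rid!r} not present (have {raters})"])
        out = df.loc[df.rater_id == rid].copy()
    elif policy == "mean":
        grouped = df.groupby(key, sort=False, as_index=False)["value"].mean()
        if round_to_grid:
            grouped["value"] = _round_half_away(grouped["value"]).astype(int)
        grouped["rater_id"] = "mean"
        out = grouped
    elif policy == "consensus_required":
        has_consensus = "consensus" in raters
        scored = df.loc[df.rater_id != "consensus"]
        nun = scored.groupby(key, sort=False)["value"].nunique()
        disagree = nun[nun > 1]
        agreed = scored.groupby(key, sort=False, as_index=False)["value"].first()
        if len(disagree):
            if not has_consensus:
                keys = [str(tuple(k)) for k in disagree.index[:10]]
                raise CohortValidationError(
                    [f"disagreement without a 'consensus' rater at key {k}" for k in keys]
                )
            cons = df.loc[df.rater_id == "consensus", key + ["value"]]
            agreed = agreed.merge(cons, on=key, how="left", suffixes=("", "_cons"))
            mask = agreed.set_index(key).index.isin(disagree.index)
            missing = mask & agreed["value_cons"].isna().to_numpy()
            if missing.any():
                raise CohortValidationError(
                    ["disagreement key missing from consensus rater: "
                     + str(tuple(agreed.loc[i, key]))
                     for i in agreed.index[missing][:10]]
                )
            agreed.loc[mask, "value"] = agreed.loc[mask, "value_cons"]
            agreed = agreed.drop(columns=["value_cons"])
        agreed["rater_id"] = "consensus" if has_consensus else "agreed"
        agreed["value"] = agreed["value"].astype(int)
        out = agreed
    else:
        raise ValueError(f"unknown rater policy {policy!r}")

    out = out.loc[:, list(COLUMNS)].reset_index(drop=True)
    return CohortTable.from_frame(out, cohort.schema,
                                  allow_fractional=not round_to_grid)


# -- aggregation ----------------------------------------------------------

@dataclass
class AggregateScore:
    """Sum scores for one patient at one timepoint, at every granularity."""

    patient_id: str
    timepoint: str
    overall: float
    per_feature: dict[str, float] = field(default_factory=dict)
    per_joint: dict[str, float] = field(default_factory=dict)
    per_joint_feature: dict[tuple[str, str], float] = field(default_factory=dict)


def aggregate(
    cohort: CohortTable,
    schema: Optional[ScoreSchema] = None,
    *,
    missing: str = "error",
) -> list[AggregateScore]:
    """Sum item scores per patient x timepoint.

    Passing a reduced ``schema`` restricts the records first, so the
    simplified score is the full cohort aggregated under the reduced
    instrument.  Every schema item must be present for each patient and
    timepoint unless ``missing='zero'`` (imputation is logged loudly).
    """
    schema = schema or cohort.schema
    work = cohort.restrict(schema) if schema is not cohort.schema else cohort
    df = work.frame
    if df["rater_id"].nunique() > 1:
        raise CohortValidationError(
            [f"aggregate needs a single effective rater; found {work.raters}; "
             "apply resolve_raters first"]
        )

    expected = schema.item_count
    sizes = df.groupby(["patient_id", "timepoint"], sort=True).size()
    short = sizes[sizes != expected]
    if len(short):
        if missing == "error":
            msgs = []
            full_keys = {
                (j.token, s, f.name)
                for j in schema.joints for s in schema.sites for f in schema.features
            }
            for (pid, tp) in short.index[:5]:
                have = set(map(tuple, df.loc[
                    (df.patient_id == pid) & (df.timepoint == tp),
                    ["joint", "site", "feature"]].to_numpy()))
                gone = sorted(full_keys - have)[:5]
                msgs.append(f"patient {pid!r} {tp}: {expected - sizes[(pid, tp)]} "
                            f"missing item(s), e.g. {gone}")
            raise CohortValidationError(msgs)
        log.warning("aggregate: imputing 0 for missing items in %d patient-timepoint "
                    "group(s) (missing='zero')", len(short))

    jf = df.groupby(["patient_id", "timepoint", "joint", "feature"],
                    sort=True)["value"].sum()
    results: list[AggregateScore] = []
    joint_tokens = schema.joint_tokens
    feature_names = schema.feature_names
    for (pid, tp), group in jf.groupby(level=[0, 1], sort=True):
        cell = group.droplevel([0, 1])
        pjf = {(j, f): float(cell.get((j, f), 0.0))
               for j in joint_tokens for f in feature_names}
        per_joint = {j: sum(pjf[(j, f)] for f in feature_names) for j in joint_tokens}
        per_feature = {f: sum(pjf[(j, f)] for j in joint_tokens) for f in feature_names}
        overall = sum(per_joint.values())
        ceiling = max_total_score(schema)
        if not 0 <= overall <= ceiling:  # pragma: no cover - guarded by validation
            raise CohortValidationError(
                [f"patient {pid!r} {tp}: overall {overall} outside [0, {ceiling}]"]
            )
        results.append(AggregateScore(pid, tp, overall, per_feature, per_joint, pjf))
    return results


# -- descriptive summary --------------------------------------------------

Scope = Union[str, JointId, tuple]


def normalize_scope(scope: Scope) -> tuple:
    """Normalize a scope spec to ('overall',) / ('feature', f) / ('joint', j)
    / ('joint_feature', j, f)."""
    if isinstance(scope, tuple):
        if len(scope) == 1 and scope[0] == "overall":
            return ("overall",)
        if len(scope) == 2 and str(scope[0]).lower() == "feature":
            return ("feature", str(scope[1]))
        if len(scope) == 2 and str(scope[0]).lower() == "joint":
            return ("joint", as_joint(scope[1]).token)
        if len(scope) == 2:
            return ("joint_feature", as_joint(scope[0]).token, str(scope[1]))
        if len(scope) == 3 and scope[0] == "joint_feature":
            return ("joint_feature", as_joint(scope[1]).token, str(scope[2]))
        raise ValueError(f"cannot interpret scope {scope!r}")
    if isinstance(scope, JointId):
        return ("joint", scope.token)
    text = str(scope)
    if text == "overall":
        return ("overall",)
    try:
        return ("joint", as_joint(text).token)
    except SchemaError:
        return ("feature", text)


def field_values(aggregates: Sequence[AggregateScore], scope: Scope) -> list[float]:
    norm = normalize_scope(scope)
    if norm[0] == "overall":
        return [a.overall for a in aggregates]
    if norm[0] == "feature":
        return [a.per_feature[norm[1]] for a in aggregates]
    if norm[0] == "joint":
        return [a.per_joint[norm[1]] for a in aggregates]
    return [a.per_joint_feature[(norm[1], norm[2])] for a in aggregates]


@dataclass(frozen=True)
class Summary:
    n: int
    mean: float
    sd: float
    min: float
    max: float
    median: float


def summarize(values, scope: Optional[Scope] = None) -> Summary:
    """Descriptive statistics (mean, sample SD, min, max, median).

    ``values`` is either a numeric sequence or a list of
    :class:`AggregateScore` with a ``scope`` selector.  SD uses the n-1
    denominator and is NaN for a single observation.
    """
    if scope is not None:
        values = field_values(values, scope)
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("summarize: empty input")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else math.nan
    return Summary(
        n=int(arr.size),
        mean=float(np.mean(arr)),
        sd=sd,
        min=float(np.min(arr)),
        max=float(np.max(arr)),
        median=float(np.median(arr)),
    )
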