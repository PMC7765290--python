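"""Change scores and standardized response means (SRMs).

The SRM is an effect-size index of an instrument's responsiveness to
change: the mean within-patient score change divided by the sample
standard deviation of that change.  Change is defined as baseline minus
follow-up (t0 - t1), so scores that rise under therapy give negative
SRMs.  Responsiveness strata follow the conventional 0.2 / 0.5 / 0.8
bands on |SRM|: trivial, small, moderate, large.

Degenerate cases are kept explicit rather than silently coerced:

* a sub-score whose underlying items are zero everywhere (feature
  absent from the cohort) has no defined responsiveness -> SRM NaN,
  label ``not_available``;
* zero change variance with zero mean change -> SRM 0;
* zero change variance with non-zero mean change -> SRM NaN with a
  degenerate-variance warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import AggregateScore, CohortTable, CohortValidationError, Scope, \
    field_values, normalize_scope
from .schema import ScoreSchema

__all__ = [
    "SRM_STRATA",
    "ChangeRecord",
    "ChangeSet",
    "SRMResult",
    "SRMGrid",
    "change_scores",
    "srm",
    "classify_srm",
    "srm_grid",
]

#: (threshold on |SRM|, label), scanned top-down.
SRM_STRATA = ((0.8, "large"), (0.5, "moderate"), (0.2, "small"), (0.0, "trivial"))


@dataclass(frozen=True)
class ChangeRecord:
    patient_id: str
    scope: tuple
    change: float


@dataclass
class ChangeSet:
    """Per-patient changes for one scope, plus the excluded incomplete cases."""

    records: list[ChangeRecord]
    excluded: tuple[str, ...] = ()

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def values(self) -> np.ndarray:
        return np.array([r.change for r in self.records], dtype=float)


@dataclass(frozen=True)
class SRMResult:
    scope: tuple
    n: int
    mean_change: float
    sd_change: float
    srm: float
    label: str


def classify_srm(value: float) -> str:
    """Stratify |SRM| into trivial/small/moderate/large; NaN -> not_available."""
    if value is None or math.isnan(value):
        return "not_available"
    magnitude = abs(value)
    for threshold, label in SRM_STRATA:
        if magnitude >= threshold:
            return label
    return "trivial"  # pragma: no cover - unreachable (last threshold is 0)


def change_scores(
    aggregates: Sequence[AggregateScore],
    scope: Scope = "overall",
) -> ChangeSet:
    """Per-patient change (t0 - t1) for one scope, complete cases only."""
    norm = normalize_scope(scope)
    by_patient: dict[str, dict[str, AggregateScore]] = {}
    for agg in aggregates:
        by_patient.setdefault(agg.patient_id, {})[agg.timepoint] = agg
    records, excluded = [], []
    for pid in sorted(by_patient):
        pair = by_patient[pid]
        if "t0" in pair and "t1" in pair:
            v0 = field_values([pair["t0"]], norm)[0]
            v1 = field_values([pair["t1"]], norm)[0]
            records.append(ChangeRecord(pid, norm, v0 - v1))
        else:
            excluded.append(pid)
    if len(records) < 2:
        raise ValueError(
            f"need >= 2 complete-case patients for change scores, got {len(records)}"
        )
    return ChangeSet(records=records, excluded=tuple(excluded))


def _srm_from_array(
    changes: np.ndarray,
    *,
    scores_all_zero: bool,
    ddof: int,
) -> tuple[float, float, float]:
    mean = float(np.mean(changes))
    sd = float(np.std(changes, ddof=ddof))
    if scores_all_zero:
        return mean, sd, math.nan
    if sd > 0:
        return mean, sd, mean / sd
    if mean == 0:
        return mean, sd, 0.0
    warnings.warn(
        f"degenerate change variance (sd=0, mean={mean:g}): SRM undefined",
        RuntimeWarning,
        stacklevel=3,
    )
    return mean, sd, math.nan


def srm(
    changes: Iterable[ChangeRecord],
    *,
    scores_all_zero: bool = False,
    ddof: int = 1,
) -> SRMResult:
    """SRM of a set of per-patient changes: mean(change) / SD(change).

    ``ddof=1`` (sample SD) is the default; ``scores_all_zero`` marks the
    feature-absent case, which is reported as not available rather than 0.
    """
    records = list(changes)
    if len(records) < 2:
        raise ValueError(f"SRM needs >= 2 changes, got {len(records)}")
    arr = np.array([r.change for r in records], dtype=float)
    mean, sd, value = _srm_from_array(arr, scores_all_zero=scores_all_zero, ddof=ddof)
    scope = records[0].scope
    return SRMResult(scope=scope, n=len(records), mean_change=mean,
                     sd_change=sd, srm=value, label=classify_srm(value))


@dataclass
class SRMGrid:
    """SRMs for every joint x (overall + feature) cell plus the
    instrument-level column (overall and per-feature SRMs)."""

    schema: ScoreSchema
    cells: dict[tuple[str, str], SRMResult]
    instrument: dict[str, SRMResult]
    n_complete: int
    excluded: tuple[str, ...] = ()

    def joint_overall(self) -> dict[str, float]:
        return {j: self.cells[(j, "overall")].srm for j in self.schema.joint_tokens}

    def table2_frame(self, decimals: Optional[int] = 2) -> pd.DataFrame:
        """Wide layout: rows = overall + features, columns = joints."""
        rows = ["overall"] + list(self.schema.feature_names)
        data = {
            j: [self.cells[(j, r)].srm for r in rows]
            for j in self.schema.joint_tokens
        }
        frame = pd.DataFrame(data, index=rows)
        frame.index.name = "scope"
        return frame.round(decimals) if decimals is not None else frame

    def long_frame(self) -> pd.DataFrame:
        """Tidy full-precision layout with n, mean and SD of change."""
        records = []
        for (j, r), res in sorted(self.cells.items()):
            records.append({"joint": j, "scope": r, "n": res.n,
                            "mean_change": res.mean_change,
                            "sd_change": res.sd_change,
                            "srm": res.srm, "label": res.label})
        for r, res in self.instrument.items():
            records.append({"joint": "ALL", "scope": r, "n": res.n,
                            "mean_change": res.mean_change,
                            "sd_change": res.sd_change,
                            "srm": res.srm, "label": res.label})
        return pd.DataFrame(records)


def srm_grid(cohort: CohortTable, schema: Optional[ScoreSchema] = None) -> SRMGrid:
    """SRMs of every sub-score of ``schema`` on a single-rater cohort.

    Sub-scores are local: a cell's SRM depends only on that joint's (and
    feature's) items.  Cells whose items are zero throughout the cohort
    are reported as not available.
    """
    schema = schema or cohort.schema
    work = cohort.restrict(schema) if schema is not cohort.schema else cohort
    df = work.frame
    if df["rater_id"].nunique() > 1:
        raise CohortValidationError(
            ["srm_grid needs a single effective rater; apply resolve_raters first"]
        )

    complete = [p for p in work.complete_cases()]
    excluded = tuple(p for p in work.patients if p not in set(complete))
    if len(complete) < 2:
        raise ValueError(f"need >= 2 complete-case patients, got {len(complete)}")

    joints = list(schema.joint_tokens)
    feats = list(schema.feature_names)

    sub = df[df.patient_id.isin(complete)]
    pivot = sub.pivot_table(index="patient_id",
                            columns=["timepoint", "joint", "feature"],
                            values="value", aggfunc="sum", fill_value=0)
    cols = pd.MultiIndex.from_product([["t0", "t1"], joints, feats])
    pivot = pivot.reindex(columns=cols, fill_value=0).sort_index()
    n = len(pivot)

    # n_patients x n_joints x n_features change tensor, change = t0 - t1
    t0 = pivot["t0"].to_numpy(dtype=float).reshape(n, len(joints), len(feats))
    t1 = pivot["t1"].to_numpy(dtype=float).reshape(n, len(joints), len(feats))
    delta = t0 - t1

    # feature-absent detection uses the whole cohort (both timepoints,
    # incomplete patients included)
    nonzero = df[df.value != 0].groupby(["joint", "feature"]).size()
    absent = np.array([[(j, f) not in nonzero.index for f in feats] for j in joints])

    def make(changes: np.ndarray, scope: tuple, all_zero: bool) -> SRMResult:
        mean, sd, value = _srm_from_array(changes, scores_all_zero=all_zero, ddof=1)
        return SRMResult(scope=scope, n=n, mean_change=mean, sd_change=sd,
                         srm=value, label=classify_srm(value))

    cells: dict[tuple[str, str], SRMResult] = {}
    for ji, j in enumerate(joints):
        cells[(j, "overall")] = make(delta[:, ji, :].sum(axis=1),
                                     ("joint", j), bool(absent[ji].all()))
        for fi, f in enumerate(feats):
            cells[(j, f)] = make(delta[:, ji, fi], ("joint_feature", j, f),
                                 bool(absent[ji, fi]))

    instrument = {
        "overall": make(delta.sum(axis=(1, 2)), ("overall",), bool(absent.all()))
    }
    for fi, f in enumerate(feats):
        instrument[f] = make(delta[:, :, fi].sum(axis=1), ("feature", f),
                             bool(absent[:, fi].all()))

    return SRMGrid(schema=schema, cells=cells, instrument=instrument,
                   n_complete=n, excluded=excluded)
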