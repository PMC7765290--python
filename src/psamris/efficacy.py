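"""Relative efficacy of two instruments with bootstrap percentile bounds.

RE = (SRM_simplified / SRM_reference)^2 compares the responsiveness of
a simplified score against a reference score on the same cohort;
RE > 1 means the simplified instrument detects change more efficiently.
Confidence bounds come from resampling patients — the only exchangeable
unit in a paired pre/post design — with replacement and taking
empirical percentiles (nearest-rank) of the replicate REs.

Replicates where either SRM is undefined (all resampled scores zero, or
zero change variance with non-zero mean) yield NaN RE; these are
excluded from the quantiles and counted, while infinite REs (reference
SRM exactly 0) stay in the ranking.  Heavy-tailed replicate behavior is
thus surfaced rather than hidden.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cohort import CohortTable
from .schema import ScoreSchema

__all__ = ["EfficacyResult", "relative_efficacy", "bootstrap_re"]

_EXHAUSTIVE_LIMIT = 8  # n^n resamples; 8^8 ~ 1.7e7 is the practical ceiling


@dataclass(frozen=True)
class EfficacyResult:
    srm_simplified: float
    srm_reference: float
    re_point: float
    B: int
    lower: float
    upper: float
    n_degenerate_replicates: int
    n_infinite_replicates: int
    seed: Optional[int]

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.lower, self.upper)

    @property
    def interpretation(self) -> str:
        if math.isnan(self.re_point):
            return "undefined (both SRMs zero or unavailable)"
        if self.re_point > 1:
            return "simplified more efficient"
        if self.re_point < 1:
            return "reference more efficient"
        return "equally efficient"


def relative_efficacy(srm_s: float, srm_ref: float) -> float:
    """Squared SRM ratio.  0/0 is NaN; x/0 with x != 0 is +inf (both warned)."""
    if math.isnan(srm_s) or math.isnan(srm_ref):
        warnings.warn("relative efficacy undefined: NaN SRM input", RuntimeWarning,
                      stacklevel=2)
        return math.nan
    if srm_ref == 0.0:
        if srm_s == 0.0:
            warnings.warn("relative efficacy 0/0 is undefined", RuntimeWarning,
                          stacklevel=2)
            return math.nan
        warnings.warn("reference SRM is 0: relative efficacy infinite",
                      RuntimeWarning, stacklevel=2)
        return math.inf
    return (srm_s / srm_ref) ** 2


def _change_vectors(cohort: CohortTable, schema: ScoreSchema):
    """Per complete-case patient: overall change (t0 - t1) under ``schema``
    and whether the patient's restricted scores are all zero."""
    work = cohort.restrict(schema)
    df = work.frame
    if df["rater_id"].nunique() > 1:
        raise ValueError("bootstrap_re needs a single effective rater")
    complete = list(work.complete_cases())
    sub = df[df.patient_id.isin(complete)]
    totals = sub.pivot_table(index="patient_id", columns="timepoint",
                             values="value", aggfunc="sum", fill_value=0)
    totals = totals.reindex(columns=["t0", "t1"], fill_value=0).sort_index()
    change = (totals["t0"] - totals["t1"]).to_numpy(dtype=float)
    any_nonzero = sub.groupby("patient_id")["value"].max().reindex(totals.index)
    all_zero = (any_nonzero.fillna(0) == 0).to_numpy()
    return change, all_zero


def _srm_rows(changes: np.ndarray, all_zero_rows: np.ndarray) -> np.ndarray:
    """Row-wise SRM with the degenerate-case rules (rows = replicates)."""
    mean = changes.mean(axis=1)
    sd = changes.std(axis=1, ddof=1)
    out = np.full(mean.shape, np.nan)
    ok = sd > 0
    out[ok] = mean[ok] / sd[ok]
    flat_zero_mean = (~ok) & (mean == 0)
    out[flat_zero_mean & ~all_zero_rows] = 0.0
    # sd == 0 with mean != 0, or all-zero scores: stays NaN
    out[all_zero_rows] = np.nan
    return out


def bootstrap_re(
    cohort: CohortTable,
    schema_simplified: ScoreSchema,
    schema_reference: Optional[ScoreSchema] = None,
    *,
    B: int = 5000,
    seed: Optional[int] = None,
    exhaustive: bool = False,
) -> EfficacyResult:
    """Point RE plus percentile bootstrap bounds over patient resamples.

    ``exhaustive=True`` enumerates every one of the n^n ordered
    with-replacement resamples instead of sampling (feasible for tiny
    cohorts only); otherwise B resamples are drawn from ``seed``.
    Bounds are the 2.5% / 97.5% empirical quantiles by the nearest-rank
    definition, so a fixed seed reproduces them bit-for-bit.
    """
    schema_reference = schema_reference or cohort.schema
    d_s, z_s = _change_vectors(cohort, schema_simplified)
    d_r, z_r = _change_vectors(cohort, schema_reference)
    if len(d_s) != len(d_r):
        raise ValueError("instruments disagree on the complete-case patient set")
    n = len(d_s)
    if n < 2:
        raise ValueError(f"need >= 2 complete-case patients, got {n}")

    point_s = _srm_rows(d_s[None, :], np.array([z_s.all()]))[0]
    point_r = _srm_rows(d_r[None, :], np.array([z_r.all()]))[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        point = relative_efficacy(point_s, point_r)

    if exhaustive:
        if n > _EXHAUSTIVE_LIMIT:
            raise ValueError(f"exhaustive enumeration infeasible for n={n}")
        idx = np.array(list(itertools.product(range(n), repeat=n)), dtype=int)
    else:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(B, n))
    n_rep = len(idx)

    zero_rows_s = z_s[idx].all(axis=1)
    zero_rows_r = z_r[idx].all(axis=1)
    srm_s = _srm_rows(d_s[idx], zero_rows_s)
    srm_r = _srm_rows(d_r[idx], zero_rows_r)

    with np.errstate(divide="ignore", invalid="ignore"):
        re = (srm_s / srm_r) ** 2
    # 0/0 and NaN inputs -> NaN; x/0 -> +inf kept in the ranking
    nonzero_over_zero = (srm_r == 0) & (srm_s != 0)
    re[nonzero_over_zero] = np.inf

    valid = re[~np.isnan(re)]
    n_degenerate = int(n_rep - len(valid))
    if len(valid) == 0:
        raise ValueError("every bootstrap replicate was degenerate (NaN RE)")
    n_infinite = int(np.isinf(valid).sum())

    ordered = np.sort(valid)
    m = len(ordered)
    lo_rank = max(1, math.ceil(0.025 * m))
    hi_rank = max(1, math.ceil(0.975 * m))
    lower = float(ordered[lo_rank - 1])
    upper = float(ordered[hi_rank - 1])

    return EfficacyResult(
        srm_simplified=float(point_s),
        srm_reference=float(point_r),
        re_point=float(point),
        B=n_rep,
        lower=lower,
        upper=upper,
        n_degenerate_replicates=n_degenerate,
        n_infinite_replicates=n_infinite,
        seed=None if exhaustive else seed,
    )
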