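"""SRM-driven joint selection: the score-simplification step.

Joints are ranked by the magnitude of the overall SRM of their
sub-score (responsiveness to change), ties broken by anatomical order,
and the top k form the simplified instrument.  Magnitude rather than
signed ranking is the default because a score can be responsive in
either direction; signed ranking is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence, Union

from .responsiveness import SRMGrid
from .schema import JointId, ScoreSchema, as_joint, build_reduced_schema

__all__ = ["SelectionResult", "rank_joints", "select_joints", "derive_simplified"]

RankedEntry = tuple[JointId, float, float]  # (joint, srm, |srm|)


@dataclass
class SelectionResult:
    """Ranked joints with the selected prefix block.

    ``selected`` preserves rank order and is a prefix of ``ranked``;
    it exceeds ``k_requested`` only when ``tie_expanded`` (the |SRM| at
    the cut is shared beyond rank k).
    """

    ranked: list[RankedEntry]
    selected: tuple[JointId, ...]
    k_requested: int
    tie_expanded: bool
    notes: str = ""


def _overall_map(grid) -> dict[JointId, float]:
    if isinstance(grid, SRMGrid):
        return {as_joint(j): v for j, v in grid.joint_overall().items()}
    if isinstance(grid, Mapping):
        return {as_joint(j): float(v) for j, v in grid.items()}
    raise TypeError("rank_joints expects an SRMGrid or a mapping joint -> SRM")


def rank_joints(grid: Union[SRMGrid, Mapping], *, signed: bool = False) -> list[RankedEntry]:
    """Order joints by responsiveness: |overall SRM| descending by
    default (``signed=True`` ranks by the signed value), NaN last, ties
    broken anatomically.  Deterministic for a given input."""
    srms = _overall_map(grid)
    if all(math.isnan(v) for v in srms.values()):
        raise ValueError("cannot rank joints: every overall SRM is NaN")

    def key(item: tuple[JointId, float]):
        joint, value = item
        if math.isnan(value):
            return (1, 0.0, joint.sort_key)
        score = -value if signed else -abs(value)
        return (0, score, joint.sort_key)

    ordered = sorted(srms.items(), key=key)
    return [(j, v, abs(v)) for j, v in ordered]


def select_joints(ranked: Sequence[RankedEntry], k: int = 3) -> SelectionResult:
    """Take the top-k block; a magnitude tie across the cut includes the
    whole tie block and flags ``tie_expanded``."""
    ranked = list(ranked)
    if not ranked:
        raise ValueError("select_joints: empty ranking")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(ranked):
        raise ValueError(f"k={k} exceeds the {len(ranked)} ranked joints")

    end = k
    cut = ranked[k - 1][2]
    while end < len(ranked) and not math.isnan(cut) and ranked[end][2] == cut:
        end += 1
    tie_expanded = end > k
    selected = tuple(entry[0] for entry in ranked[:end])
    notes = (f"|SRM|={cut:g} shared through rank {end}; tie block included"
             if tie_expanded else "")
    return SelectionResult(ranked=ranked, selected=selected, k_requested=k,
                           tie_expanded=tie_expanded, notes=notes)


def derive_simplified(
    full: ScoreSchema,
    selection: SelectionResult,
    name: str = "sPsAMRIS",
) -> ScoreSchema:
    """The simplified instrument: ``full`` restricted to the selected joints."""
    return build_reduced_schema(full, selection.selected, name=name)
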