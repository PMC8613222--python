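"""Extrinsic difficulty transformations for raw score matrices.

When no intrinsic difficulty metric is available, difficulty can be derived
from the score matrix itself (or from a reference agent / reference
distribution), after which the generality analysis proceeds exactly as in
the intrinsic case.  The modalities implemented here:

======  =====================================================================
Opp     match-play data: the difficulty of facing opponent ``o`` is ``o``'s
        average performance across its matches; the matrix passes through.
ARef    real scores + a reference agent: responses are binarised as
        score >= reference score, and the difficulty of an item is the
        fraction of the population scoring strictly worse than the reference.
Rnk     real scores: each item expands into ``c`` binary columns, one per
        rank level l = 1..c; a cell is 1 when the agent's score reaches the
        l-th best score on the item, and the level's difficulty is
        (c - l + 1)/c (beating the top rank is hardest).
DRef    real scores + per-item reference samples: each item expands into
        ``c`` binary columns at the k/(c+1) quantiles of the reference
        distribution (strict >); works even for a single agent.
IRT     binary matrices: a classical difficulty proxy, the logit of the
        population failure rate (clipped away from 0/1), shifted so the
        easiest item sits at difficulty zero.
======  =====================================================================

Difficulty scales from different modalities are not commensurate; each
result records its modality and parameters, and difficulties from different
modalities should never be mixed in one analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .matrix import DifficultyAssignment, ResponseMatrix, ValidationError

__all__ = [
    "TransformResult",
    "transform_opp",
    "transform_aref",
    "transform_rnk",
    "transform_dref",
    "difficulty_from_failure_rate",
]


@dataclass
class TransformResult:
    """A (possibly binarised / column-expanded) matrix plus derived difficulties."""

    matrix: ResponseMatrix
    difficulties: DifficultyAssignment
    modality: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = pd.Index(self.matrix.item_ids).difference(self.difficulties.values.index)
        if len(missing):
            raise ValidationError(f"transform produced items without difficulty: {list(missing[:5])}")


def _as_frame(raw) -> pd.DataFrame:
    if isinstance(raw, ResponseMatrix):
        return raw.data
    return pd.DataFrame(raw).astype(float)


def transform_opp(match_matrix) -> TransformResult:
    """Difficulty from match play: the opponent's average performance.

    ``match_matrix`` is square with identical agent ids on rows and columns;
    cell (j, o) is agent j's score against opponent o (draws may be 0.5) and
    the diagonal is missing.  The difficulty of column o is the mean of
    row o over its non-missing entries: beating a strong opponent is hard.
    """
    frame = _as_frame(match_matrix)
    if frame.shape[0] != frame.shape[1] or not frame.index.equals(frame.columns):
        raise ValidationError("Opp requires a square matrix with matching agent ids")
    diff = frame.mean(axis=1, skipna=True)  # row means = each opponent's avg performance
    difficulties = DifficultyAssignment.from_series(diff, scale="opp")
    return TransformResult(
        matrix=ResponseMatrix(frame, domain="unit"),
        difficulties=difficulties,
        modality="Opp",
        provenance={"n_agents": frame.shape[0]},
    )


def transform_aref(raw, ref_agent, direction: str = "population") -> TransformResult:
    """Binarise against a reference agent; difficulty = how hard the reference is to match.

    ``ref_agent`` is either a row id of ``raw`` or an external per-item score
    Series over the same items.  Cells become 1 when the agent's raw score is
    at least the reference's score on that item.  With the default
    ``direction="population"``, the difficulty of an item is the fraction of
    the population scoring strictly worse than the reference there;
    ``direction="reference"`` flips the comparison (fraction scoring strictly
    better than the reference).  Both readings are invariant to strictly
    increasing per-item transformations of the scores.
    """
    frame = _as_frame(raw)
    if isinstance(ref_agent, (pd.Series, Mapping)):
        ref = pd.Series(ref_agent, dtype=float)
        ref_id = "<external>"
    else:
        if ref_agent not in frame.index:
            raise ValidationError(f"unknown reference agent {ref_agent!r}")
        ref = frame.loc[ref_agent]
        ref_id = ref_agent
    missing = frame.columns.difference(ref.index)
    if len(missing):
        raise ValidationError(f"reference lacks scores for items: {list(missing[:5])}")
    ref = ref.reindex(frame.columns)

    binary = frame.ge(ref, axis=1).astype(float).where(~frame.isna())
    if direction == "population":
        diff = frame.lt(ref, axis=1).mean(axis=0)
    elif direction == "reference":
        diff = frame.gt(ref, axis=1).mean(axis=0)
    else:
        raise ValidationError(f"unknown ARef direction {direction!r}")
    difficulties = DifficultyAssignment.from_series(diff, q=1.0, scale="aref")
    return TransformResult(
        matrix=ResponseMatrix(binary, domain="binary"),
        difficulties=difficulties,
        modality="ARef",
        provenance={"ref_agent": ref_id, "direction": direction},
    )


def transform_rnk(raw, c: int) -> TransformResult:
    """Expand each item into ``c`` binary rank columns.

    For each original item the scores of the M agents are ranked; the l-th
    derived column marks the agents whose score reaches the l-th best score
    (ties share ranks, so an agent tied at the l-th ranked score clears
    level l).  The difficulty of level l is (c - l + 1)/c: beating the top
    rank is hardest.  Invariant to strictly increasing per-item transforms.
    """
    frame = _as_frame(raw)
    m = frame.shape[0]
    if m < 2:
        raise ValidationError("Rnk needs at least two agents")
    c = int(c)
    if not 1 <= c <= m - 1:
        raise ValidationError(f"c must lie in [1, M-1] = [1, {m - 1}]")
    cols: dict[str, np.ndarray] = {}
    diffs: dict[str, float] = {}
    for item in frame.columns:
        scores = frame[item].to_numpy()
        order = np.sort(scores)[::-1]  # descending: order[l-1] is the l-th best
        for level in range(1, c + 1):
            name = f"{item}#r{level}"
            cols[name] = (scores >= order[level - 1]).astype(float)
            diffs[name] = (c - level + 1) / c
    out = pd.DataFrame(cols, index=frame.index)
    difficulties = DifficultyAssignment.from_series(pd.Series(diffs), q=1.0, scale="rnk")
    return TransformResult(
        matrix=ResponseMatrix(out, domain="binary"),
        difficulties=difficulties,
        modality="Rnk",
        provenance={"c": c},
    )


def transform_dref(raw, ref_dist, c: int) -> TransformResult:
    """Expand each item into ``c`` binary columns at reference-distribution quantiles.

    ``ref_dist`` maps each item to a sample of reference scores (a mapping,
    DataFrame of columns, or a single array applied to every item).  The
    k-th derived column (k = 1..c) marks agents whose score strictly exceeds
    the k/(c+1) quantile (type-7 linear interpolation) of the reference
    sample; its difficulty is the quantile level k/(c+1).  Being referenced
    against an external distribution, this modality works for a single agent.
    """
    frame = _as_frame(raw)
    c = int(c)
    if c < 1:
        raise ValidationError("c must be at least 1")
    if isinstance(ref_dist, pd.DataFrame):
        ref_map = {col: ref_dist[col].dropna().to_numpy() for col in ref_dist.columns}
    elif isinstance(ref_dist, Mapping):
        ref_map = {k: np.asarray(v, dtype=float) for k, v in ref_dist.items()}
    else:
        sample = np.asarray(ref_dist, dtype=float)
        ref_map = {item: sample for item in frame.columns}
    cols: dict[str, np.ndarray] = {}
    diffs: dict[str, float] = {}
    for item in frame.columns:
        if item not in ref_map:
            raise ValidationError(f"no reference sample for item {item!r}")
        sample = np.asarray(ref_map[item], dtype=float)
        if sample.size == 0:
            raise ValidationError(f"empty reference sample for item {item!r}")
        scores = frame[item].to_numpy()
        for k in range(1, c + 1):
            level = k / (c + 1)
            threshold = float(np.quantile(sample, level))  # type-7 linear rule
            name = f"{item}#q{k}"
            cols[name] = (scores > threshold).astype(float)
            diffs[name] = level
    out = pd.DataFrame(cols, index=frame.index)
    difficulties = DifficultyAssignment.from_series(
        pd.Series(diffs), q=c / (c + 1), scale="dref"
    )
    return TransformResult(
        matrix=ResponseMatrix(out, domain="binary"),
        difficulties=difficulties,
        modality="DRef",
        provenance={"c": c},
    )


def difficulty_from_failure_rate(binary) -> TransformResult:
    """Classical item-difficulty proxy: logit of the population failure rate.

    Failure rates are clipped to [1/(2M), 1 - 1/(2M)] so items everyone
    passes (or fails) keep a finite difficulty, and the scale is shifted so
    the easiest item sits at zero (the shift is recorded, since capability
    is translation-sensitive).  The matrix passes through unchanged.
    """
    if isinstance(binary, ResponseMatrix):
        frame = binary.data
    else:
        frame = pd.DataFrame(binary).astype(float)
    matrix = ResponseMatrix(frame, domain="binary")  # validates 0/1
    m = frame.shape[0]
    if m < 2:
        raise ValidationError("failure-rate difficulties need at least two agents")
    fail = 1.0 - frame.mean(axis=0, skipna=True)
    clipped = fail.clip(lower=1.0 / (2 * m), upper=1.0 - 1.0 / (2 * m))
    logits = np.log(clipped / (1.0 - clipped))
    shift = -float(logits.min())
    difficulties = DifficultyAssignment.from_series(logits + shift, scale="irtproxy")
    return TransformResult(
        matrix=matrix,
        difficulties=difficulties,
        modality="IRTproxy",
        provenance={"shift": shift, "clip": 1.0 / (2 * m)},
    )
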