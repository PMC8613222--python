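"""Containers for response matrices and item-difficulty assignments.

A response matrix holds the accomplishment ``r[j, i]`` of agent ``j`` (row)
on item ``i`` (column).  Accomplishments are dimensionless, either in [0, 1]
(proportions, normalised scores) or raw real scores destined for one of the
extrinsic difficulty transformations.  A difficulty assignment maps every
item to a non-negative real difficulty ``h`` and carries the bounds
``[origin, q]`` of the difficulty range used for integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GeneralityError",
    "ValidationError",
    "MissingDifficultyError",
    "EmptyAgentError",
    "IntegrationInconsistencyError",
    "ResponseMatrix",
    "DifficultyAssignment",
]


class GeneralityError(Exception):
    """Base class for errors raised by this package."""


class ValidationError(GeneralityError, ValueError):
    """Input data violates a documented contract."""


class MissingDifficultyError(GeneralityError, KeyError):
    """An item in the response matrix has no difficulty assigned."""


class EmptyAgentError(GeneralityError, ValueError):
    """An agent has no non-missing responses."""


class IntegrationInconsistencyError(GeneralityError, ArithmeticError):
    """2M - Psi^2 is negative beyond numerical tolerance; the curve is inconsistent."""


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:5]}")


@dataclass
class ResponseMatrix:
    """M x N table of accomplishments with agent and item identifiers.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by agent id, columns by item id, float values.
        Missing responses are NaN.
    domain : {"unit", "real", "binary"}
        Validation domain of the values.  ``"unit"`` demands values in
        [0, 1] (the canonical accomplishment scale), ``"binary"`` demands
        values in {0, 1}, ``"real"`` accepts any finite real score (inputs
        to the rank/reference transformations).
    """

    data: pd.DataFrame
    domain: str = "unit"

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValidationError("response matrix needs at least one agent and one item")
        _check_unique(self.data.index, "agent ids")
        _check_unique(self.data.columns, "item ids")
        self.data = self.data.astype(float)
        vals = self.data.to_numpy()
        finite = vals[~np.isnan(vals)]
        if np.isinf(finite).any():
            raise ValidationError("response matrix contains infinite values")
        if self.domain == "unit":
            if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
                bad = finite[(finite < 0) | (finite > 1)][0]
                raise ValidationError(f"response value {bad} outside [0, 1]")
        elif self.domain == "binary":
            if finite.size and not np.isin(finite, (0.0, 1.0)).all():
                raise ValidationError("response matrix is not binary (values outside {0, 1})")
        elif self.domain != "real":
            raise ValidationError(f"unknown response domain {self.domain!r}")

    # -- basic introspection -------------------------------------------------
    @property
    def agent_ids(self) -> list:
        return list(self.data.index)

    @property
    def item_ids(self) -> list:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def row(self, agent) -> pd.Series:
        """Responses of one agent as an item -> value Series."""
        if agent not in self.data.index:
            raise ValidationError(f"unknown agent {agent!r}")
        return self.data.loc[agent]

    # -- constructors --------------------------------------------------------
    @classmethod
    def from_wide(cls, frame: pd.DataFrame, domain: str = "unit") -> "ResponseMatrix":
        return cls(frame.copy(), domain=domain)

    @classmethod
    def from_long(
        cls,
        frame: pd.DataFrame,
        agent_col: str = "agent",
        item_col: str = "item",
        response_col: str = "response",
        domain: str = "unit",
    ) -> "ResponseMatrix":
        """Build from long records; duplicate (agent, item) pairs are rejected."""
        dup = frame.duplicated(subset=[agent_col, item_col])
        if dup.any():
            pair = frame.loc[dup, [agent_col, item_col]].iloc[0].tolist()
            raise ValidationError(f"duplicate (agent, item) pair {tuple(pair)} in long input")
        wide = frame.pivot(index=agent_col, columns=item_col, values=response_col)
        wide.index.name = None
        wide.columns.name = None
        return cls(wide, domain=domain)

    def to_long(self) -> pd.DataFrame:
        long = self.data.stack(future_stack=True).rename("response").reset_index()
        long.columns = ["agent", "item", "response"]
        return long.dropna(subset=["response"]).reset_index(drop=True)


@dataclass
class DifficultyAssignment:
    """Item -> difficulty map plus the bounds of the difficulty range.

    Difficulties must lie in ``[origin, q]`` with ``q > origin`` and must be
    non-negative; negative inputs are rejected unless ``shift=True`` is
    passed to :meth:`from_series`, in which case all difficulties are
    translated so the minimum is zero and the applied shift is recorded
    (capability is translation-sensitive, so silent shifts would corrupt
    comparisons between runs).
    """

    values: pd.Series
    q: float
    origin: float = 0.0
    shift_applied: float = 0.0
    scale: str = "intrinsic"

    def __post_init__(self) -> None:
        self.values = pd.Series(self.values, dtype=float)
        _check_unique(self.values.index, "item ids in difficulty table")
        if self.values.isna().any():
            raise ValidationError("difficulty table contains missing values")
        self.q = float(self.q)
        self.origin = float(self.origin)
        if not self.q > self.origin:
            raise ValidationError(f"q ({self.q}) must exceed origin ({self.origin})")
        lo = float(self.values.min())
        if lo < 0.0:
            raise ValidationError(
                f"negative difficulty {lo}; pass shift=True to translate the scale"
            )
        if lo < self.origin - 1e-12 or float(self.values.max()) > self.q + 1e-12:
            raise ValidationError("difficulties fall outside [origin, q]")

    @classmethod
    def from_series(
        cls,
        values,
        q: float | None = None,
        origin: float = 0.0,
        shift: bool = False,
        scale: str = "intrinsic",
    ) -> "DifficultyAssignment":
        s = pd.Series(values, dtype=float)
        applied = 0.0
        if shift and len(s) and float(s.min()) < 0.0:
            applied = -float(s.min())
            s = s + applied
        if q is None:
            q = float(s.max())
            if not q > origin:  # all difficulties at the origin
                q = origin + 1.0
        return cls(s, q=q, origin=origin, shift_applied=applied, scale=scale)

    @classmethod
    def from_mapping(cls, mapping: Mapping, **kwargs) -> "DifficultyAssignment":
        return cls.from_series(pd.Series(dict(mapping)), **kwargs)

    def lookup(self, items) -> np.ndarray:
        """Difficulties for the given items; raises if any item is unknown."""
        idx = pd.Index(items)
        missing = idx.difference(self.values.index)
        if len(missing):
            raise MissingDifficultyError(
                f"no difficulty for item(s): {list(missing[:5])}"
            )
        return self.values.reindex(idx).to_numpy()

    def __len__(self) -> int:
        return len(self.values)
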