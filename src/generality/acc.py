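"""Agent characteristic curves (ACCs) and the per-agent metrics derived from them.

An ACC plots the mean accomplishment psi(h) of one agent against task
difficulty h.  The curve summaries implemented here are

* capability            Psi  = integral of psi(h) over [origin, q]
* first partial moment  M    = integral of h * psi(h)
* expected difficulty   H    = M / Psi (mean difficulty of the successes)
* spread                S    = sqrt(2M - Psi^2)
* generality            Gamma = 1 / S (infinite for a perfect decreasing step)
* normalised spread / generality  s, gamma = -s in [-1, +1]

Spread measures how far the success mass deviates from an ideal step fully
compacted on the easy side: a decreasing step at h = Psi has S = 0 (maximum
generality), a constant curve at level c has S = q*sqrt(c(1-c)), and an
increasing step has S^2 = 2*Psi*(q - Psi), the most abstruse arrangement.
The normalisation rescales S^2 against the constant-curve isometric
S^2_cnst = Psi*(q - Psi) so that gamma is +1 / 0 / -1 on those three
reference curves; agents with gamma < 0 ("abstruse") fail more on the easy
items than on the hard ones.

Curves are piecewise linear between observed points and constant beyond the
first and last point (down to ``origin`` and up to ``q``).  Duplicated
abscissae are allowed and encode jump discontinuities, so the analytic step
curves are representable exactly.  Two staircase
readings are available for binary data on ordinal difficulty levels:
``interpolation="previous"`` holds psi constant until the next observed
difficulty, and ``interpolation="nearest"`` places the jumps at the
midpoints between observed difficulties, the unbiased discrete reading
under which a perfectly difficulty-ordered (Guttman) agent is an exact
step with zero spread.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .matrix import (
    DifficultyAssignment,
    EmptyAgentError,
    IntegrationInconsistencyError,
    MissingDifficultyError,
    ValidationError,
)

__all__ = [
    "ACC",
    "AgentMetrics",
    "build_acc",
    "capability",
    "partial_moment",
    "expected_difficulty",
    "spread",
    "generality_index",
    "normalised_spread",
    "normalised_generality",
    "agent_metrics",
    "isometric_curves",
    "span_length",
]

#: Above this many distinct difficulty values the default binning switches
#: from identity (one point per distinct difficulty) to equal-width bins.
IDENTITY_BIN_LIMIT = 25
DEFAULT_N_BINS = 10

#: Tolerance (relative to q^2) below which a negative 2M - Psi^2 is treated
#: as round-off and clamped to zero; larger negatives signal a bug.
SPREAD_CLAMP_REL_TOL = 1e-9


@dataclass(frozen=True)
class ACC:
    """One agent's characteristic curve.

    ``h`` is non-decreasing; strictly equal consecutive abscissae encode a
    jump discontinuity (left value first).  ``psi`` values lie in [0, 1].
    """

    h: np.ndarray
    psi: np.ndarray
    q: float
    origin: float = 0.0
    interpolation: str = "linear"
    bin_spec: str = "points"
    n_items: int | None = None

    def __post_init__(self) -> None:
        h = np.asarray(self.h, dtype=float)
        psi = np.asarray(self.psi, dtype=float)
        object.__setattr__(self, "h", h)
        object.__setattr__(self, "psi", psi)
        if h.ndim != 1 or h.shape != psi.shape or h.size < 1:
            raise ValidationError("ACC needs matching 1-D h and psi with at least one point")
        if np.any(np.diff(h) < 0):
            raise ValidationError("ACC difficulties must be non-decreasing")
        if np.any((psi < -1e-12) | (psi > 1 + 1e-12)):
            raise ValidationError("ACC psi values must lie in [0, 1]")
        if self.interpolation not in ("linear", "previous", "nearest"):
            raise ValidationError(f"unknown interpolation {self.interpolation!r}")
        q = float(self.q)
        origin = float(self.origin)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "origin", origin)
        if not q > origin:
            raise ValidationError("ACC requires q > origin")
        if h[0] < origin - 1e-12 or h[-1] > q + 1e-12:
            raise ValidationError("ACC points fall outside [origin, q]")

    # ------------------------------------------------------------------
    @classmethod
    def from_function(
        cls,
        fn: Callable[[float], float],
        q: float,
        n: int = 1001,
        origin: float = 0.0,
        jumps: Sequence[float] = (),
        interpolation: str = "linear",
    ) -> "ACC":
        """Sample ``fn`` on an ``n``-point uniform grid over [origin, q].

        Known discontinuities can be listed in ``jumps``; each is encoded as
        a duplicated abscissa carrying the one-sided limits, so step curves
        are represented (and integrated) exactly.
        """
        grid = np.linspace(origin, q, n)
        eps = 1e-9 * (q - origin)
        pts: list[tuple[float, int, float]] = [(float(x), 1, float(fn(x))) for x in grid]
        for j in jumps:
            j = float(j)
            if not origin <= j <= q:
                raise ValidationError(f"jump {j} outside [origin, q]")
            pts = [p for p in pts if abs(p[0] - j) > eps / 2]
            pts.append((j, 0, float(fn(max(j - eps, origin)))))
            pts.append((j, 2, float(fn(min(j + eps, q)))))
        pts.sort(key=lambda p: (p[0], p[1]))
        h = np.array([p[0] for p in pts])
        psi = np.clip([p[2] for p in pts], 0.0, 1.0)
        return cls(h, psi, q=q, origin=origin, interpolation=interpolation,
                   bin_spec=f"function-grid-{n}")

    def extended_points(self) -> tuple[np.ndarray, np.ndarray]:
        """Curve points after constant extrapolation to origin and q."""
        h, psi = self.h, self.psi
        if h[0] > self.origin:
            h = np.concatenate(([self.origin], h))
            psi = np.concatenate(([psi[0]], psi))
        if h[-1] < self.q:
            h = np.concatenate((h, [self.q]))
            psi = np.concatenate((psi, [psi[-1]]))
        return h, psi

    def rescale(self, factor: float) -> "ACC":
        """Multiply all difficulties (and q, origin) by a positive constant."""
        if factor <= 0:
            raise ValidationError("rescale factor must be positive")
        return replace(self, h=self.h * factor, q=self.q * factor,
                       origin=self.origin * factor)


# ----------------------------------------------------------------------
# curve construction from responses
# ----------------------------------------------------------------------

def build_acc(
    responses,
    difficulties: DifficultyAssignment,
    bins: int | str | None = None,
    interpolation: str = "linear",
) -> ACC:
    """Build an agent characteristic curve from one agent's responses.

    Parameters
    ----------
    responses : mapping or pandas.Series
        item -> accomplishment in [0, 1]; NaN marks missing responses,
        which are excluded from the bin means.
    difficulties : DifficultyAssignment
        Per-item difficulty plus the range [origin, q].
    bins : None, "identity" or int
        ``"identity"`` gives one curve point per distinct difficulty value
        (responses at tied difficulties are averaged).  An integer gives
        that many equal-width bins over [origin, q], represented at bin
        midpoints; empty bins are skipped and the curve spans the gap.
        ``None`` selects identity when there are at most 25 distinct
        difficulties and 10 equal-width bins otherwise.
    """
    s = pd.Series(responses, dtype=float).dropna()
    if s.empty:
        raise EmptyAgentError("agent has no non-missing responses")
    vals = s.to_numpy()
    if vals.min() < -1e-12 or vals.max() > 1 + 1e-12:
        raise ValidationError("responses must lie in [0, 1] to build an ACC")
    h = difficulties.lookup(s.index)
    origin, q = difficulties.origin, difficulties.q

    distinct = np.unique(h)
    if bins is None:
        bins = "identity" if distinct.size <= IDENTITY_BIN_LIMIT else DEFAULT_N_BINS

    if bins == "identity":
        frame = pd.DataFrame({"h": h, "r": vals}).groupby("h", sort=True)["r"].mean()
        return ACC(frame.index.to_numpy(), frame.to_numpy(), q=q, origin=origin,
                   interpolation=interpolation, bin_spec="identity", n_items=len(s))

    nbins = int(bins)
    if nbins < 1:
        raise ValidationError("number of bins must be positive")
    edges = np.linspace(origin, q, nbins + 1)
    # right-inclusive last bin so h == q is kept
    idx = np.clip(np.digitize(h, edges[1:-1]), 0, nbins - 1)
    mids, means = [], []
    for b in range(nbins):
        mask = idx == b
        if mask.any():
            mids.append(0.5 * (edges[b] + edges[b + 1]))
            means.append(vals[mask].mean())
    return ACC(np.array(mids), np.array(means), q=q, origin=origin,
               interpolation=interpolation, bin_spec=f"equal-width-{nbins}",
               n_items=len(s))


# ----------------------------------------------------------------------
# integrals
# ----------------------------------------------------------------------

def _integrals(acc: ACC) -> tuple[float, float]:
    """(Psi, M) over [origin, q], with M taken about the origin.

    Psi is the exact integral of the interpolant (trapezoid on linear
    segments).  M uses the exact segment formula for the quadratic product
    h * psi(h); integrating the sampled product with a plain trapezoid would
    break the analytic guarantee 2M - Psi^2 >= 0 near discontinuities.
    """
    if acc.interpolation == "nearest":
        # staircase with jumps at midpoints between observed difficulties
        u = acc.h - acc.origin
        edges = np.concatenate(([0.0], (u[:-1] + u[1:]) / 2.0, [acc.q - acc.origin]))
        widths = np.diff(edges)
        area = float(np.sum(widths * acc.psi))
        moment = float(np.sum(acc.psi * (edges[1:] ** 2 - edges[:-1] ** 2) / 2.0))
        return area, moment
    h, psi = acc.extended_points()
    u = h - acc.origin
    du = np.diff(u)
    if acc.interpolation == "previous":
        p0 = psi[:-1]
        area = float(np.sum(du * p0))
        moment = float(np.sum(p0 * (u[1:] ** 2 - u[:-1] ** 2) / 2.0))
        return area, moment
    p0, p1 = psi[:-1], psi[1:]
    u0, u1 = u[:-1], u[1:]
    area = float(np.sum(du * (p0 + p1) / 2.0))
    moment = float(np.sum(du * ((2 * u0 + u1) * p0 + (u0 + 2 * u1) * p1) / 6.0))
    return area, moment


def capability(acc: ACC) -> float:
    """Area under the extrapolated curve over [origin, q] (difficulty units)."""
    return _integrals(acc)[0]


def partial_moment(acc: ACC) -> float:
    """First partial moment: integral of (h - origin) * psi(h) over [origin, q]."""
    return _integrals(acc)[1]


def expected_difficulty(acc: ACC) -> float:
    """Mean difficulty of the successes, M / Psi; NaN when Psi = 0."""
    psi_j, m_j = _integrals(acc)
    if psi_j <= 0.0:
        return math.nan
    return acc.origin + m_j / psi_j


def _spread_from(psi_j: float, m_j: float, q_range: float) -> float:
    v = 2.0 * m_j - psi_j * psi_j
    tol = SPREAD_CLAMP_REL_TOL * max(q_range * q_range, 1.0)
    if v < -tol:
        raise IntegrationInconsistencyError(
            f"2M - Psi^2 = {v:.3e} below -{tol:.1e}; inconsistent curve integrals"
        )
    return math.sqrt(max(v, 0.0))


def spread(acc: ACC) -> float:
    """S = sqrt(2M - Psi^2), in difficulty units; 0 for a perfect decreasing step."""
    psi_j, m_j = _integrals(acc)
    return _spread_from(psi_j, m_j, acc.q - acc.origin)


def generality_index(acc: ACC) -> float:
    """Gamma = 1 / S; +inf sentinel when S = 0 (maximum generality)."""
    s = spread(acc)
    return math.inf if s == 0.0 else 1.0 / s


def _normalised_spread_from(psi_j: float, s_j: float, q_range: float) -> float:
    """Signed-root normalisation of S^2 against the constant-curve isometric.

    s = sign(S^2 - S^2_cnst) * sqrt(|S^2 - S^2_cnst| / (Psi (q - Psi))),
    where S^2_cnst = Psi (q - Psi) and the same quantity is the distance from
    S^2_cnst to both extreme isometrics, so one denominator serves both
    branches and pins the result to exactly -1 / +1 on the step curves.
    Undefined (NaN) when Psi is 0 or q: the isometrics collapse there.
    """
    if psi_j <= 0.0 or psi_j >= q_range:
        return math.nan
    band = psi_j * (q_range - psi_j)
    d = s_j * s_j - band
    val = math.copysign(math.sqrt(min(abs(d) / band, 1.0)), d)
    return val


def normalised_spread(acc: ACC) -> float:
    psi_j, m_j = _integrals(acc)
    s_j = _spread_from(psi_j, m_j, acc.q - acc.origin)
    return _normalised_spread_from(psi_j, s_j, acc.q - acc.origin)


def normalised_generality(acc: ACC) -> float:
    """gamma = -s, from -1 (most abstruse) to +1 (maximally general)."""
    return -normalised_spread(acc) + 0.0


# ----------------------------------------------------------------------
# all metrics in one pass
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class AgentMetrics:
    """All curve summaries for one agent.

    ``defined`` is False when Psi is 0 or q, where the normalised measures
    are undefined (the isometrics collapse at the extremes); ``spread`` and
    ``capability`` remain valid there.
    """

    capability: float
    moment: float
    expected_difficulty: float
    spread: float
    generality: float
    norm_spread: float
    norm_generality: float
    defined: bool
    n_items: int | None = None
    agent: object = None

    def as_dict(self) -> dict:
        return {
            "agent": self.agent,
            "n_items": self.n_items,
            "capability": self.capability,
            "moment": self.moment,
            "expected_difficulty": self.expected_difficulty,
            "spread": self.spread,
            "generality": self.generality,
            "norm_spread": self.norm_spread,
            "norm_generality": self.norm_generality,
            "defined": self.defined,
        }


def metrics_from_acc(acc: ACC, agent=None) -> AgentMetrics:
    """Compute every per-agent metric from a built curve."""
    q_range = acc.q - acc.origin
    psi_j, m_j = _integrals(acc)
    s_j = _spread_from(psi_j, m_j, q_range)
    hbar = math.nan if psi_j <= 0 else acc.origin + m_j / psi_j
    gamma_abs = math.inf if s_j == 0.0 else 1.0 / s_j
    ns = _normalised_spread_from(psi_j, s_j, q_range)
    return AgentMetrics(
        capability=psi_j,
        moment=m_j,
        expected_difficulty=hbar,
        spread=s_j,
        generality=gamma_abs,
        norm_spread=ns,
        norm_generality=(-ns + 0.0) if not math.isnan(ns) else math.nan,
        defined=not math.isnan(ns),
        n_items=acc.n_items,
        agent=agent,
    )


def agent_metrics(
    responses,
    difficulties: DifficultyAssignment,
    bins: int | str | None = None,
    interpolation: str = "linear",
    agent=None,
) -> AgentMetrics:
    """Build the ACC for one agent and compute all metrics in one call."""
    acc = build_acc(responses, difficulties, bins=bins, interpolation=interpolation)
    return metrics_from_acc(acc, agent=agent)


# ----------------------------------------------------------------------
# isometrics and the span-length statistic
# ----------------------------------------------------------------------

def isometric_curves(q: float, grid_size: int = 101, origin: float = 0.0) -> pd.DataFrame:
    """The three reference isometrics in the capability-vs-spread plane.

    Returns a frame with columns ``capability``, ``s_general`` (gamma = +1,
    identically zero), ``s_constant`` (gamma = 0, sqrt(Psi (q - Psi))) and
    ``s_abstruse`` (gamma = -1, sqrt(2 Psi (q - Psi))).  All three collapse
    to zero at Psi = 0 and Psi = q.
    """
    if q <= origin:
        raise ValidationError("isometric_curves requires q > origin")
    if grid_size < 2:
        raise ValidationError("grid_size must be at least 2")
    psi = np.linspace(0.0, q - origin, grid_size)
    band = psi * ((q - origin) - psi)
    return pd.DataFrame(
        {
            "capability": psi,
            "s_general": np.zeros_like(psi),
            "s_constant": np.sqrt(band),
            "s_abstruse": np.sqrt(2.0 * band),
        }
    )


def span_length(binary_sequence: Iterable[int]) -> int:
    """Length of the initial run of correct responses, minus one.

    The statistic used in serial memory-span protocols (e.g. the odour span
    task): counting from the first trial, the number of consecutive correct
    responses minus one.  A failure on the very first trial gives -1.
    """
    seq = np.asarray(list(binary_sequence))
    if seq.size == 0:
        raise ValidationError("span_length of an empty sequence is undefined")
    if not np.isin(seq, (0, 1)).all():
        raise ValidationError("span_length expects a 0/1 sequence")
    run = 0
    for v in seq:
        if v != 1:
            break
        run += 1
    return run - 1
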