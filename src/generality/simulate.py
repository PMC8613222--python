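"""Synthetic agent populations with known ground-truth capability and generality.

The simulator produces response matrices from idealised agent models so the
metric pipeline can be exercised end to end without external data:

* ``step``            — full success up to a threshold theta, nothing beyond;
                        the maximally general agent (gamma = +1, Psi = theta).
* ``reverse_step``    — success only from q - theta upwards; the maximally
                        abstruse agent (gamma = -1).
* ``constant``        — success level c at every difficulty (gamma = 0).
* ``bernoulli``       — like constant but meant for stochastic 0/1 draws;
                        difficulty-independent chance performance.
* ``probit``          — success probability Phi((theta - h) / sigma): ability
                        theta, and a spread that equals sigma when theta sits
                        well inside the difficulty range.
* ``subdomain_specialist`` — a base model that completely neglects some item
                        domains (scores 0 there), the classic narrow agent.

``draws="expected"`` writes the success probability itself (a deterministic
ACC); ``draws="bernoulli"`` samples 0/1 responses with a seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .matrix import DifficultyAssignment, ResponseMatrix, ValidationError

__all__ = [
    "AgentModel",
    "ItemBank",
    "make_item_bank",
    "success_probability",
    "simulate_matrix",
    "step_population",
    "guttman_scores",
]

_KINDS = {"step", "reverse_step", "constant", "probit", "subdomain_specialist", "bernoulli"}


@dataclass(frozen=True)
class AgentModel:
    """Parametric description of one synthetic agent."""

    kind: str
    theta: float | None = None       # threshold / ability, difficulty units
    sigma: float | None = None       # probit slope scale, difficulty units
    level: float | None = None       # constant success level c in [0, 1]
    p: float | None = None           # bernoulli success probability
    neglected_domains: frozenset = frozenset()
    base_kind: str = "constant"      # behaviour of a specialist outside neglected domains
    name: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValidationError(f"unknown agent kind {self.kind!r}")
        if self.kind in ("step", "reverse_step", "probit") and self.theta is None:
            raise ValidationError(f"{self.kind} agent needs theta")
        if self.kind == "probit" and (self.sigma is None or self.sigma <= 0):
            raise ValidationError("probit agent needs sigma > 0")
        if self.kind == "constant":
            if self.level is None or not 0.0 <= self.level <= 1.0:
                raise ValidationError("constant agent needs level in [0, 1]")
        if self.kind == "bernoulli":
            if self.p is None or not 0.0 <= self.p <= 1.0:
                raise ValidationError("bernoulli agent needs p in [0, 1]")
        if self.kind == "subdomain_specialist" and not self.neglected_domains:
            raise ValidationError("specialist needs at least one neglected domain")

    def label(self, index: int) -> str:
        return self.name if self.name is not None else f"agent{index}"


@dataclass
class ItemBank:
    """Items with difficulties on [0, q] and optional domain tags."""

    frame: pd.DataFrame  # columns: difficulty [, domain]; index: item ids
    q: float
    origin: float = 0.0

    def __post_init__(self) -> None:
        if "difficulty" not in self.frame.columns:
            raise ValidationError("item bank frame needs a 'difficulty' column")
        d = self.frame["difficulty"]
        if len(d) < 1:
            raise ValidationError("item bank must contain at least one item")
        if d.min() < self.origin - 1e-12 or d.max() > self.q + 1e-12:
            raise ValidationError("item difficulties outside [origin, q]")

    @property
    def difficulties(self) -> DifficultyAssignment:
        return DifficultyAssignment(self.frame["difficulty"].copy(), q=self.q,
                                    origin=self.origin, scale="synthetic")

    @property
    def domains(self) -> pd.Series | None:
        return self.frame["domain"] if "domain" in self.frame.columns else None


def make_item_bank(
    n: int,
    q: float,
    spacing: str = "uniform_grid",
    domains: int = 0,
    seed: int | None = None,
) -> ItemBank:
    """Create ``n`` items on [0, q], on a uniform grid or uniformly at random.

    With ``domains > 0`` the items are tagged cyclically with domain labels
    A, B, C, ... so specialist agents have subdomains to neglect.
    """
    if n < 1:
        raise ValidationError("item bank needs n >= 1")
    if q <= 0:
        raise ValidationError("q must be positive")
    if spacing == "uniform_grid":
        h = np.linspace(0.0, q, n) if n > 1 else np.array([q / 2.0])
    elif spacing == "uniform_random":
        rng = np.random.default_rng(seed)
        h = np.sort(rng.uniform(0.0, q, size=n))
    else:
        raise ValidationError(f"unknown spacing {spacing!r}")
    frame = pd.DataFrame({"difficulty": h}, index=[f"i{j}" for j in range(n)])
    if domains > 0:
        tags = [chr(ord("A") + (j % domains)) for j in range(n)]
        frame["domain"] = tags
    return ItemBank(frame, q=q)


def success_probability(model: AgentModel, difficulty, q: float, domain=None) -> np.ndarray:
    """Success probability of ``model`` on items of the given difficulty.

    Step agents succeed AT the threshold (h <= theta), so a step agent's
    capability equals theta on the closed interval.  Vectorised over
    ``difficulty`` (and ``domain`` where given).
    """
    h = np.asarray(difficulty, dtype=float)
    kind = model.kind
    if kind == "subdomain_specialist":
        base = AgentModel(
            kind=model.base_kind, theta=model.theta, sigma=model.sigma,
            level=model.level, p=model.p, name=model.name,
        )
        p = success_probability(base, h, q)
        if domain is not None:
            mask = np.isin(np.asarray(domain), list(model.neglected_domains))
            p = np.where(mask, 0.0, p)
        return p
    if kind == "step":
        return (h <= model.theta).astype(float)
    if kind == "reverse_step":
        return (h >= q - model.theta).astype(float)
    if kind == "constant":
        return np.full_like(h, float(model.level))
    if kind == "bernoulli":
        return np.full_like(h, float(model.p))
    if kind == "probit":
        return norm.cdf((model.theta - h) / model.sigma)
    raise ValidationError(f"unknown agent kind {kind!r}")  # pragma: no cover


def simulate_matrix(
    models: Sequence[AgentModel],
    bank: ItemBank,
    draws: str = "expected",
    seed: int | None = None,
) -> ResponseMatrix:
    """Simulate the M x N response matrix of the given agents on the bank.

    ``draws="expected"`` stores the success probabilities themselves, giving
    deterministic curves; ``draws="bernoulli"`` samples binary responses
    with ``numpy.random.default_rng(seed)``.  Identical inputs and seed give
    identical matrices.
    """
    if len(models) == 0:
        raise ValidationError("at least one agent model is required")
    if draws not in ("expected", "bernoulli"):
        raise ValidationError(f"unknown draw mode {draws!r}")
    h = bank.frame["difficulty"].to_numpy()
    dom = bank.domains.to_numpy() if bank.domains is not None else None
    rows = np.vstack([success_probability(m, h, bank.q, dom) for m in models])
    if draws == "bernoulli":
        rng = np.random.default_rng(seed)
        rows = (rng.random(rows.shape) < rows).astype(float)
    index = [m.label(i) for i, m in enumerate(models)]
    frame = pd.DataFrame(rows, index=index, columns=bank.frame.index)
    return ResponseMatrix(frame, domain="unit")


def step_population(thetas: Iterable[float], prefix: str = "step") -> list[AgentModel]:
    """A Guttman population: step agents with the given thresholds.

    On a shared item bank sorted by difficulty their expected responses form
    a perfectly banded (diagonal) matrix: each agent solves every item up to
    its threshold and nothing beyond.
    """
    return [AgentModel(kind="step", theta=float(t), name=f"{prefix}{i}")
            for i, t in enumerate(thetas)]


def guttman_scores(thetas: Sequence[float], difficulties: Sequence[float],
                   graded: bool = False) -> pd.DataFrame:
    """Raw score matrix of a perfectly difficulty-ordered population.

    Binary by default (1 when theta >= difficulty).  With ``graded=True``
    the scores are theta - difficulty, a real-valued matrix with the same
    ordering on every item, suitable as input to the rank and
    reference-distribution transformations (which only use score order).
    """
    t = np.asarray(thetas, dtype=float)[:, None]
    h = np.asarray(difficulties, dtype=float)[None, :]
    vals = (t - h) if graded else (t >= h).astype(float)
    return pd.DataFrame(
        vals,
        index=[f"a{i}" for i in range(t.shape[0])],
        columns=[f"i{j}" for j in range(h.shape[1])],
    )
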