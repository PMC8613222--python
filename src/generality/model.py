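"""Model/Results interface for a full generality analysis.

``GeneralityAnalysis`` binds a response matrix to a difficulty assignment
(intrinsic, or produced by one of the extrinsic transformations); ``fit``
builds every agent's characteristic curve and returns a
``GeneralityResults`` object carrying the per-agent estimates, the
population summary, the SLODR median-split diagnostic, the isometric
reference curves and a capability-vs-spread plot.

Example
-------
>>> from generality import GeneralityAnalysis, make_item_bank, simulate_matrix, step_population
>>> bank = make_item_bank(101, q=10.0)
>>> rm = simulate_matrix(step_population([2.0, 5.0, 8.0]), bank)
>>> res = GeneralityAnalysis(rm, bank.difficulties, bins="identity").fit()
>>> res.metrics[["capability", "spread", "norm_generality"]].round(3)  # doctest: +SKIP
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from . import acc as _acc
from .matrix import DifficultyAssignment, ResponseMatrix, ValidationError
from .population import PopulationSummary, SlodrSplit, slodr_test, summarise
from .transforms import TransformResult

__all__ = ["GeneralityAnalysis", "GeneralityResults"]

METRIC_COLUMNS = [
    "n_items",
    "capability",
    "moment",
    "expected_difficulty",
    "spread",
    "generality",
    "norm_spread",
    "norm_generality",
    "defined",
]


class GeneralityAnalysis:
    """Generality analysis of a response matrix over a difficulty metric.

    Parameters
    ----------
    responses : ResponseMatrix or DataFrame
        Accomplishments in [0, 1]; rows are agents, columns items.
    difficulties : DifficultyAssignment, Series or mapping
        Per-item difficulty.  A Series/mapping is wrapped with q defaulting
        to the maximum item difficulty.
    bins : None, "identity" or int
        Binning rule for the curves (see :func:`generality.build_acc`).
    q, origin : float, optional
        Override the difficulty range.
    interpolation : {"linear", "previous"}
        Curve reading between observed difficulties.  ``"previous"``
        (staircase) is the natural choice for binary matrices on ordinal
        difficulty levels; ``"linear"`` (trapezoidal) is the default.
    """

    def __init__(
        self,
        responses,
        difficulties,
        bins: int | str | None = None,
        q: float | None = None,
        origin: float | None = None,
        interpolation: str = "linear",
    ):
        if not isinstance(responses, ResponseMatrix):
            responses = ResponseMatrix(pd.DataFrame(responses))
        if not isinstance(difficulties, DifficultyAssignment):
            difficulties = DifficultyAssignment.from_series(pd.Series(dict(difficulties))
                                                            if isinstance(difficulties, Mapping)
                                                            else difficulties)
        if q is not None or origin is not None:
            difficulties = DifficultyAssignment(
                difficulties.values,
                q=float(q) if q is not None else difficulties.q,
                origin=float(origin) if origin is not None else difficulties.origin,
                shift_applied=difficulties.shift_applied,
                scale=difficulties.scale,
            )
        missing = pd.Index(responses.item_ids).difference(difficulties.values.index)
        if len(missing):
            raise ValidationError(f"items without difficulty: {list(missing[:5])}")
        self.responses = responses
        self.difficulties = difficulties
        self.bins = bins
        self.interpolation = interpolation

    # -- alternative constructors -----------------------------------------
    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, difficulties, **kwargs) -> "GeneralityAnalysis":
        """Wide DataFrame (agents x items) plus a difficulty Series/mapping."""
        return cls(ResponseMatrix(frame), difficulties, **kwargs)

    @classmethod
    def from_long(cls, frame: pd.DataFrame, difficulties,
                  agent_col: str = "agent", item_col: str = "item",
                  response_col: str = "response", **kwargs) -> "GeneralityAnalysis":
        rm = ResponseMatrix.from_long(frame, agent_col, item_col, response_col)
        return cls(rm, difficulties, **kwargs)

    @classmethod
    def from_transform(cls, result: TransformResult, **kwargs) -> "GeneralityAnalysis":
        """Analysis of a transformed matrix with its derived difficulties."""
        return cls(result.matrix, result.difficulties, **kwargs)

    # -- fitting ------------------------------------------------------------
    def build_acc(self, agent) -> _acc.ACC:
        """The characteristic curve of one agent under this model's settings."""
        return _acc.build_acc(self.responses.row(agent), self.difficulties,
                              bins=self.bins, interpolation=self.interpolation)

    def fit(self) -> "GeneralityResults":
        rows = []
        for agent in self.responses.agent_ids:
            m = _acc.agent_metrics(self.responses.row(agent), self.difficulties,
                                   bins=self.bins, interpolation=self.interpolation,
                                   agent=agent)
            rows.append(m.as_dict())
        metrics = pd.DataFrame(rows).set_index("agent")
        metrics = metrics[METRIC_COLUMNS]
        return GeneralityResults(self, metrics)


class GeneralityResults:
    """Per-agent estimates and population diagnostics of a fitted analysis."""

    def __init__(self, model: GeneralityAnalysis, metrics: pd.DataFrame):
        self.model = model
        self.metrics = metrics
        self._population: PopulationSummary | None = None

    @property
    def q(self) -> float:
        return self.model.difficulties.q

    @property
    def population(self) -> PopulationSummary:
        if self._population is None:
            self._population = summarise(self.metrics)
        return self._population

    def slodr(self, corr_method: str = "pearson") -> SlodrSplit:
        """Median-split test of Spearman's Law of Diminishing Returns."""
        return slodr_test(self.metrics, corr_method=corr_method)

    def isometrics(self, grid_size: int = 101) -> pd.DataFrame:
        """The gamma = +1 / 0 / -1 reference curves for this difficulty range."""
        return _acc.isometric_curves(self.q, grid_size, origin=self.model.difficulties.origin)

    def summary(self) -> str:
        """Plain-text summary in the spirit of a statsmodels results table."""
        pop = self.population
        lines = [
            "Generality analysis",
            "=" * 66,
            f"Agents: {len(self.metrics):>5d}    Items: {len(self.model.difficulties):>6d}"
            f"    Difficulty range: [{self.model.difficulties.origin:g}, {self.q:g}]",
            f"Difficulty scale: {self.model.difficulties.scale}"
            f"    Interpolation: {self.model.interpolation}",
            "-" * 66,
            f"Mean normalised generality (gamma): {pop.mean_norm_generality:8.4f}",
            f"Abstruse agents (gamma < 0):        {pop.pct_abstruse:7.2f} %",
            f"Corr(gamma, capability):            {pop.corr_gamma_capability:8.4f}"
            f"  ({pop.corr_method})",
            f"Defined / undefined agents:         {pop.n_agents} / {pop.n_undefined}",
            "-" * 66,
        ]
        show = self.metrics[["capability", "expected_difficulty", "spread",
                             "norm_generality"]].describe().loc[["mean", "std", "min", "max"]]
        lines.append(show.to_string(float_format=lambda v: f"{v:10.4f}"))
        lines.append("=" * 66)
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        from .io import write_metrics

        write_metrics(self.metrics, path)

    def plot(self, ax=None, annotate: bool = False):
        """Capability-vs-spread scatter with the three isometric curves."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        iso = self.isometrics(201)
        ax.plot(iso["capability"], iso["s_abstruse"], "r:", label=r"$\gamma=-1$")
        ax.plot(iso["capability"], iso["s_constant"], "b:", label=r"$\gamma=0$")
        ax.plot(iso["capability"], iso["s_general"], "g:", label=r"$\gamma=+1$")
        ax.scatter(self.metrics["capability"], self.metrics["spread"],
                   s=18, c="k", zorder=3)
        if annotate:
            for agent, row in self.metrics.iterrows():
                ax.annotate(str(agent), (row["capability"], row["spread"]),
                            fontsize=7, xytext=(2, 2), textcoords="offset points")
        ax.set_xlabel(r"capability $\Psi$")
        ax.set_ylabel(r"spread $S$")
        ax.legend(loc="best", fontsize=8)
        return ax

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<GeneralityResults: {len(self.metrics)} agents, "
                f"q={self.q:g}, mean gamma="
                f"{self.population.mean_norm_generality:.3f}>")
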