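"""Population-level summaries of per-agent capability and generality.

Capability and generality are individual measures: adding, removing or
duplicating other agents never changes them (unlike factor-analytic or
variance-based notions of a general factor).  The summaries here simply
aggregate the individual values — the mean normalised generality of a
population, the share of "abstruse" agents (gamma < 0, failing more on the
easy items than the hard ones), the correlation between normalised
generality and capability, and a median-split diagnostic for Spearman's Law
of Diminishing Returns (SLODR): under SLODR the high-capability half of a
population should be *less* general than the low half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .acc import AgentMetrics
from .matrix import ValidationError

__all__ = ["PopulationSummary", "SlodrSplit", "summarise", "slodr_test", "classify_abstruse"]


@dataclass(frozen=True)
class PopulationSummary:
    mean_norm_generality: float
    pct_abstruse: float              # percentage of defined agents with gamma < 0
    corr_gamma_capability: float     # Pearson (or Spearman) r; NaN when undefined
    n_agents: int                    # defined agents entering the summary
    n_undefined: int                 # agents excluded because gamma is undefined
    corr_method: str = "pearson"

    def as_dict(self) -> dict:
        return {
            "mean_norm_generality": self.mean_norm_generality,
            "pct_abstruse": self.pct_abstruse,
            "corr_gamma_capability": self.corr_gamma_capability,
            "n_agents": self.n_agents,
            "n_undefined": self.n_undefined,
            "corr_method": self.corr_method,
        }


@dataclass(frozen=True)
class SlodrSplit:
    split_value: float               # the capability median
    low: PopulationSummary
    high: PopulationSummary
    slodr_consistent: bool           # mean gamma(high) < mean gamma(low)


def _as_frame(metrics) -> pd.DataFrame:
    if isinstance(metrics, pd.DataFrame):
        return metrics
    rows = [m.as_dict() for m in metrics]
    if not rows:
        raise ValidationError("no agent metrics supplied")
    return pd.DataFrame(rows)


def summarise(metrics, corr_method: str = "pearson") -> PopulationSummary:
    """Aggregate per-agent metrics into a population summary.

    Agents with undefined normalised generality (capability at 0 or q) are
    excluded from the mean and the correlation and reported separately.
    The correlation needs at least three defined agents and non-degenerate
    variance in both variables; otherwise it is NaN.
    """
    frame = _as_frame(metrics)
    defined = frame[frame["defined"].astype(bool)]
    n_undefined = len(frame) - len(defined)
    if defined.empty:
        raise ValidationError("no agents with defined normalised generality")
    gamma = defined["norm_generality"].to_numpy(dtype=float)
    psi = defined["capability"].to_numpy(dtype=float)
    mean_gamma = float(gamma.mean())
    pct_abstruse = float((gamma < 0).mean() * 100.0)
    corr = math.nan
    if len(gamma) >= 3 and np.std(gamma) > 0 and np.std(psi) > 0:
        if corr_method == "pearson":
            corr = float(stats.pearsonr(gamma, psi).statistic)
        elif corr_method == "spearman":
            corr = float(stats.spearmanr(gamma, psi).statistic)
        else:
            raise ValidationError(f"unknown correlation method {corr_method!r}")
    return PopulationSummary(
        mean_norm_generality=mean_gamma,
        pct_abstruse=pct_abstruse,
        corr_gamma_capability=corr,
        n_agents=len(defined),
        n_undefined=n_undefined,
        corr_method=corr_method,
    )


def slodr_test(metrics, corr_method: str = "pearson") -> SlodrSplit:
    """Median split on capability; SLODR predicts lower generality in the high group.

    Agents with capability at or below the median go to the low group
    (deterministic tie rule).  Each group must keep at least two agents.
    """
    frame = _as_frame(metrics)
    defined = frame[frame["defined"].astype(bool)]
    if len(defined) < 4:
        raise ValidationError("SLODR split needs at least four defined agents")
    median = float(defined["capability"].median())
    low = defined[defined["capability"] <= median]
    high = defined[defined["capability"] > median]
    if len(low) < 2 or len(high) < 2:
        raise ValidationError("SLODR split left fewer than two agents in a group")
    low_summary = summarise(low, corr_method=corr_method)
    high_summary = summarise(high, corr_method=corr_method)
    return SlodrSplit(
        split_value=median,
        low=low_summary,
        high=high_summary,
        slodr_consistent=high_summary.mean_norm_generality < low_summary.mean_norm_generality,
    )


def classify_abstruse(metrics: AgentMetrics) -> bool | None:
    """True when the agent's normalised generality is strictly negative.

    Abstruse agents fail more on the easy items than on the hard ones.
    Returns None when gamma is undefined.
    """
    if not metrics.defined or math.isnan(metrics.norm_generality):
        return None
    return metrics.norm_generality < 0.0
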