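"""Unit tests for curve construction and the per-agent metrics."""

import math

import numpy as np
import pandas as pd
import pytest

from generality import (
    ACC,
    DifficultyAssignment,
    EmptyAgentError,
    IntegrationInconsistencyError,
    MissingDifficultyError,
    ValidationError,
    agent_metrics,
    build_acc,
    capability,
    expected_difficulty,
    generality_index,
    isometric_curves,
    metrics_from_acc,
    normalised_generality,
    partial_moment,
    span_length,
    spread,
)
from generality.acc import _spread_from


def step_acc(theta=5.0, q=10.0, n=1001):
    return ACC.from_function(lambda h: 1.0 if h <= theta else 0.0, q=q, n=n, jumps=[theta])


def const_acc(c=0.5, q=10.0, n=1001):
    return ACC.from_function(lambda h: c, q=q, n=n)


def reverse_step_acc(theta=7.0, q=10.0, n=1001):
    return ACC.from_function(lambda h: 1.0 if h >= theta else 0.0, q=q, n=n, jumps=[theta])


class TestBuildACC:
    def test_ties_are_averaged(self):
        diff = DifficultyAssignment.from_mapping({"i1": 1.0, "i2": 1.0, "i3": 2.0}, q=2.0)
        acc = build_acc({"i1": 1.0, "i2": 1.0, "i3": 0.0}, diff, bins="identity")
        assert acc.h.tolist() == [1.0, 2.0]
        assert acc.psi.tolist() == [1.0, 0.0]

    @pytest.mark.parametrize("c", [0.0, 0.3, 1.0])
    def test_constant_agent_has_flat_curve(self, c):
        diff = DifficultyAssignment.from_series(
            pd.Series(np.linspace(0, 10, 7), index=[f"i{k}" for k in range(7)]))
        acc = build_acc({f"i{k}": c for k in range(7)}, diff)
        assert np.allclose(acc.psi, c)

    def test_binned_means_match_direct_grouping(self, rng):
        n = 200
        h = rng.uniform(0, 10, size=n)
        r = (rng.random(n) < 0.5).astype(float)
        items = [f"i{k}" for k in range(n)]
        diff = DifficultyAssignment.from_series(pd.Series(h, index=items), q=10.0)
        acc = build_acc(pd.Series(r, index=items), diff, bins=10)
        # brute-force recomputation of the bin means
        edges = np.linspace(0, 10, 11)
        for mid, psi in zip(acc.h, acc.psi):
            b = int(np.searchsorted(edges, mid) - 1)
            mask = (h >= edges[b]) & (h < edges[b + 1]) if b < 9 else (h >= edges[9])
            assert psi == pytest.approx(r[mask].mean())
            assert mid == pytest.approx((edges[b] + edges[b + 1]) / 2)

    def test_default_binning_switches_at_25_distinct_values(self):
        items = [f"i{k}" for k in range(30)]
        diff = DifficultyAssignment.from_series(
            pd.Series(np.linspace(0, 10, 30), index=items))
        acc = build_acc(pd.Series(1.0, index=items), diff)
        assert acc.bin_spec == "equal-width-10"
        diff20 = DifficultyAssignment.from_series(
            pd.Series(np.linspace(0, 10, 20), index=items[:20]))
        acc20 = build_acc(pd.Series(1.0, index=items[:20]), diff20)
        assert acc20.bin_spec == "identity"

    def test_missing_responses_are_dropped_and_counted(self):
        diff = DifficultyAssignment.from_mapping({"a": 1.0, "b": 2.0, "c": 3.0})
        acc = build_acc({"a": 1.0, "b": np.nan, "c": 0.0}, diff, bins="identity")
        assert acc.n_items == 2
        assert acc.h.tolist() == [1.0, 3.0]

    def test_errors(self):
        diff = DifficultyAssignment.from_mapping({"a": 1.0})
        with pytest.raises(MissingDifficultyError):
            build_acc({"a": 1.0, "zz": 0.5}, diff)
        with pytest.raises(EmptyAgentError):
            build_acc({"a": np.nan}, diff)


class TestCapability:
    def test_decreasing_step_area_is_threshold(self):
        assert capability(step_acc(5.0)) == pytest.approx(5.0, abs=1e-12)

    def test_constant_half_area(self):
        assert capability(const_acc(0.5)) == pytest.approx(5.0, abs=1e-12)

    def test_probit_matches_fine_grid_quadrature(self):
        from scipy.stats import norm

        acc = ACC.from_function(lambda h: norm.cdf((6.0 - h) / 1.0), q=12.0, n=1001)
        grid = np.linspace(0, 12, 2_000_001)
        oracle = np.trapezoid(norm.cdf((6.0 - grid) / 1.0), grid)
        assert capability(acc) == pytest.approx(oracle, abs=1e-3)


class TestPartialMoment:
    def test_step(self):
        assert partial_moment(step_acc(5.0)) == pytest.approx(12.5, abs=1e-12)

    def test_constant(self):
        assert partial_moment(const_acc(0.5)) == pytest.approx(25.0, abs=1e-12)

    def test_piecewise_linear_toy_vs_oracle(self, make_piecewise):
        from conftest import riemann_oracle

        acc = make_piecewise()
        _, m_oracle = riemann_oracle(acc)
        assert partial_moment(acc) == pytest.approx(m_oracle, abs=1e-6)


class TestExpectedDifficulty:
    def test_step_is_half_capability(self):
        assert expected_difficulty(step_acc(5.0)) == pytest.approx(2.5)

    def test_constant_is_midpoint(self):
        assert expected_difficulty(const_acc(0.5)) == pytest.approx(5.0)

    def test_zero_capability_is_nan_not_crash(self):
        acc = const_acc(0.0)
        assert math.isnan(expected_difficulty(acc))
        m = metrics_from_acc(acc)
        assert not m.defined and math.isnan(m.expected_difficulty)

    def test_ratio_of_oracle_integrals(self, make_piecewise):
        from conftest import riemann_oracle

        acc = make_piecewise()
        a, m = riemann_oracle(acc)
        assert expected_difficulty(acc) == pytest.approx(m / a, rel=1e-6)


class TestSpread:
    def test_decreasing_step_any_threshold(self):
        for theta in (1.0, 5.0, 9.0):
            assert spread(step_acc(theta)) == pytest.approx(0.0, abs=1e-9)

    def test_constant_closed_form(self):
        c, q = 0.5, 10.0
        assert spread(const_acc(c, q)) == pytest.approx(q * math.sqrt(c * (1 - c)), abs=1e-9)

    def test_increasing_step_closed_form(self):
        acc = reverse_step_acc(7.0)  # Psi = 3, q = 10
        assert spread(acc) ** 2 == pytest.approx(2 * 3 * 7, abs=1e-9)

    def test_large_negative_radicand_raises(self):
        with pytest.raises(IntegrationInconsistencyError):
            _spread_from(5.0, 1.0, 10.0)  # 2M - Psi^2 = -23

    def test_tiny_negative_radicand_clamps_to_zero(self):
        assert _spread_from(1.0, 0.5 - 1e-12, 10.0) == 0.0


class TestGenerality:
    def test_reciprocal(self):
        assert generality_index(const_acc(0.5)) == pytest.approx(0.2)

    def test_step_gives_infinity_sentinel(self):
        assert generality_index(step_acc()) == math.inf

    def test_spread_two_gives_half(self):
        # increasing step with Psi chosen so S = 2: 2 Psi (q - Psi) = 4
        q = 10.0
        theta = q - (5 - math.sqrt(23))  # Psi = 5 - sqrt(23) => S^2 = 4
        acc = reverse_step_acc(theta, q)
        assert generality_index(acc) == pytest.approx(0.5, rel=1e-9)


class TestNormalisedGenerality:
    def test_three_anchors(self):
        assert normalised_generality(step_acc()) == pytest.approx(1.0, abs=1e-12)
        assert normalised_generality(const_acc()) == pytest.approx(0.0, abs=1e-12)
        assert normalised_generality(reverse_step_acc()) == pytest.approx(-1.0, abs=1e-12)

    def test_undefined_at_extremes(self):
        assert math.isnan(normalised_generality(const_acc(0.0)))
        assert math.isnan(normalised_generality(const_acc(1.0)))
        m = metrics_from_acc(const_acc(1.0))
        assert not m.defined and m.spread == pytest.approx(0.0, abs=1e-9)


class TestAgentMetrics:
    def test_step_agent_full_pipeline(self):
        items = [f"i{k}" for k in range(21)]
        h = np.linspace(0, 10, 21)
        diff = DifficultyAssignment.from_series(pd.Series(h, index=items), q=10.0)
        resp = pd.Series((h <= 4.0).astype(float), index=items)
        m = agent_metrics(resp, diff, bins="identity", interpolation="previous")
        assert m.capability == pytest.approx(4.5)  # first failed level at 4.5
        assert m.spread == pytest.approx(0.0, abs=1e-9)
        assert m.norm_generality == pytest.approx(1.0)
        assert m.generality == math.inf

    def test_constant_agent_gamma_zero(self):
        items = [f"i{k}" for k in range(11)]
        diff = DifficultyAssignment.from_series(
            pd.Series(np.linspace(0, 10, 11), index=items))
        m = agent_metrics(pd.Series(0.5, index=items), diff)
        assert m.norm_generality == pytest.approx(0.0, abs=1e-12)
        assert m.defined

    def test_probit_spread_close_to_sigma(self):
        from scipy.stats import norm

        acc = ACC.from_function(lambda h: norm.cdf((10.0 - h) / 1.0), q=20.0, n=2001)
        m = metrics_from_acc(acc)
        assert abs(m.spread - 1.0) < 0.05
        assert m.capability == pytest.approx(10.0, abs=1e-3)


class TestIsometrics:
    def test_formula_values(self):
        iso = isometric_curves(10.0, 101)
        mid = iso.iloc[50]
        assert mid["capability"] == pytest.approx(5.0)
        assert mid["s_constant"] == pytest.approx(5.0)
        assert mid["s_abstruse"] == pytest.approx(math.sqrt(50.0))
        assert mid["s_general"] == 0.0

    def test_collapse_at_extremes(self):
        iso = isometric_curves(10.0, 3)
        assert iso["capability"].tolist() == [0.0, 5.0, 10.0]
        for col in ("s_general", "s_constant", "s_abstruse"):
            assert iso[col].iloc[0] == 0.0 and iso[col].iloc[-1] == 0.0

    def test_invalid_q(self):
        with pytest.raises(ValidationError):
            isometric_curves(0.0)


class TestSpanLength:
    @pytest.mark.parametrize(
        "seq,expected",
        [([1, 1, 1, 0, 1], 2), ([0, 1, 1], -1), ([1] * 7, 6), ([1, 0], 0)],
    )
    def test_examples(self, seq, expected):
        assert span_length(seq) == expected

    def test_empty_raises(self):
        with pytest.raises(ValidationError):
            span_length([])


class TestACCValidation:
    def test_decreasing_h_rejected(self):
        with pytest.raises(ValidationError):
            ACC([2.0, 1.0], [1.0, 0.0], q=10.0)

    def test_psi_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            ACC([0.0, 1.0], [0.5, 1.5], q=10.0)

    def test_duplicate_h_encodes_jump(self):
        acc = ACC([0.0, 5.0, 5.0, 10.0], [1.0, 1.0, 0.0, 0.0], q=10.0)
        assert capability(acc) == pytest.approx(5.0)
        assert spread(acc) == pytest.approx(0.0, abs=1e-12)
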