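import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from generality import ACC


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_piecewise_linear(rng, q=10.0, max_knots=8):
    """Random piecewise-linear curve as an ACC with knots on [0, q]."""
    k = rng.integers(2, max_knots + 1)
    h = np.sort(rng.uniform(0, q, size=k))
    h[0], h[-1] = 0.0, q
    psi = rng.uniform(0, 1, size=k)
    return ACC(h, psi, q=q)


@pytest.fixture
def make_piecewise(rng):
    return lambda: random_piecewise_linear(rng)


def riemann_oracle(acc, n=200_001):
    """Independent fine-grid oracle for (Psi, M): np.interp + np.trapezoid.

    The grid is refined around the curve's own knots so the piecewise-linear
    interpolant is reproduced exactly; integration uses numpy's trapezoid,
    a different code path from the package's exact segment formulas.
    """
    h, psi = acc.extended_points()
    grid = np.union1d(np.linspace(acc.origin, acc.q, n), h)
    vals = np.interp(grid, h, psi)
    area = np.trapezoid(vals, grid)
    moment = np.trapezoid((grid - acc.origin) * vals, grid)
    return float(area), float(moment)
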