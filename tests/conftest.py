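"""Shared fixtures and numeric oracles for the test suite."""

import numpy as np
import pytest
from scipy import integrate

from ntpqed.distribution import Params, pdf, sf

# A sweep across qualitatively different corners of the parameter space:
# decreasing/unimodal densities, increasing/decreasing/bathtub hazards,
# small and large rates.
PARAM_GRID = [
    Params(0.5, 0.1),
    Params(0.5, 0.5),
    Params(1.0, 1.0),
    Params(1.5, 2.5),
    Params(2.0, 3.0),
    Params(6.0, 2.0),
    Params(0.05, 1.5),
    Params(10.0, 0.3),
]


@pytest.fixture(params=PARAM_GRID, ids=lambda p: f"a{p.alpha}_b{p.beta}")
def p_any(request) -> Params:
    return request.param


@pytest.fixture
def p_ref() -> Params:
    return Params(1.5, 2.5)


def quad_moment(r: float, p: Params, upper: float | None = None) -> float:
    """Quadrature oracle for E[X^r 1{X <= upper}] (upper=None: full moment).

    Splits the integral at the mean to help the adaptive rule, and uses the
    semi-infinite tail directly.
    """
    mean = (2 * p.beta**2 + p.alpha * p.beta**2 + 6) / (p.beta * p.D)

    def g(x):
        return x**r * pdf(x, p)

    if upper is None:
        v1, _ = integrate.quad(g, 0.0, mean, limit=200)
        v2, _ = integrate.quad(g, mean, np.inf, limit=200)
        return v1 + v2
    cut = min(mean, upper)
    v1, _ = integrate.quad(g, 0.0, cut, limit=200)
    v2, _ = integrate.quad(g, cut, upper, limit=200)
    return v1 + v2


def quad_tail_survival(x: float, p: Params) -> float:
    """Quadrature oracle for the survival integral ∫_x^∞ S(u) du."""
    v, _ = integrate.quad(lambda u: sf(u, p), x, np.inf, limit=200)
    return v
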