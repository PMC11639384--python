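"""Fifteen frequentist estimators for the quadratic exponential parameters.

Each non-likelihood method is a scalar objective over (alpha, beta) built from
the fitted CDF at the order statistics (plotting-position discrepancies,
Anderson-Darling variants, Kolmogorov distance) or from the CDF spacings
(maximum product of spacings and its minimum-spacing-distance relatives).
A single dispatcher minimizes every objective; the maximum-product-of-spacings
criterion is stored negated so that convention is uniform.

Two optimizers are available:

* ``optimizer="nelder-mead"`` (default): multi-start derivative-free simplex
  on (log alpha, log beta) — robust, used for data analysis.
* ``optimizer="bfgs"``: single-start finite-difference quasi-Newton in the
  natural parameter space.  On the nonsmooth max/absolute-value objectives it
  terminates near its starting point; the Monte-Carlo engine uses it with
  truth initialization to emulate the estimator-comparison study protocol
  (see docs/methods.md).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .distribution import Params, cdf as _cdf, sf as _sf

__all__ = [
    "METHODS",
    "SPACING_METHODS",
    "Sample",
    "EstimationResult",
    "spacings",
    "loglik",
    "neg2_loglik",
    "objective",
    "fit",
    "mle_standard_errors",
    "auto_init",
]

METHODS = (
    "mle", "ade", "cvme", "mpse", "olse", "rtade", "wlse", "ltade",
    "msade", "msalde", "adsoe", "ke", "mssd", "mssld", "mslnd",
)
SPACING_METHODS = frozenset({"mpse", "msade", "msalde", "mssd", "mssld", "mslnd"})

_TINY = 1e-300
_FMAX = 1.0 - 1e-16


@dataclass(frozen=True)
class Sample:
    """Positive observations with cached ascending order statistics."""

    values: np.ndarray
    provenance: str = "unknown"
    sorted_values: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float).ravel()
        if vals.size == 0:
            raise ValueError("sample is empty")
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ValueError("sample values must be positive finite reals")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "sorted_values", np.sort(vals))

    @property
    def n(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class EstimationResult:
    method: str
    alpha_hat: float
    beta_hat: float
    objective_value: float
    converged: bool
    n_evals: int
    init_used: tuple
    se_alpha: float | None = None
    se_beta: float | None = None

    @property
    def params(self) -> Params:
        return Params(self.alpha_hat, self.beta_hat)


def _break_ties(xs: np.ndarray) -> np.ndarray:
    """Deterministic jitter of exact ties before forming spacings.

    The k-th repeat of a tied value is shifted by k * 1e-9 * scale so the
    sorted sample is strictly increasing (spacing objectives degenerate on
    zero spacings).
    """
    if xs.size == np.unique(xs).size:
        return xs
    scale = max(xs[-1] - xs[0], xs[-1], 1.0)
    out = xs.copy()
    k = 0
    for i in range(1, out.size):
        if out[i] <= out[i - 1]:
            k += 1
            out[i] = out[i - 1] + k * 1e-9 * scale
        else:
            k = 0
    return out


def spacings(s: Sample, p: Params) -> np.ndarray:
    """CDF spacings Λ_i = F(x_{i:n}) − F(x_{i−1:n}) with F(x₀)=0, F(x_{n+1})=1.

    Returns n+1 nonnegative values summing to one (before the log-guard
    clipping applied inside the spacing objectives).
    """
    xs = _break_ties(s.sorted_values)
    F = _cdf(xs, p)
    return np.diff(np.concatenate(([0.0], F, [1.0])))


def loglik(s: Sample, p: Params) -> float:
    """Log-likelihood 3n logβ + Σ log(α+βxᵢ+xᵢ²) − n log D − β Σ xᵢ."""
    x = s.values
    a, b = p.alpha, p.beta
    return float(
        3 * s.n * np.log(b)
        + np.log(a + b * x + x * x).sum()
        - s.n * np.log(p.D)
        - b * x.sum()
    )


def neg2_loglik(s: Sample, p: Params) -> float:
    return -2.0 * loglik(s, p)


def _objective_impl(method: str, s: Sample, a: float, b: float,
                    adsoe_as_printed: bool) -> float:
    p = Params(a, b)
    n = s.n
    if method == "mle":
        return neg2_loglik(s, p)

    xs = s.sorted_values
    i = np.arange(1, n + 1)

    if method in SPACING_METHODS:
        lam = np.clip(spacings(s, p), _TINY, None)
        u = 1.0 / (n + 1)
        if method == "mpse":
            return -np.log(lam).mean()          # negated: dispatcher minimizes
        if method == "msade":
            return float(np.abs(lam - u).sum())
        if method == "msalde":
            return float(np.abs(np.log(lam) - np.log(u)).sum())
        if method == "mssd":
            return float((lam * lam - u).sum())
        if method == "mssld":
            return float(((np.log(lam) - np.log(u)) ** 2).sum())
        # mslnd
        d = lam - u
        return float((np.exp(d) - d - 1.0).sum())

    F = np.clip(_cdf(xs, p), _TINY, _FMAX)
    S = np.clip(_sf(xs, p), _TINY, _FMAX)

    if method == "ade":
        return float(-n - ((2 * i - 1) * (np.log(F) + np.log(S[::-1]))).sum() / n)
    if method == "cvme":
        return float(1.0 / (12 * n) + ((F - (2 * i - 1) / (2 * n)) ** 2).sum())
    if method == "olse":
        return float(((F - i / (n + 1)) ** 2).sum())
    if method == "rtade":
        # standard right-tail AD pairing: (2i-1) against S(x_{n+1-i:n})
        return float(n / 2 - 2 * F.sum() - ((2 * i - 1) * np.log(S[::-1])).sum() / n)
    if method == "wlse":
        w = (n + 1) ** 2 * (n + 2) / (i * (n - i + 1))
        return float((w * (F - i / (n + 1)) ** 2).sum())
    if method == "ltade":
        return float(-1.5 * n + 2 * F.sum() - ((2 * i - 1) * np.log(F)).sum() / n)
    if method == "adsoe":
        if adsoe_as_printed:
            return float(2 * np.log(F).sum() + ((2 * i - 1) * F).sum() / n)
        return float(2 * np.log(F).sum() + ((2 * i - 1) / F).sum() / n)
    if method == "ke":
        return float(np.maximum(i / n - F, F - (i - 1) / n).max())
    raise ValueError(f"unknown method {method!r}")


def objective(method: str, s: Sample, p: Params, *,
              adsoe_as_printed: bool = False) -> float:
    """Evaluate a method's criterion at given parameters (lower is better).

    The maximum-product-of-spacings value is returned negated so every method
    is minimized.  CDF/survival values are clipped away from {0, 1} inside
    logarithms; a degenerate evaluation yields a large finite value rather
    than raising.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    with np.errstate(over="ignore", invalid="ignore"):
        val = _objective_impl(method, s, p.alpha, p.beta, adsoe_as_printed)
    return val if np.isfinite(val) else np.inf


def auto_init(s: Sample) -> tuple[float, float]:
    """Moment-matching start: coarse grid on (alpha, beta) scored against the
    sample mean and second moment; falls back to (1, 1/mean)."""
    m1 = s.values.mean()
    m2 = (s.values**2).mean()
    a_grid = np.logspace(-2, 2, 25)
    b_grid = (1.0 / m1) * np.logspace(-1.2, 1.2, 25)
    A, B = np.meshgrid(a_grid, b_grid, indexing="ij")
    D = B**2 + A * B**2 + 2
    mean = (2 * B**2 + A * B**2 + 6) / (B * D)
    mom2 = (24 + 6 * B**2 + 2 * A * B**2) / (B**2 * D)
    score = ((mean - m1) / m1) ** 2 + ((mom2 - m2) / m2) ** 2
    k = np.unravel_index(np.argmin(score), score.shape)
    if np.isfinite(score[k]):
        return float(A[k]), float(B[k])
    return 1.0, 1.0 / m1


def _penalized(fun):
    def wrapped(t):
        a, b = t
        if a <= 0 or b <= 0 or not np.isfinite(a) or not np.isfinite(b):
            return 1e8 * (1.0 + abs(min(a, 0.0)) + abs(min(b, 0.0)))
        return fun(a, b)
    return wrapped


def fit(s: Sample, method: str = "mle", init="auto", *,
        optimizer: str = "nelder-mead", adsoe_as_printed: bool = False,
        compute_se: bool = True) -> EstimationResult:
    """Fit (alpha, beta) by the requested method.

    ``init`` is ``"auto"`` (moment-matching start), a ``Params``, or an
    (alpha, beta) tuple.  The default optimizer runs a deterministic
    multi-start Nelder-Mead on (log alpha, log beta) — the supplied start,
    four local perturbations of it, and three diverse moment-scale starts;
    the best criterion value wins.  ``optimizer="bfgs"`` runs one
    finite-difference BFGS search in natural space from ``init``.
    Standard errors (inverse observed information) are attached for the MLE.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if init == "auto":
        a0, b0 = auto_init(s)
    elif isinstance(init, Params):
        a0, b0 = init.alpha, init.beta
    else:
        a0, b0 = float(init[0]), float(init[1])

    def crit(a, b):
        if not (np.isfinite(a) and np.isfinite(b)) or a <= 0 or b <= 0:
            return 1e12
        with np.errstate(over="ignore", invalid="ignore"):
            v = _objective_impl(method, s, a, b, adsoe_as_printed)
        return v if np.isfinite(v) else 1e12

    n_evals = 0
    if optimizer == "bfgs":
        res = optimize.minimize(_penalized(crit), [a0, b0], method="BFGS")
        best_x = np.maximum(res.x, 1e-12)
        best_f, conv, n_evals = float(res.fun), bool(res.success), int(res.nfev)
    elif optimizer == "nelder-mead":
        # the supplied start, local perturbations of it, and three diverse
        # moment-scale starts (guards against ridge-shaped objectives whose
        # basins the local perturbations cannot escape)
        m1 = s.values.mean()
        starts = [(a0, b0), (1.5 * a0, b0), (a0 / 1.5, b0),
                  (a0, 1.5 * b0), (a0, b0 / 1.5),
                  (1.0, 1.0 / m1), (0.5, 2.0 / m1), (2.0, 0.5 / m1)]
        best_f, best_x, conv = np.inf, np.array([a0, b0]), False
        for sa, sb in starts:
            res = optimize.minimize(
                lambda t: crit(np.exp(t[0]), np.exp(t[1])),
                [np.log(sa), np.log(sb)], method="Nelder-Mead",
                options=dict(xatol=1e-10, fatol=1e-10, maxfev=5000),
            )
            n_evals += int(res.nfev)
            if res.fun < best_f:
                best_f, best_x = float(res.fun), np.exp(res.x)
                conv = conv or bool(res.success)
    else:
        raise ValueError("optimizer must be 'nelder-mead' or 'bfgs'")

    se_a = se_b = None
    if method == "mle" and compute_se:
        try:
            se_a, se_b = mle_standard_errors(s, Params(*best_x))
        except ValueError:
            se_a = se_b = np.nan
    return EstimationResult(
        method=method, alpha_hat=float(best_x[0]), beta_hat=float(best_x[1]),
        objective_value=best_f, converged=conv, n_evals=n_evals,
        init_used=(a0, b0), se_alpha=se_a, se_beta=se_b,
    )


def mle_standard_errors(s: Sample, p_hat: Params) -> tuple[float, float]:
    """Wald standard errors from the inverse observed information.

    The Hessian of the log-likelihood at the optimum is approximated by
    central finite differences; a non-positive-definite information matrix
    (flat likelihood, e.g. boundary-adjacent alpha) yields NaNs with a
    warning rather than an exception.
    """
    from statsmodels.tools.numdiff import approx_hess

    theta = np.array([p_hat.alpha, p_hat.beta])

    def ll(t):
        if t[0] <= 0 or t[1] <= 0:
            return -1e12
        return loglik(s, Params(t[0], t[1]))

    H = approx_hess(theta, ll)
    info = -H
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        warnings.warn("observed information is singular; SEs undefined")
        return np.nan, np.nan
    diag = np.diag(cov)
    if np.any(diag <= 0) or np.any(np.linalg.eigvalsh(info) <= 0):
        warnings.warn("observed information is not positive definite; SEs undefined")
        return np.nan, np.nan
    return float(np.sqrt(diag[0])), float(np.sqrt(diag[1]))
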