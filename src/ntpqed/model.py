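"""Model / Results objects in the statsmodels idiom.

``NTPQEDModel`` wraps a positive-valued sample; ``fit`` dispatches to any of
the fifteen estimators and returns an ``NTPQEDResults`` carrying the
estimates, their standard errors (likelihood fits), information criteria,
goodness-of-fit diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import estimation, measures
from .distribution import Params, hazard_shape, pdf_shape
from .estimation import EstimationResult, Sample

__all__ = ["NTPQEDModel", "NTPQEDResults"]


class NTPQEDModel:
    """Quadratic exponential lifetime model for a univariate positive sample."""

    def __init__(self, data, provenance: str = "user"):
        self.sample = data if isinstance(data, Sample) else Sample(np.asarray(data), provenance)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, column: str) -> "NTPQEDModel":
        return cls(df[column].to_numpy(dtype=float), provenance=f"column {column!r}")

    @property
    def endog(self) -> np.ndarray:
        return self.sample.values

    def loglike(self, params: Params) -> float:
        return estimation.loglik(self.sample, params)

    def fit(self, method: str = "mle", init="auto", **kwargs) -> "NTPQEDResults":
        res = estimation.fit(self.sample, method, init=init, **kwargs)
        return NTPQEDResults(self, res)


class NTPQEDResults:
    """Fit results: point estimates, uncertainty, diagnostics, summaries."""

    def __init__(self, model: NTPQEDModel, res: EstimationResult):
        self.model = model
        self._res = res

    # ---- estimates -------------------------------------------------------
    @property
    def params(self) -> np.ndarray:
        return np.array([self._res.alpha_hat, self._res.beta_hat])

    @property
    def alpha(self) -> float:
        return self._res.alpha_hat

    @property
    def beta(self) -> float:
        return self._res.beta_hat

    @property
    def bse(self) -> np.ndarray:
        se = (self._res.se_alpha, self._res.se_beta)
        return np.array([np.nan if v is None else v for v in se])

    @property
    def method(self) -> str:
        return self._res.method

    @property
    def converged(self) -> bool:
        return self._res.converged

    @property
    def objective_value(self) -> float:
        return self._res.objective_value

    @property
    def distribution(self) -> Params:
        return Params(*self.params)

    # ---- likelihood-based diagnostics -----------------------------------
    @property
    def llf(self) -> float:
        return self.model.loglike(self.distribution)

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 4.0

    @property
    def hqic(self) -> float:
        return -2.0 * self.llf + 4.0 * math.log(math.log(self.model.sample.n))

    def gof(self):
        """Goodness-of-fit report (KS/CVM/AD with p-values, AIC, HQIC)."""
        from .compare import FittedModel, gof as _gof

        m = FittedModel("ntpqed", tuple(self.params), 2, self.llf)
        return _gof(self.model.sample, m)

    def moment_summary(self) -> measures.MomentSummary:
        return measures.summary_stats(self.distribution)

    def simulate(self, n: int | None = None, seed=None) -> np.ndarray:
        from .distribution import rvs

        return rvs(n or self.model.sample.n, self.distribution, seed)

    # ---- presentation ----------------------------------------------------
    def summary(self) -> str:
        s = self.model.sample
        ms = self.moment_summary()
        shape = pdf_shape(self.distribution)
        hz = hazard_shape(self.distribution)
        se = self.bse
        lines = [
            "Quadratic exponential lifetime model",
            "=" * 52,
            f"n obs:            {s.n}",
            f"method:           {self._res.method}",
            f"converged:        {self._res.converged}   (fn evals: {self._res.n_evals})",
            f"objective:        {self._res.objective_value:.6f}",
            "-" * 52,
            f"{'param':<8}{'estimate':>12}{'std err':>12}",
            f"{'alpha':<8}{self.alpha:>12.4f}{se[0]:>12.4f}",
            f"{'beta':<8}{self.beta:>12.4f}{se[1]:>12.4f}",
            "-" * 52,
            f"-2 logL: {-2 * self.llf:.4f}   AIC: {self.aic:.4f}   HQIC: {self.hqic:.4f}",
            f"fitted mean: {ms.mean:.4f}   sd: {ms.sd:.4f}   cv: {ms.cv:.4f}",
            f"density shape: {shape.kind.value} (mode {shape.mode:.4f});"
            f" hazard: {hz.kind.value}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<NTPQEDResults method={self._res.method} alpha={self.alpha:.4g} "
                f"beta={self.beta:.4g} converged={self._res.converged}>")
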