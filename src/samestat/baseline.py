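"""Naive GLM comparator: treat observed calls as the true status.

This is the standard practice the latent-status test improves on — regress
the outcome on covariates plus the raw caller output (missing calls counted
as 0) and report a two-sided Wald test on the call coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.stats import norm
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .msame import _design

__all__ = ["WaldResult", "glm_wald_test", "NaiveGLM"]


@dataclass
class WaldResult:
    beta_hat: float
    se: float
    z: float
    pvalue: float
    diagnostics: dict | None = None

    @classmethod
    def invalid(cls, reason: str) -> "WaldResult":
        return cls(np.nan, np.nan, np.nan, np.nan, {"reason": reason})


def glm_wald_test(calls, Y, X, family: str = "gaussian") -> WaldResult:
    """Wald test of the call coefficient in an ordinary GLM.

    ``calls`` are per-sample 0/1 with missing entries (NaN) counted as 0;
    constant calls or a separated logistic fit yield an NA result with a
    diagnostic rather than an exception.
    """
    calls = np.asarray(calls, dtype=float)
    calls = np.where(np.isnan(calls), 0.0, calls)
    y = np.asarray(Y, dtype=float)
    Z = np.column_stack([_design(X), calls])
    if np.ptp(calls) == 0:
        return WaldResult.invalid("constant mutation calls")
    if family == "gaussian":
        fit = sm.OLS(y, Z).fit()
        # normal (not t) reference, matching the large-sample Wald test
        z = fit.params[-1] / fit.bse[-1]
        return WaldResult(
            beta_hat=float(fit.params[-1]),
            se=float(fit.bse[-1]),
            z=float(z),
            pvalue=float(2.0 * norm.sf(abs(z))),
        )
    if family != "binomial":
        raise ValueError(f"unknown family {family!r}")
    try:
        fit = sm.GLM(y, Z, family=sm.families.Binomial()).fit()
    except Exception as err:  # pragma: no cover - statsmodels failure modes
        return WaldResult.invalid(f"GLM failure: {err}")
    se = float(fit.bse[-1])
    if not np.isfinite(se) or se > 1e3:
        return WaldResult.invalid("separation in logistic fit")
    z = float(fit.params[-1] / se)
    return WaldResult(
        beta_hat=float(fit.params[-1]),
        se=se,
        z=z,
        pvalue=float(2.0 * norm.sf(abs(z))),
    )


class NaiveGLM(BaseEstimator):
    """Estimator wrapper for the naive observed-call GLM Wald test."""

    def __init__(self, family: str = "gaussian"):
        self.family = family

    def fit(self, X, y, *, calls):
        res = glm_wald_test(calls, y, X, family=self.family)
        self.result_ = res
        self.beta_ = res.beta_hat
        self.se_ = res.se
        self.statistic_ = res.z
        self.pvalue_ = res.pvalue
        return self

    def predict(self, X):  # pragma: no cover - convenience only
        check_is_fitted(self, "result_")
        raise NotImplementedError(
            "the naive comparator is a test, not a predictive model"
        )
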