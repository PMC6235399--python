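"""Mutation-level association test with latent true status (mSAME).

A variant caller's binary output ``O`` is an error-prone surrogate for the
true somatic status ``S``. Treating ``S`` as latent, the observed-data
likelihood for one mutation across ``n`` samples is

    L = prod_i sum_{s in {0,1}} rho_s * f_Y(Y_i | S_i = s)
                                * f(A_i, D_i, O_i | S_i = s),

where ``f_Y`` is a GLM (gaussian/identity or binomial/logit) in the
covariates and the mutation status, and the evidence term combines a
beta-binomial for the alternative read count with a Bernoulli for the call
given the status (sensitivity ``gamma1``, specificity ``gamma0``). The
association test is a likelihood-ratio test of the mutation effect
``beta = 0`` against a chi-square(1) reference, with both fits obtained by
EM over the latent status.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import chi2
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .distributions import (
    OutcomeModel,
    ReadCountModel,
    betabinom_logpmf,
    mixture_posterior,
    outcome_logdensity,
)

__all__ = [
    "SiteData",
    "CallErrorModel",
    "MixturePrior",
    "MsameFit",
    "LrtResult",
    "evidence_loglik",
    "estimate_call_error",
    "msame_em",
    "msame_test",
    "MutationSAME",
]

_GAMMA_MIN = 0.5 + 1e-6


@dataclass
class SiteData:
    """Per-sample read counts and calls for one mutation locus.

    ``O`` is stored as float with NaN marking missing calls; a call must be
    missing exactly where ``D < d0``, which :meth:`validate` enforces.
    """

    A: np.ndarray
    D: np.ndarray
    O: np.ndarray
    site_id: str = ""
    gene: str = ""

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=np.int64)
        self.D = np.asarray(self.D, dtype=np.int64)
        self.O = np.asarray(self.O, dtype=float)
        if not (self.A.shape == self.D.shape == self.O.shape):
            raise ValueError("A, D, O must have identical shape")
        if self.A.ndim != 1 or self.n < 1:
            raise ValueError("site data must be 1-D with at least one sample")
        if np.any(self.A < 0) or np.any(self.A > self.D):
            raise ValueError("require 0 <= A <= D elementwise")

    @property
    def n(self) -> int:
        return self.A.size

    def validate(self, d0: int) -> None:
        missing = np.isnan(self.O)
        bad_hi = missing & (self.D >= d0)
        if np.any(bad_hi):
            raise ValueError(
                f"site {self.site_id or '?'}: missing call at depth >= d0 "
                f"for samples {np.flatnonzero(bad_hi).tolist()}"
            )
        bad_lo = ~missing & (self.D < d0)
        if np.any(bad_lo):
            raise ValueError(
                f"site {self.site_id or '?'}: call present at depth < d0 "
                f"for samples {np.flatnonzero(bad_lo).tolist()}"
            )


@dataclass(frozen=True)
class CallErrorModel:
    """Caller sensitivity P(O=1|S=1) and specificity P(O=0|S=0)."""

    gamma1: float = 0.9
    gamma0: float = 0.98

    def __post_init__(self) -> None:
        for name, g in (("gamma1", self.gamma1), ("gamma0", self.gamma0)):
            if not 0.5 < g <= 1.0:
                raise ValueError(f"{name} must lie in (0.5, 1], got {g}")


@dataclass(frozen=True)
class MixturePrior:
    """Marginal probability that a sample truly carries the mutation."""

    rho1: float

    def __post_init__(self) -> None:
        if not 0.0 < self.rho1 < 1.0:
            raise ValueError(f"rho1 must lie in (0, 1), got {self.rho1}")

    @property
    def rho0(self) -> float:
        return 1.0 - self.rho1


@dataclass
class MsameFit:
    """One EM fit (null or alternative) of the latent-status model."""

    outcome: OutcomeModel
    prior: MixturePrior
    loglik: float
    n_iter: int
    converged: bool
    posterior: np.ndarray
    diagnostics: dict = field(default_factory=dict)


@dataclass
class LrtResult:
    """Likelihood-ratio test result; chi-square reference with 1 df."""

    statistic: float
    pvalue: float
    fit_alt: MsameFit
    fit_null: MsameFit
    df: int = 1
    site_id: str = ""
    diagnostics: dict = field(default_factory=dict)

    @property
    def beta_hat(self) -> float:
        return self.fit_alt.outcome.beta


def _log_bernoulli_call(o: np.ndarray, s: int, ce: CallErrorModel) -> np.ndarray:
    """log P(O=o | S=s); log(0) allowed when gamma hits 1."""
    p1 = ce.gamma1 if s == 1 else 1.0 - ce.gamma0  # P(O=1 | S=s)
    with np.errstate(divide="ignore"):
        return np.where(o > 0.5, np.log(p1), np.log1p(-p1))


def evidence_loglik(
    site: SiteData, rc: ReadCountModel, ce: CallErrorModel
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample log f(A, D, O | S=s) for s = 0, 1.

    High-depth samples contribute a beta-binomial term from the (s, O)
    component plus the Bernoulli call term; low-depth samples contribute
    only the status-indexed low-depth beta-binomial. Depth itself is
    ancillary and omitted (it cancels from every likelihood ratio).
    """
    site.validate(rc.d0)
    hi = site.D >= rc.d0
    out = []
    for s in (0, 1):
        ll = np.zeros(site.n, dtype=float)
        if np.any(~hi):
            ll[~hi] = betabinom_logpmf(site.A[~hi], site.D[~hi], rc.low_depth[s])
        if np.any(hi):
            o = site.O[hi]
            a, d = site.A[hi], site.D[hi]
            term = np.where(
                o > 0.5,
                betabinom_logpmf(a, d, rc.high_depth[s, 1]),
                betabinom_logpmf(a, d, rc.high_depth[s, 0]),
            )
            ll[hi] = term + _log_bernoulli_call(o, s, ce)
        out.append(ll)
    return out[0], out[1]


def estimate_call_error(site: SiteData, rc: ReadCountModel) -> CallErrorModel:
    """Plug-in estimate of (sensitivity, specificity) for one mutation.

    High-depth samples are soft-classified by the posterior weight
    ``w_i = P(S_i=1 | A_i, D_i)`` under a two-component beta-binomial
    mixture built from the model's dominant concordant components
    ((S=0,O=0) and (S=1,O=1)); sensitivity is the weighted call rate among
    putative carriers and specificity the weighted no-call rate among
    putative non-carriers. Estimates are clipped into (0.5, 1].
    """
    hi = site.D >= rc.d0
    if not np.any(hi):
        raise ValueError("no samples at or above the calling depth threshold")
    a, d, o = site.A[hi], site.D[hi], site.O[hi]
    w = mixture_posterior(a, d, rc.high_depth[0, 0], rc.high_depth[1, 1])
    sw = float(np.sum(w))
    if sw < 1e-12:
        warnings.warn(
            f"site {site.site_id or '?'}: no evidence of mutated samples; "
            "sensitivity set to 1",
            stacklevel=2,
        )
        gamma1 = 1.0
    else:
        gamma1 = float(np.sum(w * o) / sw)
    sw0 = float(np.sum(1.0 - w))
    if sw0 < 1e-12:
        warnings.warn(
            f"site {site.site_id or '?'}: no evidence of unmutated samples; "
            "specificity set to 1",
            stacklevel=2,
        )
        gamma0 = 1.0
    else:
        gamma0 = float(np.sum((1.0 - w) * (1.0 - o)) / sw0)
    return CallErrorModel(
        gamma1=float(np.clip(gamma1, _GAMMA_MIN, 1.0)),
        gamma0=float(np.clip(gamma0, _GAMMA_MIN, 1.0)),
    )


# ---------------------------------------------------------------------------
# Weighted GLM M-step
# ---------------------------------------------------------------------------


def _design(X) -> np.ndarray:
    """Covariates (n,) or (n, k) -> design matrix with a leading intercept."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    elif X.ndim != 2:
        raise ValueError("covariates must be a vector or a 2-D matrix")
    return np.column_stack([np.ones(X.shape[0]), X])


def _weighted_glm(
    Z: np.ndarray, y: np.ndarray, w: np.ndarray, family: str,
    coef0: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Maximize sum_i w_i log f(y_i | z_i'b); returns (coef, dispersion)."""
    if family == "gaussian":
        ZW = Z * w[:, None]
        coef, *_ = np.linalg.lstsq(ZW.T @ Z, ZW.T @ y, rcond=None)
        resid = y - Z @ coef
        disp = float(np.sum(w * resid**2) / np.sum(w))
        return coef, max(disp, 1e-12)
    # binomial: Newton-Raphson with observation weights
    coef = np.zeros(Z.shape[1]) if coef0 is None else coef0.copy()
    for _ in range(100):
        eta = np.clip(Z @ coef, -30, 30)
        mu = expit(eta)
        grad = Z.T @ (w * (y - mu))
        wirls = w * mu * (1.0 - mu)
        H = (Z * wirls[:, None]).T @ Z
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(H.shape[0]), grad)
        except np.linalg.LinAlgError:
            break
        coef = coef + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return coef, 1.0


def _mstep_outcome(
    y: np.ndarray,
    Z: np.ndarray,
    w1: np.ndarray,
    family: str,
    fit_beta: bool,
    prev: OutcomeModel | None = None,
) -> OutcomeModel:
    """Weighted GLM on the status-duplicated design.

    Each sample contributes a status-0 row with weight ``1 - w1`` and a
    status-1 row with weight ``w1``; under the null the status column is
    dropped (``beta`` fixed at 0) and the fit collapses to an unweighted GLM.
    """
    n, k = Z.shape
    if fit_beta:
        Zd = np.vstack([np.column_stack([Z, np.zeros(n)]),
                        np.column_stack([Z, np.ones(n)])])
        yd = np.concatenate([y, y])
        wd = np.concatenate([1.0 - w1, w1])
        coef0 = None if prev is None else np.append(prev.alpha, prev.beta)
        coef, disp = _weighted_glm(Zd, yd, wd, family, coef0)
        alpha, beta = coef[:-1], float(coef[-1])
    else:
        coef0 = None if prev is None else prev.alpha
        coef, disp = _weighted_glm(Z, y, np.ones(n), family, coef0)
        alpha, beta = coef, 0.0
    return OutcomeModel(family=family, alpha=alpha, beta=beta, dispersion=disp)


def _init_rho(site: SiteData, ce: CallErrorModel, d0: int) -> float:
    """Method-of-moments inversion of the observed call frequency."""
    o = site.O[site.D >= d0]
    n = site.n
    if o.size == 0:
        return 1.0 / n
    p_obs = float(np.mean(o))
    denom = ce.gamma1 - (1.0 - ce.gamma0)
    rho = (p_obs - (1.0 - ce.gamma0)) / denom if denom > 1e-8 else p_obs
    return float(np.clip(rho, 1.0 / n, 1.0 - 1.0 / n))


def msame_em(
    site: SiteData,
    Y,
    X,
    rc: ReadCountModel,
    ce: CallErrorModel,
    beta_fixed: float | None = None,
    family: str = "gaussian",
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> MsameFit:
    """EM fit of the latent-status association model.

    The read-count and call-error models are plug-in quantities estimated
    beforehand and held fixed; EM alternates the posterior over the latent
    status (E-step) with a weighted GLM for the outcome parameters and the
    update ``rho1 = mean(posterior)`` (M-step). ``beta_fixed=0`` gives the
    null fit. The observed-data log-likelihood is non-decreasing across
    iterations; non-convergence at ``max_iter`` is reported, not raised.
    """
    y = np.asarray(Y, dtype=float)
    Z = _design(X)
    if y.size != site.n or Z.shape[0] != site.n:
        raise ValueError("Y, X and site data disagree on the number of samples")
    fit_beta = beta_fixed is None
    if not fit_beta and beta_fixed != 0.0:
        raise ValueError("only beta_fixed=0 (the null) is supported")

    l0, l1 = evidence_loglik(site, rc, ce)
    rho1 = _init_rho(site, ce, rc.d0)
    calls0 = np.where(np.isnan(site.O), 0.0, site.O)
    w_init = np.clip(calls0, 0.05, 0.95) if fit_beta else None
    outcome = _mstep_outcome(
        y, Z, w_init if fit_beta else np.zeros(site.n), family, fit_beta
    )

    loglik = -np.inf
    w = np.full(site.n, rho1)
    converged = False
    trace: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        ly0 = outcome_logdensity(y, Z, 0, outcome)
        ly1 = outcome_logdensity(y, Z, 1, outcome)
        num0 = np.log1p(-rho1) + ly0 + l0
        num1 = np.log(rho1) + ly1 + l1
        norm = np.logaddexp(num0, num1)
        new_loglik = float(np.sum(norm))
        if not np.isfinite(new_loglik):
            raise FloatingPointError(
                f"non-finite log-likelihood at EM iteration {it}"
                + (f" (site {site.site_id})" if site.site_id else "")
            )
        trace.append(new_loglik)
        w = np.exp(num1 - norm)
        if abs(new_loglik - loglik) < tol:
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik
        rho1 = float(np.clip(np.mean(w), 1e-10, 1.0 - 1e-10))
        outcome = _mstep_outcome(y, Z, w, family, fit_beta, prev=outcome)
    if not converged:
        warnings.warn(
            f"EM did not converge in {max_iter} iterations"
            + (f" (site {site.site_id})" if site.site_id else ""),
            stacklevel=2,
        )
    return MsameFit(
        outcome=outcome,
        prior=MixturePrior(rho1=float(np.clip(rho1, 1e-12, 1 - 1e-12))),
        loglik=loglik,
        n_iter=it,
        converged=converged,
        posterior=w,
        diagnostics={"loglik_trace": trace},
    )


def _lrt_from_fits(
    fit_alt: MsameFit, fit_null: MsameFit, site_id: str = ""
) -> LrtResult:
    T = -2.0 * (fit_null.loglik - fit_alt.loglik)
    diagnostics = {}
    if T < 0:
        diagnostics["clipped_negative_T"] = T
        T = 0.0
    post = fit_alt.posterior
    if np.all(post < 1e-10) or np.all(post > 1 - 1e-10):
        diagnostics["monomorphic"] = True
        pvalue = np.nan
    else:
        pvalue = float(chi2.sf(T, df=1))
    return LrtResult(
        statistic=float(T),
        pvalue=pvalue,
        fit_alt=fit_alt,
        fit_null=fit_null,
        site_id=site_id,
        diagnostics=diagnostics,
    )


def msame_test(
    site: SiteData,
    Y,
    X,
    rc: ReadCountModel,
    ce: CallErrorModel,
    family: str = "gaussian",
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> LrtResult:
    """Likelihood-ratio test of the mutation effect for one locus.

    Fits the model with the effect free and with it fixed at zero, and
    refers ``T = -2 (loglik_null - loglik_alt)`` (clipped at 0) to
    chi-square with 1 df. Sites whose posterior status is degenerate across
    all samples yield ``pvalue = nan`` with a ``monomorphic`` diagnostic.
    """
    try:
        fit_alt = msame_em(site, Y, X, rc, ce, family=family, tol=tol,
                           max_iter=max_iter)
        fit_null = msame_em(site, Y, X, rc, ce, beta_fixed=0.0, family=family,
                            tol=tol, max_iter=max_iter)
    except FloatingPointError as err:
        raise FloatingPointError(
            f"mSAME EM failed for site {site.site_id or '?'}: {err}"
        ) from err
    return _lrt_from_fits(fit_alt, fit_null, site_id=site.site_id)


class MutationSAME(BaseEstimator):
    """Mutation-level latent-status association test, estimator-style.

    Parameters
    ----------
    read_count_model : ReadCountModel, optional
        Allele-count evidence components; defaults to the shipped
        exome-calibrated components with ``d0 = 20``.
    call_error : CallErrorModel or "estimate", default "estimate"
        Caller sensitivity/specificity. ``"estimate"`` derives them from the
        site's own read counts before the association fit.
    family : {"gaussian", "binomial"}
        Outcome GLM family (identity / logit link respectively).
    tol, max_iter : EM stopping rule on the observed-data log-likelihood.

    After :meth:`fit`, exposes ``beta_``, ``alpha_``, ``rho1_``,
    ``posterior_``, ``statistic_``, ``pvalue_``, ``loglik_``, ``n_iter_``,
    ``converged_``, ``call_error_`` and ``result_`` (the full
    :class:`LrtResult`).
    """

    def __init__(
        self,
        read_count_model: ReadCountModel | None = None,
        call_error: CallErrorModel | str = "estimate",
        family: str = "gaussian",
        tol: float = 1e-8,
        max_iter: int = 1000,
    ):
        self.read_count_model = read_count_model
        self.call_error = call_error
        self.family = family
        self.tol = tol
        self.max_iter = max_iter

    def _resolve(self, site: SiteData) -> tuple[ReadCountModel, CallErrorModel]:
        rc = self.read_count_model or ReadCountModel()
        if isinstance(self.call_error, CallErrorModel):
            ce = self.call_error
        elif self.call_error == "estimate":
            ce = estimate_call_error(site, rc)
        else:
            raise ValueError("call_error must be a CallErrorModel or 'estimate'")
        return rc, ce

    def fit(self, X, y, *, site: SiteData):
        """Fit null and alternative models and run the LRT.

        ``X`` is the covariate matrix (no intercept column; one is added),
        ``y`` the outcome, and ``site`` the locus read-count data.
        """
        rc, ce = self._resolve(site)
        res = msame_test(
            site, y, X, rc, ce, family=self.family, tol=self.tol,
            max_iter=self.max_iter,
        )
        self.result_ = res
        self.call_error_ = ce
        self.beta_ = res.fit_alt.outcome.beta
        self.alpha_ = res.fit_alt.outcome.alpha
        self.dispersion_ = res.fit_alt.outcome.dispersion
        self.rho1_ = res.fit_alt.prior.rho1
        self.posterior_ = res.fit_alt.posterior
        self.statistic_ = res.statistic
        self.pvalue_ = res.pvalue
        self.loglik_ = res.fit_alt.loglik
        self.n_iter_ = res.fit_alt.n_iter
        self.converged_ = res.fit_alt.converged
        return self

    def predict(self, X):
        """Expected outcome for new samples without read-count data.

        Marginalizes the latent status at the fitted prevalence, i.e. the
        linear predictor uses ``E[S] = rho1_``.
        """
        check_is_fitted(self, "result_")
        Z = _design(X)
        eta = Z @ self.alpha_ + self.rho1_ * self.beta_
        return eta if self.family == "gaussian" else expit(eta)
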