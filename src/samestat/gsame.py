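"""Gene-level association test over collapsed latent statuses (gSAME).

A gene's true mutation status is the OR over its ``p`` constituent loci.
Conditional on the gene carrying no mutation, every locus is unmutated;
conditional on it carrying at least one, the per-locus statuses follow
independent Bernoulli draws (common inclusion probability ``q``)
renormalized to exclude the all-zero vector. Loci whose alternative read
count is zero in a sample cannot plausibly be mutated there and are pinned
to status 0, so only ``2**m_i - 1`` configurations over the ``m_i`` active
loci enter the sample's likelihood.

The likelihood mirrors the mutation-level model with the gene status in the
outcome GLM and the per-locus read-count/call evidence multiplied across
loci; the branch sum over configurations factorizes as
``prod_j [(1-q) + q * r_j] - prod_j (1-q)`` with ``r_j`` the per-locus
evidence ratio, which is evaluated in log space instead of enumerating
subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import expit

from .distributions import (
    OutcomeModel,
    ReadCountModel,
    mixture_posterior,
    outcome_logdensity,
)
from .msame import (
    CallErrorModel,
    LrtResult,
    MixturePrior,
    MsameFit,
    SiteData,
    _design,
    _lrt_from_fits,
    _mstep_outcome,
    estimate_call_error,
    evidence_loglik,
)
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "GeneData",
    "collapse_true_status",
    "collapse_observed_calls",
    "enumerate_configs",
    "config_prior",
    "locus_inclusion_prob",
    "estimate_gene_call_errors",
    "gsame_loglik",
    "gsame_em",
    "gsame_test",
    "GeneSAME",
]

#: Largest number of active loci per sample; 2**12 - 1 configurations.
MAX_ACTIVE_LOCI = 12


@dataclass
class GeneData:
    """Stacked per-locus read-count data for one gene.

    ``A``, ``D``, ``O`` are ``p x n`` arrays sharing the sample axis; ``O``
    uses NaN for missing calls. ``call_errors`` carries one sensitivity/
    specificity pair per locus.
    """

    A: np.ndarray
    D: np.ndarray
    O: np.ndarray
    call_errors: list[CallErrorModel] | None = None
    gene_id: str = ""
    site_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=np.int64))
        self.D = np.atleast_2d(np.asarray(self.D, dtype=np.int64))
        self.O = np.atleast_2d(np.asarray(self.O, dtype=float))
        if not (self.A.shape == self.D.shape == self.O.shape):
            raise ValueError("A, D, O must share the p x n shape")
        if self.p < 1:
            raise ValueError("a gene needs at least one locus")
        if np.any(self.A < 0) or np.any(self.A > self.D):
            raise ValueError("require 0 <= A <= D elementwise")
        if self.call_errors is not None and len(self.call_errors) != self.p:
            raise ValueError("need one CallErrorModel per locus")

    @property
    def p(self) -> int:
        return self.A.shape[0]

    @property
    def n(self) -> int:
        return self.A.shape[1]

    def locus(self, j: int) -> SiteData:
        sid = self.site_ids[j] if self.site_ids else f"{self.gene_id}:{j}"
        return SiteData(self.A[j], self.D[j], self.O[j], site_id=sid,
                        gene=self.gene_id)


def collapse_true_status(s_vec) -> int:
    """Gene status: 1 if any locus is mutated."""
    s = np.asarray(s_vec)
    if np.any((s != 0) & (s != 1)):
        raise ValueError("statuses must be 0/1")
    return int(s.max(initial=0))


def collapse_observed_calls(o_vec) -> tuple[int, bool]:
    """Observed gene call: 1 if any non-missing call is 1, else 0.

    Missing calls count as 0 (the naive comparator has no other recourse);
    the second element flags the fully-missing, low-coverage case.
    """
    o = np.asarray(o_vec, dtype=float)
    all_missing = bool(np.all(np.isnan(o)))
    call = int(np.nansum(o) > 0) if not all_missing else 0
    return call, all_missing


def enumerate_configs(a_row, cap: int = MAX_ACTIVE_LOCI):
    """Admissible status vectors for one sample given its alt counts.

    Loci with zero alternative reads are pinned to status 0; the remaining
    ``m_i`` active loci contribute the ``2**m_i - 1`` non-zero 0/1 vectors
    (the gene-mutated branch). Returns ``(active_idx, configs)`` where
    ``configs`` is a ``(2**m_i - 1) x m_i`` array; ``m_i = 0`` yields an
    empty config set (the mutated branch is impossible).
    """
    a = np.asarray(a_row)
    if np.any(a < 0):
        raise ValueError("alt counts must be non-negative")
    active = np.flatnonzero(a > 0)
    m = active.size
    if m > cap:
        raise ValueError(
            f"{m} active loci exceed the enumeration cap {cap}; "
            "pre-filter loci before gene-level testing"
        )
    if m == 0:
        return active, np.zeros((0, 0), dtype=int)
    configs = np.array([c for c in product((0, 1), repeat=m) if any(c)],
                       dtype=int)
    return active, configs


def config_prior(configs: np.ndarray, q) -> np.ndarray:
    """Probability of each non-zero configuration given a mutated gene.

    Independent Bernoulli(``q``) per active locus, renormalized over the
    non-zero vectors; ``q`` may be scalar or per-locus.
    """
    if configs.size == 0:
        return np.zeros(0)
    q = np.broadcast_to(np.asarray(q, dtype=float), (configs.shape[1],))
    if np.any(q <= 0) or np.any(q >= 1):
        raise ValueError("inclusion probabilities must lie in (0, 1)")
    raw = np.prod(np.where(configs > 0, q, 1.0 - q), axis=1)
    return raw / raw.sum()


def locus_inclusion_prob(rho1_g: float, p: int) -> float:
    """Common per-locus rate ``q`` with ``P(any locus mutated) = rho1_g``."""
    return 1.0 - (1.0 - rho1_g) ** (1.0 / p)


def estimate_gene_call_errors(
    gene: GeneData, rc: ReadCountModel, min_carriers: int = 3
) -> list[CallErrorModel]:
    """Per-locus (sensitivity, specificity) with a pooled fallback.

    Loci with fewer than ``min_carriers`` high-depth putative carriers
    (mixture posterior > 0.5) borrow the gene-wide pooled estimate.
    """
    pooled_site = SiteData(
        gene.A.ravel(), gene.D.ravel(), gene.O.ravel(),
        site_id=f"{gene.gene_id}:pooled",
    )
    pooled = estimate_call_error(pooled_site, rc)
    out = []
    for j in range(gene.p):
        site = gene.locus(j)
        hi = site.D >= rc.d0
        w = mixture_posterior(
            site.A[hi], site.D[hi], rc.high_depth[0, 0], rc.high_depth[1, 1]
        )
        if int(np.sum(w > 0.5)) < min_carriers:
            out.append(pooled)
        else:
            out.append(estimate_call_error(site, rc))
    return out


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------


def _locus_evidence(
    gene: GeneData, rc: ReadCountModel
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus per-sample evidence log f(A, D, O | S_j = s), s = 0, 1."""
    ce_list = gene.call_errors or [CallErrorModel()] * gene.p
    l0 = np.empty((gene.p, gene.n))
    l1 = np.empty((gene.p, gene.n))
    for j in range(gene.p):
        l0[j], l1[j] = evidence_loglik(gene.locus(j), rc, ce_list[j])
    return l0, l1


def _branch_logliks(
    l0: np.ndarray, l1: np.ndarray, active: np.ndarray, q: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample log f(data | S^g = 0) and log f(data | S^g = 1).

    The mutated branch sums ``prior(c) * prod_j f(.|S_j=c_j)`` over the
    non-zero configurations of the active loci. With an independent
    Bernoulli prior the sum over all configurations factorizes across loci,
    so the branch equals (product over loci of the two-term mass) minus the
    all-zero term, renormalized by ``1 - (1-q)**m`` — evaluated in log
    space, no enumeration needed. Samples with no active locus get ``-inf``
    (the branch is impossible under the zero-count restriction).
    """
    B0 = l0.sum(axis=0)
    logq, log1mq = np.log(q), np.log1p(-q)
    m = active.sum(axis=0)
    # T: log sum over ALL configurations (incl. all-zero) of the joint
    # evidence x Bernoulli mass; E: log mass of the excluded all-zero
    # configuration. Computed on the absolute scale so that infinitely
    # informative evidence terms (a locus pinned by a perfect caller,
    # log f = -inf) stay well-defined.
    with np.errstate(invalid="ignore"):
        f = np.where(active, np.logaddexp(log1mq + l0, logq + l1), l0)
    T = f.sum(axis=0)
    E = np.where(active, log1mq + l0, l0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        gap = E - T  # <= 0 by construction
        log_num = T + np.log1p(-np.exp(np.minimum(gap, 0.0)))
        log_den = np.log1p(-(1.0 - q) ** m)
        B1 = np.where((m > 0) & np.isfinite(T), log_num - log_den, -np.inf)
    return B0, B1


def _obs_loglik(
    y, Z, outcome: OutcomeModel, rho1_g: float, B0, B1
) -> tuple[float, np.ndarray]:
    ly0 = outcome_logdensity(y, Z, 0, outcome)
    ly1 = outcome_logdensity(y, Z, 1, outcome)
    num0 = np.log1p(-rho1_g) + ly0 + B0
    with np.errstate(invalid="ignore"):
        num1 = np.log(rho1_g) + ly1 + B1
    norm = np.logaddexp(num0, num1)
    if not np.all(np.isfinite(norm)):
        bad = np.flatnonzero(~np.isfinite(norm)).tolist()
        raise FloatingPointError(
            f"zero likelihood under both gene-status branches for samples {bad}"
        )
    with np.errstate(invalid="ignore"):
        w = np.where(np.isneginf(num1), 0.0, np.exp(num1 - norm))
    return float(norm.sum()), w


def _active_mask(gene: GeneData, restrict_active: bool) -> np.ndarray:
    """Which loci may carry a mutation in each sample.

    By default a locus with zero alternative reads is pinned to status 0
    (the enumeration-reducing approximation); ``restrict_active=False``
    drops the approximation and enumerates over all loci, which is required
    for exact agreement with the single-locus model and with full brute
    force.
    """
    active = (gene.A > 0) if restrict_active else np.ones_like(gene.A, bool)
    if np.any(active.sum(axis=0) > MAX_ACTIVE_LOCI):
        raise ValueError(
            f"a sample exceeds the enumeration cap of {MAX_ACTIVE_LOCI} "
            "active loci; pre-filter loci before gene-level testing"
        )
    return active


def gsame_loglik(
    gene: GeneData, Y, X, rc: ReadCountModel, outcome: OutcomeModel,
    rho1_g: float, restrict_active: bool = True,
) -> float:
    """Observed-data log-likelihood of the gene-level model at fixed params."""
    y = np.asarray(Y, dtype=float)
    Z = _design(X)
    l0, l1 = _locus_evidence(gene, rc)
    active = _active_mask(gene, restrict_active)
    q = locus_inclusion_prob(rho1_g, gene.p)
    B0, B1 = _branch_logliks(l0, l1, active, q)
    ll, _ = _obs_loglik(y, Z, outcome, rho1_g, B0, B1)
    return ll


def gsame_em(
    gene: GeneData,
    Y,
    X,
    rc: ReadCountModel,
    beta_fixed: float | None = None,
    family: str = "gaussian",
    tol: float = 1e-8,
    max_iter: int = 1000,
    restrict_active: bool = True,
) -> MsameFit:
    """EM / coordinate-ascent fit of the gene-level latent-status model.

    Outcome parameters are updated by the weighted GLM M-step given the
    posterior gene status; the gene-level prevalence ``rho1_g`` (which also
    sets the per-locus inclusion probability ``q``) is updated by a bounded
    1-D maximization of the observed-data log-likelihood, so the objective
    is non-decreasing at every step.
    """
    y = np.asarray(Y, dtype=float)
    Z = _design(X)
    if y.size != gene.n or Z.shape[0] != gene.n:
        raise ValueError("Y, X and gene data disagree on the number of samples")
    fit_beta = beta_fixed is None
    if not fit_beta and beta_fixed != 0.0:
        raise ValueError("only beta_fixed=0 (the null) is supported")

    l0, l1 = _locus_evidence(gene, rc)
    active = _active_mask(gene, restrict_active)

    gene_calls = np.array([collapse_observed_calls(gene.O[:, i])[0]
                           for i in range(gene.n)], dtype=float)
    rho1 = float(np.clip(np.mean(gene_calls), 1.0 / gene.n, 1.0 - 1.0 / gene.n))
    w_init = np.clip(gene_calls, 0.05, 0.95)
    outcome = _mstep_outcome(y, Z, w_init, family, fit_beta)

    def branch(r):
        return _branch_logliks(l0, l1, active, locus_inclusion_prob(r, gene.p))

    loglik = -np.inf
    w = np.full(gene.n, rho1)
    converged = False
    trace: list[float] = []
    it = 0
    B0, B1 = branch(rho1)
    for it in range(1, max_iter + 1):
        new_loglik, w = _obs_loglik(y, Z, outcome, rho1, B0, B1)
        if not np.isfinite(new_loglik):
            raise FloatingPointError(
                f"non-finite log-likelihood at iteration {it}"
                + (f" (gene {gene.gene_id})" if gene.gene_id else "")
            )
        trace.append(new_loglik)
        if abs(new_loglik - loglik) < tol:
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik
        outcome = _mstep_outcome(y, Z, w, family, fit_beta, prev=outcome)

        def neg_ll(r):
            b0, b1 = branch(r)
            try:
                ll, _ = _obs_loglik(y, Z, outcome, r, b0, b1)
            except FloatingPointError:
                return np.inf
            return -ll

        res = minimize_scalar(
            neg_ll, bounds=(1e-6, 1.0 - 1e-6), method="bounded",
            options={"xatol": 1e-10},
        )
        if np.isfinite(res.fun) and -res.fun >= -neg_ll(rho1):
            rho1 = float(res.x)
        B0, B1 = branch(rho1)
    if not converged:
        warnings.warn(
            f"EM did not converge in {max_iter} iterations"
            + (f" (gene {gene.gene_id})" if gene.gene_id else ""),
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


def gsame_test(
    gene: GeneData,
    Y,
    X,
    rc: ReadCountModel,
    family: str = "gaussian",
    tol: float = 1e-8,
    max_iter: int = 1000,
    restrict_active: bool = True,
) -> LrtResult:
    """Likelihood-ratio test of the gene-level mutation effect (1 df)."""
    try:
        fit_alt = gsame_em(gene, Y, X, rc, family=family, tol=tol,
                           max_iter=max_iter, restrict_active=restrict_active)
        fit_null = gsame_em(gene, Y, X, rc, beta_fixed=0.0, family=family,
                            tol=tol, max_iter=max_iter,
                            restrict_active=restrict_active)
    except FloatingPointError as err:
        raise FloatingPointError(
            f"gSAME EM failed for gene {gene.gene_id or '?'}: {err}"
        ) from err
    return _lrt_from_fits(fit_alt, fit_null, site_id=gene.gene_id)


class GeneSAME(BaseEstimator):
    """Gene-level latent-status association test, estimator-style.

    Collapses the latent per-locus statuses into a gene status (OR over
    loci) and tests its effect on the outcome by a likelihood-ratio test,
    accounting for calling errors at every locus. Per-locus sensitivity/
    specificity are estimated from the read counts when ``call_errors`` is
    ``"estimate"`` (the default); pass a list of :class:`CallErrorModel`
    to fix them.
    """

    def __init__(
        self,
        read_count_model: ReadCountModel | None = None,
        call_errors: list[CallErrorModel] | str = "estimate",
        family: str = "gaussian",
        tol: float = 1e-8,
        max_iter: int = 1000,
    ):
        self.read_count_model = read_count_model
        self.call_errors = call_errors
        self.family = family
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, *, gene: GeneData):
        rc = self.read_count_model or ReadCountModel()
        if isinstance(self.call_errors, str):
            if self.call_errors != "estimate":
                raise ValueError("call_errors must be a list or 'estimate'")
            ce_list = estimate_gene_call_errors(gene, rc)
        else:
            ce_list = list(self.call_errors)
        gene = GeneData(gene.A, gene.D, gene.O, call_errors=ce_list,
                        gene_id=gene.gene_id, site_ids=gene.site_ids)
        res = gsame_test(gene, y, X, rc, family=self.family, tol=self.tol,
                         max_iter=self.max_iter)
        self.result_ = res
        self.call_errors_ = ce_list
        self.beta_ = res.fit_alt.outcome.beta
        self.alpha_ = res.fit_alt.outcome.alpha
        self.dispersion_ = res.fit_alt.outcome.dispersion
        self.rho1_g_ = res.fit_alt.prior.rho1
        self.posterior_ = res.fit_alt.posterior
        self.statistic_ = res.statistic
        self.pvalue_ = res.pvalue
        self.loglik_ = res.fit_alt.loglik
        self.n_iter_ = res.fit_alt.n_iter
        self.converged_ = res.fit_alt.converged
        return self

    def predict(self, X):
        """Expected outcome for new samples, marginalizing the gene status."""
        check_is_fitted(self, "result_")
        Z = _design(X)
        eta = Z @ self.alpha_ + self.rho1_g_ * self.beta_
        return eta if self.family == "gaussian" else expit(eta)
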