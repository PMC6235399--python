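"""Probability kernels for allele-count and outcome data.

The read-count evidence model has two regimes, split by the calling-depth
threshold ``d0``:

* **high depth** (``D >= d0``): a variant caller emits a binary call ``O``,
  and the alternative-allele count ``A`` given depth ``D`` follows a
  beta-binomial whose parameters depend on the pair ``(S, O)`` of true
  status and call;
* **low depth** (``D < d0``): no call is made and ``A | D`` follows a
  beta-binomial indexed by the true status ``S`` alone.

Beta-binomials are parameterized by the mean alternative-allele fraction
``pi`` and the intra-class correlation ``phi`` (``phi = 0`` degenerates to a
binomial). Sequencing depth itself is modeled as negative binomial with
variance ``mu + mu**2 / phi_nb`` and is ancillary: it carries no information
about the mutation status and cancels from every likelihood ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import betaln, expit, gammaln, logit

__all__ = [
    "BetaBinomParams",
    "NegBinParams",
    "ReadCountModel",
    "OutcomeModel",
    "betabinom_logpmf",
    "betabinom_sample",
    "negbin_sample",
    "outcome_logdensity",
    "mixture_posterior",
    "fit_betabinom_mle",
    "fit_betabinom_highdepth",
    "fit_betabinom_lowdepth",
    "DEFAULT_READ_COUNT_MODEL",
]

# Binomial limit below this intra-class correlation; the beta shapes
# (1 - phi) / phi overflow as phi -> 0.
_PHI_BINOM_EPS = 1e-12

_PI_FLOOR, _PI_CEIL = 1e-4, 1.0 - 1e-4
_PHI_FLOOR, _PHI_CEIL = 1e-6, 0.999


@dataclass(frozen=True)
class BetaBinomParams:
    """Beta-binomial in mean / intra-class-correlation form.

    Shape parameters are ``a = pi * (1 - phi) / phi`` and
    ``b = (1 - pi) * (1 - phi) / phi``, so ``pi`` is the mean allele
    fraction and ``phi`` the overdispersion in ``[0, 1)``.
    """

    pi: float
    phi: float

    def __post_init__(self) -> None:
        if not 0.0 < self.pi < 1.0:
            raise ValueError(f"pi must lie in (0, 1), got {self.pi}")
        if not 0.0 <= self.phi < 1.0:
            raise ValueError(f"phi must lie in [0, 1), got {self.phi}")

    @property
    def shapes(self) -> tuple[float, float]:
        if self.phi <= _PHI_BINOM_EPS:
            raise ValueError("binomial limit has no finite beta shapes")
        scale = (1.0 - self.phi) / self.phi
        return self.pi * scale, (1.0 - self.pi) * scale


@dataclass(frozen=True)
class NegBinParams:
    """Negative binomial with mean ``mu`` and variance ``mu + mu**2/phi_nb``."""

    mu: float
    phi_nb: float

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError(f"mu must be positive, got {self.mu}")
        if self.phi_nb <= 0:
            raise ValueError(f"phi_nb must be positive, got {self.phi_nb}")

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.mu + self.mu**2 / self.phi_nb))


#: Published allele-count components estimated from TCGA colon-cancer
#: exome data: high-depth (S, O) strata and low-depth S strata.
_HIGH_DEFAULTS = {
    (0, 0): BetaBinomParams(0.001, 0.0006),
    (0, 1): BetaBinomParams(0.002, 0.3457),
    (1, 0): BetaBinomParams(0.1179, 0.0001),
    (1, 1): BetaBinomParams(0.3207, 0.1018),
}
_LOW_DEFAULTS = {
    0: BetaBinomParams(0.001, 0.001),
    1: BetaBinomParams(0.146, 0.10),
}


@dataclass(frozen=True)
class ReadCountModel:
    """Allele-count evidence model: four high-depth and two low-depth components."""

    high_depth: dict[tuple[int, int], BetaBinomParams] = field(
        default_factory=lambda: dict(_HIGH_DEFAULTS)
    )
    low_depth: dict[int, BetaBinomParams] = field(
        default_factory=lambda: dict(_LOW_DEFAULTS)
    )
    d0: int = 20

    def __post_init__(self) -> None:
        missing = {(s, o) for s in (0, 1) for o in (0, 1)} - set(self.high_depth)
        if missing:
            raise ValueError(f"missing high-depth components: {sorted(missing)}")
        if set(self.low_depth) != {0, 1}:
            raise ValueError("low-depth components must be keyed by status 0 and 1")
        if self.d0 < 1:
            raise ValueError(f"d0 must be >= 1, got {self.d0}")
        # Separability: mutated components should sit at higher allele fraction.
        hi0 = max(self.high_depth[0, 0].pi, self.high_depth[0, 1].pi)
        hi1 = min(self.high_depth[1, 0].pi, self.high_depth[1, 1].pi)
        if hi1 <= hi0 or self.low_depth[1].pi <= self.low_depth[0].pi:
            warnings.warn(
                "mutated-component allele fractions do not exceed the "
                "unmutated ones; statuses may not be separable",
                stacklevel=2,
            )

    def to_config(self) -> dict[str, float]:
        """Flatten to key/value pairs for a plain-text config file."""
        out: dict[str, float] = {"d0": float(self.d0)}
        for (s, o), p in self.high_depth.items():
            out[f"pi_{s}{o}"] = p.pi
            out[f"phi_{s}{o}"] = p.phi
        for s, p in self.low_depth.items():
            out[f"pi_{s}"] = p.pi
            out[f"phi_{s}"] = p.phi
        return out

    @classmethod
    def from_config(cls, cfg: dict[str, float]) -> "ReadCountModel":
        high = {
            (s, o): BetaBinomParams(cfg[f"pi_{s}{o}"], cfg[f"phi_{s}{o}"])
            for s in (0, 1)
            for o in (0, 1)
        }
        low = {s: BetaBinomParams(cfg[f"pi_{s}"], cfg[f"phi_{s}"]) for s in (0, 1)}
        return cls(high_depth=high, low_depth=low, d0=int(cfg.get("d0", 20)))


DEFAULT_READ_COUNT_MODEL = ReadCountModel()


@dataclass(frozen=True)
class OutcomeModel:
    """GLM for the outcome given covariates and mutation status.

    ``alpha`` holds the covariate coefficients (intercept included), ``beta``
    the mutation effect, and ``dispersion`` the residual variance for the
    gaussian family (ignored for binomial).
    """

    family: str
    alpha: np.ndarray
    beta: float
    dispersion: float = 1.0
    link: str | None = None

    def __post_init__(self) -> None:
        expected = {"gaussian": "identity", "binomial": "logit"}
        if self.family not in expected:
            raise ValueError(f"unknown family {self.family!r}")
        link = self.link or expected[self.family]
        if link != expected[self.family]:
            raise ValueError(f"link {link!r} does not match family {self.family!r}")
        object.__setattr__(self, "link", link)
        object.__setattr__(self, "alpha", np.asarray(self.alpha, dtype=float))
        if self.family == "gaussian" and self.dispersion <= 0:
            raise ValueError("gaussian dispersion must be positive")


def _as_count_arrays(a, d) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a)
    d = np.asarray(d)
    if not (np.issubdtype(a.dtype, np.integer) or np.allclose(a, np.round(a))):
        raise ValueError("alt counts must be integers")
    if not (np.issubdtype(d.dtype, np.integer) or np.allclose(d, np.round(d))):
        raise ValueError("depths must be integers")
    a = a.astype(np.int64)
    d = d.astype(np.int64)
    if np.any(a < 0) or np.any(d < 0):
        raise ValueError("counts must be non-negative")
    if np.any(a > d):
        raise ValueError("alt count exceeds depth")
    return a, d


# Below this intra-class correlation the beta shapes exceed ~1e4 and the
# cancellation in betaln differences costs more than 1e-10 absolute; switch
# to the exact rising-factorial sums, which have no cancellation.
_PHI_SUM_FORM = 1e-4


def _logpmf_sum_form(a, d, sa: float, sb: float) -> np.ndarray:
    """log Beta-binomial via sum_k log(shape + k); exact for huge shapes."""
    k = np.arange(int(d.max()) if d.size else 0)[:, None]
    t_alt = np.where(k < a, np.log(sa + k), 0.0).sum(axis=0)
    t_ref = np.where(k < d - a, np.log(sb + k), 0.0).sum(axis=0)
    t_tot = np.where(k < d, np.log(sa + sb + k), 0.0).sum(axis=0)
    return t_alt + t_ref - t_tot


def betabinom_logpmf(a, d, params: BetaBinomParams) -> np.ndarray | float:
    """Log-pmf of the alternative count ``a`` out of depth ``d``.

    Computed from log-beta functions, with two small-``phi`` escapes: the
    exact binomial at ``phi = 0`` and a cancellation-free rising-factorial
    sum when the implied beta shapes grow past ~1e4. Vectorizes over ``a``
    and ``d``.
    """
    a, d = _as_count_arrays(a, d)
    scalar = a.ndim == 0
    a, d = np.atleast_1d(a), np.atleast_1d(d)
    log_choose = gammaln(d + 1) - gammaln(a + 1) - gammaln(d - a + 1)
    if params.phi <= _PHI_BINOM_EPS:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = log_choose + np.where(a > 0, a * np.log(params.pi), 0.0)
            out = out + np.where(d - a > 0, (d - a) * np.log1p(-params.pi), 0.0)
    elif params.phi < _PHI_SUM_FORM:
        sa, sb = params.shapes
        out = log_choose + _logpmf_sum_form(a, d, sa, sb)
    else:
        sa, sb = params.shapes
        out = log_choose + betaln(a + sa, d - a + sb) - betaln(sa, sb)
    return float(out[0]) if scalar else out


def betabinom_sample(
    d, params: BetaBinomParams, rng: np.random.Generator
) -> np.ndarray | int:
    """Draw alternative counts for depths ``d`` (beta mixing then binomial)."""
    d = np.atleast_1d(np.asarray(d, dtype=np.int64))
    if np.any(d < 0):
        raise ValueError("depth must be non-negative")
    if params.phi <= _PHI_BINOM_EPS:
        q = np.full(d.shape, params.pi)
    else:
        sa, sb = params.shapes
        q = rng.beta(sa, sb, size=d.shape)
    out = rng.binomial(d, q)
    return out if out.size > 1 else int(out[0])


def negbin_sample(
    params: NegBinParams, rng: np.random.Generator, size=None
) -> np.ndarray | int:
    """Draw depths from NB(mu, phi_nb) with variance ``mu + mu**2/phi_nb``."""
    p = params.phi_nb / (params.phi_nb + params.mu)
    out = rng.negative_binomial(params.phi_nb, p, size=size)
    return out if size is not None else int(out)


_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)


def outcome_logdensity(y, x, s, model: OutcomeModel) -> np.ndarray | float:
    """Log-density of the outcome under the GLM at status ``s``.

    ``x`` is a covariate vector (or ``n x k`` matrix) matching
    ``model.alpha``; ``s`` broadcasts against ``y``.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[-1] != model.alpha.size:
        raise ValueError(
            f"covariate dimension {x.shape[-1]} does not match "
            f"alpha dimension {model.alpha.size}"
        )
    y = np.asarray(y, dtype=float)
    eta = x @ model.alpha + np.asarray(s, dtype=float) * model.beta
    eta = np.broadcast_to(eta, np.broadcast_shapes(eta.shape, y.shape))
    if model.family == "gaussian":
        out = (
            -_HALF_LOG_2PI
            - 0.5 * np.log(model.dispersion)
            - 0.5 * (y - eta) ** 2 / model.dispersion
        )
    else:
        # Bernoulli log-mass, numerically stable via log1p(exp(.)).
        out = np.where(y > 0.5, eta, 0.0) - np.logaddexp(0.0, eta)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Component estimation
# ---------------------------------------------------------------------------


def fit_betabinom_mle(
    a,
    d,
    weights=None,
    init: BetaBinomParams | None = None,
) -> BetaBinomParams:
    """Weighted maximum-likelihood fit of a single beta-binomial component.

    Optimizes over (logit pi, logit phi) with a bounded quasi-Newton method;
    ``pi`` is clipped to ``[1e-4, 1 - 1e-4]`` and ``phi`` to
    ``[1e-6, 0.999]`` to keep shapes finite.
    """
    a, d = _as_count_arrays(a, d)
    w = np.ones(a.shape, dtype=float) if weights is None else np.asarray(weights, float)
    keep = (w > 0) & (d > 0)
    a, d, w = a[keep], d[keep], w[keep]
    if a.size == 0:
        raise ValueError("no observations with positive weight and depth")

    mean_frac = float(np.clip(np.sum(w * a) / np.sum(w * d), _PI_FLOOR, _PI_CEIL))
    if init is None:
        init = BetaBinomParams(mean_frac, 0.01)

    def nll(z):
        pi = float(np.clip(expit(z[0]), _PI_FLOOR, _PI_CEIL))
        phi = float(np.clip(expit(z[1]), _PHI_FLOOR, _PHI_CEIL))
        return -float(np.sum(w * betabinom_logpmf(a, d, BetaBinomParams(pi, phi))))

    z0 = np.array(
        [
            logit(np.clip(init.pi, _PI_FLOOR, _PI_CEIL)),
            logit(np.clip(init.phi, _PHI_FLOOR, _PHI_CEIL)),
        ]
    )
    res = minimize(
        nll,
        z0,
        method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-10},
    )
    pi = float(np.clip(expit(res.x[0]), _PI_FLOOR, _PI_CEIL))
    phi = float(np.clip(expit(res.x[1]), _PHI_FLOOR, _PHI_CEIL))
    return BetaBinomParams(pi, phi)


def mixture_posterior(
    a,
    d,
    comp0: BetaBinomParams,
    comp1: BetaBinomParams,
    rho1: float = 0.1,
    n_iter: int = 50,
    tol: float = 1e-8,
) -> np.ndarray:
    """Posterior P(S=1 | A, D) under a two-component beta-binomial mixture.

    The component shapes are held fixed; the mixing weight is re-estimated
    by EM starting from ``rho1``. Used both for the preliminary status
    classification behind component estimation and for the call-error
    estimator.
    """
    a, d = _as_count_arrays(a, d)
    if a.size == 0:
        return np.zeros(0)
    l0 = betabinom_logpmf(a, d, comp0)
    l1 = betabinom_logpmf(a, d, comp1)
    rho = float(np.clip(rho1, 1e-6, 1 - 1e-6))
    w = np.empty(a.shape, dtype=float)
    prev = -np.inf
    for _ in range(n_iter):
        num1 = np.log(rho) + l1
        num0 = np.log1p(-rho) + l0
        norm = np.logaddexp(num0, num1)
        w = np.exp(num1 - norm)
        ll = float(np.sum(norm))
        if abs(ll - prev) < tol:
            break
        prev = ll
        rho = float(np.clip(np.mean(w), 1e-6, 1 - 1e-6))
    return w


def _warn_fallback(stratum, default: BetaBinomParams) -> BetaBinomParams:
    warnings.warn(
        f"stratum {stratum} has no usable observations; "
        f"falling back to default component (pi={default.pi}, phi={default.phi})",
        stacklevel=3,
    )
    return default


def fit_betabinom_highdepth(sites, d0: int = 20) -> dict[tuple[int, int], BetaBinomParams]:
    """Estimate the four high-depth components from a collection of sites.

    ``sites`` is an iterable of objects with per-sample ``A``, ``D``, ``O``
    arrays (missing calls allowed). Samples at ``D >= d0`` are pooled across
    sites; a preliminary status label is the thresholded posterior from a
    two-component mixture seeded at the default components, crossed with the
    observed call to form the four (S, O) strata. Each stratum is fitted by
    weighted MLE; an empty stratum falls back to the defaults with a warning.
    """
    sites = list(sites)
    if len(sites) < 2:
        raise ValueError("need at least 2 sites to estimate components")
    A = np.concatenate([np.asarray(s.A) for s in sites])
    D = np.concatenate([np.asarray(s.D) for s in sites])
    O = np.concatenate([np.asarray(s.O, dtype=float) for s in sites])
    hi = D >= d0
    if not np.any(hi):
        raise ValueError(f"no samples with depth >= d0={d0}")
    A, D, O = A[hi], D[hi], O[hi]
    w = mixture_posterior(A, D, _LOW_DEFAULTS[0], _LOW_DEFAULTS[1])
    s_lab = (w > 0.5).astype(int)
    out: dict[tuple[int, int], BetaBinomParams] = {}
    for s in (0, 1):
        for o in (0, 1):
            mask = (s_lab == s) & (O == o) & (D > 0)
            if mask.sum() == 0:
                out[s, o] = _warn_fallback((s, o), _HIGH_DEFAULTS[s, o])
                continue
            try:
                out[s, o] = fit_betabinom_mle(
                    A[mask], D[mask], init=_HIGH_DEFAULTS[s, o]
                )
            except ValueError:
                out[s, o] = _warn_fallback((s, o), _HIGH_DEFAULTS[s, o])
    return out


def fit_betabinom_lowdepth(sites, d0: int = 20) -> dict[int, BetaBinomParams]:
    """Estimate the two low-depth components (status 0 / 1).

    Status labels for sub-threshold samples are imputed from the
    two-component mixture applied to their own counts, seeded at the default
    low-depth components and iterated once with refitted components. With no
    low-depth data the defaults are returned with a warning.
    """
    sites = list(sites)
    A = np.concatenate([np.asarray(s.A) for s in sites])
    D = np.concatenate([np.asarray(s.D) for s in sites])
    lo = (D < d0) & (D > 0)
    if not np.any(lo):
        warnings.warn("no low-depth observations; returning default components",
                      stacklevel=2)
        return dict(_LOW_DEFAULTS)
    A, D = A[lo], D[lo]
    comps = dict(_LOW_DEFAULTS)
    for _ in range(2):  # seed pass + one refit pass
        w = mixture_posterior(A, D, comps[0], comps[1])
        new = {}
        for s, ws in ((0, 1.0 - w), (1, w)):
            if np.sum(ws) < 1e-8:
                new[s] = _warn_fallback(s, _LOW_DEFAULTS[s])
                continue
            try:
                new[s] = fit_betabinom_mle(A, D, weights=ws, init=comps[s])
            except ValueError:
                new[s] = _warn_fallback(s, _LOW_DEFAULTS[s])
        comps = new
    return comps
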