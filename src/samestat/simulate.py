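"""Synthetic data matching the exome/genome sequencing study design.

The generator emulates somatic-mutation data as observed in tumor
exome-seq cohorts: true statuses are Bernoulli draws; outcomes follow a
GLM in one standard-normal covariate and the status; depth is drawn in two
stages (a per-mutation mean from NB(113, 3.28), then per-sample depths
from an NB with that mean and overdispersion 1.9); calls are flipped
Bernoulli surrogates of the truth with sensitivity 0.9 and specificity
0.98; and allele counts come from the stratified beta-binomial components.
Depths below the calling threshold ``d0 = 20`` yield a missing call and a
status-indexed low-depth allele-count distribution. A whole-genome mode
replaces the depth model with a single-stage NB(40, 1.9).

`run_experiment` wraps replicate loops for type-I-error and power studies,
running each requested method on identical data within a replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baseline import glm_wald_test
from .distributions import (
    NegBinParams,
    ReadCountModel,
    betabinom_sample,
    negbin_sample,
)
from .gsame import (
    GeneData,
    collapse_observed_calls,
    estimate_gene_call_errors,
    gsame_test,
    locus_inclusion_prob,
)
from .msame import CallErrorModel, SiteData, estimate_call_error, msame_test

__all__ = [
    "SimulationConfig",
    "MethodSummary",
    "ExperimentResult",
    "simulate_mutation_site",
    "simulate_gene",
    "run_experiment",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulation cell.

    Defaults are the exome-seq study conditions: 400 samples, caller
    sensitivity 0.9 / specificity 0.98, two-stage negative-binomial depth
    with between-mutation mean 113 (overdispersion 3.28) and within-mutation
    overdispersion 1.9, calling threshold 20, and the published
    beta-binomial allele-count components. Gene-level cells draw per-locus
    sensitivity from {0.9, 1} and specificity from {0.98, 1} with equal
    probability.
    """

    n: int = 400
    level: str = "mutation"  # "mutation" | "gene"
    rho1: float = 0.05  # mutation (or gene-level) prevalence
    p: int = 10  # loci per gene
    beta: float = 0.0
    family: str = "gaussian"
    gamma1: float = 0.9
    gamma0: float = 0.98
    gene_gamma1_choices: tuple[float, ...] = (0.9, 1.0)
    gene_gamma0_choices: tuple[float, ...] = (0.98, 1.0)
    depth_between: NegBinParams = field(
        default_factory=lambda: NegBinParams(113.0, 3.28)
    )
    depth_within_phi: float = 1.9
    d0: int = 20
    read_count_model: ReadCountModel = field(default_factory=ReadCountModel)
    wgs_mode: bool = False
    wgs_depth: NegBinParams = field(default_factory=lambda: NegBinParams(40.0, 1.9))
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.rho1 < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.level not in ("mutation", "gene"):
            raise ValueError("level must be 'mutation' or 'gene'")
        if self.family not in ("gaussian", "binomial"):
            raise ValueError("family must be 'gaussian' or 'binomial'")


def _simulate_depths(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.wgs_mode:
        return negbin_sample(cfg.wgs_depth, rng, size=cfg.n)
    site_mean = max(int(negbin_sample(cfg.depth_between, rng)), 1)
    within = NegBinParams(float(site_mean), cfg.depth_within_phi)
    return negbin_sample(within, rng, size=cfg.n)


def _simulate_outcome(
    cfg: SimulationConfig, s: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    x = rng.standard_normal(cfg.n)
    if cfg.family == "gaussian":
        y = 1.0 + x + cfg.beta * s + rng.standard_normal(cfg.n)
    else:
        eta = -0.5 + x + cfg.beta * s
        y = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta))).astype(float)
    return y, x


def _simulate_reads(
    s: np.ndarray,
    depths: np.ndarray,
    gamma1: float,
    gamma0: float,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Calls and alt counts given true statuses and depths."""
    rc = cfg.read_count_model
    n = s.size
    o = np.full(n, np.nan)
    a = np.zeros(n, dtype=np.int64)
    hi = depths >= cfg.d0
    p_call = np.where(s == 1, gamma1, 1.0 - gamma0)
    o[hi] = rng.binomial(1, p_call[hi]).astype(float)
    for si in (0, 1):
        for oi in (0, 1):
            m = hi & (s == si) & (o == oi)
            if np.any(m):
                a[m] = np.atleast_1d(
                    betabinom_sample(depths[m], rc.high_depth[si, oi], rng)
                )
        m = ~hi & (s == si)
        if np.any(m):
            a[m] = np.atleast_1d(
                betabinom_sample(depths[m], rc.low_depth[si], rng)
            )
    return o, a


def simulate_mutation_site(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[SiteData, np.ndarray, np.ndarray, np.ndarray]:
    """One mutation locus: returns (site, true status, outcome, covariate)."""
    s = rng.binomial(1, cfg.rho1, size=cfg.n)
    y, x = _simulate_outcome(cfg, s, rng)
    depths = _simulate_depths(cfg, rng)
    o, a = _simulate_reads(s, depths, cfg.gamma1, cfg.gamma0, cfg, rng)
    site = SiteData(a, depths, o, site_id="sim:1")
    return site, s, y, x


def simulate_gene(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[GeneData, np.ndarray, np.ndarray, np.ndarray, list[CallErrorModel]]:
    """One gene of ``p`` loci: returns (gene, true gene status, Y, X, true
    per-locus call-error models).

    Per-locus statuses are independent Bernoulli with rate
    ``1 - (1 - rho1)**(1/p)`` so the collapsed gene status has prevalence
    ``rho1``; per-locus sensitivity/specificity are drawn fresh from the
    two-point sets.
    """
    q = locus_inclusion_prob(cfg.rho1, cfg.p)
    s_loci = rng.binomial(1, q, size=(cfg.p, cfg.n))
    s_gene = s_loci.max(axis=0)
    y, x = _simulate_outcome(cfg, s_gene, rng)
    A = np.zeros((cfg.p, cfg.n), dtype=np.int64)
    D = np.zeros((cfg.p, cfg.n), dtype=np.int64)
    O = np.full((cfg.p, cfg.n), np.nan)
    truth = []
    for j in range(cfg.p):
        g1 = float(rng.choice(cfg.gene_gamma1_choices))
        g0 = float(rng.choice(cfg.gene_gamma0_choices))
        truth.append(CallErrorModel(gamma1=g1, gamma0=g0))
        depths = _simulate_depths(cfg, rng)
        o, a = _simulate_reads(s_loci[j], depths, g1, g0, cfg, rng)
        A[j], D[j], O[j] = a, depths, o
    gene = GeneData(A, D, O, gene_id="sim:gene")
    return gene, s_gene, y, x, truth


# ---------------------------------------------------------------------------
# Experiment harness
# ---------------------------------------------------------------------------


@dataclass
class MethodSummary:
    method: str
    rejection_rate: float
    mc_se: float
    beta_mean: float
    beta_mse: float
    pvalues: np.ndarray
    beta_hats: np.ndarray
    n_failed: int


@dataclass
class ExperimentResult:
    """Per-method rejection rates and effect-estimate accuracy."""

    config: SimulationConfig
    reps: int
    xi: float
    methods: dict[str, MethodSummary]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.methods.values():
            rows.append(
                {
                    "method": m.method,
                    "reps": self.reps,
                    "xi": self.xi,
                    "rejection_rate": m.rejection_rate,
                    "mc_se": m.mc_se,
                    "beta_mean": m.beta_mean,
                    "beta_mse": m.beta_mse,
                    "n_failed": m.n_failed,
                }
            )
        return pd.DataFrame(rows)


def _run_mutation_replicate(cfg: SimulationConfig, rng, methods):
    site, s, y, x = simulate_mutation_site(cfg, rng)
    out = {}
    if "msame" in methods:
        ce = estimate_call_error(site, cfg.read_count_model)
        res = msame_test(site, y, x, cfg.read_count_model, ce, family=cfg.family)
        out["msame"] = (res.pvalue, res.beta_hat)
    if "glm" in methods:
        res = glm_wald_test(site.O, y, x, family=cfg.family)
        out["glm"] = (res.pvalue, res.beta_hat)
    return out


def _run_gene_replicate(cfg: SimulationConfig, rng, methods):
    gene, s_g, y, x, _ = simulate_gene(cfg, rng)
    out = {}
    if "gsame" in methods:
        ce_list = estimate_gene_call_errors(gene, cfg.read_count_model)
        gene_fit = GeneData(gene.A, gene.D, gene.O, call_errors=ce_list,
                            gene_id=gene.gene_id)
        res = gsame_test(gene_fit, y, x, cfg.read_count_model, family=cfg.family)
        out["gsame"] = (res.pvalue, res.beta_hat)
    if "glm" in methods:
        calls = np.array(
            [collapse_observed_calls(gene.O[:, i])[0] for i in range(gene.n)],
            dtype=float,
        )
        res = glm_wald_test(calls, y, x, family=cfg.family)
        out["glm"] = (res.pvalue, res.beta_hat)
    return out


def run_experiment(
    cfg: SimulationConfig,
    reps: int,
    methods: tuple[str, ...] | None = None,
    xi: float = 0.05,
) -> ExperimentResult:
    """Replicate loop for one simulation cell.

    Each replicate draws a fresh dataset from an independent substream of
    the master seed and runs every requested method on the same data.
    Replicate-level failures (degenerate data, numerical breakdown) are
    counted per method and excluded from the aggregates rather than raised.
    """
    if reps < 50:
        raise ValueError("use at least 50 replicates for stable rates")
    if cfg.seed is None:
        raise ValueError("SimulationConfig.seed is required for experiments")
    if methods is None:
        methods = ("msame", "glm") if cfg.level == "mutation" else ("gsame", "glm")
    run_one = (
        _run_mutation_replicate if cfg.level == "mutation" else _run_gene_replicate
    )
    streams = np.random.SeedSequence(cfg.seed).spawn(reps)
    pvals: dict[str, list[float]] = {m: [] for m in methods}
    betas: dict[str, list[float]] = {m: [] for m in methods}
    failed = {m: 0 for m in methods}
    for ss in streams:
        rng = np.random.default_rng(ss)
        try:
            res = run_one(cfg, rng, methods)
        except (FloatingPointError, ValueError):
            for m in methods:
                failed[m] += 1
            continue
        for m in methods:
            pv, bh = res[m]
            if np.isnan(pv):
                failed[m] += 1
            else:
                pvals[m].append(pv)
                betas[m].append(bh)
    summaries = {}
    for m in methods:
        pv = np.asarray(pvals[m])
        bh = np.asarray(betas[m])
        rate = float(np.mean(pv < xi)) if pv.size else np.nan
        summaries[m] = MethodSummary(
            method=m,
            rejection_rate=rate,
            mc_se=float(np.sqrt(rate * (1 - rate) / pv.size)) if pv.size else np.nan,
            beta_mean=float(np.mean(bh)) if bh.size else np.nan,
            beta_mse=float(np.mean((bh - cfg.beta) ** 2)) if bh.size else np.nan,
            pvalues=pv,
            beta_hats=bh,
            n_failed=failed[m],
        )
    return ExperimentResult(config=cfg, reps=reps, xi=xi, methods=summaries)
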