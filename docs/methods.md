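# Methods

## Model

### Data per sample and locus

For sample *i* at a locus: alternative-read count `A_i`, total depth
`D_i`, binary caller output `O_i` (missing exactly when `D_i < d0`, the
calling depth threshold, default `d0 = 20`), outcome `Y_i` and covariates
`x_i`. The true mutation status `S_i ∈ {0, 1}` is latent.

### Mutation-level likelihood

The observed-data log-likelihood is

```
ℓ(θ) = Σ_i log[ ρ1 f_Y(Y_i | S=1) f_E(A_i, D_i, O_i | S=1)
              + (1−ρ1) f_Y(Y_i | S=0) f_E(A_i, D_i, O_i | S=0) ]
```

with three factors:

- **Outcome model** `f_Y`: Gaussian `Y = α0 + α'x + βS + ε` or logistic
  `logit P(Y=1) = α0 + α'x + βS`. The association test is the
  likelihood-ratio test of `β = 0` against free `β`, referred to χ²(1).
- **Read-count evidence** `f_E`, split by depth:
  - `D_i ≥ d0`: `A_i | D_i, S, O ~` beta-binomial with component
    parameters indexed by the pair (true status, call). Conditioning on
    the call as well as the status reflects that callers select for
    allele-fraction signal, so the count distribution differs between
    concordant and discordant calls. The call itself contributes a
    Bernoulli factor with sensitivity `γ1 = P(O=1|S=1)` and specificity
    `γ0 = P(O=0|S=0)`.
  - `D_i < d0`: no call is attempted; `A_i | D_i, S ~` beta-binomial with
    components indexed by status alone.
  - `D_i = 0`: no read evidence; the factor is 1.
- **Prevalence** `ρ1 = P(S=1)`, a free parameter.

Beta-binomial components are parameterized as (mean π, intraclass
correlation φ), with shapes `a = π(1−φ)/φ`, `b = (1−π)(1−φ)/φ`; `φ → 0`
recovers the binomial. The default components (`ReadCountModel()`) were
calibrated on deep-exome colon-adenocarcinoma data and are exposed — and
re-estimable from any dataset via `fit_betabinom_highdepth` /
`fit_betabinom_lowdepth` or the `samestat fit-rc` subcommand — rather
than hard-coded.

### Call-error estimation

`estimate_call_error` fits a two-component beta-binomial mixture to the
high-depth counts (components fixed at the status-0/status-1 read-count
parameters, mixing weight fitted by EM), obtains posterior carrier
probabilities `w_i`, and sets `γ̂1 = Σ w_i O_i / Σ w_i`,
`γ̂0 = Σ (1−w_i)(1−O_i) / Σ (1−w_i)`, clipped to (0.5, 1]. Values of
exactly 1 are legal and handled in log space.

### EM algorithm

- **E-step**: posterior carrier probability `w_i` from the current
  parameters (all three likelihood factors).
- **M-step**: the outcome regression is a weighted GLM on the
  status-duplicated design (each sample appears once with `S=0`, weight
  `1−w_i`, and once with `S=1`, weight `w_i`): closed-form weighted least
  squares for the Gaussian family, Newton–Raphson for the logistic.
  `ρ1 ← mean(w)`. The null fit constrains `β = 0` and is otherwise
  identical, so the models are nested by construction.
- Convergence: relative log-likelihood change below `1e-8`, at most 1000
  iterations; the log-likelihood trace is recorded and is non-decreasing
  (checked in the tests).

If no sample shows any carrier evidence (the fitted `ρ̂1` collapses to
the boundary and the alternative is empty), the test is not identified;
the result carries `pvalue = NaN` with a `monomorphic` diagnostic rather
than a fabricated p-value.

### Gene-level likelihood

A gene with loci `j = 1..p` is mutated in sample *i* iff any locus is
(`S_i^g = max_j S_ij`). The outcome model uses `S_i^g`; the evidence
factorizes over loci given the per-locus statuses. Per-locus priors are
i.i.d. Bernoulli(`q`) with `q = 1 − (1−ρ1g)^{1/p}`, so that
`P(S^g=1) = ρ1g`; within the mutated branch the all-zero configuration is
excluded and the prior renormalized. The branch sum over `2^{m_i} − 1`
configurations factorizes as

```
Π_j [(1−q) + q r_ij] − (1−q)^{m_i}
```

over the `m_i` "active" loci of sample *i*, where `r_ij` is the
evidence ratio for locus *j*; it is evaluated in log space, so no
configuration is ever enumerated during fitting. (The explicit
enumeration, capped at 12 active loci, is retained for the brute-force
oracle checks.) By default a locus with `A_ij = 0` is pinned to `S_ij=0`
(`restrict_active=True`): with zero alternative reads the mutated branch
carries negligible mass, and pinning makes per-sample cost linear in `p`.
`restrict_active=False` disables the pinning; it is used to verify exact
equality with the mutation-level test at `p = 1` and with the brute-force
enumeration.

In the M-step the outcome/covariate parameters update as above (with
`w_i = P(S_i^g = 1 | data)`), but `ρ1g` enters the configuration prior
non-linearly, so the plain mean-posterior update does not maximize the
expected complete-data log-likelihood. Instead `ρ1g` is updated by
bounded one-dimensional maximization of the observed log-likelihood
(coordinate ascent), which preserves the monotone-ascent guarantee.

Per-locus call errors are estimated as at the mutation level; a locus
with fewer than 3 apparent carriers falls back to estimates pooled across
the gene's loci.

### Naive GLM baseline

`glm_wald_test` regresses the outcome on covariates plus the observed
call with missing calls set to 0, and reports the Wald test for the call
coefficient. Constant calls or separated logistic fits return `NaN` with
a diagnostic.

## Simulation engine

`SimulationConfig` defaults describe a deep-exome study: `n = 400`
samples, Gaussian outcome `Y = 1 + x + βS + ε` with `x, ε ~ N(0,1)` (or
logistic `logit p = −0.5 + x + βS`), carrier frequency `ρ1 = 0.05`,
sensitivity 0.9 and specificity 0.98, and a two-stage depth model: a
per-site mean from NB(μ=113, φ=3.28) (variance `μ + μ²/φ`, SD 63.3), then
per-sample depths from a negative binomial around that mean with
overdispersion 1.9. `wgs_mode=True` swaps in a single-stage NB(40, 1.9)
whole-genome depth model, where missingness below `d0 = 20` is common and
the advantage over the naive GLM widens. Gene-level simulation draws
per-locus statuses at rate `1 − (1−ρ1g)^{1/p}` and per-locus error rates
from {0.9, 1} × {0.98, 1}. Reads are drawn from the same beta-binomial
components used for inference; the generator's scope is the operating
characteristics of the tests under the model, not caller realism.

`run_experiment` replicates one cell: replicate streams are spawned from
a single `SeedSequence` (reproducible, order-independent), all methods
see the same data within a replicate, call errors are re-estimated per
replicate (the read-count components are treated as known plug-ins), and
replicate-level failures are counted per method rather than aborting the
run.

## Numerical choices

- **Beta-binomial pmf**: the `betaln` form cancels catastrophically when
  `φ` is tiny (shapes ~ 1/φ). For `φ ≤ 1e-12` the binomial limit is used;
  for `1e-12 < φ < 1e-4` a rising-factorial sum
  `Σ_k log(a+k)` replaces the `betaln` differences. Verified against
  quadrature and `scipy.stats.betabinom` to ≤ 1e-10.
- **Log-space evidence** throughout; `γ = 1` produces `−inf` evidence
  logs, and the gene-level branch sum is computed on the absolute scale
  with `logaddexp`/`log1p` so that pinned or impossible branches yield
  `−inf` rather than NaN.
- **Degenerate inputs** raise with the offending sample/site named
  (likelihood exactly zero for some sample, counts exceeding depth,
  missingness inconsistent with depth).

## Problem sizes

Designed for cohort-scale testing: hundreds to a few thousand samples,
one test per mutation or gene, typically thousands of tests corrected by
`bonferroni_threshold`. One mutation-level fit on `n = 400` takes a few
milliseconds; a gene-level fit with `p = 10` takes ~70 ms; 1000-replicate
calibration experiments run in minutes on one CPU. Genes with more than
12 simultaneously active loci in one sample are outside the enumeration
oracle's range but pose no problem for the factorized likelihood used in
fitting.
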