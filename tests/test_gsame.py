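from itertools import product

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st

from samestat import (
    BetaBinomParams,
    CallErrorModel,
    GeneData,
    GeneSAME,
    OutcomeModel,
    ReadCountModel,
    SimulationConfig,
    SiteData,
    collapse_observed_calls,
    collapse_true_status,
    config_prior,
    enumerate_configs,
    evidence_loglik,
    gsame_em,
    gsame_loglik,
    gsame_test,
    locus_inclusion_prob,
    msame_test,
    simulate_gene,
)
from samestat.gsame import estimate_gene_call_errors
from samestat.msame import _design
from samestat.distributions import outcome_logdensity

RC = ReadCountModel()


class TestCollapse:
    @pytest.mark.parametrize(
        "vec,expected",
        [((0, 0, 0), 0), ((0, 1, 0), 1), ((1, 1, 1), 1), ((1,), 1)],
    )
    def test_true_status_is_any_locus(self, vec, expected):
        assert collapse_true_status(vec) == expected

    def test_non_binary_status_rejected(self):
        with pytest.raises(ValueError):
            collapse_true_status((0, 2))

    @pytest.mark.parametrize(
        "vec,call,flagged",
        [
            ((0.0, np.nan, 0.0), 0, False),
            ((np.nan, 1.0), 1, False),
            ((np.nan, np.nan), 0, True),
        ],
    )
    def test_observed_calls_treat_missing_as_zero(self, vec, call, flagged):
        got, flag = collapse_observed_calls(vec)
        assert got == call and flag == flagged


class TestEnumeration:
    def test_zero_counts_pin_statuses(self):
        active, configs = enumerate_configs((0, 0, 0))
        assert active.size == 0 and configs.shape == (0, 0)

    def test_two_active_loci_give_three_configs(self):
        active, configs = enumerate_configs((3, 0, 1))
        assert list(active) == [0, 2]
        assert sorted(map(tuple, configs)) == [(0, 1), (1, 0), (1, 1)]

    def test_three_active_loci_give_seven(self):
        _, configs = enumerate_configs((1, 1, 1))
        assert configs.shape[0] == 7

    def test_cap_exceeded_raises(self):
        with pytest.raises(ValueError, match="pre-filter"):
            enumerate_configs(np.ones(13, dtype=int))


class TestConfigPrior:
    def test_single_active_locus_is_certain(self):
        _, configs = enumerate_configs((4,))
        assert config_prior(configs, 0.3) == pytest.approx([1.0])

    def test_symmetric_two_locus_prior(self):
        _, configs = enumerate_configs((1, 1))
        pri = config_prior(configs, 0.5)
        np.testing.assert_allclose(pri, [1 / 3] * 3)

    def test_asymmetric_limit_concentrates(self):
        _, configs = enumerate_configs((1, 1))
        pri = config_prior(configs, [1 - 1e-9, 1e-9])
        idx = [tuple(c) for c in configs].index((1, 0))
        assert pri[idx] == pytest.approx(1.0, abs=1e-6)

    @given(
        m=st.integers(1, 6),
        q=st.floats(0.01, 0.99),
    )
    def test_normalizes_over_enumeration(self, m, q):
        _, configs = enumerate_configs(np.ones(m, dtype=int))
        assert config_prior(configs, q).sum() == pytest.approx(1.0, abs=1e-12)


def brute_force_loglik(gene, y, x, rc, outcome, rho1g, restrict):
    """Independent oracle: explicit sum over all 2**p latent vectors."""
    Z = _design(x)
    ev = [evidence_loglik(gene.locus(j), rc, gene.call_errors[j])
          for j in range(gene.p)]
    q = 1.0 - (1.0 - rho1g) ** (1.0 / gene.p)
    total = 0.0
    for i in range(gene.n):
        ly0 = np.asarray(outcome_logdensity(y[i], Z[i], 0, outcome)).item()
        ly1 = np.asarray(outcome_logdensity(y[i], Z[i], 1, outcome)).item()
        lik0 = (1 - rho1g) * np.exp(ly0) * np.prod(
            [np.exp(ev[j][0][i]) for j in range(gene.p)]
        )
        allowed = [j for j in range(gene.p)
                   if (gene.A[j, i] > 0 or not restrict)]
        branch = 0.0
        norm = 0.0
        for s_vec in product((0, 1), repeat=len(allowed)):
            if sum(s_vec) == 0:
                continue
            pri = np.prod([q if sj else 1 - q for sj in s_vec])
            norm += pri
            lik = pri
            s_full = dict(zip(allowed, s_vec))
            for j in range(gene.p):
                sj = s_full.get(j, 0)
                lik *= np.exp(ev[j][sj][i])
            branch += lik
        if norm > 0:
            branch = branch / norm * np.exp(ly1) * rho1g
        total += np.log(lik0 + branch)
    return total


def _toy_gene(rng, p=3, n=8):
    s = rng.binomial(1, 0.3, size=(p, n))
    D = rng.integers(25, 60, size=(p, n))
    A = np.where(s == 1, rng.binomial(D, 0.3), rng.binomial(D, 0.02))
    O = np.where(s == 1, rng.binomial(1, 0.9, (p, n)),
                 rng.binomial(1, 0.02, (p, n))).astype(float)
    ce = [CallErrorModel(0.9, 0.98)] * p
    return GeneData(A, D, O, call_errors=ce, gene_id="toy")


class TestGsameLikelihood:
    @pytest.mark.parametrize("restrict", [True, False])
    @pytest.mark.parametrize("p,n", [(2, 3), (3, 8), (4, 10)])
    def test_matches_brute_force_enumeration(self, rng, p, n, restrict):
        gene = _toy_gene(rng, p=p, n=n)
        x = rng.standard_normal(n)
        y = 1.0 + x + rng.standard_normal(n)
        outcome = OutcomeModel("gaussian", alpha=[1.0, 1.0], beta=0.5,
                               dispersion=1.2)
        for rho in (0.05, 0.2):
            ours = gsame_loglik(gene, y, x, RC, outcome, rho,
                                restrict_active=restrict)
            ref = brute_force_loglik(gene, y, x, RC, outcome, rho, restrict)
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_single_locus_equals_mutation_level_likelihood(self, rng):
        """With the activity restriction loosened, p=1 is exactly mSAME."""
        cfg = SimulationConfig(rho1=0.10, beta=0.5, seed=71)
        from samestat import simulate_mutation_site

        site, s, y, x = simulate_mutation_site(cfg, rng)
        ce = CallErrorModel(0.9, 0.98)
        gene = GeneData(site.A[None, :], site.D[None, :], site.O[None, :],
                        call_errors=[ce], gene_id="single")
        m_res = msame_test(site, y, x, RC, ce)
        g_res = gsame_test(gene, y, x, RC, restrict_active=False)
        assert g_res.fit_alt.loglik == pytest.approx(m_res.fit_alt.loglik,
                                                     abs=1e-8)
        assert g_res.statistic == pytest.approx(m_res.statistic, abs=1e-8)
        assert g_res.pvalue == pytest.approx(m_res.pvalue, abs=1e-8)

    def test_all_zero_counts_suppress_mutated_branch(self, rng):
        p, n = 3, 50
        gene = GeneData(
            np.zeros((p, n), dtype=int),
            np.full((p, n), 100),
            np.zeros((p, n)),
            call_errors=[CallErrorModel(0.9, 0.98)] * p,
        )
        x = rng.standard_normal(n)
        y = 1.0 + x + rng.standard_normal(n)
        fit = gsame_em(gene, y, x, RC)
        assert np.all(fit.posterior < 0.10)  # below any plausible prior mass

    def test_enumeration_cap_enforced_in_likelihood(self, rng):
        p, n = 13, 4
        gene = GeneData(
            np.ones((p, n), dtype=int),
            np.full((p, n), 40),
            np.zeros((p, n)),
            call_errors=[CallErrorModel(0.9, 0.98)] * p,
        )
        outcome = OutcomeModel("gaussian", alpha=[0.0, 0.0], beta=0.0)
        with pytest.raises(ValueError, match="pre-filter"):
            gsame_loglik(gene, np.zeros(n), np.zeros(n), RC, outcome, 0.1)


class TestGsameEm:
    def test_informative_evidence_recovers_oracle_glm(self, rng):
        p, n = 3, 400
        s = rng.binomial(1, 0.15, size=(p, n))
        s_gene = s.max(axis=0)
        D = np.full((p, n), 400)
        A = np.where(s == 1, rng.binomial(D, 0.5), 0)
        O = s.astype(float)
        high = {
            (0, 0): BetaBinomParams(0.001, 0.001),
            (0, 1): BetaBinomParams(0.001, 0.001),
            (1, 0): BetaBinomParams(0.5, 0.001),
            (1, 1): BetaBinomParams(0.5, 0.001),
        }
        rc = ReadCountModel(high_depth=high, d0=20)
        gene = GeneData(A, D, O, call_errors=[CallErrorModel(1.0, 1.0)] * p)
        x = rng.standard_normal(n)
        y = 1.0 + x + 0.7 * s_gene + rng.standard_normal(n)
        fit = gsame_em(gene, y, x, rc)
        ref = sm.OLS(y, np.column_stack([np.ones(n), x, s_gene])).fit()
        np.testing.assert_allclose(
            np.append(fit.outcome.alpha, fit.outcome.beta), ref.params,
            atol=1e-5,
        )

    def test_null_nesting_and_monotone_loglik(self, rng):
        cfg = SimulationConfig(level="gene", rho1=0.10, beta=0.6, seed=73)
        gene, s_g, y, x, truth = simulate_gene(cfg, rng)
        gene = GeneData(gene.A, gene.D, gene.O, call_errors=truth)
        alt = gsame_em(gene, y, x, RC)
        null = gsame_em(gene, y, x, RC, beta_fixed=0.0)
        assert null.outcome.beta == 0.0
        assert null.loglik <= alt.loglik + 1e-9
        for fit in (alt, null):
            trace = np.array(fit.diagnostics["loglik_trace"])
            assert np.all(np.diff(trace) >= -1e-8)

    def test_effect_estimate_recovery(self):
        cfg = SimulationConfig(level="gene", rho1=0.10, beta=1.0, seed=79)
        betas = []
        for ss in np.random.SeedSequence(79).spawn(200):
            rng = np.random.default_rng(ss)
            gene, s_g, y, x, truth = simulate_gene(cfg, rng)
            ce = estimate_gene_call_errors(gene, cfg.read_count_model)
            gene = GeneData(gene.A, gene.D, gene.O, call_errors=ce)
            betas.append(
                gsame_em(gene, y, x, cfg.read_count_model).outcome.beta
            )
        assert abs(np.mean(betas) - 1.0) < 0.12


class TestGeneSameEstimator:
    def test_fit_exposes_test_result(self, rng):
        cfg = SimulationConfig(level="gene", rho1=0.10, beta=0.8, seed=83)
        gene, s_g, y, x, truth = simulate_gene(cfg, rng)
        est = GeneSAME().fit(x, y, gene=gene)
        assert est.pvalue_ == est.result_.pvalue
        assert len(est.call_errors_) == gene.p
        assert est.predict(x).shape == y.shape

    def test_per_locus_error_estimation_with_pooled_fallback(self, rng):
        cfg = SimulationConfig(level="gene", rho1=0.10, seed=89)
        gene, *_ = simulate_gene(cfg, rng)
        ces = estimate_gene_call_errors(gene, RC)
        assert len(ces) == gene.p
        for ce in ces:
            assert 0.5 < ce.gamma1 <= 1.0 and 0.5 < ce.gamma0 <= 1.0


def test_locus_inclusion_probability_formula():
    assert locus_inclusion_prob(0.10, 10) == pytest.approx(0.010480742, abs=1e-8)
    assert locus_inclusion_prob(0.10, 1) == pytest.approx(0.10)
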