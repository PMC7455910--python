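import numpy as np
import pytest
import scipy.optimize
import scipy.stats as st

from nbmix import (RunConfig, fit_all_genes, gibbs_update_sigma, nb_loglik,
                   run_chain, rw_update_log_dispersion, wls_proposal,
                   mh_update_regression)
from nbmix.diagnostics import long_run_variance
from nbmix.sampler import ChainState, GenePrior

from conftest import make_design


def mc_se(chain):
    """Monte Carlo standard error of a chain mean, autocorrelation-aware."""
    return np.sqrt(long_run_variance(chain) / chain.size)


def flat_prior(p, scale=1e6, A=-1.0, B=0.5):
    return GenePrior(M=np.zeros(p), T=np.eye(p) * scale**2, U=0.01, V=0.01,
                     A=A, B=B)


class TestNbLoglik:
    def test_closed_form_at_zero(self):
        # P(Y=0) = (1 + alpha*mu)^(-1/alpha)
        for mu, alpha in [(2.0, 0.5), (10.0, 0.1), (0.3, 2.0)]:
            assert nb_loglik(0, mu, alpha) == pytest.approx(
                -(1 / alpha) * np.log(1 + alpha * mu))

    def test_poisson_limit(self):
        assert nb_loglik(3, 2.0, 1e-8) == pytest.approx(
            st.poisson.logpmf(3, 2.0), abs=1e-5)

    def test_normalization(self):
        y = np.arange(0, 4000)
        total = np.sum(np.exp(nb_loglik(y, 5.0, 0.5)))
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_kernel_matches_scipy(self):
        from nbmix._kernel import _nb_const, _nb_mu_part
        from scipy.special import gammaln

        rng = np.random.default_rng(0)
        y = rng.poisson(8.0, 12).astype(float)
        eta = rng.normal(2.0, 0.3, 12)
        mu = np.exp(eta)
        for alpha in (0.05, 0.7):
            r = 1.0 / alpha
            kernel = (_nb_const(y, r) + _nb_mu_part(y, eta, mu, r)
                      - np.sum(gammaln(y + 1)))
            assert kernel == pytest.approx(float(np.sum(nb_loglik(y, mu, alpha))))


class TestWlsProposal:
    def test_poisson_intercept_fixed_point(self):
        """Intercept-only Poisson-limit model with a flat prior: at
        beta0 = ln(mean y) the WLS step is a fixed point with variance
        1/sum(w), w = mu."""
        y = np.array([4.0, 6.0, 5.0, 9.0])
        design = make_design(np.ones((4, 1)))
        state = ChainState(beta=np.array([np.log(y.mean())]), b=None,
                           log_alpha=np.log(1e-8), sigma2=1.0)
        mean, cov = wls_proposal(y, design, state, flat_prior(1))
        assert mean[0] == pytest.approx(np.log(y.mean()), abs=1e-6)
        assert cov[0, 0] == pytest.approx(1.0 / y.sum(), rel=1e-4)

    def test_poisson_limit_weights(self):
        # alpha -> 0: w -> mu, so the flat-prior precision is sum(mu) x'x
        y = np.array([3.0, 4.0])
        design = make_design(np.ones((2, 1)))
        state = ChainState(beta=np.array([1.0]), b=None,
                           log_alpha=np.log(1e-10), sigma2=1.0)
        _, cov = wls_proposal(y, design, state, flat_prior(1))
        assert 1.0 / cov[0, 0] == pytest.approx(2 * np.e, rel=1e-4)

    def test_fixed_point_is_penalized_likelihood_maximizer(self):
        """Iterating the WLS map converges to the penalized-likelihood
        maximizer found by an independent numerical optimizer."""
        y = np.array([1.0, 2.0, 3.0])
        design = make_design(np.ones((3, 1)))
        alpha = 0.5
        prior = GenePrior(M=np.zeros(1), T=np.eye(1) * 4.0, U=0.01, V=0.01,
                          A=-1.0, B=0.5)
        state = ChainState(beta=np.array([0.0]), b=None,
                           log_alpha=np.log(alpha), sigma2=1.0)
        for _ in range(200):
            mean, _ = wls_proposal(y, design, state, prior)
            state = ChainState(beta=mean.copy(), b=None,
                               log_alpha=state.log_alpha, sigma2=1.0)

        def neg_penalized(b0):
            ll = np.sum(nb_loglik(y, np.exp(b0), alpha))
            return -(ll - b0**2 / (2 * 4.0))

        opt = scipy.optimize.minimize_scalar(neg_penalized, bounds=(-3, 3),
                                             method="bounded",
                                             options={"xatol": 1e-10})
        assert state.beta[0] == pytest.approx(opt.x, abs=1e-6)

    def test_random_intercept_block_structure(self):
        """With q=1 the proposal covariance couples each subject's random
        effect to the fixed effects but not to other subjects."""
        rng = np.random.default_rng(1)
        y = rng.poisson(10, 6).astype(float)
        design = make_design(np.ones((6, 1)),
                             subject_index=np.array([0, 0, 1, 1, 2, 2]),
                             n_subjects=3)
        state = ChainState(beta=np.array([np.log(10.0)]), b=np.zeros(3),
                           log_alpha=np.log(0.1), sigma2=0.5)
        _, cov = wls_proposal(y, design, state, flat_prior(1))
        prec = np.linalg.inv(cov)
        assert prec.shape == (4, 4)
        # subject-subject off-diagonals of the precision are exactly zero
        off = prec[1:, 1:] - np.diag(np.diag(prec[1:, 1:]))
        assert np.allclose(off, 0.0, atol=1e-8)


class TestMhRegression:
    def test_posterior_mean_matches_reference_sampler(self):
        """Large-count q=0 case: the WLS-proposal chain and an independent
        random-walk MH sampler must agree on posterior means within
        combined Monte Carlo error."""
        rng = np.random.default_rng(2)
        n = 30
        x = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        X = np.column_stack([np.ones(n), x])
        alpha = 0.1
        r = 1 / alpha
        mu = np.exp(3.0 + 0.5 * x)
        y = rng.negative_binomial(r, r / (r + mu)).astype(float)
        design = make_design(X)
        prior = GenePrior(M=np.zeros(2), T=np.eye(2) * 49.0, U=0.01, V=0.01,
                          A=np.log(alpha), B=0.5)

        state = ChainState(beta=np.array([3.0, 0.0]), b=None,
                           log_alpha=np.log(alpha), sigma2=1.0)
        rng_mh = np.random.default_rng(3)
        draws = []
        for _ in range(4000):
            state, _ = mh_update_regression(y, design, state, prior, rng_mh)
            draws.append(state.beta.copy())
        draws = np.array(draws)[500:]

        def log_post(beta):
            m = np.exp(X @ beta)
            return (np.sum(nb_loglik(y, m, alpha))
                    - 0.5 * beta @ np.linalg.solve(prior.T, beta))

        rng_rw = np.random.default_rng(4)
        beta = np.array([3.0, 0.0])
        lp = log_post(beta)
        ref = []
        for _ in range(40000):
            prop = beta + 0.05 * rng_rw.standard_normal(2)
            lp_p = log_post(prop)
            if np.log(rng_rw.random()) < lp_p - lp:
                beta, lp = prop, lp_p
            ref.append(beta.copy())
        ref = np.array(ref)[5000:]

        for j in range(2):
            se = 3 * np.sqrt(mc_se(draws[:, j])**2 + mc_se(ref[:, j])**2)
            assert abs(draws[:, j].mean() - ref[:, j].mean()) < se

    def test_acceptance_fraction_is_healthy(self, fitted_small):
        fit, _ = fitted_small
        rates = fit.diagnostics_frame.accept_regression
        assert (rates >= 0.10).all()


class TestRwDispersion:
    def test_zero_step_is_constant_and_accepted(self):
        y = np.array([3.0, 5.0])
        design = make_design(np.ones((2, 1)))
        state = ChainState(beta=np.array([1.0]), b=None, log_alpha=-1.0,
                           sigma2=1.0)
        rng = np.random.default_rng(5)
        la, accepted = rw_update_log_dispersion(y, design, state,
                                                flat_prior(1), 0.0, rng)
        assert la == -1.0 and accepted

    def test_prior_only_target(self):
        """With no data the random walk samples the N(A, B) prior."""
        y = np.zeros(0)
        design = make_design(np.ones((0, 1)))
        prior = flat_prior(1, A=-1.5, B=0.36)
        state = ChainState(beta=np.zeros(1), b=None, log_alpha=-1.5,
                           sigma2=1.0)
        rng = np.random.default_rng(6)
        draws = np.empty(20000)
        for i in range(20000):
            la, _ = rw_update_log_dispersion(y, design, state, prior, 0.8, rng)
            state.log_alpha = la
            draws[i] = la
        draws = draws[2000:]
        assert abs(draws.mean() - (-1.5)) < 3 * mc_se(draws)
        assert draws.var() == pytest.approx(0.36, rel=0.1)

    def test_grid_oracle_for_dispersion_posterior(self):
        """Fixing beta at truth, the chain histogram of log alpha must match
        a dense grid evaluation of the exact conditional posterior."""
        rng = np.random.default_rng(7)
        alpha_true, mu_true = 0.3, 20.0
        r = 1 / alpha_true
        y = rng.negative_binomial(r, r / (r + mu_true), 40).astype(float)
        design = make_design(np.ones((40, 1)))
        prior = flat_prior(1, A=np.log(0.3), B=1.0)
        state = ChainState(beta=np.array([np.log(mu_true)]), b=None,
                           log_alpha=np.log(0.3), sigma2=1.0)
        rng_mh = np.random.default_rng(8)
        draws = np.empty(20000)
        for i in range(20000):
            la, _ = rw_update_log_dispersion(y, design, state, prior, 0.5,
                                             rng_mh)
            state.log_alpha = la
            draws[i] = la
        draws = draws[2000:]

        grid = np.linspace(-4, 2, 600)
        mu = np.full_like(y, mu_true)
        logpost = np.array([
            np.sum(nb_loglik(y, mu, np.exp(la)))
            - 0.5 * (la - prior.A) ** 2 / prior.B
            for la in grid
        ])
        dens = np.exp(logpost - logpost.max())
        dens /= np.trapezoid(dens, grid)
        cdf_grid = np.cumsum(dens) * (grid[1] - grid[0])
        emp_cdf = np.searchsorted(np.sort(draws), grid) / draws.size
        assert np.max(np.abs(emp_cdf - cdf_grid)) < 0.05


class TestGibbsSigma:
    def test_conditional_mean_closed_form(self):
        # U=V=0.01, I=20, sum b^2 = 2 -> IG(10.01, 1.01), mean 1.01/9.01
        rng = np.random.default_rng(9)
        b = np.zeros(20)
        b[0] = np.sqrt(2.0)
        draws = np.array([gibbs_update_sigma(b, 0.01, 0.01, rng)
                          for _ in range(100_000)])
        expected = 1.01 / 9.01
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - expected) < 3 * se
        assert expected == pytest.approx(0.1121, abs=2e-4)

    def test_all_zero_random_effects(self):
        rng = np.random.default_rng(10)
        draws = np.array([gibbs_update_sigma(np.zeros(4), 0.01, 0.01, rng)
                          for _ in range(50_000)])
        # IG(2.01, 0.01): mean 0.01/1.01
        assert draws.mean() == pytest.approx(0.01 / 1.01, rel=0.1)

    def test_sigma_prior_recovery_with_no_subjects(self):
        # I=0 draws straight from the IG(U, V) prior; use U=3, V=2
        rng = np.random.default_rng(11)
        draws = np.array([gibbs_update_sigma(np.zeros(0), 3.0, 2.0, rng)
                          for _ in range(100_000)])
        assert draws.mean() == pytest.approx(2.0 / 2.0, rel=0.05)
        assert draws.var() == pytest.approx(1.0, rel=0.2)


class TestRunChain:
    @staticmethod
    def _toy(seed=0, S=8):
        rng = np.random.default_rng(seed)
        y = rng.negative_binomial(5, 5 / (5 + 20.0), S).astype(float)
        design = make_design(np.ones((S, 1)))
        prior = GenePrior(M=np.array([np.log(20.0)]), T=np.eye(1) * 49.0,
                          U=0.01, V=0.01, A=np.log(0.2), B=0.5)
        return y, design, prior

    def test_identical_seed_identical_chain(self):
        y, design, prior = self._toy()
        config = RunConfig(n_iter=2000, master_seed=1)
        c1 = run_chain(y, design, prior, config, np.random.default_rng(42))
        c2 = run_chain(y, design, prior, config, np.random.default_rng(42))
        assert np.array_equal(c1.beta, c2.beta)
        assert np.array_equal(c1.log_alpha, c2.log_alpha)
        assert np.array_equal(c1.accept_beta, c2.accept_beta)

    def test_default_retained_length(self):
        y, design, prior = self._toy()
        config = RunConfig()  # 30,000 iterations, 10% burn-in
        chains = run_chain(y, design, prior, config, np.random.default_rng(0))
        assert chains.n_retained == 27_000

    def test_compiled_and_python_paths_agree(self):
        y, design, prior = self._toy()
        config = RunConfig(n_iter=1500, master_seed=1)
        fast = run_chain(y, design, prior, config, np.random.default_rng(3))
        slow = run_chain(y, design, prior, config, np.random.default_rng(3),
                         compiled=False)
        assert np.allclose(fast.beta, slow.beta)
        assert np.allclose(fast.log_alpha, slow.log_alpha)

    def test_grid_oracle_exactness_q0(self):
        """Posterior moments of (beta0, log alpha) for a tiny q=0 gene match
        a dense 2-D grid evaluation of the unnormalized posterior."""
        y = np.array([3.0, 5.0, 7.0])
        design = make_design(np.ones((3, 1)))
        prior = GenePrior(M=np.array([np.log(5.0)]), T=np.eye(1) * 49.0,
                          U=0.01, V=0.01, A=-1.0, B=0.5)
        config = RunConfig(n_iter=40000, master_seed=1)
        chains = run_chain(y, design, prior, config, np.random.default_rng(12))

        b_grid = np.linspace(-1.5, 4.5, 401)
        la_grid = np.linspace(-6.0, 3.0, 401)
        BB, LL = np.meshgrid(b_grid, la_grid, indexing="ij")
        logp = np.zeros_like(BB)
        for obs in y:
            logp += nb_loglik(obs, np.exp(BB), np.exp(LL))
        logp -= 0.5 * (BB - prior.M[0]) ** 2 / 49.0
        logp -= 0.5 * (LL - prior.A) ** 2 / prior.B
        w = np.exp(logp - logp.max())
        w /= w.sum()
        for chain, grid, axis in [(chains.beta[:, 0], BB, None),
                                  (chains.log_alpha, LL, None)]:
            exact_mean = float(np.sum(w * grid))
            exact_sd = float(np.sqrt(np.sum(w * (grid - exact_mean) ** 2)))
            assert abs(chain.mean() - exact_mean) < 3 * mc_se(chain)
            # second moment with a tolerant bound (MC error of an SD)
            assert chain.std() == pytest.approx(exact_sd, rel=0.05)

    def test_prior_recovery_with_no_data(self):
        """Zero-length data: the sampler must reproduce the N(M, T) and
        N(A, B) priors."""
        y = np.zeros(0)
        design = make_design(np.ones((0, 1)))
        prior = GenePrior(M=np.array([1.0]), T=np.eye(1) * 2.25, U=0.01,
                          V=0.01, A=-2.0, B=0.49)
        config = RunConfig(n_iter=30000, master_seed=1)
        chains = run_chain(y, design, prior, config, np.random.default_rng(13))
        beta = chains.beta[:, 0]
        la = chains.log_alpha
        assert abs(beta.mean() - 1.0) < 3 * mc_se(beta)
        assert beta.var() == pytest.approx(2.25, rel=0.1)
        assert abs(la.mean() - (-2.0)) < 3 * mc_se(la)
        assert la.var() == pytest.approx(0.49, rel=0.1)

    def test_posterior_width_reflects_dispersion_uncertainty(self):
        """Letting the chain estimate alpha cannot narrow the posterior of
        beta relative to fixing alpha at its true value."""
        rng = np.random.default_rng(14)
        alpha_true = 0.3
        r = 1 / alpha_true
        sds_free, sds_fixed = [], []
        for g in range(8):
            y = rng.negative_binomial(r, r / (r + 50.0), 10).astype(float)
            design = make_design(np.ones((10, 1)))
            config = RunConfig(n_iter=6000, master_seed=g)
            free = GenePrior(M=np.array([np.log(50.0)]), T=np.eye(1) * 49.0,
                             U=0.01, V=0.01, A=np.log(alpha_true), B=1.0)
            pinned = GenePrior(M=np.array([np.log(50.0)]), T=np.eye(1) * 49.0,
                               U=0.01, V=0.01, A=np.log(alpha_true), B=1e-12)
            cf = run_chain(y, design, free, config, np.random.default_rng(100 + g))
            cp = run_chain(y, design, pinned, config, np.random.default_rng(200 + g))
            sds_free.append(cf.beta[:, 0].std())
            sds_fixed.append(cp.beta[:, 0].std())
        assert np.mean(sds_free) >= np.mean(sds_fixed) * 0.98


class TestFitAllGenes:
    def test_worker_count_does_not_change_output(self, sim_small):
        counts, metadata, _ = sim_small
        from nbmix import build_design, default_priors
        from nbmix.preprocess import median_of_ratios_size_factors

        offsets = median_of_ratios_size_factors(counts).offsets
        design = build_design(metadata, "group * time", offsets=offsets)
        priors = default_priors(counts, design)
        sub = counts.subset_genes(np.arange(counts.n_genes) < 10)
        priors_sub = type(priors)(M=priors.M[:10], T=priors.T, U=priors.U,
                                  V=priors.V, A=priors.A[:10], B=priors.B,
                                  k=priors.k)
        out1 = fit_all_genes(sub, design, priors_sub,
                             RunConfig(n_iter=800, master_seed=9, n_workers=1))
        out4 = fit_all_genes(sub, design, priors_sub,
                             RunConfig(n_iter=800, master_seed=9, n_workers=4))
        for a, b in zip(out1, out4):
            assert np.array_equal(a.beta, b.beta)
            assert np.array_equal(a.log_alpha, b.log_alpha)

    def test_gene_subsetting_leaves_chains_unchanged(self, sim_small):
        """Seeding by gene id means fitting a gene alone reproduces its
        chain from the full run exactly."""
        counts, metadata, _ = sim_small
        from nbmix import build_design, default_priors

        design = build_design(metadata, "group * time")
        priors = default_priors(counts, design)
        config = RunConfig(n_iter=600, master_seed=9)
        full = fit_all_genes(counts, design, priors, config)
        keep = np.zeros(counts.n_genes, dtype=bool)
        keep[7] = True
        sub = counts.subset_genes(keep)
        priors_sub = type(priors)(M=priors.M[[7]], T=priors.T, U=priors.U,
                                  V=priors.V, A=priors.A[[7]], B=priors.B,
                                  k=priors.k)
        alone = fit_all_genes(sub, design, priors_sub, config)
        assert np.array_equal(full[7].beta, alone[0].beta)

    def test_empty_gene_list(self):
        from nbmix import CountMatrix
        from nbmix.priors import PriorSpec

        cm = CountMatrix([], ["s1", "s2"], np.zeros((0, 2), dtype=int))
        design = make_design(np.ones((2, 1)))
        priors = PriorSpec(M=np.zeros((0, 1)), T=np.eye(1), U=0.01, V=0.01,
                           A=np.zeros(0), B=1.0, k=2.0)
        assert fit_all_genes(cm, design, priors,
                             RunConfig(n_iter=200, master_seed=0)) == []

    def test_individual_failure_does_not_abort_run(self, sim_small,
                                                   monkeypatch):
        counts, metadata, _ = sim_small
        from nbmix import build_design, default_priors
        import nbmix.sampler as sampler_mod

        design = build_design(metadata, "group * time")
        priors = default_priors(counts, design)
        sub = counts.subset_genes(np.arange(counts.n_genes) < 3)
        priors_sub = type(priors)(M=priors.M[:3], T=priors.T, U=priors.U,
                                  V=priors.V, A=priors.A[:3], B=priors.B,
                                  k=priors.k)
        real = sampler_mod.run_chain

        def flaky(y, design, prior, config, rng, gene_id="gene", **kw):
            if gene_id == sub.gene_ids[1]:
                raise RuntimeError("boom")
            return real(y, design, prior, config, rng, gene_id=gene_id, **kw)

        monkeypatch.setattr(sampler_mod, "run_chain", flaky)
        out = sampler_mod.fit_all_genes(sub, design, priors_sub,
                                        RunConfig(n_iter=300, master_seed=0))
        assert out[1] is None
        assert out[0] is not None and out[2] is not None
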