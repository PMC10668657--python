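"""Sampler machinery: predictors, diagnostics, posterior correctness."""

import numpy as np
import pytest

from agecjs import (
    MCMCConfig,
    build_design,
    build_age_covariate,
    build_trap_covariate,
    gelman_rubin,
    inverse_logit,
    linear_predictors,
    make_fixture,
    pool_to_occasions,
    sample_posterior,
    simulate,
)


@pytest.fixture(scope="module")
def tiny_prepared():
    cfg = make_fixture("tiny", seed=12)
    records, truth = simulate(cfg)
    history, _ = pool_to_occasions(records, cfg.grid)
    return history, build_age_covariate(history), build_trap_covariate(history)


class TestLinearPredictors:
    def test_zero_intercept_gives_half(self, tiny_prepared):
        history, A, T = tiny_prepared
        design = build_design(history, A, T, random_effects="none")
        phi, p = linear_predictors(design, np.zeros(design.nb), np.zeros(design.na))
        defined = design.bidx >= 0
        assert np.allclose(phi[defined], 0.5)
        assert np.allclose(p[defined], 0.5)
        assert np.isnan(phi[~defined]).all()

    def test_closed_form_inverse_logit(self, tiny_prepared):
        history, A, T = tiny_prepared
        design = build_design(history, A, T, random_effects="none")
        phi, _ = linear_predictors(design, np.full(design.nb, 1.3863),
                                   np.zeros(design.na))
        defined = design.bidx >= 0
        assert np.allclose(phi[defined], 0.8, atol=1e-4)

    def test_zero_frailty_draws_share_cell_probabilities(self, tiny_prepared):
        history, A, T = tiny_prepared
        design = build_design(history, A, T, random_effects="cell")
        rng = np.random.default_rng(0)
        beta = rng.normal(size=design.nb)
        alpha = rng.normal(size=design.na)
        eps = np.zeros(len(design.eps_group))
        omega = np.zeros(len(design.omega_group))
        phi0, p0 = linear_predictors(design, beta, alpha, eps, omega)
        phi1, p1 = linear_predictors(design, beta, alpha)
        np.testing.assert_allclose(phi0[design.bidx >= 0], phi1[design.bidx >= 0])
        np.testing.assert_allclose(p0[design.bidx >= 0], p1[design.bidx >= 0])

    def test_wrong_parameter_length_rejected(self, tiny_prepared):
        history, A, T = tiny_prepared
        design = build_design(history, A, T, random_effects="none")
        with pytest.raises(ValueError):
            linear_predictors(design, np.zeros(design.nb - 1), np.zeros(design.na))


class TestGelmanRubin:
    def test_identical_chains_give_unity(self):
        rng = np.random.default_rng(1)
        chain = rng.normal(size=200)
        rhat = gelman_rubin(np.stack([chain, chain, chain]))
        assert rhat == pytest.approx(1.0, abs=0.01)

    def test_textbook_formula_on_small_arrays(self):
        draws = np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0],
                          [2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0, 11.0]])
        m, n = draws.shape
        means = draws.mean(axis=1)
        w = draws.var(axis=1, ddof=1).mean()
        b_over_n = means.var(ddof=1)
        expected = np.sqrt(((n - 1) / n * w + b_over_n) / w)
        assert gelman_rubin(draws) == pytest.approx(expected, rel=1e-12)

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 1000)
        b = rng.normal(5, 1, 1000)
        assert gelman_rubin(np.stack([a, b])) > 1.1

    def test_iid_chains_converge(self):
        rng = np.random.default_rng(3)
        draws = rng.normal(size=(3, 10_000))
        assert gelman_rubin(draws) < 1.01

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))


class TestSampler:
    def test_retained_draw_count_and_determinism(self, tiny_prepared):
        history, A, T = tiny_prepared
        cfg = MCMCConfig(chains=2, iterations=900, burn_in=300, thin=7,
                         seed=5, random_effects="none")
        post = sample_posterior(history, A, T, cfg)
        assert post.draws.shape == (2, (900 - 300) // 7, len(post.param_names))
        again = sample_posterior(history, A, T, cfg)
        np.testing.assert_array_equal(post.draws, again.draws)

    def test_empty_cell_reported_prior_only(self, history_builder):
        from agecjs import make_grid

        # adults only: every juvenile/immature cell is empty
        grid = make_grid(2012, 1, 5)
        rows = [[1, 1, 0, 1, 0], [1, 0, 1, 0, 0], [0, 1, 1, 1, 1]]
        history = history_builder(rows, [5, 5, 5], grid)
        A = build_age_covariate(history)
        T = build_trap_covariate(history)
        cfg = MCMCConfig(chains=2, iterations=400, burn_in=100, thin=3,
                         seed=2, random_effects="none")
        post = sample_posterior(history, A, T, cfg)
        assert any("prior-only" in w for w in post.warnings)
        assert post.cell_is_prior_only("phi", 1, 1)
        assert not post.cell_is_prior_only("phi", 4, 1)
        # a prior-only intercept is sampled from its Uniform(0,1) prior on
        # the probability scale
        draws = post.phi_draws(1, 1)
        assert 0.4 < draws.mean() < 0.6
        assert np.percentile(draws, 97.5) > 0.9

    def test_posterior_matches_independent_ensemble_sampler(self):
        """Cross-check the Metropolis-within-Gibbs kernel against emcee on
        the identical no-frailty posterior (same likelihood, same priors).
        A single-period design with ~120 individuals keeps the posterior
        well identified so both samplers' means must agree closely.
        """
        emcee = pytest.importorskip("emcee")


        from agecjs import make_grid
        from agecjs.synthetic_data import SimulationConfig

        grid = make_grid(2012, 1, 5)
        releases = np.zeros((5, 3), dtype=np.int64)
        releases[:4, :] = 10
        sim = SimulationConfig(
            grid=grid, releases=releases,
            phi=[[0.8], [0.85], [0.9]], tau=0.0,
            p=[[0.45], [0.45], [0.45], [0.35]],
            sigma_phi=0.0, sigma_p=0.0, seed=31,
        )
        records, _ = simulate(sim)
        history, _ = pool_to_occasions(records, sim.grid)
        A = build_age_covariate(history)
        T = build_trap_covariate(history)
        design = build_design(history, A, T, random_effects="none")
        from agecjs.cjs_model import dataset_loglik

        occupied_b = np.flatnonzero(design.beta_occupancy > 0)
        occupied_a = np.flatnonzero(design.alpha_occupancy > 0)

        def log_post(theta):
            beta = np.zeros(design.nb)
            alpha = np.zeros(design.na)
            beta[occupied_b] = theta[: len(occupied_b)]
            alpha[occupied_a] = theta[len(occupied_b):]
            lp = -np.sum(np.abs(theta) + 2 * np.log1p(np.exp(-np.abs(theta))))
            return lp + dataset_loglik(design, beta, alpha)

        ndim = len(occupied_b) + len(occupied_a)
        rng = np.random.default_rng(8)
        sampler = emcee.EnsembleSampler(max(2 * ndim + 2, 24), ndim, log_post)
        start = rng.normal(0, 0.5, size=(sampler.nwalkers, ndim))
        sampler.run_mcmc(start, 1500, progress=False)
        ref = sampler.get_chain(discard=500, thin=5, flat=True)

        cfg = MCMCConfig(chains=3, iterations=6000, burn_in=2000, thin=2,
                         seed=9, random_effects="none")
        post = sample_posterior(history, A, T, cfg)
        ours = post.draws.reshape(-1, len(post.param_names))
        cols = np.concatenate([occupied_b, design.nb + occupied_a])
        ours = ours[:, cols]

        # compare posterior means of every occupied intercept on the
        # probability scale, within a tolerance driven by both MC errors
        ours_mean = inverse_logit(ours).mean(axis=0)
        ref_mean = inverse_logit(ref).mean(axis=0)
        np.testing.assert_allclose(ours_mean, ref_mean, atol=0.035)

    def test_frailty_posterior_concentrates_when_truth_is_homogeneous(self):
        # sigma = 0 truth: the posterior of every frailty SD should put its
        # mass well below the prior median of 5
        cfg = make_fixture("null_model", seed=21)
        records, _ = simulate(cfg)
        history, _ = pool_to_occasions(records, cfg.grid)
        A = build_age_covariate(history)
        T = build_trap_covariate(history)
        mc = MCMCConfig(chains=2, iterations=2500, burn_in=1000, thin=3, seed=4,
                        random_effects="cell")
        post = sample_posterior(history, A, T, mc)
        summary = post.summary()
        sig = summary[summary.parameter.str.startswith("sigma")]
        assert np.median(sig["mean"]) < 2.0

    def test_no_transience_truth_gives_tau_near_zero(self):
        """Data without transients: newly-marked and resident survival
        coincide, so the transient proportion concentrates at zero."""
        from agecjs import make_grid, transient_proportion
        from agecjs.synthetic_data import SimulationConfig

        grid = make_grid(2012, 1, 10)
        releases = np.zeros((10, 3), dtype=np.int64)
        releases[:9, :] = 20
        sim = SimulationConfig(
            grid=grid, releases=releases,
            phi=[[0.80], [0.85], [0.90]], tau=0.0,
            p=0.30, sigma_phi=0.2, sigma_p=0.2, seed=43,
        )
        records, _ = simulate(sim)
        history, _ = pool_to_occasions(records, sim.grid)
        A = build_age_covariate(history)
        T = build_trap_covariate(history)
        mc = MCMCConfig(chains=3, iterations=3000, burn_in=1000, thin=4, seed=6)
        post = sample_posterior(history, A, T, mc)
        for age in ("immature", "adult"):
            s = transient_proportion(post, age, 1)
            assert abs(s.mean) < 0.15
            assert s.lo95 < 0 < s.hi95

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            MCMCConfig(iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            MCMCConfig(thin=0)
        with pytest.raises(ValueError):
            MCMCConfig(chains=0)
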