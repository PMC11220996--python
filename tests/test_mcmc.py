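"""Sampler kernels: exactness, determinism, stationarity and calibration."""

import numpy as np
import pytest

from stcar import (
    ChainConfig,
    ModelSpec,
    PosteriorSamples,
    SimulationConfig,
    build_graph,
    lattice_graph,
    run_chain,
    simulate_panel,
)
from stcar.graphs import leroux_precision
from stcar.mcmc import Sampler, metropolis_accept

from conftest import make_panel


def small_sampler(variant="anova", n=4, T=3, likelihood=True, seed=0, **cfg_kw):
    g = lattice_graph(n)
    panel = make_panel(n=n, T=T, graph=g, seed=seed)
    spec = ModelSpec(variant=variant, n_covariates=0, intercept=True)
    cfg = ChainConfig(
        n_iter=cfg_kw.pop("n_iter", 200), burn_in=cfg_kw.pop("burn_in", 100),
        thin=cfg_kw.pop("thin", 1), seed=seed, **cfg_kw,
    )
    mask = None if likelihood else np.zeros((n, T), dtype=bool)
    return Sampler(panel, spec, cfg, mask=mask)


class TestChainConfig:
    def test_default_retains_ten_thousand(self):
        assert ChainConfig().n_retained == 10_000

    @pytest.mark.parametrize(
        "n_iter,burn,thin,expected",
        [(1000, 200, 4, 200), (1000, 200, 1, 800), (101, 100, 1, 1)],
    )
    def test_retained_count(self, n_iter, burn, thin, expected):
        assert ChainConfig(n_iter=n_iter, burn_in=burn, thin=thin).n_retained == expected

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            ChainConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            ChainConfig(thin=0)


class TestDeterminismAndBookkeeping:
    @pytest.mark.parametrize("variant", ["linear", "anova", "separable", "ar"])
    def test_same_seed_bit_identical(self, variant):
        cfg = SimulationConfig(n_areas=9, n_times=4, variant=variant, seed=1)
        panel, _ = simulate_panel(cfg)
        spec = ModelSpec(variant=variant, n_covariates=5)
        chain_cfg = ChainConfig(n_iter=400, burn_in=200, thin=2, seed=11)
        s1 = run_chain(panel, spec, chain_cfg)
        s2 = run_chain(panel, spec, chain_cfg)
        for key in s1.draws:
            assert np.array_equal(s1.draws[key], s2.draws[key]), key

    def test_retained_draws_match_config(self):
        panel, _ = simulate_panel(SimulationConfig(n_areas=9, n_times=4, seed=2))
        spec = ModelSpec(variant="anova", n_covariates=5)
        cfg = ChainConfig(n_iter=600, burn_in=100, thin=5, seed=0)
        s = run_chain(panel, spec, cfg)
        assert s.n_retained == cfg.n_retained == 100
        assert s.draws["beta"].shape == (100, 6)
        assert np.all(s.draws["tau2_interaction"] > 0)
        assert np.all((s.draws["rho_spatial"] > 0) & (s.draws["rho_spatial"] < 1))

    def test_adaptation_only_during_burn_in(self):
        s = small_sampler(n_iter=400, burn_in=200)
        s.run()
        expected = 200 // s.config.adapt_interval
        assert all(c == expected for c in s._adapt_count.values())

    def test_save_load_round_trip(self, tmp_path):
        panel, _ = simulate_panel(SimulationConfig(n_areas=9, n_times=4, seed=3))
        spec = ModelSpec(variant="anova", n_covariates=5)
        s = run_chain(panel, spec, ChainConfig(n_iter=120, burn_in=20, thin=2, seed=0))
        s.save(tmp_path / "fit")
        s2 = PosteriorSamples.load(tmp_path / "fit")
        for key in s.draws:
            assert np.array_equal(s.draws[key], s2.draws[key])
        assert s2.config == s.config
        assert s2.spec == s.spec


class TestKernels:
    def test_two_state_detailed_balance(self):
        """Empirical occupancy of a 2-point target matches pi within 1%."""
        rng = np.random.default_rng(0)
        log_pi = np.log([0.3, 0.7])
        state = 0
        visits = np.zeros(2)
        for _ in range(300_000):
            prop = 1 - state
            if metropolis_accept(log_pi[prop] - log_pi[state], rng):
                state = prop
            visits[state] += 1
        freq = visits / visits.sum()
        assert abs(freq[1] - 0.7) < 0.01

    def test_zero_width_proposal_keeps_chain_put_and_accepts(self):
        s = small_sampler()
        for block in s.log_f:
            s.log_f[block] = -500.0   # proposal scale -> 0
        beta0 = s.state.beta.copy()
        phi0 = s.state.phi.copy()
        rho0 = dict(s.state.rho)
        s.update_beta()
        s.update_random_effects()
        s.update_rho()
        assert np.array_equal(s.state.beta, beta0)
        assert np.allclose(s.state.phi, phi0)
        assert s.state.rho == pytest.approx(rho0)
        # delta = 0 proposals are always accepted
        assert s._total["beta"] == [1, 1]
        assert s._total["phi"][0] == s._total["phi"][1]

    def test_tau2_gibbs_matches_closed_form_posterior_mean(self):
        s = small_sampler(n=4, T=3, likelihood=False)
        st = s.state
        rng = np.random.default_rng(1)
        st.gamma = rng.standard_normal((4, 3))
        quad = float((st.gamma ** 2).sum())
        a, b = s.spec.prior.tau2_shape, s.spec.prior.tau2_scale
        m = 12
        expected = (b + quad / 2) / (a + m / 2 - 1)
        draws = np.empty(20_000)
        for k in range(draws.size):
            s.update_tau2()
            draws[k] = st.tau2["interaction"]
        assert np.mean(draws) == pytest.approx(expected, rel=0.03)

    def test_tau2_to_zero_pins_block(self):
        # a degenerate prior keeps the block glued to its zero mean
        s = small_sampler(likelihood=False)
        st = s.state
        st.tau2["interaction"] = 1e-12
        st.gamma[:] = 0.0
        for _ in range(200):
            s.update_random_effects()
        assert np.all(np.abs(st.gamma) < 1e-4)

    def test_prior_covariance_recovery_on_four_node_toy(self):
        """Likelihood off: the sampled spatial block matches CAR(rho, tau2)."""
        g = lattice_graph(4)
        panel = make_panel(n=4, T=2, graph=g)
        spec = ModelSpec(variant="anova", n_covariates=0, intercept=False)
        cfg = ChainConfig(n_iter=100, burn_in=50, seed=0, recenter=False)
        s = Sampler(panel, spec, cfg, mask=np.zeros((4, 2), dtype=bool))
        st = s.state
        st.tau2 = {"spatial": 1.5, "temporal": 1.0, "interaction": 1.0}
        st.rho = {"spatial": 0.7, "temporal": 0.3}
        N, warm = 30_000, 5_000
        draws = np.empty((N, 4))
        for k in range(N):
            s.update_random_effects()
            draws[k] = st.phi
        emp = np.cov(draws[warm:].T)
        true = 1.5 * np.linalg.inv(leroux_precision(g, 0.7).Q)
        assert np.abs(emp - true).max() / np.abs(true).max() < 0.10

    def test_beta_posterior_mean_near_mle_without_random_effects(self):
        """Bernstein-von-Mises: vague priors + negligible latent structure."""
        import statsmodels.api as sm

        cfg = SimulationConfig(
            n_areas=16, n_times=8, intercept=-1.0,
            tau2={"spatial": 1e-8, "temporal": 1e-8, "interaction": 1e-8},
            seed=3,
        )
        panel, _ = simulate_panel(cfg)
        spec = ModelSpec(variant="anova", n_covariates=5)
        s = run_chain(panel, spec, ChainConfig(n_iter=8000, burn_in=3000, thin=1, seed=5))
        X = np.column_stack([np.ones(panel.n_cells), panel.X])
        res = sm.GLM(
            panel.y.reshape(-1), X, family=sm.families.Poisson(),
            offset=panel.log_offset.reshape(-1),
        ).fit()
        pm = s.draws["beta"].mean(axis=0)
        assert np.all(np.abs(pm - res.params) < 0.8 * res.bse)

    def test_exchangeable_areas_have_symmetric_posteriors(self):
        g = build_graph([("A", "B")], ["A", "B"])
        y = np.array([[6, 7, 5, 8], [6, 7, 5, 8]])
        panel = make_panel(n=2, T=4, y=y, population=np.ones((2, 4)), graph=g)
        spec = ModelSpec(variant="anova", n_covariates=0, intercept=True)
        s = run_chain(panel, spec, ChainConfig(n_iter=12000, burn_in=2000, thin=2, seed=1))
        phi = s.draws["phi"]
        assert abs(phi.mean(axis=0)[0] - phi.mean(axis=0)[1]) < 0.05

    def test_relabeling_areas_leaves_posteriors_invariant(self):
        from stcar import PanelData, SpatialGraph

        panel, _ = simulate_panel(SimulationConfig(n_areas=12, n_times=6, seed=7))
        perm = np.random.default_rng(0).permutation(12)
        g = panel.graph
        g2 = SpatialGraph(
            tuple(g.area_ids[i] for i in perm), g.W[np.ix_(perm, perm)]
        )
        X2 = panel.X.reshape(12, 6, -1)[perm].reshape(72, -1)
        panel2 = PanelData(
            g2.area_ids, panel.years, panel.y[perm], panel.population[perm],
            X2, panel.covariate_names, g2,
        )
        spec = ModelSpec(variant="anova", n_covariates=5)
        cfg = ChainConfig(n_iter=12000, burn_in=4000, thin=2, seed=3)
        s1 = run_chain(panel, spec, cfg)
        s2 = run_chain(panel2, spec, cfg)
        b1, b2 = s1.draws["beta"].mean(axis=0), s2.draws["beta"].mean(axis=0)
        assert np.abs(b1 - b2).max() < 0.3 * s1.draws["beta"].std(axis=0).mean()
        t1 = s1.draws["tau2_interaction"].mean()
        t2 = s2.draws["tau2_interaction"].mean()
        assert abs(t1 - t2) / t1 < 0.2
        assert abs(s1.draws["rho_spatial"].mean() - s2.draws["rho_spatial"].mean()) < 0.1


class TestMultiChain:
    def test_run_chains_and_diagnostics(self):
        from stcar.mcmc import diagnostics, run_chains

        panel, _ = simulate_panel(SimulationConfig(n_areas=9, n_times=4, seed=5))
        spec = ModelSpec(variant="anova", n_covariates=5)
        cfg = ChainConfig(n_iter=600, burn_in=200, thin=2, seed=0, n_chains=2)
        chains = run_chains(panel, spec, cfg)
        assert len(chains) == 2
        assert not np.array_equal(chains[0].draws["beta"], chains[1].draws["beta"])
        diag = diagnostics(chains)
        assert {"ess", "rhat"} <= set(diag.columns)
        assert np.all(diag["ess"] > 1)
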