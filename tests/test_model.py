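import numpy as np
import pytest
from scipy.special import digamma, polygamma

from stcar.model import (
    MODEL_VARIANTS,
    ModelConfig,
    car_full_conditional_params,
    competing_model_family,
    log_mean,
    run_mcmc,
    update_latent_block,
    variance_posterior_params,
)
from stcar.panel_io import AdjacencyGraph, AreaPanel
from stcar.synthetic import CovariateSpec, GroundTruth, make_lattice_graph, simulate_panel


def _star_graph():
    # node 0 adjacent to 1, 2, 3
    return AdjacencyGraph.from_edges(["a", "b", "c", "d"], [("a", "b"), ("a", "c"), ("a", "d")])


class TestLogMean:
    def test_all_zero(self):
        assert log_mean(0.0, np.zeros(2), np.zeros(2)) == 0.0

    def test_intercept_only(self):
        assert np.exp(log_mean(np.log(10), np.zeros(1), np.zeros(1))) == pytest.approx(10)

    def test_composition_with_covariate(self):
        # overall level 11.22 with one covariate one unit above its mean at
        # coefficient 0.69 -> mean 11.22 * e^0.69
        eta = log_mean(np.log(11.22), np.array([0.69]), np.array([1.0]))
        assert np.exp(eta) == pytest.approx(11.22 * np.exp(0.69), rel=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(FloatingPointError):
            log_mean(np.inf, np.zeros(1), np.zeros(1))


class TestCARFullConditional:
    def test_neighbour_average(self):
        g = _star_graph()
        phi = np.array([9.0, 1.0, 2.0, 3.0])
        mean, var = car_full_conditional_params(0, phi, g, var_phi=1.0)
        assert mean == pytest.approx(2.0)
        assert var == pytest.approx(1.0 / 3.0)

    def test_all_neighbours_zero(self):
        g = _star_graph()
        mean, _ = car_full_conditional_params(0, np.zeros(4), g, 1.0)
        assert mean == 0.0

    def test_two_node_graph(self):
        g = AdjacencyGraph.from_edges(["a", "b"], [("a", "b")])
        mean, var = car_full_conditional_params(0, np.array([0.0, 5.0]), g, var_phi=2.0)
        assert (mean, var) == (5.0, 2.0)

    def test_isolated_area_gets_exchangeable_prior(self):
        g = AdjacencyGraph.from_edges(["a", "b", "c"], [("a", "b")])
        mean, var = car_full_conditional_params(2, np.array([1.0, -1.0, 4.0]), g, 0.7)
        assert (mean, var) == (0.0, 0.7)


class TestVariancePosterior:
    def test_phi_zero_field_connected_four_nodes(self):
        # rank = 4 - 1 = 3: shape 0.5 + 1.5 = 2, rate stays at prior 0.005;
        # implied precision mean 2 / 0.005 = 400
        sh, ra = variance_posterior_params("phi", np.zeros(4), _star_graph())
        assert (sh, ra) == (2.0, 0.005)
        assert sh / ra == pytest.approx(400)

    def test_xi_constant_field_shifts_shape_only(self):
        sh, ra = variance_posterior_params("xi", np.full(5, 3.3))
        assert sh == pytest.approx(0.5 + 2.0)
        assert ra == pytest.approx(0.005)

    def test_xi_one_step_walk(self):
        sh, ra = variance_posterior_params("xi", np.array([-1.0, 1.0]))
        assert sh == pytest.approx(1.0)
        assert ra == pytest.approx(0.005 + 2.0)  # (1 - (-1))^2 / 2

    def test_phi_quadratic_form_on_edge_graph(self):
        g = AdjacencyGraph.from_edges(["a", "b"], [("a", "b")])
        sh, ra = variance_posterior_params("phi", np.array([1.0, -1.0]), g)
        assert sh == pytest.approx(1.0)
        assert ra == pytest.approx(0.005 + 2.0)

    def test_delta_row_increments(self):
        d = np.array([[0.0, 2.0], [1.0, 1.0]])  # increments 2 and 0
        sh, ra = variance_posterior_params("delta", d)
        assert sh == pytest.approx(0.5 + 1.0)
        assert ra == pytest.approx(0.005 + 2.0)

    def test_iid_spatial_counts_every_area(self):
        sh, ra = variance_posterior_params(
            "phi", np.array([1.0, -1.0]), spatial_structure="iid"
        )
        assert sh == pytest.approx(0.5 + 1.0)
        assert ra == pytest.approx(0.005 + 1.0)


def _glm_panel(seed=21, n_rows=5, n_cols=6, t=6, beta=(0.4, -0.3)):
    g = make_lattice_graph(n_rows, n_cols)
    n = g.n_areas
    truth = GroundTruth(
        alpha=2.0, beta=np.array(beta), phi=np.zeros(n), xi=np.zeros(t),
        delta=np.zeros((n, t)), var_phi=0, var_xi=0, var_delta=0,
    )
    panel, truth = simulate_panel(g, truth, CovariateSpec(P=len(beta)), seed=seed)
    return g, panel, truth


class TestPriorSampling:
    def test_prior_only_chain_reproduces_prior_moments(self):
        g, panel, _ = _glm_panel(seed=30, n_rows=2, n_cols=2, t=2, beta=(0.0,))
        cfg = ModelConfig(
            n_chains=1, n_burnin=500, n_samples=4000, seed=31, prior_only=True
        )
        post = run_mcmc(panel, g, cfg)
        beta = post.stacked("beta")[:, 0]
        assert beta.var() == pytest.approx(1000, rel=0.25)
        prec = 1.0 / post.stacked("var_phi")
        # prior precision ~ Gamma(0.5, 0.005): mean 100, sd ~ 141
        assert prec.mean() == pytest.approx(100, abs=3 * 141 / np.sqrt(4000) * 2)


class TestPosteriorCorrectness:
    def test_intercept_only_posterior_matches_loggamma(self):
        # one area, one year, y = 7, no random effects, flat prior on alpha:
        # exp(alpha) | y ~ Gamma(7, 1)  =>  E[alpha] = digamma(7)
        panel = AreaPanel(["A"], np.array([2011]), np.array([[7]]),
                          np.zeros((1, 1, 0)), []).validate()
        g = AdjacencyGraph(["A"], [set()])
        cfg = ModelConfig(
            n_chains=1, n_burnin=200, n_samples=6000, seed=40,
            include_spatial=False, include_temporal=False, include_interaction=False,
        )
        post = run_mcmc(panel, g, cfg)
        a = post.stacked("alpha")
        se = np.sqrt(polygamma(1, 7) / a.size)  # draws are iid (exact Gibbs)
        assert a.mean() == pytest.approx(digamma(7), abs=3 * se + 1e-3)

    def test_glm_limit_matches_maximum_likelihood(self):
        # no random effects in truth or model: posterior beta should agree
        # with the frequentist Poisson regression within its standard error
        import statsmodels.api as sm

        g, panel, truth = _glm_panel()
        cfg = ModelConfig(
            n_chains=1, n_burnin=1000, n_samples=2000, seed=41,
            include_spatial=False, include_temporal=False, include_interaction=False,
        )
        post = run_mcmc(panel, g, cfg)
        x = panel.covariates.reshape(-1, 2)
        y = panel.counts.reshape(-1)
        glm = sm.GLM(y, sm.add_constant(x), family=sm.families.Poisson()).fit()
        bmean = post.stacked("beta").mean(axis=0)
        for p in range(2):
            assert abs(bmean[p] - glm.params[p + 1]) < glm.bse[p + 1]

    def test_same_seed_bit_identical(self):
        g, panel, _ = _glm_panel(seed=50, n_rows=3, n_cols=3, t=3)
        cfg = ModelConfig(n_chains=2, n_burnin=100, n_samples=100, seed=51)
        p1 = run_mcmc(panel, g, cfg)
        p2 = run_mcmc(panel, g, cfg)
        np.testing.assert_array_equal(p1.alpha, p2.alpha)
        np.testing.assert_array_equal(p1.beta, p2.beta)
        np.testing.assert_array_equal(p1.delta, p2.delta)

    def test_constraints_hold_in_every_draw(self, fitted_paper):
        assert np.abs(fitted_paper.phi.sum(axis=2)).max() < 1e-8
        assert np.abs(fitted_paper.xi.sum(axis=2)).max() < 1e-8
        assert np.abs(fitted_paper.delta.sum(axis=3)).max() < 1e-8

    def test_variances_strictly_positive(self, fitted_paper):
        for name in ("var_phi", "var_xi", "var_delta"):
            assert getattr(fitted_paper, name).min() > 0

    def test_phi_concentrates_when_truth_has_no_spatial_field(self):
        g, panel, _ = _glm_panel(seed=60, n_rows=4, n_cols=4, t=5, beta=(0.0,))
        cfg = ModelConfig(n_chains=1, n_burnin=800, n_samples=800, seed=61,
                          include_temporal=False, include_interaction=False)
        post = run_mcmc(panel, g, cfg)
        assert np.abs(post.stacked("phi").mean(axis=0)).max() < 0.3
        assert post.stacked("var_phi").mean() < 0.2


class TestBlockUpdates:
    def test_update_latent_block_returns_valid_state(self):
        g, panel, _ = _glm_panel(seed=70, n_rows=2, n_cols=2, t=3, beta=(0.1,))
        cfg = ModelConfig(n_chains=1, n_burnin=10, n_samples=10, seed=71)
        state = {
            "alpha": 2.0, "beta": np.zeros(1), "phi": np.zeros(4),
            "xi": np.zeros(3), "delta": np.zeros((4, 3)),
            "var_phi": 0.5, "var_xi": 0.1, "var_delta": 0.1,
        }
        rng = np.random.default_rng(72)
        for block in ("alpha", "beta", "phi", "xi", "delta"):
            state, acc = update_latent_block(block, state, panel, g, cfg, rng)
            assert 0.0 <= acc <= 1.0
            assert np.all(np.isfinite(state["phi"]))


class TestCompetingFamily:
    def test_variant_lattice_enumerates(self):
        assert set(MODEL_VARIANTS) == {
            "full", "no_interaction", "iid_spatial", "no_spatial", "no_temporal"
        }
        cfg = ModelConfig()
        ni = cfg.replace(**MODEL_VARIANTS["no_interaction"])
        assert not ni.include_interaction and ni.include_spatial
        assert cfg.replace(**MODEL_VARIANTS["iid_spatial"]).spatial_structure == "iid"

    def test_family_fits_named_variants(self):
        g, panel, _ = _glm_panel(seed=80, n_rows=3, n_cols=3, t=3, beta=(0.2,))
        cfg = ModelConfig(n_chains=1, n_burnin=150, n_samples=150, seed=81)
        fits = competing_model_family(panel, g, cfg, ["full", "no_interaction"])
        assert set(fits) == {"full", "no_interaction"}
        assert fits["no_interaction"].config.include_interaction is False

    def test_unknown_variant_rejected(self):
        g, panel, _ = _glm_panel(seed=82, n_rows=2, n_cols=2, t=2, beta=(0.0,))
        with pytest.raises(ValueError, match="unknown variant"):
            competing_model_family(panel, g, ModelConfig(), ["bogus"])


class TestSamplesStore:
    def test_save_load_roundtrip(self, tmp_path):
        g, panel, _ = _glm_panel(seed=90, n_rows=2, n_cols=2, t=2, beta=(0.1,))
        cfg = ModelConfig(n_chains=2, n_burnin=50, n_samples=60, seed=91)
        post = run_mcmc(panel, g, cfg)
        post.save(tmp_path / "s.npz")
        from stcar.model import PosteriorSamples

        back = PosteriorSamples.load(tmp_path / "s.npz")
        np.testing.assert_array_equal(back.alpha, post.alpha)
        np.testing.assert_array_equal(back.delta, post.delta)
        assert back.config == post.config
        assert back.area_ids == post.area_ids
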