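import numpy as np
import pytest

import geotriad as gt
from geotriad.stvc import rw2_penalty_matrix
from geotriad.validation import exact_posterior_mean


def manual_panel(log_y, x, weights, rows, cols):
    """AreaPanel wrapper around explicit log-response and covariates."""
    n, t = log_y.shape
    y = np.exp(log_y)
    population = np.full((n, t), 1000.0)
    land_area = np.ones(n)
    from geotriad.simulate import block_regions

    area_ids = [f"A{i:03d}" for i in range(n)]
    labels = block_regions(rows, cols, 1)
    return gt.AreaPanel(
        area_ids=area_ids,
        region_of={a: labels[i] for i, a in enumerate(area_ids)},
        years=np.arange(2000, 2000 + t),
        beds=gt.beds_from_hrdi(y, population, land_area[:, None]),
        population=population,
        land_area=land_area,
        covariates=x,
        covariate_names=[f"X{j+1}" for j in range(x.shape[2])],
        covariate_group={f"X{j+1}": "socioeconomic" for j in range(x.shape[2])},
    )


class TestBuild:
    def test_structure_matrix_ranks(self, small_panel):
        panel, weights, _ = small_panel
        spec = gt.STVCSpec(chains=1, iterations=10, burn_in=5, thin=1)
        state = gt.build_stvc(panel, weights, spec)
        n, t = panel.n_areas, panel.n_years
        assert np.linalg.matrix_rank(state.laplacian) == n - 1
        assert np.linalg.matrix_rank(state.rw2_penalty) == t - 2
        # RW2 null space holds constants and linear trends
        lin = np.arange(t, dtype=float)
        assert np.allclose(state.rw2_penalty @ lin, 0.0, atol=1e-10)

    def test_zero_response_rejected(self, small_panel):
        panel, weights, _ = small_panel
        beds = panel.beds.copy()
        beds[0, 0] = 0.0
        bad = gt.AreaPanel(
            area_ids=panel.area_ids, region_of=panel.region_of, years=panel.years,
            beds=beds, population=panel.population, land_area=panel.land_area,
            covariates=panel.covariates, covariate_names=panel.covariate_names,
            covariate_group=panel.covariate_group,
        )
        with pytest.raises(ValueError, match="strictly positive"):
            gt.build_stvc(bad, weights, gt.STVCSpec(chains=1, iterations=10, burn_in=5))

    def test_disconnected_graph_rejected(self, small_panel):
        panel, _, _ = small_panel
        n = panel.n_areas
        ring = gt.SpatialWeights(
            n, [{(i + 1) % (n // 2)} if False else set() for i in range(n)]
        )
        with pytest.raises(ValueError, match="connected"):
            gt.build_stvc(panel, ring, gt.STVCSpec(chains=1, iterations=10, burn_in=5))

    def test_covariate_rescaling_leaves_exact_fit_invariant(self):
        # scaling a covariate by c and its prior SDs by 1/c is a pure
        # reparameterization: the exact posterior fit is unchanged
        rows = cols = 3
        t = 6
        rng = np.random.default_rng(0)
        w = gt.make_lattice_weights(rows, cols, "rook")
        x = rng.standard_normal((9, t, 1))
        log_y = 1.5 * x[:, :, 0] + 0.1 * rng.standard_normal((9, t))
        panel = manual_panel(log_y, x, w, rows, cols)
        spec = gt.STVCSpec(chains=1, iterations=10, burn_in=5, standardize=False)
        state_a = gt.build_stvc(panel, w, spec)
        exact_a = exact_posterior_mean(state_a, 0.5, 0.3, 0.2)
        c = 4.0
        panel_b = manual_panel(log_y, c * x, w, rows, cols)
        state_b = gt.build_stvc(panel_b, w, spec)
        exact_b = exact_posterior_mean(state_b, 0.5 / c, 0.3 / c, 0.2)
        fit_a = (exact_a["beta"] + exact_a["mu"][:, None, 0] + exact_a["gamma"][None, :, 0]) * x[:, :, 0]
        fit_b = (exact_b["beta"] + exact_b["mu"][:, None, 0] + exact_b["gamma"][None, :, 0]) * c * x[:, :, 0]
        np.testing.assert_allclose(fit_a, fit_b, atol=1e-8)

    def test_rw2_penalty_is_second_difference_gram(self):
        t = 7
        r = rw2_penalty_matrix(t)
        path = np.random.default_rng(1).standard_normal(t)
        assert path @ r @ path == pytest.approx(np.sum(np.diff(path, n=2) ** 2), rel=1e-12)


class TestFit:
    def test_degenerate_truth_beta_recovery(self):
        # constant coefficient, near-zero noise: beta posterior tight at truth
        rows = cols = 4
        t = 6
        rng = np.random.default_rng(3)
        w = gt.make_lattice_weights(rows, cols, "rook")
        x = np.ones((16, t, 1))
        log_y = 2.0 * x[:, :, 0] + 0.01 * rng.standard_normal((16, t))
        panel = manual_panel(log_y, x, w, rows, cols)
        spec = gt.STVCSpec(chains=2, iterations=800, burn_in=300, thin=1,
                           standardize=False, seed=4)
        post = gt.fit_stvc(gt.build_stvc(panel, w, spec))
        assert 1.95 <= post.stacked("beta")[:, 0].mean() <= 2.05

    def test_noiseless_fixture_interpolates(self):
        cfg = gt.SimulationConfig(
            grid_rows=5, grid_cols=5, n_years=8, n_covariates=1, region_blocks=1,
            sd_mu=0.5, sd_gamma=0.3, beta=1.0, sd_eps=0.0, seed=6,
        )
        panel, w, _ = gt.simulate_panel(cfg)
        spec = gt.STVCSpec(chains=2, iterations=1000, burn_in=400, thin=1, seed=7)
        post = gt.fit_stvc(gt.build_stvc(panel, w, spec))
        rmse = float(np.sqrt((post.residuals**2).mean()))
        assert rmse < 0.01

    def test_determinism(self, small_panel):
        panel, w, _ = small_panel
        spec = gt.STVCSpec(chains=2, iterations=120, burn_in=60, thin=2, seed=11)
        p1 = gt.fit_stvc(gt.build_stvc(panel, w, spec))
        p2 = gt.fit_stvc(gt.build_stvc(panel, w, spec))
        np.testing.assert_array_equal(p1.beta, p2.beta)
        np.testing.assert_array_equal(p1.mu, p2.mu)
        np.testing.assert_array_equal(p1.sd_eps, p2.sd_eps)

    def test_constraints_on_every_draw(self, small_panel):
        panel, w, _ = small_panel
        spec = gt.STVCSpec(chains=2, iterations=300, burn_in=100, thin=1, seed=12)
        post = gt.fit_stvc(gt.build_stvc(panel, w, spec))
        assert np.abs(post.stacked("mu").sum(axis=1)).max() < 1e-8
        assert np.abs(post.stacked("gamma").sum(axis=1)).max() < 1e-8
        assert (post.stacked("sd_mu") > 0).all()
        assert (post.stacked("sd_eps") > 0).all()

    def test_gibbs_matches_exact_posterior_tiny_instance(self):
        # fixed variances make the joint Gaussian; the sampler's posterior
        # mean of beta must match the dense linear-algebra solution
        cfg = gt.SimulationConfig(
            grid_rows=3, grid_cols=3, n_years=5, n_covariates=1, region_blocks=1,
            sd_mu=0.5, sd_gamma=0.3, beta=2.0, sd_eps=0.3, seed=7,
        )
        panel, w, _ = gt.simulate_panel(cfg)
        fixed = {"sd_mu": [0.5], "sd_gamma": [0.3], "sd_eps": 0.3}
        spec = gt.STVCSpec(chains=2, iterations=4000, burn_in=1000, thin=1,
                           seed=2, fix_variances=fixed)
        state = gt.build_stvc(panel, w, spec)
        post = gt.fit_stvc(state)
        exact = exact_posterior_mean(state, 0.5, 0.3, 0.3)
        draws = post.stacked("beta")[:, 0]
        import arviz as az

        ess = float(az.ess(az.convert_to_dataset({"b": post.beta[:, :, 0]}))["b"].values)
        se = draws.std() / np.sqrt(ess)
        assert abs(draws.mean() - exact["beta"][0]) < 3 * se

    def test_permuting_areas_permutes_exact_sc(self):
        rows = cols = 3
        t = 5
        rng = np.random.default_rng(8)
        w = gt.make_lattice_weights(rows, cols, "rook")
        x = rng.standard_normal((9, t, 1))
        log_y = rng.standard_normal((9, t))
        panel = manual_panel(log_y, x, w, rows, cols)
        spec = gt.STVCSpec(chains=1, iterations=10, burn_in=5, standardize=False)
        exact = exact_posterior_mean(gt.build_stvc(panel, w, spec), 0.5, 0.3, 0.2)
        perm = rng.permutation(9)
        inv = np.argsort(perm)
        w_p = gt.SpatialWeights(
            9, [{int(inv[j]) for j in w.neighbor_sets[perm[i]]} for i in range(9)]
        )
        panel_p = manual_panel(log_y[perm], x[perm], w_p, rows, cols)
        exact_p = exact_posterior_mean(gt.build_stvc(panel_p, w_p, spec), 0.5, 0.3, 0.2)
        np.testing.assert_allclose(exact_p["mu"][:, 0], exact["mu"][perm, 0], atol=1e-8)


@pytest.fixture(scope="module")
def posterior(small_panel):
    panel, w, _ = small_panel
    spec = gt.STVCSpec(chains=2, iterations=400, burn_in=200, thin=2, seed=14)
    return gt.fit_stvc(gt.build_stvc(panel, w, spec))


class TestExtract:

    def test_quantile_tables_shapes(self, posterior, small_panel):
        panel, _, _ = small_panel
        sc, tc = gt.extract_sc_tc(posterior)
        assert len(sc) == panel.n_areas * panel.n_covariates
        assert len(tc) == panel.n_years * panel.n_covariates
        assert {"q2.5", "q25", "q50", "q75", "q97.5"} <= set(tc.columns)

    def test_quantiles_ordered(self, posterior):
        sc, tc = gt.extract_sc_tc(posterior)
        for df in (sc, tc):
            assert (df["q25"] <= df["q50"]).all() and (df["q50"] <= df["q75"]).all()
            assert (df["q2.5"] <= df["q25"]).all() and (df["q75"] <= df["q97.5"]).all()

    def test_centered_vs_total_differ_by_beta(self, posterior):
        sc_tot, _ = gt.extract_sc_tc(posterior, centered=False)
        sc_cen, _ = gt.extract_sc_tc(posterior, centered=True)
        beta_med = np.median(posterior.stacked("beta"), axis=0)
        for j, cov in enumerate(posterior.covariate_names):
            tot = sc_tot[sc_tot.covariate == cov]["q50"].to_numpy()
            cen = sc_cen[sc_cen.covariate == cov]["q50"].to_numpy()
            assert np.allclose(tot - cen, beta_med[j], atol=0.1)
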