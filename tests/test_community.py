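import numpy as np
import pandas as pd
import pytest

import treedna as td

from conftest import make_history


def tiny_history():
    """One species, two trees, one roller + one soil event each."""
    return make_history(
        [("sp1", "t1", 1, "roller", 1), ("sp1", "t1", 1, "soil", 0),
         ("sp1", "t2", 1, "roller", 0), ("sp1", "t2", 1, "soil", 0)]
    )


class TestOracle:
    def test_no_data_returns_prior(self):
        hist = make_history(
            [("sp1", "t1", 1, "roller", None), ("sp1", "t1", 1, "soil", None)]
        )
        grid = td.CommunityGrid.from_logit_normal(0.3, 1.0, -0.5, 1.0, 0.8, 1.0, 21)
        res = td.exact_posterior_oracle(hist, grid)
        prior_psi = float(grid.weight @ grid.psi)
        prior_pr = float(grid.weight @ grid.p_roller)
        assert res.summary.loc["sp1", "psi_mean"] == pytest.approx(prior_psi, abs=1e-12)
        assert res.summary.loc["sp1", "p_roller_mean"] == pytest.approx(prior_pr, abs=1e-12)

    def test_all_detections_concentrate_high(self):
        hist = make_history(
            [("sp1", "t1", 1, "roller", 1), ("sp1", "t1", 2, "roller", 1),
             ("sp1", "t2", 1, "roller", 1), ("sp1", "t2", 2, "roller", 1)]
        )
        grid = td.CommunityGrid.product(
            np.linspace(0.05, 0.95, 10), np.linspace(0.05, 0.95, 10),
            np.linspace(0.05, 0.95, 10),
        )
        res = td.exact_posterior_oracle(hist, grid)
        assert res.summary.loc["sp1", "psi_mean"] > grid.weight @ grid.psi
        assert res.summary.loc["sp1", "p_roller_mean"] > 0.6

    def test_hand_computed_likelihood_table(self):
        """1 species, 1 tree, 2 roller events, y = (1, 0): likelihood is
        psi * p_roller * (1 - p_roller); posterior grid weights match the
        pencil-and-paper table."""
        hist = make_history(
            [("sp1", "t1", 1, "roller", 1), ("sp1", "t1", 2, "roller", 0)]
        )
        grid = td.CommunityGrid.product([0.25, 0.75], [0.5], [0.3, 0.6])
        res = td.exact_posterior_oracle(hist, grid)
        # by hand: lik = psi * p (1-p) over (psi, p_roller) combos
        # (.25,.3): .0525  (.25,.6): .06  (.75,.3): .1575  (.75,.6): .18
        expect = np.array([0.0525, 0.06, 0.1575, 0.18])
        expect = expect / expect.sum()
        np.testing.assert_allclose(res.posterior_weights["sp1"], expect, rtol=1e-12)

    def test_tree_relabelling_invariance(self):
        grid = td.CommunityGrid.from_logit_normal(0, 1, 0, 1, 0.5, 1, 15)
        a = td.exact_posterior_oracle(tiny_history(), grid).summary
        swapped = make_history(
            [("sp1", "t2", 1, "roller", 1), ("sp1", "t2", 1, "soil", 0),
             ("sp1", "t1", 1, "roller", 0), ("sp1", "t1", 1, "soil", 0)]
        )
        b = td.exact_posterior_oracle(swapped, grid).summary
        pd.testing.assert_frame_equal(a, b)

    def test_refuses_large_instance(self):
        cfg = td.CommunitySimConfig(n_species=4, n_trees=6, seed=0)
        hist, _ = td.simulate_community(cfg)
        grid = td.CommunityGrid.product([0.5], [0.5], [0.5])
        with pytest.raises(ValueError, match="too large"):
            td.exact_posterior_oracle(hist, grid)


class TestSampler:
    def test_saturated_species_has_high_occupancy(self):
        hist = make_history(
            [("sp1", f"t{i}", v, m, 1) for i in range(15)
             for v in (1, 2) for m in ("roller", "soil")]
        )
        post = td.fit_community_model(
            hist, td.McmcSettings(n_chains=2, n_iter=2000, n_burn=500, thin=1, seed=3),
            fixed_hypers=td.FixedHypers(sd_psi=2.0, sd_alpha=2.0, sd_beta=1.0),
        )
        assert post.psi_draws.mean() > 0.9
        assert post.p_roller_draws.mean() > 0.8

    def test_observed_cells_have_z_one_in_every_draw(self):
        cfg = td.CommunitySimConfig(n_species=4, n_trees=5, seed=1)
        hist, _ = td.simulate_community(cfg)
        post = td.fit_community_model(
            hist, td.McmcSettings(n_chains=2, n_iter=800, n_burn=200, thin=2, seed=5)
        )
        obs = hist.obs[hist.obs["y"] == 1]
        sp_idx = {s: k for k, s in enumerate(post.species)}
        tr_idx = {t: i for i, t in enumerate(post.trees)}
        for row in obs.itertuples(index=False):
            assert (post.z[:, :, sp_idx[row.species], tr_idx[row.tree]] == 1).all()

    def test_never_detected_species_dropped_with_warning(self, caplog):
        import logging
        recs = [("seen", "t1", 1, "roller", 1), ("seen", "t2", 1, "roller", 0),
                ("ghost", "t1", 1, "roller", 0), ("ghost", "t2", 1, "roller", 0)]
        with caplog.at_level(logging.WARNING):
            post = td.fit_community_model(
                make_history(recs),
                td.McmcSettings(n_chains=2, n_iter=400, n_burn=100, thin=1, seed=2),
            )
        assert post.species == ["seen"]
        assert post.dropped_species == ["ghost"]
        assert any("never detected" in r.message for r in caplog.records)

    def test_seed_reproducibility(self):
        hist = tiny_history()
        s = td.McmcSettings(n_chains=2, n_iter=600, n_burn=100, thin=2, seed=9)
        a = td.fit_community_model(hist, s)
        b = td.fit_community_model(hist, s)
        np.testing.assert_array_equal(a.draws["u"], b.draws["u"])
        np.testing.assert_array_equal(a.z, b.z)


class TestMethodEffectSummary:
    def _post_with_beta(self, beta_draws, mu_beta_draws):
        K = beta_draws.shape[-1]
        draws = {
            "u": np.zeros_like(beta_draws), "alpha": np.zeros_like(beta_draws),
            "beta": beta_draws, "mu_beta": mu_beta_draws,
        }
        for n in ("mu_psi", "sd_psi", "mu_alpha", "sd_alpha", "sd_beta"):
            draws[n] = np.zeros_like(mu_beta_draws)
        return td.CommunityPosterior(
            species=[f"s{k}" for k in range(K)], trees=["t"], draws=draws,
            z=np.ones((1, beta_draws.shape[1], K, 1), dtype=np.uint8),
            accept={}, rhat={}, converged=True, settings=td.McmcSettings(seed=0),
        )

    def test_positive_slopes_have_positive_intervals(self):
        rng = np.random.default_rng(0)
        beta = rng.normal(2.0, 0.1, size=(1, 500, 3))
        post = self._post_with_beta(beta, rng.normal(2.0, 0.1, size=(1, 500)))
        summ = td.method_effect_summary(post)
        assert (summ["lo"] > 0).all()

    def test_symmetric_draws_center_near_zero(self):
        rng = np.random.default_rng(1)
        beta = rng.normal(0.0, 1.0, size=(1, 4000, 2))
        post = self._post_with_beta(beta, rng.normal(0.0, 1.0, size=(1, 4000)))
        summ = td.method_effect_summary(post)
        assert abs(summ.loc["community", "mean"]) < 0.06
        assert (summ["lo"] < 0).all() and (summ["hi"] > 0).all()
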