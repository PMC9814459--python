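import numpy as np
import pytest
from hypothesis import given, strategies as st

import treedna as td

from conftest import make_multimethod_history


class TestCumulativeDetection:
    def test_certain_detection(self):
        assert td.cumulative_detection(1.0, 1) == 1.0
        assert td.cumulative_detection(1.0, 50) == 1.0

    def test_closed_form_examples(self):
        assert td.cumulative_detection(0.5, 2) == pytest.approx(0.75)
        # iterative product oracle
        p, prob_miss = 0.15, 1.0
        for _ in range(27):
            prob_miss *= 1 - p
        assert td.cumulative_detection(0.15, 27) == pytest.approx(1 - prob_miss, rel=1e-12)
        assert td.cumulative_detection(0.15, 27) == pytest.approx(0.9876, abs=1e-4)

    def test_identity_and_monotonicity(self):
        for p in np.linspace(0.05, 0.95, 10):
            assert td.cumulative_detection(p, 1) == pytest.approx(p)
            vals = [td.cumulative_detection(p, n) for n in range(1, 10)]
            assert all(b > a for a, b in zip(vals, vals[1:]))
        # limit 1 as n grows
        assert td.cumulative_detection(0.3, 200) == pytest.approx(1.0)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            td.cumulative_detection(1.5, 3)
        with pytest.raises(ValueError):
            td.cumulative_detection(0.5, 0)


class TestVisitsForConfidence:
    @pytest.mark.parametrize(
        "p,target,n",
        [(0.95, 0.95, 1), (0.5, 0.95, 5), (0.21, 0.95, 13), (0.5, 0.75, 2)],
    )
    def test_known_values(self, p, target, n):
        assert td.visits_for_confidence(p, target) == n

    def test_unreachable(self):
        with pytest.raises(ValueError, match="unreachable"):
            td.visits_for_confidence(0.0, 0.95)

    @given(
        st.integers(1, 99).map(lambda k: k / 100),
        st.sampled_from([0.8, 0.9, 0.95]),
    )
    def test_minimality_against_brute_force(self, p, target):
        n = td.visits_for_confidence(p, target)
        brute = next(
            m for m in range(1, 1000) if td.cumulative_detection(p, m) >= target
        )
        assert n == brute
        assert td.cumulative_detection(p, n) >= target
        if n > 1:
            assert td.cumulative_detection(p, n - 1) < target


class TestDetectionRateRatio:
    def _post_with_probs(self, p_q, p_m, n=100):
        d0 = np.log(p_m / (1 - p_m))
        d1 = np.log(p_q / (1 - p_q)) - d0
        draws = {
            "psi": np.full((1, n), 0.5),
            "gamma0": np.zeros((1, n)), "gamma1": np.zeros((1, n)),
            "delta0": np.full((1, n), d0), "delta1": np.full((1, n), d1),
        }
        return td.MultimethodPosterior(
            draws=draws, z=np.ones((1, n, 1), np.uint8),
            a=np.ones((1, n, 1, 1), np.uint8), trees=["t"], accept={},
            rhat={}, converged=True, no_detections=False,
            settings=td.McmcSettings(seed=0),
        )

    def test_fixed_probability_arithmetic(self):
        post = self._post_with_probs(0.49, 0.15)
        ratio = td.detection_rate_ratio(post)
        assert ratio["mean"] == pytest.approx(0.49 / 0.15, rel=1e-9)
        assert ratio["mean"] == pytest.approx(3.2667, abs=1e-4)

    def test_identical_methods_ratio_one(self):
        post = self._post_with_probs(0.3, 0.3)
        assert td.detection_rate_ratio(post)["mean"] == pytest.approx(1.0)

    def test_per_visit_rate_combines_layers(self):
        post = self._post_with_probs(0.49, 0.15)
        rate = post.per_visit_rate_draws("roller", "qpcr")
        assert rate.mean() == pytest.approx(0.5 * 0.49)  # theta = expit(0) = 0.5


class TestSampler:
    def test_saturated_history(self):
        hist = make_multimethod_history(
            [(f"t{i}", v, "roller", 1, 1) for i in range(10) for v in (1, 2)]
        )
        post = td.fit_multimethod_model(
            hist, td.McmcSettings(n_chains=2, n_iter=3000, n_burn=1000, thin=1, seed=1)
        )
        assert post.psi_draws.mean() > 0.9
        assert post.theta_roller_draws.mean() > 0.9
        assert post.p_qpcr_draws.mean() > 0.9
        assert post.p_metabarcoding_draws.mean() > 0.9

    def test_all_zero_history_flagged_and_near_prior(self):
        hist = make_multimethod_history(
            [(t, v, m, 0, 0) for t in ("t1", "t2") for v, m in
             ((1, "roller"), (2, "soil"))]
        )
        post = td.fit_multimethod_model(
            hist, td.McmcSettings(n_chains=2, n_iter=2000, n_burn=500, thin=1, seed=2)
        )
        assert post.no_detections
        # with 4 all-zero samples psi posterior shifts low but stays diffuse
        assert 0.05 < post.psi_draws.mean() < 0.5

    def test_posterior_hierarchy_a_le_z_and_detections_available(self):
        hist, _ = td.simulate_multimethod(td.MultimethodSimConfig(n_trees=15, seed=3))
        post = td.fit_multimethod_model(
            hist, td.McmcSettings(n_chains=2, n_iter=1000, n_burn=300, thin=2, seed=4)
        )
        assert (post.a <= post.z[:, :, :, None]).all()
        # any detected sample must be available in every draw
        obs = hist.observed()
        piv = obs.pivot_table(index=["tree", "visit"], columns="molecular_method",
                              values="y")
        det = piv[(piv > 0).any(axis=1)]
        tr_idx = {t: i for i, t in enumerate(post.trees)}
        for (tree, visit) in det.index:
            assert (post.a[:, :, tr_idx[tree], visit - 1] == 1).all()

    def test_mismatched_method_labels_rejected(self):
        hist = make_multimethod_history([("t1", 1, "roller", 1, 1)])
        hist.obs.loc[hist.obs["molecular_method"] == "qpcr", "y"] = np.nan
        with pytest.raises(ValueError, match="both molecular methods"):
            td.fit_multimethod_model(
                hist, td.McmcSettings(n_chains=2, n_iter=200, n_burn=50, thin=1, seed=1)
            )

    def test_seed_reproducibility(self):
        hist, _ = td.simulate_multimethod(td.MultimethodSimConfig(n_trees=10, seed=6))
        s = td.McmcSettings(n_chains=2, n_iter=500, n_burn=100, thin=1, seed=7)
        a = td.fit_multimethod_model(hist, s)
        b = td.fit_multimethod_model(hist, s)
        np.testing.assert_array_equal(a.draws["delta0"], b.draws["delta0"])
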