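"""Gibbs sampler correctness, scoring, reliability, DIC and the 0-100
transform.  Heavy recovery runs live in the acceptance suite; here the
focus is exactness on small constructions and invariants on a short fit."""

import numpy as np
import pandas as pd
import pytest
from numpy.polynomial.hermite_e import hermegauss
from scipy.special import ndtr

from healthtrait.config import GeneratorConfig
from healthtrait.panel import ItemCatalog, ItemInfo, ResponsePanel
from healthtrait.synthetic import generate_cohort
from healthtrait import irt, item_prep


def _binary_catalog(n_items, n_waves=1):
    return ItemCatalog([
        ItemInfo(name=f"i{k}", n_categories=2, factors=(0,),
                 available=tuple([True] * n_waves))
        for k in range(n_items)
    ])


class TestSpecValidation:
    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            irt.MLIRTSpec(variance_config="M9")
        with pytest.raises(ValueError):
            irt.MLIRTSpec(burn_in=10, n_iter=10)

    def test_single_category_item_rejected(self):
        data = np.zeros((30, 1, 2), dtype=np.int16)
        data[:, 0, 1] = np.arange(30) % 2
        panel = ResponsePanel(data, np.arange(30), ["i0", "i1"])
        with pytest.raises(ValueError, match="< 2 categories"):
            irt.fit_mlirt(panel, _binary_catalog(2), irt.MLIRTSpec(n_iter=10, burn_in=0))


class TestSamplerExactness:
    def test_single_binary_item_threshold_posterior_centred(self):
        # a = 1 fixed, true b = 0, theta pinned at N(0,1) draws: the
        # posterior mean of b must sit near 0
        rng = np.random.default_rng(0)
        n = 2000
        theta = rng.normal(size=n)
        x = (rng.random(n) < ndtr(theta)).astype(np.int16)
        panel = ResponsePanel(x[:, None, None], np.arange(n), ["i0"])
        spec = irt.MLIRTSpec(
            variance_config="M1", n_iter=800, burn_in=200, seed=1,
            fixed_slopes=None, fixed_person_resid_sd=1.0, fixed_wave_effect_sd=0.0,
        )
        post = irt.fit_mlirt(panel, _binary_catalog(1), spec)
        b_mean = post.chains["thresholds"].mean()
        assert abs(b_mean) < 0.1

    def test_eap_matches_gauss_hermite_quadrature(self):
        # two binary items with known parameters; theta ~ N(0,1).
        # Oracle: 61-node Gauss-Hermite quadrature posterior mean per
        # response pattern.
        rng = np.random.default_rng(1)
        n = 600
        a = np.array([1.0, 1.0])
        b = [np.array([0.0]), np.array([0.0])]
        theta = rng.normal(size=n)
        X = (rng.random((n, 2)) < ndtr(a * theta[:, None] - np.array([0.0, 0.0]))).astype(np.int16)
        panel = ResponsePanel(X[:, None, :], np.arange(n), ["i0", "i1"])
        spec = irt.MLIRTSpec(
            variance_config="M1", n_iter=2500, burn_in=300, seed=2,
            fixed_slopes=a, fixed_thresholds=b,
            fixed_person_resid_sd=1.0, fixed_wave_effect_sd=0.0,
        )
        post = irt.fit_mlirt(panel, _binary_catalog(2), spec)
        eap, _ = post.theta_eap()

        nodes, weights = hermegauss(61)  # weight exp(-x^2/2): N(0,1) up to const
        def oracle(pattern):
            like = np.ones_like(nodes)
            for j in range(2):
                p1 = ndtr(a[j] * nodes - b[j][0])
                like *= p1 if pattern[j] == 1 else (1 - p1)
            w = weights * like
            return np.sum(w * nodes) / np.sum(w)

        for pattern in [(0, 0), (0, 1), (1, 0), (1, 1)]:
            mask = (X[:, 0] == pattern[0]) & (X[:, 1] == pattern[1])
            assert mask.any()
            got = eap[mask, 0].mean()
            assert abs(got - oracle(pattern)) < 0.02


class TestFitInvariants:
    def test_mean_slope_is_one_in_every_draw(self, small_recovery_setup):
        _, _, post = small_recovery_setup
        means = post.chains["slopes"].mean(axis=1)
        np.testing.assert_allclose(means, 1.0, atol=1e-10)

    def test_thresholds_ordered_in_every_retained_draw(self, small_recovery_setup):
        cohort, _, post = small_recovery_setup
        sl = post.chains["thresholds_slices"]
        for draw in post.chains["thresholds"]:
            for i in range(len(post.item_names)):
                b = draw[sl[i]: sl[i + 1]]
                if b.size > 1:
                    assert np.all(np.diff(b) > 0)

    def test_chain_reproducible_under_seed(self):
        cfg = GeneratorConfig(n_persons=60, n_items=6, n_waves=3, n_varying_items=1,
                              covariate_effects={}, second_order_loadings=[1.0] * 5,
                              seed=4)
        cohort = generate_cohort(cfg)
        panel, pw = item_prep.filter_personwave_irt(cohort.panel)
        spec = irt.MLIRTSpec(variance_config="M2", n_iter=120, burn_in=20, seed=7,
                             geweke_check=False)
        p1 = irt.fit_mlirt(panel, cohort.catalog, spec, pw_mask=pw)
        p2 = irt.fit_mlirt(panel, cohort.catalog, spec, pw_mask=pw)
        np.testing.assert_array_equal(p1.chains["slopes"], p2.chains["slopes"])
        np.testing.assert_array_equal(p1.chains["theta"], p2.chains["theta"])

    def test_m3_pools_intercept_drift_variance(self):
        cfg = GeneratorConfig(n_persons=80, n_items=6, n_waves=3, n_varying_items=1,
                              covariate_effects={}, second_order_loadings=[1.0] * 5,
                              seed=6)
        cohort = generate_cohort(cfg)
        panel, pw = item_prep.filter_personwave_irt(cohort.panel)
        spec = irt.MLIRTSpec(variance_config="M3", n_iter=150, burn_in=50, seed=2,
                             geweke_check=False)
        post = irt.fit_mlirt(panel, cohort.catalog, spec, pw_mask=pw)
        assert post.chains["sigma_b2"].shape[1] == 1   # one pooled variance
        assert np.all(post.chains["sigma_b2"] > 0)

    def test_anchors_carry_the_link_when_varying_item_dropped(self):
        # deleting a wave-varying item from half the waves moves that wave's
        # mean EAP by less than 0.1 * sigma_theta: anchors hold the scale
        cfg = GeneratorConfig(n_persons=200, n_items=10, n_waves=4,
                              n_varying_items=0, covariate_effects={},
                              wave_effect_sd=0.7, person_resid_sd=0.7,
                              second_order_loadings=[1.0] * 5, seed=13)
        cohort = generate_cohort(cfg)
        spec = irt.MLIRTSpec(variance_config="M1", n_iter=500, burn_in=150, seed=1,
                             geweke_check=False)
        panel, pw = item_prep.filter_personwave_irt(cohort.panel)
        post_full = irt.fit_mlirt(panel, cohort.catalog, spec, pw_mask=pw)
        dropped = cohort.panel.copy()
        dropped.data[:, 2:, 9] = -2  # item 10 becomes wave-varying (absent w3+)
        panel_d, pw_d = item_prep.filter_personwave_irt(dropped)
        post_drop = irt.fit_mlirt(panel_d, cohort.catalog, spec, pw_mask=pw_d)
        eap_f, _ = post_full.theta_eap()
        eap_d, _ = post_drop.theta_eap()
        # the common location is only weakly identified (threshold priors)
        # and is immaterial after the pooled min-max transform, so compare
        # wave means relative to the grand mean
        cf = eap_f - eap_f.mean()
        cd = eap_d - eap_d.mean()
        for w in (2, 3):
            shift = abs(cf[:, w].mean() - cd[:, w].mean())
            assert shift < 0.1 * 0.7

    def test_anchor_free_wave_rejected(self):
        # three waves; in wave 2 the anchor item is entirely unanswered and
        # only a wave-varying item is observed -> the scale cannot be linked
        cat = ItemCatalog([
            ItemInfo(name="anchor", n_categories=2, factors=(0,),
                     available=(True, True, True)),
            ItemInfo(name="vary", n_categories=2, factors=(0,),
                     available=(True, True, False)),
        ])
        rng = np.random.default_rng(0)
        data = rng.integers(0, 2, size=(40, 3, 2)).astype(np.int16)
        data[:, 1, 0] = -1   # anchor responses missing throughout wave 2
        data[:, 2, 1] = -2   # varying item structurally absent in wave 3
        panel = ResponsePanel(data, np.arange(40), cat.names)
        with pytest.raises(ValueError, match="no anchor"):
            irt.fit_mlirt(panel, cat, irt.MLIRTSpec(n_iter=10, burn_in=0))


def _posterior_stub(theta_draws, sigma_u2=None, sigma_th2=None):
    n_draws, n, W = theta_draws.shape
    chains = {
        "theta": theta_draws,
        "deviance": np.zeros(n_draws),
        "sigma_u2": sigma_u2 if sigma_u2 is not None else np.ones(n_draws),
        "sigma_theta2": sigma_th2 if sigma_th2 is not None else np.ones(n_draws),
    }
    return irt.IRTPosterior(
        spec=irt.MLIRTSpec(n_iter=2, burn_in=0), person_ids=np.arange(n),
        pw_mask=np.ones((n, W), dtype=bool), item_names=["i0"],
        n_categories=np.array([2]), chains=chains, acceptance={}, burn_in_used=0,
    )


class TestScoring:
    def test_constant_chain_has_zero_psd_and_unit_reliability(self):
        theta = np.tile(np.linspace(-1, 1, 8)[None, :, None], (5, 1, 2))
        post = _posterior_stub(theta.transpose(0, 1, 2))
        scores = irt.eap_scores(post)
        assert np.all(scores["theta_psd"] < 1e-12)
        assert irt.eap_reliability(post) == pytest.approx(1.0)

    def test_pure_noise_chain_has_near_zero_reliability(self):
        rng = np.random.default_rng(3)
        theta = rng.normal(size=(400, 30, 2))
        post = _posterior_stub(theta)
        assert irt.eap_reliability(post) < 0.1

    def test_wave_icc_zero_when_no_wave_variance(self):
        theta = np.zeros((50, 4, 2))
        post = _posterior_stub(theta, sigma_u2=np.zeros(50))
        icc, (lo, hi) = irt.wave_icc(post)
        assert icc == 0.0 and lo <= icc <= hi

    def test_health_score_endpoints_and_reversal(self):
        eap = pd.DataFrame({
            "person_id": [0, 1, 2], "wave": [1, 1, 1],
            "theta_eap": [-2.0, 0.0, 3.0], "theta_psd": [0.1, 0.1, 0.1],
        })
        scores, tr = irt.to_health_score(eap)
        assert scores["score"].iloc[0] == 100.0  # least ill-health -> best
        assert scores["score"].iloc[2] == 0.0
        assert scores["score"].is_monotonic_decreasing

    def test_stored_transform_clamps_out_of_range(self):
        tr = irt.HealthScoreTransform(theta_min=-1.0, theta_max=1.0)
        with pytest.warns(UserWarning, match="clamped"):
            s = tr.apply(np.array([-3.0, 2.0]))
        assert s[0] == 100.0 and s[1] == 0.0

    def test_degenerate_range_rejected(self):
        eap = pd.DataFrame({"person_id": [0, 1], "wave": [1, 1],
                            "theta_eap": [0.5, 0.5], "theta_psd": [0.1, 0.1]})
        with pytest.raises(ValueError, match="degenerate"):
            irt.to_health_score(eap)

    def test_sumscore_correlation_is_one_for_affine_score(self):
        rng = np.random.default_rng(5)
        data = rng.integers(0, 3, size=(100, 1, 8)).astype(np.int16)
        panel = ResponsePanel(data, np.arange(100), [f"i{k}" for k in range(8)])
        mean_resp = data[:, 0, :].mean(axis=1)
        scores = pd.DataFrame({"person_id": np.arange(100), "wave": 1,
                               "score": 100 - 10 * mean_resp})
        assert irt.sumscore_correlation(scores, panel) == pytest.approx(1.0)

    def test_sumscore_correlation_near_zero_for_noise(self):
        rng = np.random.default_rng(6)
        data = rng.integers(0, 3, size=(2000, 1, 8)).astype(np.int16)
        panel = ResponsePanel(data, np.arange(2000), [f"i{k}" for k in range(8)])
        scores = pd.DataFrame({"person_id": np.arange(2000), "wave": 1,
                               "score": rng.normal(size=2000)})
        assert irt.sumscore_correlation(scores, panel) < 0.08


class TestDicAndComparison:
    def test_single_draw_chain_has_zero_pd(self):
        cfg = GeneratorConfig(n_persons=50, n_items=5, n_waves=2, n_varying_items=0,
                              covariate_effects={}, second_order_loadings=[1.0] * 5,
                              seed=8)
        cohort = generate_cohort(cfg)
        panel, pw = item_prep.filter_personwave_irt(cohort.panel)
        spec = irt.MLIRTSpec(variance_config="M1", n_iter=51, burn_in=50, seed=1,
                             geweke_check=False)
        post = irt.fit_mlirt(panel, cohort.catalog, spec, pw_mask=pw)
        assert post.n_draws == 1
        dic_val, pd_eff, dbar = irt.dic(post, panel, cohort.catalog)
        assert pd_eff == pytest.approx(0.0, abs=1e-6)
        assert dic_val == pytest.approx(dbar, abs=1e-6)

    def test_compare_models_single_and_tie_rules(self):
        assert irt.compare_models({"M1": (0.9, 100.0)})["selected"] == "M1"
        rep = irt.compare_models({"A": (0.95, 200.0), "B": (0.90, 100.0)})
        assert rep["selected"] == "B"          # DIC wins on disagreement
        assert not rep["criteria_agree"]
        rep2 = irt.compare_models({"A": (0.9, 100.0), "B": (0.9, 90.0)})
        assert rep2["selected"] == "B"
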