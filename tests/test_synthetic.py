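"""Generator tests: catalog construction, latent model, response model,
missingness, outcomes and reproducibility."""

import numpy as np
import pytest
from scipy.special import ndtr, ndtri

from healthtrait.config import GeneratorConfig
from healthtrait.panel import MISSING, UNAVAILABLE, ResponsePanel
from healthtrait import synthetic as syn
from healthtrait.synthetic import (
    apply_missingness,
    build_item_catalog,
    generate_cohort,
    sample_covariates,
    sample_item_responses,
    sample_latent_health,
    sample_outcomes,
    sample_true_parameters,
)


class TestCatalog:
    def test_default_design_has_39_anchor_and_6_varying(self):
        cat = build_item_catalog(GeneratorConfig())
        assert len(cat) == 45
        assert cat.anchor_indices().size == 39
        assert cat.varying_indices().size == 6
        # varying items are fielded at baseline but absent somewhere later
        for i in cat.varying_indices():
            assert cat[i].available[0]
            assert not all(cat[i].available[1:])

    def test_zero_varying_items_yields_full_availability(self):
        cat = build_item_catalog(GeneratorConfig(n_varying_items=0))
        assert all(it.is_anchor for it in cat)

    def test_round_robin_assignment_balances_factors(self):
        cat = build_item_catalog(
            GeneratorConfig(n_items=10, n_varying_items=2, n_cross_loading_items=0)
        )
        counts = np.bincount([it.factors[0] for it in cat], minlength=5)
        assert list(counts) == [2, 2, 2, 2, 2]

    def test_too_many_varying_items_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n_items=5, n_varying_items=5)


class TestLatentHealth:
    def test_degenerate_config_gives_iid_residuals(self):
        cfg = GeneratorConfig(n_persons=20000, n_waves=5, wave_effect_sd=0.0,
                              covariate_effects={}, person_resid_sd=0.7, seed=1)
        cov = sample_covariates(cfg, seed=1)
        tp = sample_true_parameters(cfg, build_item_catalog(cfg), seed=1)
        lat = sample_latent_health(cfg, cov, tp, seed=2)
        n = lat.theta.size
        mc_se = 0.49 * np.sqrt(2.0 / n)
        assert abs(lat.theta.var() - 0.49) < 3 * mc_se

    def test_wave_icc_near_half_with_equal_variances(self):
        # Monte-Carlo oracle: with sigma_u = sigma_theta the wave-level share
        # of variance is 1/2; 200 waves make the empirical ratio stable.
        cfg = GeneratorConfig(n_persons=400, n_waves=200, wave_effect_sd=1.0,
                              person_resid_sd=1.0, covariate_effects={}, seed=3)
        cov = sample_covariates(cfg, seed=3)
        tp = sample_true_parameters(cfg, build_item_catalog(cfg), seed=3)
        lat = sample_latent_health(cfg, cov, tp, seed=4)
        wave_means = lat.theta.mean(axis=0)
        icc = wave_means.var() / lat.theta.var()
        assert abs(icc - 0.5) < 0.12

    def test_same_seed_reproduces_latent_table(self):
        cfg = GeneratorConfig(n_persons=50, seed=9)
        cov = sample_covariates(cfg, seed=9)
        tp = sample_true_parameters(cfg, build_item_catalog(cfg), seed=9)
        a = sample_latent_health(cfg, cov, tp, seed=5).theta
        b = sample_latent_health(cfg, cov, tp, seed=5).theta
        np.testing.assert_array_equal(a, b)

    def test_theta_variance_matches_components(self):
        # wave effect disabled so the expected variance has no noisy
        # few-draws component; covariate variance enters analytically
        cfg = GeneratorConfig(n_persons=20000, n_waves=5, wave_effect_sd=0.0, seed=2)
        cov = sample_covariates(cfg, seed=2)
        tp = sample_true_parameters(cfg, build_item_catalog(cfg), seed=2)
        lat = sample_latent_health(cfg, cov, tp, seed=6)
        var_cov = 0.0
        for name, eff in cfg.covariate_effects.items():
            p = np.asarray(cfg.covariate_levels[name], dtype=float)
            lv = np.arange(p.size)
            var_cov += eff**2 * (np.sum(p * lv**2) - np.sum(p * lv) ** 2)
        expected = cfg.person_resid_sd**2 + var_cov
        assert abs(lat.theta.var() / expected - 1) < 0.03


class TestResponses:
    def _setup(self, n=20000, k=2, a=1.0, b=(0.0,), seed=0):
        cfg = GeneratorConfig(n_persons=n, n_waves=2, n_items=1, n_varying_items=0,
                              categories_per_item=[k], n_cross_loading_items=0,
                              covariate_effects={}, wave_effect_sd=0.0,
                              person_resid_sd=1.0, second_order_loadings=[1.0] * 5,
                              seed=seed)
        cat = build_item_catalog(cfg)
        tp = sample_true_parameters(cfg, cat, seed=seed)
        tp.slopes = np.array([a])
        tp.thresholds = [np.asarray(b, dtype=float)]
        tp.slope_offsets[:] = 0.0
        tp.threshold_offsets[:] = 0.0
        cov = sample_covariates(cfg, seed=seed)
        lat = sample_latent_health(cfg, cov, tp, seed=seed + 1)
        return cfg, cat, tp, lat

    def test_zero_slope_marginals_follow_threshold_gaussian(self):
        cfg, cat, tp, lat = self._setup(k=3, a=0.0, b=(-0.5, 0.8), seed=1)
        panel = sample_item_responses(lat, cat, tp, seed=2)
        x = panel.data[:, 0, 0]
        # survivor construction: P(X >= k) ~= Phi(-b_k) for a ~= 0
        surv = np.concatenate([[1.0], ndtr(-np.array([-0.5, 0.8])), [0.0]])
        expected = -np.diff(surv)
        props = np.bincount(x, minlength=3) / x.size
        assert np.allclose(props, expected, atol=0.015)

    def test_binary_marginal_matches_closed_form(self):
        # integral of Phi(theta - b) d Phi(theta) = Phi(-b / sqrt(2))
        for b, expected in [(0.0, 0.5), (1.0, ndtr(-1 / np.sqrt(2)))]:
            cfg, cat, tp, lat = self._setup(k=2, a=1.0, b=(b,), seed=3)
            panel = sample_item_responses(lat, cat, tp, seed=4)
            x = panel.data[:, 0, 0]
            assert abs(x.mean() - expected) < 3 * np.sqrt(expected * (1 - expected) / x.size)

    def test_nonmonotone_thresholds_rejected(self):
        cfg, cat, tp, lat = self._setup(n=50, k=3, b=(0.5, -0.5), seed=5)
        with pytest.raises(ValueError, match="strictly increasing"):
            sample_item_responses(lat, cat, tp, seed=1)


class TestMissingness:
    def test_rate_zero_leaves_panel_unchanged(self, default_cohort):
        panel = sample_item_responses(
            syn.LatentState(default_cohort.true_params.theta,
                            default_cohort.true_params.factor_scores,
                            default_cohort.true_params.wave_effects),
            default_cohort.catalog, default_cohort.true_params, seed=1)
        out = apply_missingness(panel, default_cohort.catalog, 0.0, seed=2)
        np.testing.assert_array_equal(out.data, panel.data)

    def test_empirical_rate_within_binomial_error(self):
        cfg = GeneratorConfig(n_persons=400, n_items=45, mcar_rate=0.1, seed=8)
        cat = build_item_catalog(cfg, seed=8)
        rng = np.random.default_rng(0)
        data = rng.integers(0, 2, size=(400, 6, 45)).astype(np.int16)
        panel = ResponsePanel(data, np.arange(400), cat.names)
        out = apply_missingness(panel, cat, 0.1, seed=9, baseline_cap=None)
        frac = (out.data == MISSING).mean()
        n_cells = out.data.size
        assert abs(frac - 0.1) < 3 * np.sqrt(0.1 * 0.9 / n_cells)

    def test_structural_cells_stay_unavailable(self, default_cohort):
        data = default_cohort.panel.data
        avail = default_cohort.catalog.availability_matrix()
        for i in default_cohort.catalog.varying_indices():
            for w in range(default_cohort.panel.n_waves):
                if not avail[i, w]:
                    assert np.all(data[:, w, i] == UNAVAILABLE)

    def test_baseline_cap_enforced(self, default_cohort):
        base = default_cohort.panel.wave(1)
        administered = (base != UNAVAILABLE).sum(axis=1)
        miss = (base == MISSING).sum(axis=1)
        assert np.all(miss / administered < 0.25)


class TestOutcomes:
    @staticmethod
    def _auc(theta, y):
        from scipy.stats import rankdata
        r = rankdata(theta)
        m = y == 1
        return (r[m].sum() - m.sum() * (m.sum() + 1) / 2) / (m.sum() * (y.size - m.sum()))

    def _latent(self, n, seed=0):
        cfg = GeneratorConfig(n_persons=n, covariate_effects={}, seed=seed)
        theta = np.random.default_rng(seed).normal(0, 1.0, size=(n, 6))
        lat = syn.LatentState(theta, np.zeros((n, 6, 5)), np.zeros(6))
        return cfg, lat

    def test_null_slope_gives_chance_auc(self):
        cfg, lat = self._latent(20000, seed=1)
        cfg.mortality_slope = 0.0
        out = sample_outcomes(lat, cfg, seed=2)
        assert abs(self._auc(lat.theta[:, 0], out["mortality"].to_numpy()) - 0.5) < 0.02

    def test_large_slope_approaches_perfect_separation(self):
        cfg, lat = self._latent(5000, seed=2)
        cfg.mortality_slope = 20.0
        out = sample_outcomes(lat, cfg, seed=3)
        assert self._auc(lat.theta[:, 0], out["mortality"].to_numpy()) > 0.97

    def test_auc_matches_numeric_integration_oracle(self):
        # oracle: P(case) = Phi(a0 + a1 * z); AUC = P(theta_case > theta_ctrl)
        # computed by quadrature over the two conditional densities
        cfg, lat = self._latent(150000, seed=4)
        a1 = cfg.mortality_slope
        a0 = ndtri(cfg.mortality_base_rate)
        z = np.linspace(-6, 6, 4001)
        from scipy.stats import norm
        w = norm.pdf(z) * (z[1] - z[0])
        pcase = ndtr(a0 + a1 * z)
        f1 = w * pcase
        f0 = w * (1 - pcase)
        F0 = np.cumsum(f0)
        auc_oracle = np.sum(f1 * (F0 - 0.5 * f0)) / (f1.sum() * f0.sum())
        # generator centres theta before applying the probit; theta here is
        # already centred so the comparison is direct
        out = sample_outcomes(lat, cfg, seed=5)
        auc_emp = self._auc(lat.theta[:, 0], out["mortality"].to_numpy())
        assert abs(auc_emp - auc_oracle) < 0.01


class TestCohort:
    def test_row_counts_and_id_consistency(self, default_cohort):
        c = default_cohort
        assert c.panel.data.shape == (300, 6, 45)
        assert len(c.covariates) == 300
        assert len(c.outcomes) == 300
        np.testing.assert_array_equal(c.covariates["person_id"], c.panel.person_ids)

    def test_same_seed_reproduces_cohort(self):
        cfg = GeneratorConfig(n_persons=40, seed=17)
        a = generate_cohort(cfg)
        b = generate_cohort(GeneratorConfig(n_persons=40, seed=17))
        np.testing.assert_array_equal(a.panel.data, b.panel.data)
        assert a.outcomes.equals(b.outcomes)
        assert a.covariates.equals(b.covariates)
        np.testing.assert_array_equal(a.true_params.slopes, b.true_params.slopes)

    def test_roundtrip_through_disk(self, tmp_path):
        cfg = GeneratorConfig(n_persons=25, seed=3)
        cohort = generate_cohort(cfg)
        cohort.save(tmp_path)
        cfg2 = GeneratorConfig.from_yaml(tmp_path / "config.yaml")
        cohort2 = generate_cohort(cfg2)
        np.testing.assert_array_equal(cohort.panel.data, cohort2.panel.data)

    def test_category_probabilities_sum_to_one(self, default_cohort):
        # survivor-function construction: P(X>=0)=1 minus telescoping terms
        tp = default_cohort.true_params
        theta = 0.3
        for i in [0, 7, 23]:
            b = tp.thresholds[i]
            surv = np.concatenate([[1.0], ndtr(tp.slopes[i] * theta - b), [0.0]])
            probs = -np.diff(surv)
            assert abs(probs.sum() - 1) < 1e-12
            assert np.all(probs >= 0)
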