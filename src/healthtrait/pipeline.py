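"""End-to-end orchestration: simulate -> prep -> factor screen -> IRT ->
scoring -> determinants -> patterns.

Every stage writes plain CSV/JSON artifacts into the output directory so
any stage can be re-run or inspected standalone; a manifest records the
configuration, seeds and stage timings.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from healthtrait import determinants as det
from healthtrait import factor_structure as fs
from healthtrait import irt
from healthtrait import item_prep as prep
from healthtrait import patterns as pat
from healthtrait.config import GeneratorConfig
from healthtrait.synthetic import generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    seed: int = 0
    split_fraction: float = 0.7
    fa_missing_threshold: float = 0.25
    irt_missing_threshold: float = 0.5
    loading_cutoff: float = 0.25
    irt_models: tuple[str, ...] = ("M1", "M4")
    irt_n_iter: int = 1500
    irt_burn_in: int = 300
    run_factor_stage: bool = True
    run_determinants_stage: bool = True
    run_patterns_stage: bool = True
    patterns_n_trees: int = 100
    patterns_min_accuracy: float = 0.40
    forest_n_trees: int = 100


def _baseline_frame(cohort) -> pd.DataFrame:
    """Baseline-wave responses as an (n, p) float frame with NaN missing."""
    base = cohort.panel.wave(1).astype(float)
    base[base < 0] = np.nan
    return pd.DataFrame(base, columns=cohort.catalog.names)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run all enabled stages; returns the summary dict (also written)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    timings: dict = {}
    t0 = time.time()

    # --- simulate ----------------------------------------------------------
    cohort = generate_cohort(config.generator)
    cohort.save(out / "cohort")
    timings["simulate"] = time.time() - t0

    # --- prep --------------------------------------------------------------
    t = time.time()
    filtered, fa_report = prep.filter_participants_fa(
        cohort.panel, threshold=config.fa_missing_threshold
    )
    anchors, varying = prep.classify_items(cohort.catalog)
    dev_ids, val_ids = prep.split_sample(
        filtered.person_ids,
        frac=config.split_fraction,
        stratify=cohort.covariates.set_index("person_id").loc[filtered.person_ids, "gender"].to_numpy()
        if "gender" in cohort.covariates else None,
        seed=config.seed,
    )
    summary["prep"] = {
        "fa_filter": {k: v for k, v in fa_report.items() if k != "excluded_person_ids"},
        "n_anchor_items": len(anchors),
        "n_varying_items": len(varying),
        "n_development": int(dev_ids.size),
        "n_validation": int(val_ids.size),
    }
    timings["prep"] = time.time() - t

    # --- factor screen ------------------------------------------------------
    if config.run_factor_stage:
        t = time.time()
        base = _baseline_frame(cohort)
        base = base.loc[np.isin(cohort.panel.person_ids, filtered.person_ids)]
        dev_mask = np.isin(filtered.person_ids, dev_ids)
        poly_dev = fs.polychoric_matrix(base.iloc[dev_mask].to_numpy(),
                                        item_names=list(base.columns))
        n_fac, curve = fs.map_test(poly_dev.rho)
        n_fac = max(n_fac, 1)
        unrotated = fs.efa(poly_dev.rho, n_fac)
        rotated = fs.rotate_geomin(unrotated, seed=config.seed) if n_fac > 1 else \
            fs.rotate_geomin(unrotated)
        structure, unassigned = fs.assign_items(rotated.loadings, cutoff=config.loading_cutoff)
        structure = {f: v for f, v in structure.items() if len(v) >= 2}
        poly_val = fs.polychoric_matrix(base.iloc[~dev_mask].to_numpy(),
                                        item_names=list(base.columns))
        cfa_est, fit = fs.cfa_second_order(poly_val.rho, structure, N=int((~dev_mask).sum()))
        ev = fs.explained_variance(poly_dev.rho, n_fac)
        summary["factor"] = {
            "map_n_factors": int(n_fac),
            "explained_variance_total": float(ev.sum()),
            "explained_variance_first": float(ev[0]),
            "n_unassigned_items": len(unassigned),
            "second_order_loadings": [float(g) for g in cfa_est.second_order],
            "fit": {"chi2": fit.chi2, "df": fit.df, "cfi": fit.cfi,
                    "tli": fit.tli, "rmsea": fit.rmsea, "rmsea_ci": list(fit.rmsea_ci)},
        }
        pd.DataFrame(rotated.loadings, index=base.columns).to_csv(out / "efa_loadings.csv")
        timings["factor"] = time.time() - t

    # --- IRT calibration and scoring ----------------------------------------
    t = time.time()
    panel_irt, pw_mask = prep.filter_personwave_irt(
        cohort.panel, threshold=config.irt_missing_threshold
    )
    fits = {}
    results = {}
    for model in config.irt_models:
        spec = irt.MLIRTSpec(
            variance_config=model,
            n_iter=config.irt_n_iter,
            burn_in=config.irt_burn_in,
            seed=config.seed,
        )
        post = irt.fit_mlirt(panel_irt, cohort.catalog, spec, pw_mask=pw_mask)
        rel = irt.eap_reliability(post)
        dic_val, pd_eff, dbar = irt.dic(post, panel_irt, cohort.catalog)
        fits[model] = (rel, dic_val)
        results[model] = post
    report = irt.compare_models(fits)
    selected = report["selected"]
    post = results[selected]
    eap = irt.eap_scores(post)
    scores, transform = irt.to_health_score(eap)
    icc, icc_ci = irt.wave_icc(post)
    abs_r = irt.sumscore_correlation(scores, panel_irt)
    summary["irt"] = {
        "comparison": report,
        "selected": selected,
        "wave_icc": icc,
        "wave_icc_ci": list(icc_ci),
        "sumscore_abs_r": abs_r,
        "transform": {"theta_min": transform.theta_min, "theta_max": transform.theta_max},
    }
    scores.to_csv(out / "health_scores.csv", index=False)
    timings["irt"] = time.time() - t

    # --- determinants --------------------------------------------------------
    cov = cohort.covariates.set_index("person_id")
    merged = scores.merge(cohort.covariates, on="person_id")
    if config.run_determinants_stage:
        t = time.time()
        cov_cols = [c for c in cohort.covariates.columns if c != "person_id"]
        X = np.column_stack([np.ones(len(merged))] +
                            [merged[c].to_numpy(dtype=float) for c in cov_cols])
        names = ["intercept"] + cov_cols
        y = merged["score"].to_numpy()
        lmm = det.fit_lmm(y, X, merged["person_id"].to_numpy(), merged["wave"].to_numpy(),
                          column_names=names)
        ols = det.fit_ols(y, X)
        chi2, dfree, p = det.lrt_vs_linear(lmm, ols)
        null_lmm = det.fit_lmm(y, X[:, :1], merged["person_id"].to_numpy(),
                               merged["wave"].to_numpy(), column_names=["intercept"])
        cicc = det.conditional_icc(lmm)
        r2 = det.mcfadden_adjusted(lmm, null_lmm)

        base_scores = scores[scores["wave"] == 1].merge(cohort.outcomes, on="person_id")
        base_scores = base_scores.merge(cohort.covariates[["person_id", "gender"]], on="person_id")
        cond_cols = [c for c in cohort.outcomes.columns if c.startswith("condition_")]
        counts = det.chronic_count(base_scores[cond_cols])
        auc_score = det.auc_gender_adjusted(base_scores["score"], base_scores["mortality"],
                                            base_scores["gender"])
        auc_count = det.auc_gender_adjusted(-counts.astype(float), base_scores["mortality"],
                                            base_scores["gender"])
        delta, z, p_cmp = det.compare_auc(base_scores["score"], counts,
                                          base_scores["mortality"],
                                          gender=base_scores["gender"], orient_b=False)
        summary["determinants"] = {
            "lmm": {
                "coefficients": dict(zip(names, lmm.beta.tolist())),
                "sd_person": lmm.sd_person, "sd_wave": lmm.sd_wave, "sd_resid": lmm.sd_resid,
                "aic": lmm.aic,
            },
            "lrt_chi2": chi2, "lrt_p": p,
            "conditional_icc": cicc,
            "mcfadden_adjusted": r2,
            "auc_health_score": auc_score.auc, "auc_health_score_ci": list(auc_score.ci),
            "auc_chronic_count": auc_count.auc, "auc_chronic_count_ci": list(auc_count.ci),
            "auc_comparison": {"delta": delta, "z": z, "p": p_cmp},
        }
        timings["determinants"] = time.time() - t

    # --- pattern mining -------------------------------------------------------
    if config.run_patterns_stage:
        t = time.time()
        cov_cols = [c for c in cohort.covariates.columns if c != "person_id"]
        Xp = merged[cov_cols].to_numpy(dtype=float)
        yp = pat.bin_health(merged["score"].to_numpy())
        forest = pat.bagged_forest(Xp, yp, n_trees=config.forest_n_trees,
                                   seed=config.seed, max_depth=6, min_leaf=10,
                                   feature_names=cov_cols)
        mda = pat.mda_importance(forest, Xp, yp, n_perm=5, seed=config.seed)
        cv = pat.cv_accuracy(
            lambda Xt, yt: pat.bagged_forest(Xt, yt, n_trees=max(config.forest_n_trees // 2, 20),
                                             seed=config.seed, max_depth=6, min_leaf=10),
            Xp, yp, k=10, seed=config.seed,
        )
        rules = pat.extract_patterns(Xp, yp, cov_cols, n_trees=config.patterns_n_trees,
                                     min_accuracy=config.patterns_min_accuracy,
                                     seed=config.seed)
        top, occurrence = pat.top_patterns(rules)
        summary["patterns"] = {
            "cv_accuracy": cv,
            "oob_accuracy": forest.oob_accuracy(Xp, yp),
            "mda": mda,
            "n_rules": len(rules),
            "n_selected": len(top),
            "factor_occurrence": occurrence,
            "top_patterns": [r.describe() for r in top],
        }
        timings["patterns"] = time.time() - t

    manifest = {
        "pipeline_config": {
            **{k: v for k, v in asdict(config).items() if k != "generator"},
            "generator": asdict(config.generator),
        },
        "timings_s": {k: round(v, 2) for k, v in timings.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
    return summary
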