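"""Seeded synthetic cohorts with known ground truth.

The generator mirrors the statistical structure the analysis pipeline
assumes: ordinal items load on a handful of correlated first-order factors
under one general ill-health factor; the general factor varies by wave
(random wave effect ``u_w``) and person-wave residual; item parameters may
drift across waves; covariates shift latent ill-health linearly; binary
outcomes (mortality, institutionalisation, chronic conditions) are probit
functions of baseline ill-health.  All ground truth is retained so
recovery tests can compare estimates against it.

Latent ill-health for person ``p`` in wave ``w``::

    theta_pw = u_w + sum_c gamma_c * x_cp + e_pw
    u_w ~ N(0, sigma_u^2),  e_pw ~ N(0, sigma_theta^2)

Responses follow the graded normal-ogive model::

    P(X_pwi >= k) = Phi(a_iw * F_pw,f(i) - b_iwk),   k = 1..K_i-1

where ``F`` is the first-order factor score of the item's factor,
correlated ``gamma_f`` with the general factor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from healthtrait.config import GeneratorConfig
from healthtrait.panel import MISSING, UNAVAILABLE, ItemCatalog, ItemInfo, ResponsePanel

__all__ = [
    "TrueParameters",
    "LatentState",
    "SyntheticCohort",
    "build_item_catalog",
    "sample_covariates",
    "sample_true_parameters",
    "sample_latent_health",
    "sample_item_responses",
    "apply_missingness",
    "sample_outcomes",
    "generate_cohort",
]


@dataclass
class TrueParameters:
    """Ground-truth parameters of a generated cohort."""

    slopes: np.ndarray                  # a_i, (n_items,), mean 1 after normalisation
    thresholds: list[np.ndarray]        # b_ik per item, strictly increasing
    slope_offsets: np.ndarray           # (n_items, n_waves), wave 1 column is 0
    threshold_offsets: np.ndarray       # d_iw, (n_items, n_waves), wave 1 column is 0
    second_order_loadings: np.ndarray   # gamma_f, (n_factors,)
    covariate_effects: dict[str, float]
    wave_effects: np.ndarray            # u_w, (n_waves,)
    theta: np.ndarray                   # (n_persons, n_waves) general ill-health
    factor_scores: np.ndarray           # (n_persons, n_waves, n_factors)

    def wave_slopes(self) -> np.ndarray:
        """Effective a_iw, (n_items, n_waves)."""
        return np.maximum(self.slopes[:, None] + self.slope_offsets, 0.05)

    def wave_thresholds(self, item: int, wave: int) -> np.ndarray:
        """Effective b_iwk for 0-based ``wave``."""
        return self.thresholds[item] + self.threshold_offsets[item, wave]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "slopes": self.slopes.tolist(),
            "thresholds": [b.tolist() for b in self.thresholds],
            "slope_offsets": self.slope_offsets.tolist(),
            "threshold_offsets": self.threshold_offsets.tolist(),
            "second_order_loadings": self.second_order_loadings.tolist(),
            "covariate_effects": self.covariate_effects,
            "wave_effects": self.wave_effects.tolist(),
            "theta": self.theta.tolist(),
            "factor_scores": self.factor_scores.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrueParameters":
        d = json.loads(Path(path).read_text())
        return cls(
            slopes=np.array(d["slopes"]),
            thresholds=[np.array(b) for b in d["thresholds"]],
            slope_offsets=np.array(d["slope_offsets"]),
            threshold_offsets=np.array(d["threshold_offsets"]),
            second_order_loadings=np.array(d["second_order_loadings"]),
            covariate_effects=d["covariate_effects"],
            wave_effects=np.array(d["wave_effects"]),
            theta=np.array(d["theta"]),
            factor_scores=np.array(d["factor_scores"]),
        )


@dataclass
class LatentState:
    """Latent draws shared by the response and outcome samplers."""

    theta: np.ndarray          # (n_persons, n_waves)
    factor_scores: np.ndarray  # (n_persons, n_waves, n_factors)
    wave_effects: np.ndarray   # (n_waves,)


@dataclass
class SyntheticCohort:
    panel: ResponsePanel
    catalog: ItemCatalog
    covariates: pd.DataFrame
    outcomes: pd.DataFrame
    true_params: TrueParameters
    config: GeneratorConfig

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.panel.to_csv(out / "responses.csv")
        self.catalog.to_json(out / "catalog.json")
        self.covariates.to_csv(out / "covariates.csv", index=False)
        self.outcomes.to_csv(out / "outcomes.csv", index=False)
        self.true_params.to_json(out / "true_params.json")
        self.config.to_yaml(out / "config.yaml")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def build_item_catalog(config: GeneratorConfig, seed=None) -> ItemCatalog:
    """Item metadata: categories, round-robin factor assignment, availability.

    Wave-varying items are fielded at baseline but skipped in at least one
    later wave; all other items are anchors available everywhere.  A small
    number of items is assigned to two factors, mirroring cross-loadings.
    """
    rng = _rng(config.seed if seed is None else seed)
    cats = config.resolved_categories()
    varying = set(config.resolved_varying())
    m = config.n_first_order_factors
    items = []
    for i in range(config.n_items):
        factors = (i % m,)
        if i < config.n_cross_loading_items:
            factors = (i % m, (i + 1) % m)
        if i in varying:
            # available at baseline; each later wave kept with prob 0.5,
            # at least one later wave forced absent
            later = rng.random(config.n_waves - 1) < 0.5
            if later.all():
                later[rng.integers(config.n_waves - 1)] = False
            available = (True, *map(bool, later))
        else:
            available = tuple([True] * config.n_waves)
        items.append(
            ItemInfo(
                name=f"item_{i:02d}",
                n_categories=cats[i],
                factors=factors,
                available=available,
            )
        )
    return ItemCatalog(items)


def sample_covariates(config: GeneratorConfig, seed=None) -> pd.DataFrame:
    """Person-level ordinal covariates with independent multinomial marginals."""
    rng = _rng(config.seed if seed is None else seed)
    n = config.n_persons
    cols = {"person_id": np.arange(n)}
    for name, probs in config.covariate_levels.items():
        p = np.asarray(probs, dtype=float)
        p = p / p.sum()
        cols[name] = rng.choice(len(p), size=n, p=p)
    return pd.DataFrame(cols)


def sample_true_parameters(config: GeneratorConfig, catalog: ItemCatalog, seed=None,
                           covariates: pd.DataFrame | None = None) -> TrueParameters:
    """Draw item slopes, ordered thresholds and wave-level parameter drift."""
    rng = _rng(config.seed if seed is None else seed)
    n_items, n_waves = config.n_items, config.n_waves
    slopes = rng.lognormal(mean=0.0, sigma=0.3, size=n_items)
    slopes /= slopes.mean()  # identification convention: mean slope = 1
    thresholds = []
    for it in catalog:
        loc = rng.normal(0.0, 0.6)
        spread = rng.uniform(0.9, 1.4)
        k = np.arange(1, it.n_categories) / it.n_categories
        thresholds.append(loc + spread * ndtri(k))
    slope_off = rng.normal(0.0, config.wave_drift_sd_a, size=(n_items, n_waves))
    thr_off = rng.normal(0.0, config.wave_drift_sd_b, size=(n_items, n_waves))
    slope_off[:, 0] = 0.0  # baseline defines the reference parameterisation
    thr_off[:, 0] = 0.0
    if config.second_order_loadings is not None:
        gammas = np.asarray(config.second_order_loadings, dtype=float)
        if gammas.size != config.n_first_order_factors:
            raise ValueError("second_order_loadings length must match factor count")
    else:
        gammas = rng.uniform(0.6, 0.9, size=config.n_first_order_factors)
    return TrueParameters(
        slopes=slopes,
        thresholds=thresholds,
        slope_offsets=slope_off,
        threshold_offsets=thr_off,
        second_order_loadings=gammas,
        covariate_effects=dict(config.covariate_effects),
        wave_effects=np.zeros(n_waves),
        theta=np.zeros((config.n_persons, n_waves)),
        factor_scores=np.zeros((config.n_persons, n_waves, config.n_first_order_factors)),
    )


def sample_latent_health(
    config: GeneratorConfig,
    covariates: pd.DataFrame,
    true_params: TrueParameters,
    seed=None,
) -> LatentState:
    """Draw theta_pw = u_w + x'gamma + e_pw and the first-order factor scores.

    Factor scores equal the general factor plus independent noise sized so
    that corr(F_f, theta) equals the factor's second-order loading.
    """
    rng = _rng(config.seed if seed is None else seed)
    n, W = config.n_persons, config.n_waves
    u = rng.normal(0.0, config.wave_effect_sd, size=W)
    e = rng.normal(0.0, config.person_resid_sd, size=(n, W))
    shift = np.zeros(n)
    for name, eff in config.covariate_effects.items():
        shift += eff * covariates[name].to_numpy(dtype=float)
    theta = u[None, :] + shift[:, None] + e

    # marginal SD of theta across persons and waves (theoretical)
    var_cov = 0.0
    for name, eff in config.covariate_effects.items():
        p = np.asarray(config.covariate_levels[name], dtype=float)
        p = p / p.sum()
        lv = np.arange(len(p))
        var_cov += eff**2 * (np.sum(p * lv**2) - np.sum(p * lv) ** 2)
    sd_g = np.sqrt(config.wave_effect_sd**2 + config.person_resid_sd**2 + var_cov)

    gammas = true_params.second_order_loadings
    F = np.empty((n, W, gammas.size))
    for f, g in enumerate(gammas):
        if g >= 1.0:
            F[:, :, f] = theta
        else:
            zeta_sd = sd_g * np.sqrt(1.0 / g**2 - 1.0)
            F[:, :, f] = theta + rng.normal(0.0, zeta_sd, size=(n, W))
    true_params.wave_effects = u
    true_params.theta = theta
    true_params.factor_scores = F
    return LatentState(theta=theta, factor_scores=F, wave_effects=u)


def sample_item_responses(
    latent: LatentState,
    catalog: ItemCatalog,
    true_params: TrueParameters,
    seed=0,
) -> ResponsePanel:
    """Draw graded normal-ogive responses on the full person-wave grid.

    ``X = #{k >= 1 : U < Phi(a_iw * F - b_iwk)}`` which realises
    ``P(X >= k) = Phi(a_iw * F - b_iwk)`` exactly.  Cells for items not
    fielded in a wave are marked structurally unavailable.
    """
    rng = _rng(seed)
    n, W = latent.theta.shape
    wave_a = true_params.wave_slopes()
    data = np.full((n, W, len(catalog)), UNAVAILABLE, dtype=np.int16)
    avail = catalog.availability_matrix()
    for i, it in enumerate(catalog):
        b = true_params.thresholds[i]
        if not np.all(np.diff(b) > 0):
            raise ValueError(f"item {it.name}: thresholds must be strictly increasing")
        fac = it.factors[0]
        for w in range(W):
            if not avail[i, w]:
                continue
            eta = wave_a[i, w] * latent.factor_scores[:, w, fac]
            bw = b + true_params.threshold_offsets[i, w]
            surv = ndtr(eta[:, None] - bw[None, :])  # P(X >= k), k = 1..K-1
            u = rng.random(n)
            data[:, w, i] = (u[:, None] < surv).sum(axis=1)
    return ResponsePanel(data, np.arange(n), catalog.names)


def apply_missingness(
    panel: ResponsePanel,
    catalog: ItemCatalog,
    mcar_rate: float,
    seed=0,
    baseline_cap: float | None = 0.25,
) -> ResponsePanel:
    """Blank observed cells independently with probability ``mcar_rate``.

    Structural unavailability is left untouched and remains distinguishable
    from MCAR missingness.  If ``baseline_cap`` is given, persons whose
    baseline missing fraction would reach the cap get cells restored at
    random until they are strictly below it (the generated cohorts emulate
    a sample already screened by that rule).
    """
    if not (0 <= mcar_rate < 1):
        raise ValueError("mcar_rate must lie in [0, 1)")
    rng = _rng(seed)
    out = panel.copy()
    if mcar_rate == 0:
        return out
    observed = out.data >= 0
    blank = observed & (rng.random(out.data.shape) < mcar_rate)
    original = panel.data.copy()
    out.data[blank] = MISSING
    if baseline_cap is not None:
        avail0 = original[:, 0, :] != UNAVAILABLE
        n_avail = avail0.sum(axis=1)
        for p in range(out.n_persons):
            miss = np.flatnonzero(out.data[p, 0, :] == MISSING)
            limit = int(np.ceil(baseline_cap * n_avail[p])) - 1
            if miss.size > limit:
                restore = rng.choice(miss, size=miss.size - limit, replace=False)
                out.data[p, 0, restore] = original[p, 0, restore]
    return out


def sample_outcomes(latent: LatentState, config: GeneratorConfig, seed=0) -> pd.DataFrame:
    """Probit outcomes driven by centred baseline ill-health.

    mortality ~ Bernoulli(Phi(alpha0 + alpha1 * theta~)) with alpha1 > 0
    (worse health -> higher mortality); institutionalisation analogous with
    a smaller base rate; each chronic condition has its own intercept and a
    positive condition-specific slope.
    """
    rng = _rng(seed)
    theta_b = latent.theta[:, 0]
    centred = theta_b - theta_b.mean()
    n = centred.size

    def draw(base, slope, z=centred):
        return (rng.random(n) < ndtr(ndtri(base) + slope * z)).astype(int)

    out = {
        "person_id": np.arange(n),
        "mortality": draw(config.mortality_base_rate, config.mortality_slope),
        "institutionalisation": draw(
            config.institutionalisation_base_rate, config.institutionalisation_slope
        ),
    }
    base_rates = np.linspace(0.08, 0.35, config.n_chronic_conditions)
    for i, br in enumerate(base_rates):
        slope = config.chronic_slope * rng.uniform(0.7, 1.3)
        out[f"condition_{i + 1}"] = draw(br, slope)
    return pd.DataFrame(out)


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Compose the full cohort deterministically from ``config.seed``."""
    ss = np.random.SeedSequence(config.seed)
    s_cat, s_cov, s_par, s_lat, s_resp, s_miss, s_out = [
        np.random.default_rng(c) for c in ss.spawn(7)
    ]
    catalog = build_item_catalog(config, seed=s_cat)
    covariates = sample_covariates(config, seed=s_cov)
    true_params = sample_true_parameters(config, catalog, seed=s_par)
    latent = sample_latent_health(config, covariates, true_params, seed=s_lat)
    panel = sample_item_responses(latent, catalog, true_params, seed=s_resp)
    panel = apply_missingness(
        panel, catalog, config.mcar_rate, seed=s_miss, baseline_cap=config.baseline_missing_cap
    )
    outcomes = sample_outcomes(latent, config, seed=s_out)
    return SyntheticCohort(
        panel=panel,
        catalog=catalog,
        covariates=covariates,
        outcomes=outcomes,
        true_params=true_params,
        config=config,
    )
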