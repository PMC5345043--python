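"""Bayesian multilevel graded normal-ogive IRT with anchor and wave-varying
item parameters.

Measurement model for person ``p``, wave ``w``, item ``i`` with K_i ordered
categories (0-based, higher = worse health)::

    P(X_pwi >= k | theta_pw) = Phi(a_iw * theta_pw - b_iwk),  k = 1..K_i-1
    theta_pw = u_w + e_pw,   u_w ~ N(0, sigma_u^2),  e_pw ~ N(0, sigma_theta^2)

Wave-level item structure by variance configuration:

* ``M1`` - no intercept variance, no slope variance: a_iw = a_i, b_iwk = b_ik;
* ``M2`` - item-wise intercept variance: b_iwk = b_ik + d_iw,
  d_iw ~ N(0, sigma_b_i^2);
* ``M3`` - homogeneous intercept variance: as M2 with one shared sigma_b^2;
* ``M4`` - intercept and slope variances with hierarchical item parameters:
  additionally a_iw ~ N(a_i, sigma_a_i^2) and hyperpriors
  a_i ~ N(mu_a, tau_a^2), b_ik ~ N(mu_b, tau_b^2) with mu, tau estimated.

Estimation is Markov chain Monte Carlo: truncated-normal data augmentation
for the latent response process (Albert-Chib), conjugate normal updates
for abilities, wave effects and slopes given the augmented data,
Metropolis-within-Gibbs on the collapsed ordinal likelihood for category
thresholds and wave offsets (a partially collapsed Gibbs scheme - the
augmented data are redrawn immediately after every threshold move), and
inverse-gamma updates for all variances.  After every sweep the chain is
rescaled so that the mean item slope equals one (the identification rule),
which leaves the likelihood invariant.

Internally ``theta`` measures *ill*-health, aligned with the item coding;
the sign reversal to "higher = better" happens only in
:func:`to_health_score`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from healthtrait.panel import ItemCatalog, ResponsePanel

logger = logging.getLogger(__name__)

__all__ = [
    "MLIRTSpec",
    "IRTPosterior",
    "HealthScoreTransform",
    "fit_mlirt",
    "eap_scores",
    "eap_reliability",
    "dic",
    "wave_icc",
    "compare_models",
    "to_health_score",
    "sumscore_correlation",
]

_CONFIGS = ("M1", "M2", "M3", "M4")


@dataclass
class MLIRTSpec:
    """Sampler configuration and prior hyperparameters."""

    variance_config: str = "M4"
    n_iter: int = 5000
    burn_in: int = 100
    thin: int = 1
    seed: int = 0
    # priors
    slope_prior_mean: float = 1.0
    slope_prior_var: float = 2.0
    threshold_prior_mean: float = 0.0
    threshold_prior_var: float = 4.0
    variance_prior_shape: float = 1.0
    variance_prior_scale: float = 1.0
    hyper_mean_prior_var: float = 10.0
    # Metropolis tuning (adapted during burn-in to 20-50% acceptance)
    proposal_sd: float = 0.10
    # test hooks: fix parts of the model at known values
    fixed_slopes: np.ndarray | None = None
    fixed_thresholds: list[np.ndarray] | None = None
    fixed_person_resid_sd: float | None = None
    fixed_wave_effect_sd: float | None = None  # 0.0 pins u_w = 0
    # convergence: extend burn-in if the Geweke diagnostic fails
    geweke_check: bool = True
    geweke_z_limit: float = 3.0

    def __post_init__(self) -> None:
        if self.variance_config not in _CONFIGS:
            raise ValueError(f"variance_config must be one of {_CONFIGS}")
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        for name in ("slope_prior_var", "threshold_prior_var", "variance_prior_shape",
                     "variance_prior_scale", "hyper_mean_prior_var"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class IRTPosterior:
    """Retained MCMC draws and summaries of the multilevel IRT fit."""

    spec: MLIRTSpec
    person_ids: np.ndarray
    pw_mask: np.ndarray              # (n_persons, n_waves) included person-waves
    item_names: list[str]
    n_categories: np.ndarray
    chains: dict[str, np.ndarray]    # parameter name -> (n_draws, ...) arrays
    acceptance: dict[str, float]
    burn_in_used: int

    @property
    def n_draws(self) -> int:
        return self.chains["deviance"].shape[0]

    def theta_eap(self) -> tuple[np.ndarray, np.ndarray]:
        """(EAP, posterior SD) arrays of shape (n_persons, n_waves)."""
        th = self.chains["theta"]
        return th.mean(axis=0), th.std(axis=0)


# ---------------------------------------------------------------------------
# helpers

def _trunc_norm(rng, mu, sd, lo=-np.inf, hi=np.inf):
    """Vectorised truncated-normal draws via inverse CDF."""
    mu = np.asarray(mu, dtype=float)
    a = ndtr((lo - mu) / sd)
    b = ndtr((hi - mu) / sd)
    u = a + (b - a) * rng.random(mu.shape)
    u = np.clip(u, 1e-13, 1 - 1e-13)
    return mu + sd * ndtri(u)


def _inv_gamma(rng, shape, scale):
    return scale / rng.gamma(shape)


def _geweke_z(chain: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score with autocorrelation-robust variances."""
    n = chain.size
    if n < 40:
        return 0.0
    a = chain[: int(first * n)]
    b = chain[int((1 - last) * n):]

    def spec_var(x):
        x = x - x.mean()
        m = max(1, int(np.sqrt(x.size)))
        gamma0 = np.mean(x * x)
        s = gamma0
        for lag in range(1, m):
            w = 1 - lag / (m + 1)
            s += 2 * w * np.mean(x[lag:] * x[:-lag])
        return max(s, 1e-12) / x.size

    return float((a.mean() - b.mean()) / np.sqrt(spec_var(a) + spec_var(b)))


class _PanelCells:
    """Flattened observed cells of a response panel plus index machinery."""

    def __init__(self, panel: ResponsePanel, catalog: ItemCatalog, pw_mask: np.ndarray):
        data = panel.data
        n, W, I = data.shape
        obs = (data >= 0) & pw_mask[:, :, None]
        self.p, self.w, self.i = np.where(obs)
        self.cat = data[self.p, self.w, self.i].astype(np.int64)
        self.n, self.W, self.I = n, W, I
        self.pw = self.p * W + self.w
        self.iw = self.i * W + self.w
        self.n_cells = self.p.size
        self.Kmax = int(catalog.n_categories.max())
        # per-item wave availability restricted to waves with any data
        self.item_waves = [np.unique(self.w[self.i == i]) for i in range(I)]


def _padded_thresholds(b_list, d, I, W, Kmax):
    """Threshold tensor B[i, w, k], k = 0..Kmax with -inf/+inf padding."""
    B = np.full((I, W, Kmax + 1), np.inf)
    B[:, :, 0] = -np.inf
    for i, b in enumerate(b_list):
        B[i, :, 1: 1 + b.size] = b[None, :] + d[i, :, None]
    return B


def _cell_logprob(mu, lo, hi):
    pr = ndtr(mu - lo) - ndtr(mu - hi)
    return np.log(np.clip(pr, 1e-300, None))


# ---------------------------------------------------------------------------
# the sampler

def fit_mlirt(panel: ResponsePanel, catalog: ItemCatalog, spec: MLIRTSpec,
              pw_mask: np.ndarray | None = None) -> IRTPosterior:
    """Fit the multilevel graded normal-ogive model by Gibbs sampling.

    ``pw_mask`` marks person-waves retained by the missingness filter;
    by default every person-wave with at least one observed response is
    included.  Returns retained chains after burn-in.
    """
    data = panel.data
    n, W, I = data.shape
    K = catalog.n_categories
    if pw_mask is None:
        pw_mask = (data >= 0).any(axis=2)
    cells = _PanelCells(panel, catalog, pw_mask)
    if cells.n_cells == 0:
        raise ValueError("no observed responses")

    # validation: every item needs >= 2 observed categories; every wave with
    # data needs at least one anchor-item response (otherwise non-linkable)
    for i in range(I):
        seen = np.unique(cells.cat[cells.i == i])
        if seen.size < 2:
            raise ValueError(f"item {catalog.names[i]} observed with < 2 categories")
        if seen.max() >= K[i]:
            raise ValueError(f"item {catalog.names[i]}: response code beyond its categories")
    anchor = set(catalog.anchor_indices().tolist())
    for w in range(W):
        if not pw_mask[:, w].any():
            continue
        items_w = set(np.unique(cells.i[cells.w == w]).tolist())
        if not (items_w & anchor):
            raise ValueError(f"wave {w + 1} has no anchor-item responses; scale is not linkable")

    cfg = spec.variance_config
    rng = np.random.default_rng(spec.seed)
    fixed_items = spec.fixed_slopes is not None

    # --- state ------------------------------------------------------------
    a_item = (np.asarray(spec.fixed_slopes, dtype=float).copy() if fixed_items
              else np.ones(I))
    if spec.fixed_thresholds is not None:
        b_list = [np.asarray(b, dtype=float).copy() for b in spec.fixed_thresholds]
    else:
        b_list = [ndtri(np.arange(1, k) / k) for k in K]  # quantile starts
    d = np.zeros((I, W))
    a_wave = np.repeat(a_item[:, None], W, axis=1)
    theta = np.zeros((n, W))
    u = np.zeros(W)
    sigma_th2 = (spec.fixed_person_resid_sd or 1.0) ** 2
    sigma_u2 = (spec.fixed_wave_effect_sd if spec.fixed_wave_effect_sd is not None else 0.5) ** 2
    sigma_u2 = max(sigma_u2, 1e-12)
    sigma_b2 = np.full(I, 0.1)       # per-item intercept-drift variance (M2/M4)
    sigma_b2_pooled = 0.1            # M3
    sigma_a2 = np.full(I, 0.05)      # per-item slope-drift variance (M4)
    mu_a, tau_a2 = 1.0, 1.0
    mu_b, tau_b2 = 0.0, 4.0

    prop_b = np.full(I, spec.proposal_sd)
    prop_d = np.full((I, W), spec.proposal_sd)
    acc_b = np.zeros(I)
    acc_d = np.zeros((I, W))
    try_b = np.zeros(I)
    try_d = np.zeros((I, W))

    n_pw = pw_mask.sum()
    persons_per_wave = pw_mask.sum(axis=0)
    a0, b0 = spec.variance_prior_shape, spec.variance_prior_scale

    keep = spec.n_iter - spec.burn_in
    n_keep = (keep + spec.thin - 1) // spec.thin
    store = {
        "slopes": np.empty((n_keep, I)),
        "theta": np.empty((n_keep, n, W), dtype=np.float32),
        "u": np.empty((n_keep, W)),
        "sigma_u2": np.empty(n_keep),
        "sigma_theta2": np.empty(n_keep),
        "deviance": np.empty(n_keep),
        "thresholds": np.empty((n_keep, int(np.sum(K - 1)))),
        "d": np.empty((n_keep, I, W), dtype=np.float32),
    }
    if cfg in ("M2", "M4"):
        store["sigma_b2"] = np.empty((n_keep, I))
    if cfg == "M3":
        store["sigma_b2"] = np.empty((n_keep, 1))
    if cfg == "M4":
        store["slopes_wave"] = np.empty((n_keep, I, W), dtype=np.float32)
        store["sigma_a2"] = np.empty((n_keep, I))
        store["mu_a"] = np.empty(n_keep)
        store["tau_a2"] = np.empty(n_keep)
        store["mu_b"] = np.empty(n_keep)
        store["tau_b2"] = np.empty(n_keep)
    thr_slices = np.concatenate([[0], np.cumsum(K - 1)])

    cp, cw, ci, ccat, cpw, ciw = (cells.p, cells.w, cells.i, cells.cat, cells.pw, cells.iw)
    use_drift = cfg in ("M2", "M3", "M4")
    kidx = 0

    for sweep in range(spec.n_iter):
        in_burn = sweep < spec.burn_in

        # ---- thresholds and wave offsets (collapsed over Z) --------------
        if not fixed_items:
            theta_cell = theta[cp, cw]
            mu_cell = a_wave[ci, cw] * theta_cell

            # base thresholds b_ik: joint random-walk per item
            B = _padded_thresholds(b_list, d, I, W, cells.Kmax)
            ll_old = np.bincount(
                ci, weights=_cell_logprob(mu_cell, B[ci, cw, ccat], B[ci, cw, ccat + 1]),
                minlength=I,
            )
            b_prop = [b + rng.normal(0.0, prop_b[i], size=b.size)
                      for i, b in enumerate(b_list)]
            mono = np.array([np.all(np.diff(b) > 0) if b.size > 1 else True
                             for b in b_prop])
            Bp = _padded_thresholds(b_prop, d, I, W, cells.Kmax)
            ll_new = np.bincount(
                ci, weights=_cell_logprob(mu_cell, Bp[ci, cw, ccat], Bp[ci, cw, ccat + 1]),
                minlength=I,
            )
            pm = mu_b if cfg == "M4" else spec.threshold_prior_mean
            pv = tau_b2 if cfg == "M4" else spec.threshold_prior_var
            lp_old = np.array([np.sum(-0.5 * (b - pm) ** 2 / pv) for b in b_list])
            lp_new = np.array([np.sum(-0.5 * (b - pm) ** 2 / pv) for b in b_prop])
            log_acc = np.where(mono, (ll_new + lp_new) - (ll_old + lp_old), -np.inf)
            accept = np.log(rng.random(I)) < log_acc
            for i in np.flatnonzero(accept):
                b_list[i] = b_prop[i]
            acc_b += accept
            try_b += 1

            # wave offsets d_iw (scalar shift of all cutpoints)
            if use_drift:
                B = _padded_thresholds(b_list, d, I, W, cells.Kmax)
                ll_old_iw = np.bincount(
                    ciw, weights=_cell_logprob(mu_cell, B[ci, cw, ccat], B[ci, cw, ccat + 1]),
                    minlength=I * W,
                ).reshape(I, W)
                step = rng.normal(0.0, prop_d)
                d_prop = d + step
                Bp = _padded_thresholds(b_list, d_prop, I, W, cells.Kmax)
                ll_new_iw = np.bincount(
                    ciw, weights=_cell_logprob(mu_cell, Bp[ci, cw, ccat], Bp[ci, cw, ccat + 1]),
                    minlength=I * W,
                ).reshape(I, W)
                var_d = sigma_b2[:, None] if cfg in ("M2", "M4") else sigma_b2_pooled
                log_acc = (ll_new_iw - ll_old_iw
                           - 0.5 * d_prop**2 / var_d + 0.5 * d**2 / var_d)
                accept_iw = np.log(rng.random((I, W))) < log_acc
                d = np.where(accept_iw, d_prop, d)
                acc_d += accept_iw
                try_d += 1

                # intercept-drift variances
                ss_d = np.array([np.sum(d[i, cells.item_waves[i]] ** 2) for i in range(I)])
                n_d = np.array([len(cells.item_waves[i]) for i in range(I)])
                if cfg in ("M2", "M4"):
                    sigma_b2 = _inv_gamma(rng, a0 + n_d / 2.0, b0 + ss_d / 2.0)
                else:
                    sigma_b2_pooled = float(
                        _inv_gamma(rng, a0 + n_d.sum() / 2.0, b0 + ss_d.sum() / 2.0)
                    )

            if in_burn and (sweep + 1) % 25 == 0:
                rate_b = acc_b / np.maximum(try_b, 1)
                prop_b *= np.where(rate_b < 0.20, 0.8, np.where(rate_b > 0.50, 1.25, 1.0))
                acc_b[:] = 0
                try_b[:] = 0
                if use_drift:
                    rate_d = acc_d / np.maximum(try_d, 1)
                    prop_d *= np.where(rate_d < 0.20, 0.8, np.where(rate_d > 0.50, 1.25, 1.0))
                    acc_d[:] = 0
                    try_d[:] = 0

        # ---- latent responses Z (data augmentation) -----------------------
        B = _padded_thresholds(b_list, d, I, W, cells.Kmax)
        mu_cell = a_wave[ci, cw] * theta[cp, cw]
        Z = _trunc_norm(rng, mu_cell, 1.0, B[ci, cw, ccat], B[ci, cw, ccat + 1])

        # ---- abilities theta ---------------------------------------------
        a_cell = a_wave[ci, cw]
        sum_a2 = np.bincount(cpw, weights=a_cell**2, minlength=n * W).reshape(n, W)
        sum_az = np.bincount(cpw, weights=a_cell * Z, minlength=n * W).reshape(n, W)
        prec = 1.0 / sigma_th2 + sum_a2
        mean = (u[None, :] / sigma_th2 + sum_az) / prec
        theta = np.where(
            pw_mask, mean + rng.normal(size=(n, W)) / np.sqrt(prec), 0.0
        )
        if np.max(np.abs(theta)) > 50:
            raise RuntimeError(
                "sampler divergence: |theta| > 50; check item coding and priors"
            )

        # ---- wave effects and variance components -------------------------
        if spec.fixed_wave_effect_sd is None:
            prec_u = 1.0 / sigma_u2 + persons_per_wave / sigma_th2
            mean_u = (theta.sum(axis=0) / sigma_th2) / prec_u
            u = mean_u + rng.normal(size=W) / np.sqrt(prec_u)
            sigma_u2 = _inv_gamma(rng, a0 + W / 2.0, b0 + np.sum(u**2) / 2.0)
        elif spec.fixed_wave_effect_sd > 0:
            prec_u = 1.0 / sigma_u2 + persons_per_wave / sigma_th2
            mean_u = (theta.sum(axis=0) / sigma_th2) / prec_u
            u = mean_u + rng.normal(size=W) / np.sqrt(prec_u)
        if spec.fixed_person_resid_sd is None:
            resid = (theta - u[None, :])[pw_mask]
            sigma_th2 = _inv_gamma(rng, a0 + n_pw / 2.0, b0 + np.sum(resid**2) / 2.0)

        # ---- slopes --------------------------------------------------------
        if not fixed_items:
            theta_cell = theta[cp, cw]
            if cfg == "M4":
                # wave-level slopes a_iw
                s_t2 = np.bincount(ciw, weights=theta_cell**2, minlength=I * W).reshape(I, W)
                s_tz = np.bincount(ciw, weights=theta_cell * Z, minlength=I * W).reshape(I, W)
                prec_aw = 1.0 / sigma_a2[:, None] + s_t2
                mean_aw = (a_item[:, None] / sigma_a2[:, None] + s_tz) / prec_aw
                a_wave = mean_aw + rng.normal(size=(I, W)) / np.sqrt(prec_aw)
                # item-level slopes a_i given their wave replicates
                n_w = np.array([len(cells.item_waves[i]) for i in range(I)], dtype=float)
                s_aw = np.array([a_wave[i, cells.item_waves[i]].sum() for i in range(I)])
                prec_ai = 1.0 / tau_a2 + n_w / sigma_a2
                mean_ai = (mu_a / tau_a2 + s_aw / sigma_a2) / prec_ai
                a_item = _trunc_norm(rng, mean_ai, 1.0 / np.sqrt(prec_ai), lo=0.0)
                ss_a = np.array([
                    np.sum((a_wave[i, cells.item_waves[i]] - a_item[i]) ** 2) for i in range(I)
                ])
                sigma_a2 = _inv_gamma(rng, a0 + n_w / 2.0, b0 + ss_a / 2.0)
                # hyperpriors
                prec_mu = 1.0 / spec.hyper_mean_prior_var + I / tau_a2
                mean_mu = (spec.slope_prior_mean / spec.hyper_mean_prior_var
                           + a_item.sum() / tau_a2) / prec_mu
                mu_a = float(mean_mu + rng.normal() / np.sqrt(prec_mu))
                tau_a2 = float(_inv_gamma(rng, a0 + I / 2.0,
                                          b0 + np.sum((a_item - mu_a) ** 2) / 2.0))
                all_b = np.concatenate(b_list)
                prec_mb = 1.0 / spec.hyper_mean_prior_var + all_b.size / tau_b2
                mean_mb = (all_b.sum() / tau_b2) / prec_mb
                mu_b = float(mean_mb + rng.normal() / np.sqrt(prec_mb))
                tau_b2 = float(_inv_gamma(rng, a0 + all_b.size / 2.0,
                                          b0 + np.sum((all_b - mu_b) ** 2) / 2.0))
            else:
                s_t2 = np.bincount(ci, weights=theta_cell**2, minlength=I)
                s_tz = np.bincount(ci, weights=theta_cell * Z, minlength=I)
                prec_a = 1.0 / spec.slope_prior_var + s_t2
                mean_a = (spec.slope_prior_mean / spec.slope_prior_var + s_tz) / prec_a
                a_item = _trunc_norm(rng, mean_a, 1.0 / np.sqrt(prec_a), lo=0.0)
                a_wave = np.repeat(a_item[:, None], W, axis=1)

            # ---- identification: mean item slope = 1 ----------------------
            c = a_item.mean()
            a_item = a_item / c
            a_wave = a_wave / c
            theta = theta * c
            u = u * c
            sigma_th2 *= c**2
            sigma_u2 *= c**2
            if cfg == "M4":
                sigma_a2 = sigma_a2 / c**2
                mu_a /= c
                tau_a2 /= c**2

        # ---- record ---------------------------------------------------------
        if not in_burn and (sweep - spec.burn_in) % spec.thin == 0:
            B = _padded_thresholds(b_list, d, I, W, cells.Kmax)
            mu_cell = a_wave[ci, cw] * theta[cp, cw]
            devi = -2.0 * np.sum(_cell_logprob(mu_cell, B[ci, cw, ccat], B[ci, cw, ccat + 1]))
            store["slopes"][kidx] = a_item
            store["theta"][kidx] = theta
            store["u"][kidx] = u
            store["sigma_u2"][kidx] = sigma_u2
            store["sigma_theta2"][kidx] = sigma_th2
            store["deviance"][kidx] = devi
            store["thresholds"][kidx] = np.concatenate(b_list)
            store["d"][kidx] = d
            if cfg in ("M2", "M4"):
                store["sigma_b2"][kidx] = sigma_b2
            elif cfg == "M3":
                store["sigma_b2"][kidx, 0] = sigma_b2_pooled
            if cfg == "M4":
                store["slopes_wave"][kidx] = a_wave
                store["sigma_a2"][kidx] = sigma_a2
                store["mu_a"][kidx] = mu_a
                store["tau_a2"][kidx] = tau_a2
                store["mu_b"][kidx] = mu_b
                store["tau_b2"][kidx] = tau_b2
            kidx += 1

    for key in store:
        store[key] = store[key][:kidx]

    burn_used = spec.burn_in
    if spec.geweke_check and kidx >= 40:
        z = _geweke_z(store["deviance"].astype(float))
        if abs(z) > spec.geweke_z_limit:
            drop = kidx // 2
            logger.warning(
                "Geweke diagnostic failed (z = %.2f); extending burn-in by %d draws", z, drop
            )
            for key in store:
                store[key] = store[key][drop:]
            burn_used += drop * spec.thin

    acceptance = {
        "thresholds": float(np.mean(acc_b / np.maximum(try_b, 1))) if try_b.max() > 0 else 1.0,
        "wave_offsets": float(np.mean(acc_d / np.maximum(try_d, 1))) if try_d.max() > 0 else 1.0,
    }
    store["thresholds_slices"] = thr_slices
    return IRTPosterior(
        spec=spec,
        person_ids=np.asarray(panel.person_ids),
        pw_mask=pw_mask,
        item_names=list(panel.item_names),
        n_categories=K.copy(),
        chains=store,
        acceptance=acceptance,
        burn_in_used=burn_used,
    )


# ---------------------------------------------------------------------------
# post-processing

def eap_scores(posterior: IRTPosterior) -> pd.DataFrame:
    """Per person-wave EAP ability and posterior SD (included rows only)."""
    eap, psd = posterior.theta_eap()
    p, w = np.where(posterior.pw_mask)
    return pd.DataFrame(
        {
            "person_id": posterior.person_ids[p],
            "wave": w + 1,
            "theta_eap": eap[p, w].astype(float),
            "theta_psd": psd[p, w].astype(float),
        }
    )


def eap_reliability(posterior: IRTPosterior) -> float:
    """EAP reliability: Var(EAP) / (Var(EAP) + mean posterior variance)."""
    eap, psd = posterior.theta_eap()
    m = posterior.pw_mask
    v = float(np.var(eap[m]))
    return v / (v + float(np.mean(psd[m] ** 2)))


def dic(posterior: IRTPosterior, panel: ResponsePanel, catalog: ItemCatalog) -> tuple[float, float, float]:
    """Deviance Information Criterion: (DIC, pD, Dbar).

    Dbar is the posterior-mean deviance recorded during sampling; the
    plug-in deviance is evaluated at the posterior means of the item,
    drift and ability parameters.
    """
    ch = posterior.chains
    dbar = float(ch["deviance"].mean())
    I = len(posterior.item_names)
    W = posterior.pw_mask.shape[1]
    K = posterior.n_categories
    sl = ch["thresholds_slices"]
    b_mean = [ch["thresholds"].mean(axis=0)[sl[i]: sl[i + 1]] for i in range(I)]
    d_mean = ch["d"].mean(axis=0).astype(float)
    if "slopes_wave" in ch:
        a_wave = ch["slopes_wave"].mean(axis=0).astype(float)
    else:
        a_wave = np.repeat(ch["slopes"].mean(axis=0)[:, None], W, axis=1)
    theta_mean = ch["theta"].mean(axis=0).astype(float)
    cells = _PanelCells(panel, catalog, posterior.pw_mask)
    Kmax = int(K.max())
    B = _padded_thresholds(b_mean, d_mean, I, W, Kmax)
    mu = a_wave[cells.i, cells.w] * theta_mean[cells.p, cells.w]
    d_hat = -2.0 * np.sum(_cell_logprob(mu, B[cells.i, cells.w, cells.cat],
                                        B[cells.i, cells.w, cells.cat + 1]))
    pd_eff = dbar - float(d_hat)
    return dbar + pd_eff, pd_eff, dbar


def wave_icc(posterior: IRTPosterior) -> tuple[float, tuple[float, float]]:
    """Wave-level intraclass correlation of ability.

    Per retained draw, icc = sigma_u^2 / (sigma_u^2 + sigma_theta^2);
    returns the posterior median and the central 95% credible interval.
    """
    su = posterior.chains["sigma_u2"]
    st = posterior.chains["sigma_theta2"]
    icc = su / (su + st)
    lo, med, hi = np.percentile(icc, [2.5, 50, 97.5])
    return float(med), (float(lo), float(hi))


def compare_models(fits: dict[str, tuple[float, float]]) -> dict:
    """Rank fitted models by EAP reliability (max) and DIC (min).

    ``fits`` maps a label to ``(eap_reliability, dic)``.  If the two
    criteria disagree the report flags it and the lower-DIC model is
    selected (ties also break toward lower DIC).
    """
    if not fits:
        raise ValueError("no fits to compare")
    labels = list(fits)
    best_rel = max(labels, key=lambda k: fits[k][0])
    best_dic = min(labels, key=lambda k: fits[k][1])
    return {
        "selected": best_dic,
        "criteria_agree": best_rel == best_dic,
        "best_reliability": best_rel,
        "best_dic": best_dic,
        "table": {k: {"eap_reliability": fits[k][0], "dic": fits[k][1]} for k in labels},
    }


@dataclass
class HealthScoreTransform:
    """Stored 0-100 transform (sign-reversing: theta measures ill-health)."""

    theta_min: float
    theta_max: float

    def apply(self, theta_eap, psd=None, clamp_warn: bool = True):
        theta_eap = np.asarray(theta_eap, dtype=float)
        rng_ = self.theta_max - self.theta_min
        score = 100.0 * (self.theta_max - theta_eap) / rng_
        if clamp_warn and (np.any(score < 0) or np.any(score > 100)):
            warnings.warn("EAP outside the stored range; scores clamped to [0, 100]")
        score = np.clip(score, 0.0, 100.0)
        if psd is None:
            return score
        return score, 100.0 * np.asarray(psd, dtype=float) / rng_


def to_health_score(eap_table: pd.DataFrame,
                    transform: HealthScoreTransform | None = None
                    ) -> tuple[pd.DataFrame, HealthScoreTransform]:
    """Map EAP ill-health to a 0-100 scale with higher = better health.

    ``score = 100 * (theta_max - eap) / (theta_max - theta_min)`` with the
    pooled min/max over all person-waves; the transform is returned for
    out-of-sample application (new values clamp to [0, 100] with a warning).
    """
    eap = eap_table["theta_eap"].to_numpy()
    if transform is None:
        tmin, tmax = float(eap.min()), float(eap.max())
        if tmax == tmin:
            raise ValueError("degenerate EAP range; cannot build 0-100 transform")
        transform = HealthScoreTransform(tmin, tmax)
    score, psd = transform.apply(eap, eap_table["theta_psd"].to_numpy())
    out = eap_table[["person_id", "wave"]].copy()
    out["score"] = score
    out["score_psd"] = psd
    return out, transform


def sumscore_correlation(scores: pd.DataFrame, panel: ResponsePanel) -> float:
    """|Pearson r| between the health score and the raw mean item response.

    The comparator is the per-person-wave mean of observed recoded item
    values (missing-aware).  Returns the absolute correlation.
    """
    data = panel.data.astype(float)
    obs = data >= 0
    with np.errstate(invalid="ignore"):
        mean_resp = np.where(obs.sum(axis=2) > 0,
                             np.where(obs, data, 0.0).sum(axis=2) / np.maximum(obs.sum(axis=2), 1),
                             np.nan)
    pid_index = {p: i for i, p in enumerate(np.asarray(panel.person_ids))}
    rows_p = scores["person_id"].map(pid_index).to_numpy()
    rows_w = scores["wave"].to_numpy(dtype=int) - 1
    ss = mean_resp[rows_p, rows_w]
    sc = scores["score"].to_numpy()
    keep = ~np.isnan(ss)
    r = np.corrcoef(sc[keep], ss[keep])[0, 1]
    return float(abs(r))
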