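"""Association and validity analyses on the 0-100 health score.

* crossed random-intercept linear mixed model (person + wave) fitted by
  maximum likelihood with the two variance ratios profiled out;
* likelihood-ratio test of the mixed model against plain OLS;
* adjusted McFadden pseudo-R2 and the conditional intraclass correlation;
* criterion-validity multiple regression with standardized coefficients;
* empirical (Mann-Whitney) AUC with DeLong confidence intervals, the
  gender-stratified "covariate-adjusted" AUC, and the paired DeLong test
  comparing two markers on the same subjects.

ML (not REML) is used throughout so likelihood-ratio tests against OLS and
AIC comparisons are coherent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "MixedModelFit",
    "OLSFit",
    "AUCResult",
    "fit_lmm",
    "fit_ols",
    "lrt_vs_linear",
    "mcfadden_adjusted",
    "conditional_icc",
    "conditional_icc_from_sds",
    "ols_standardized",
    "auc_empirical",
    "auc_gender_adjusted",
    "compare_auc",
    "chronic_count",
]


@dataclass
class MixedModelFit:
    beta: np.ndarray
    se: np.ndarray
    ci: np.ndarray            # (k, 2)
    sd_person: float          # sigma_alpha
    sd_wave: float            # sigma_gamma
    sd_resid: float           # sigma_eps
    loglik: float
    aic: float
    n_obs: int
    n_persons: int
    n_params: int
    boundary: bool = False
    column_names: list | None = None


@dataclass
class OLSFit:
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    aic: float
    n_obs: int
    n_params: int


def _group_codes(ids) -> tuple[np.ndarray, int]:
    codes, uniq = pd.factorize(np.asarray(ids))
    return codes.astype(int), len(uniq)


def fit_lmm(y, X, person_ids, wave_ids, column_names=None) -> MixedModelFit:
    """ML fit of ``y = X beta + alpha_person + gamma_wave + eps``.

    Random intercepts are independent normals; beta and the residual
    variance are profiled out and the two variance ratios are optimised
    numerically.  Uses the Woodbury identity on the (persons + waves)
    random-effect design, so the cost scales with the number of groups,
    not observations.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        corr_rank = [j for j in range(k)
                     if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == np.linalg.matrix_rank(X)]
        names = column_names or list(range(k))
        raise ValueError(f"design matrix is rank deficient; aliased columns: "
                         f"{[names[j] for j in corr_rank]}")
    pc, n_p = _group_codes(person_ids)
    wc, n_w = _group_codes(wave_ids)
    if n_p < 2:
        raise ValueError("need at least 2 persons")
    q = n_p + n_w

    # U'U blocks: diag person counts, diag wave counts, person x wave cross-tab
    cnt_p = np.bincount(pc, minlength=n_p).astype(float)
    cnt_w = np.bincount(wc, minlength=n_w).astype(float)
    cross = np.zeros((n_p, n_w))
    np.add.at(cross, (pc, wc), 1.0)
    UtU = np.zeros((q, q))
    UtU[:n_p, :n_p] = np.diag(cnt_p)
    UtU[n_p:, n_p:] = np.diag(cnt_w)
    UtU[:n_p, n_p:] = cross
    UtU[n_p:, :n_p] = cross.T

    def _ut(v):
        """U' v for a vector or matrix v."""
        if v.ndim == 1:
            return np.concatenate([np.bincount(pc, weights=v, minlength=n_p),
                                   np.bincount(wc, weights=v, minlength=n_w)])
        return np.vstack([
            np.stack([np.bincount(pc, weights=v[:, j], minlength=n_p) for j in range(v.shape[1])], axis=1),
            np.stack([np.bincount(wc, weights=v[:, j], minlength=n_w) for j in range(v.shape[1])], axis=1),
        ])

    def _profile(log_lams):
        lam = np.exp(log_lams)
        dvec = np.concatenate([np.full(n_p, lam[0]), np.full(n_w, lam[1])])
        M = np.eye(q) + UtU * dvec[None, :]
        sign, logdet = np.linalg.slogdet(M)
        Minv_D = np.linalg.solve(M, np.diag(dvec))

        def vinv(v):
            utv = _ut(v)
            corr = Minv_D @ utv
            # U corr: scatter back
            add = corr[:n_p][pc] + corr[n_p:][wc]
            return v - add

        ViX = vinv(X)
        Viy = vinv(y)
        XtViX = X.T @ ViX
        beta = np.linalg.solve(XtViX, X.T @ Viy)
        resid = y - X @ beta
        rss = float(resid @ vinv(resid))
        sig2 = rss / n
        ll = -0.5 * (n * np.log(2 * np.pi * sig2) + logdet + n)
        return ll, beta, sig2, XtViX, lam

    res = optimize.minimize(
        lambda lg: -_profile(lg)[0],
        x0=np.log([0.5, 0.1]),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000},
    )
    ll, beta, sig2, XtViX, lam = _profile(res.x)
    cov_beta = np.linalg.inv(XtViX) * sig2
    se = np.sqrt(np.diag(cov_beta))
    zcrit = stats.norm.ppf(0.975)
    ci = np.column_stack([beta - zcrit * se, beta + zcrit * se])
    boundary = bool(np.any(lam < 1e-6))
    if boundary:
        logger.warning("variance component at boundary (ratio < 1e-6)")
    n_params = k + 3  # beta + two variance components + residual variance
    return MixedModelFit(
        beta=beta, se=se, ci=ci,
        sd_person=float(np.sqrt(lam[0] * sig2)),
        sd_wave=float(np.sqrt(lam[1] * sig2)),
        sd_resid=float(np.sqrt(sig2)),
        loglik=float(ll),
        aic=float(-2 * ll + 2 * n_params),
        n_obs=n, n_persons=n_p, n_params=n_params,
        boundary=boundary, column_names=column_names,
    )


def fit_ols(y, X) -> OLSFit:
    """Plain-likelihood OLS (ML variance) for the LRT comparator."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sig2 = float(resid @ resid) / n
    ll = -0.5 * n * (np.log(2 * np.pi * sig2) + 1)
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(xtx_inv) * sig2 * n / (n - k))
    n_params = k + 1
    return OLSFit(beta=beta, se=se, loglik=float(ll),
                  aic=float(-2 * ll + 2 * n_params), n_obs=n, n_params=n_params)


def lrt_vs_linear(mixed_fit: MixedModelFit, ols_fit: OLSFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of the crossed mixed model vs OLS.

    Uses the naive chi-square(2) reference; at the variance boundary this
    is conservative.
    """
    chi2 = max(2.0 * (mixed_fit.loglik - ols_fit.loglik), 0.0)
    p = float(stats.chi2.sf(chi2, df=2)) if chi2 > 0 else 1.0
    return float(chi2), 2, p


def mcfadden_adjusted(full_fit, null_fit) -> float:
    """Adjusted McFadden pseudo-R2: 1 - (ll_full - k_full) / ll_null."""
    ll_full, k_full = full_fit.loglik, full_fit.n_params
    ll_null = null_fit.loglik
    return float(1.0 - (ll_full - k_full) / ll_null)


def conditional_icc(fit: MixedModelFit) -> float:
    """Share of variance attributable to the random effects."""
    return conditional_icc_from_sds(fit.sd_person, fit.sd_wave, fit.sd_resid)


def conditional_icc_from_sds(sd_person: float, sd_wave: float, sd_resid: float) -> float:
    va, vg, ve = sd_person**2, sd_wave**2, sd_resid**2
    return float((va + vg) / (va + vg + ve))


def ols_standardized(y, X, column_names=None) -> pd.DataFrame:
    """Multiple regression table with |standardized beta| per predictor.

    Intercept column(s) (zero variance) get |beta_std| = NaN.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    model = sm.OLS(y, X).fit()
    ci = model.conf_int()
    sd_x = X.std(axis=0, ddof=1)
    sd_y = y.std(ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta_std = np.abs(model.params) * sd_x / sd_y
    beta_std = np.where(sd_x == 0, np.nan, beta_std)
    return pd.DataFrame(
        {
            "coef": model.params,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
            "p": model.pvalues,
            "abs_beta_std": beta_std,
        },
        index=column_names or [f"x{j}" for j in range(X.shape[1])],
    )


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong machinery

@dataclass
class AUCResult:
    auc: float
    ci: tuple[float, float]
    method: str  # "pooled" or "gender_adjusted"
    var: float = float("nan")


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(marker: np.ndarray, outcome: np.ndarray):
    """DeLong structural components: (auc, V10 per case, V01 per control)."""
    cases = marker[outcome == 1]
    ctrls = marker[outcome == 0]
    m, nn = cases.size, ctrls.size
    allv = np.concatenate([cases, ctrls])
    r_all = _midrank(allv)
    r_cases = _midrank(cases)
    r_ctrls = _midrank(ctrls)
    auc = (np.sum(r_all[:m]) - m * (m + 1) / 2) / (m * nn)
    v10 = (r_all[:m] - r_cases) / nn
    v01 = 1.0 - (r_all[m:] - r_ctrls) / m
    return float(auc), v10, v01


def auc_empirical(score, outcome, orient_low_score_is_risk: bool = True) -> AUCResult:
    """Mann-Whitney AUC with DeLong 95% CI.

    Orientation: a *lower* health score predicts the adverse outcome, so
    the marker entered into the ROC is the negated score (disable with
    ``orient_low_score_is_risk=False`` for markers already oriented).
    """
    score = np.asarray(score, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    if np.unique(outcome).size < 2:
        raise ValueError("outcome must contain both classes")
    marker = -score if orient_low_score_is_risk else score
    auc, v10, v01 = _delong_components(marker, outcome)
    var = (np.var(v10, ddof=1) / v10.size if v10.size > 1 else 0.0) + \
          (np.var(v01, ddof=1) / v01.size if v01.size > 1 else 0.0)
    half = stats.norm.ppf(0.975) * np.sqrt(max(var, 0.0))
    ci = (max(auc - half, 0.0), min(auc + half, 1.0))
    return AUCResult(auc=auc, ci=ci, method="pooled", var=var)


def auc_gender_adjusted(score, outcome, gender) -> AUCResult:
    """Covariate-adjusted AUC: case-control-pair-weighted within-stratum AUCs.

    Strata lacking either outcome class are excluded with a warning.
    The CI combines the stratum DeLong variances with the same weights.
    """
    score = np.asarray(score, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    gender = np.asarray(gender)
    aucs, weights, vars_ = [], [], []
    for g in np.unique(gender):
        m = gender == g
        if np.unique(outcome[m]).size < 2:
            warnings.warn(f"stratum {g!r} lacks an outcome class; excluded")
            continue
        res = auc_empirical(score[m], outcome[m])
        n1 = int(outcome[m].sum())
        n0 = int((1 - outcome[m]).sum())
        aucs.append(res.auc)
        weights.append(n1 * n0)
        vars_.append(res.var)
    if not aucs:
        raise ValueError("no stratum with both outcome classes")
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    auc = float(np.sum(w * np.asarray(aucs)))
    var = float(np.sum(w**2 * np.asarray(vars_)))
    half = stats.norm.ppf(0.975) * np.sqrt(max(var, 0.0))
    return AUCResult(auc=auc, ci=(max(auc - half, 0.0), min(auc + half, 1.0)),
                     method="gender_adjusted", var=var)


def _paired_delong(marker_a, marker_b, outcome):
    """Paired DeLong comparison on the same subjects; returns (delta, var)."""
    auc_a, v10a, v01a = _delong_components(marker_a, outcome)
    auc_b, v10b, v01b = _delong_components(marker_b, outcome)
    m, nn = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if nn > 1 else np.zeros((2, 2))
    S = s10 / m + s01 / nn
    var = S[0, 0] + S[1, 1] - 2 * S[0, 1]
    return auc_a - auc_b, float(max(var, 0.0))


def compare_auc(score_a, score_b, outcome, gender=None,
                orient_a: bool = True, orient_b: bool = True) -> tuple[float, float, float]:
    """Paired DeLong test for two markers measured on the same subjects.

    ``orient_a`` / ``orient_b`` negate the respective marker so that higher
    marker = higher risk (the health score is negated; a chronic-condition
    count is already risk-oriented and should use ``orient_b=False``).
    Optionally stratified by gender with case-control-pair weights.
    Returns (delta = AUC_a - AUC_b, z, two-sided p).
    """
    a = -np.asarray(score_a, dtype=float) if orient_a else np.asarray(score_a, dtype=float)
    b = -np.asarray(score_b, dtype=float) if orient_b else np.asarray(score_b, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    if gender is None:
        delta, var = _paired_delong(a, b, outcome)
    else:
        gender = np.asarray(gender)
        deltas, vars_, weights = [], [], []
        for g in np.unique(gender):
            m = gender == g
            if np.unique(outcome[m]).size < 2:
                warnings.warn(f"stratum {g!r} lacks an outcome class; excluded")
                continue
            dd, vv = _paired_delong(a[m], b[m], outcome[m])
            n1 = int(outcome[m].sum())
            n0 = int((1 - outcome[m]).sum())
            deltas.append(dd)
            vars_.append(vv)
            weights.append(n1 * n0)
        if not deltas:
            raise ValueError("no stratum with both outcome classes")
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
        delta = float(np.sum(w * np.asarray(deltas)))
        var = float(np.sum(w**2 * np.asarray(vars_)))
    if var == 0:
        return float(delta), 0.0, 1.0
    z = delta / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))
    return float(delta), float(z), p


def chronic_count(condition_flags: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Row-wise sum of the binary chronic-condition flags.

    Missing flags count as 0; the number of imputed cells is logged.
    """
    arr = np.asarray(condition_flags, dtype=float)
    n_missing = int(np.isnan(arr).sum())
    if n_missing:
        logger.info("chronic_count: %d missing flags treated as 0", n_missing)
        arr = np.nan_to_num(arr, nan=0.0)
    return arr.sum(axis=1).astype(int)
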