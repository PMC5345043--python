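"""Unidimensionality screening for ordinal health items.

Polychoric correlation estimation, Velicer's Minimum Average Partial test
for the number of factors, minimum-residual EFA with oblique geomin
rotation, and a second-order CFA fitted by unweighted least squares with
ML-form chi-square and the usual incremental/absolute fit indices
(CFI, TLI, RMSEA with 90% CI).

The estimator chain is designed for desk-scale data: thresholds come from
inverse-normal cumulative marginals, each pairwise latent correlation from
a bounded 1-D likelihood maximisation over bivariate-normal rectangle
probabilities (computed exactly through Owen's T function), and the EFA /
CFA operate on the resulting correlation matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import ndtr, ndtri, owens_t
from scipy.stats import ncx2

logger = logging.getLogger(__name__)

__all__ = [
    "PolychoricMatrix",
    "EFASolution",
    "FitIndices",
    "bvn_cdf",
    "polychoric_pair",
    "polychoric_matrix",
    "map_test",
    "efa",
    "rotate_geomin",
    "assign_items",
    "cfa_second_order",
    "fit_indices",
    "explained_variance",
]


# ---------------------------------------------------------------------------
# bivariate normal CDF via Owen's T (exact, vectorised)

def bvn_cdf(h, k, rho: float):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Uses the Owen's T representation; handles +/-inf limits.  ``h`` and
    ``k`` broadcast; ``rho`` is scalar in (-1, 1).
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    h, k = np.broadcast_arrays(h, k)
    rho = float(np.clip(rho, -0.9999999, 0.9999999))
    out = np.empty(h.shape, dtype=float)

    # infinite limits reduce to univariate margins
    neg_inf = (h == -np.inf) | (k == -np.inf)
    h_inf = h == np.inf
    k_inf = k == np.inf
    finite = ~(neg_inf | h_inf | k_inf)
    out[neg_inf] = 0.0
    out[h_inf & ~neg_inf] = ndtr(k[h_inf & ~neg_inf])
    out[k_inf & ~neg_inf & ~h_inf] = ndtr(h[k_inf & ~neg_inf & ~h_inf])

    hf = h[finite]
    kf = k[finite]
    # nudge exact zeros so the Owen's T arguments stay finite
    hf = np.where(hf == 0.0, 1e-12, hf)
    kf = np.where(kf == 0.0, 1e-12, kf)
    denom = np.sqrt(1.0 - rho * rho)
    a_h = (kf - rho * hf) / (hf * denom)
    a_k = (hf - rho * kf) / (kf * denom)
    beta = np.where(hf * kf > 0, 0.0,
                    np.where((hf * kf == 0) & (hf + kf >= 0), 0.0, 0.5))
    val = 0.5 * (ndtr(hf) + ndtr(kf)) - owens_t(hf, a_h) - owens_t(kf, a_k) - beta
    out[finite] = np.clip(val, 0.0, 1.0)
    return out if out.ndim else float(out)


def _thresholds_from_margin(counts: np.ndarray) -> np.ndarray:
    """Inverse-normal thresholds from category counts (len K -> K-1 taus)."""
    cum = np.cumsum(counts[:-1]) / counts.sum()
    return ndtri(np.clip(cum, 1e-10, 1 - 1e-10))


def _table_loglik(rho: float, tau_x: np.ndarray, tau_y: np.ndarray, table: np.ndarray) -> float:
    gx = np.concatenate(([-np.inf], tau_x, [np.inf]))
    gy = np.concatenate(([-np.inf], tau_y, [np.inf]))
    C = bvn_cdf(gx[:, None], gy[None, :], rho)
    P = C[1:, 1:] - C[:-1, 1:] - C[1:, :-1] + C[:-1, :-1]
    P = np.clip(P, 1e-12, 1.0)
    return float(np.sum(table * np.log(P)))


def polychoric_pair(x, y, names: tuple[str, str] = ("x", "y")) -> tuple[float, np.ndarray, np.ndarray]:
    """Two-step polychoric correlation of two ordinal vectors.

    Thresholds are estimated from the pairwise-complete marginals; the
    latent correlation maximises the bivariate-normal rectangle-probability
    likelihood of the contingency table.  The estimate is clamped to
    [-0.999, 0.999].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    xi = x[keep].astype(int)
    yi = y[keep].astype(int)
    if np.unique(xi).size < 2 or np.unique(yi).size < 2:
        raise ValueError(f"pair ({names[0]}, {names[1]}): fewer than 2 observed categories")
    kx, ky = xi.max() + 1, yi.max() + 1
    table = np.zeros((kx, ky))
    np.add.at(table, (xi, yi), 1.0)
    tau_x = _thresholds_from_margin(table.sum(axis=1))
    tau_y = _thresholds_from_margin(table.sum(axis=0))
    res = optimize.minimize_scalar(
        lambda r: -_table_loglik(r, tau_x, tau_y, table),
        bounds=(-0.999, 0.999),
        method="bounded",
        options={"xatol": 1e-6},
    )
    rho = float(np.clip(res.x, -0.999, 0.999))
    return rho, tau_x, tau_y


@dataclass
class PolychoricMatrix:
    rho: np.ndarray                  # (p, p) correlation estimates
    thresholds: list[np.ndarray]     # per-item threshold vectors
    pair_n: np.ndarray               # (p, p) pairwise sample sizes
    smoothed: bool = False
    item_names: list[str] = field(default_factory=list)


def nearest_psd_correlation(R: np.ndarray, eps: float = 1e-8) -> tuple[np.ndarray, bool]:
    """Clip negative eigenvalues and restore the unit diagonal."""
    w, V = np.linalg.eigh((R + R.T) / 2)
    if w.min() >= -eps:
        return R, False
    w = np.clip(w, 1e-8, None)
    S = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(S))
    S = S / np.outer(d, d)
    np.fill_diagonal(S, 1.0)
    return S, True


def polychoric_matrix(data, item_names: list[str] | None = None) -> PolychoricMatrix:
    """Pairwise-complete polychoric correlation matrix of ordinal columns.

    ``data``: (n, p) float array (or DataFrame) with NaN for missing.
    Failing pairs are collected and reported in a single error.  The
    output is smoothed to positive semidefiniteness if needed (logged).
    """
    X = np.asarray(data, dtype=float)
    if hasattr(data, "columns") and item_names is None:
        item_names = list(data.columns)
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 items")
    names = item_names or [f"item_{j}" for j in range(p)]
    R = np.eye(p)
    pair_n = np.zeros((p, p), dtype=int)
    thresholds: list[np.ndarray] = []
    for j in range(p):
        col = X[:, j]
        obs = col[~np.isnan(col)].astype(int)
        counts = np.bincount(obs, minlength=obs.max() + 1 if obs.size else 1)
        thresholds.append(_thresholds_from_margin(counts.astype(float)))
        pair_n[j, j] = obs.size
    failures = []
    for j in range(p):
        for k in range(j + 1, p):
            keep = ~(np.isnan(X[:, j]) | np.isnan(X[:, k]))
            pair_n[j, k] = pair_n[k, j] = int(keep.sum())
            try:
                rho, _, _ = polychoric_pair(X[:, j], X[:, k], names=(names[j], names[k]))
            except ValueError as exc:
                failures.append(str(exc))
                continue
            R[j, k] = R[k, j] = rho
    if failures:
        raise ValueError("polychoric estimation failed for pairs:\n" + "\n".join(failures))
    R, smoothed = nearest_psd_correlation(R)
    if smoothed:
        logger.warning("polychoric matrix smoothed to positive semidefiniteness")
    return PolychoricMatrix(rho=R, thresholds=thresholds, pair_n=pair_n,
                            smoothed=smoothed, item_names=names)


# ---------------------------------------------------------------------------
# Velicer's MAP test

def map_test(R: np.ndarray, max_factors: int | None = None) -> tuple[int, np.ndarray]:
    """Velicer's Minimum Average Partial test.

    For m = 0..max_factors, partial the first m principal components out
    of ``R`` and average the squared off-diagonal partial correlations;
    the minimising m is the suggested number of factors.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if max_factors is None:
        max_factors = p - 2
    if max_factors >= p:
        raise ValueError("max_factors must be smaller than the number of items")
    w, V = np.linalg.eigh(R)
    if w.min() < -1e-8:
        raise ValueError("R is not positive semidefinite; smooth it first")
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    off = ~np.eye(p, dtype=bool)
    curve = np.empty(max_factors + 1)
    curve[0] = np.mean(R[off] ** 2)
    for m in range(1, max_factors + 1):
        A = V[:, :m] * np.sqrt(np.clip(w[:m], 0, None))
        C = R - A @ A.T
        d = np.diag(C).copy()
        if np.any(d < 1e-10):
            curve[m:] = np.inf
            break
        Dg = 1.0 / np.sqrt(d)
        Pc = C * np.outer(Dg, Dg)
        curve[m] = np.mean(Pc[off] ** 2)
    return int(np.argmin(curve)), curve


# ---------------------------------------------------------------------------
# EFA: minres extraction + geomin rotation

def _smc(R: np.ndarray) -> np.ndarray:
    """Squared multiple correlations (starting communalities)."""
    try:
        Rinv = np.linalg.inv(R)
        return np.clip(1.0 - 1.0 / np.diag(Rinv), 0.0, 0.999)
    except np.linalg.LinAlgError:
        return np.full(R.shape[0], 0.5)


def _loadings_given_psi(R: np.ndarray, psi: np.ndarray, m: int) -> np.ndarray:
    w, V = np.linalg.eigh(R - np.diag(psi))
    order = np.argsort(w)[::-1][:m]
    return V[:, order] * np.sqrt(np.clip(w[order], 0, None))


def efa(R: np.ndarray, n_factors: int) -> np.ndarray:
    """Minimum-residual (OLS) factor extraction on a correlation matrix.

    Returns the (p, m) unrotated loading matrix with each column signed so
    its largest-magnitude loading is positive.  Heywood cases (communality
    above 1) are clamped with a warning.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if not (1 <= n_factors < p):
        raise ValueError("n_factors must lie in [1, p)")
    off = ~np.eye(p, dtype=bool)

    def objective(psi):
        L = _loadings_given_psi(R, psi, n_factors)
        resid = R - L @ L.T
        return np.sum(resid[off] ** 2)

    psi0 = 1.0 - _smc(R)
    res = optimize.minimize(
        objective, psi0, method="L-BFGS-B",
        bounds=[(0.001, 1.0)] * p, options={"maxiter": 1000},
    )
    L = _loadings_given_psi(R, res.x, n_factors)
    h2 = np.sum(L**2, axis=1)
    if np.any(h2 > 1 + 1e-6):
        warnings.warn("Heywood case: communality above 1 clamped")
        scale = np.where(h2 > 1, np.sqrt(1.0 / h2), 1.0)
        L = L * scale[:, None]
    signs = np.sign(L[np.argmax(np.abs(L), axis=0), np.arange(n_factors)])
    signs[signs == 0] = 1.0
    return L * signs[None, :]


@dataclass
class EFASolution:
    loadings: np.ndarray          # rotated (p, m)
    factor_corr: np.ndarray       # (m, m)
    criterion: float
    explained_variance: np.ndarray
    converged: bool = True


def _geomin_criterion(L: np.ndarray, eps: float) -> tuple[float, np.ndarray]:
    """Geomin value and its gradient with respect to the loadings."""
    m = L.shape[1]
    L2 = L**2 + eps
    logs = np.log(L2)
    pro = np.exp(logs.sum(axis=1) / m)  # row-wise geometric mean
    f = pro.sum()
    G = (2.0 / m) * (L / L2) * pro[:, None]
    return f, G


def rotate_geomin(
    loadings: np.ndarray,
    epsilon: float = 0.01,
    n_starts: int = 10,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> EFASolution:
    """Oblique geomin rotation by the gradient projection algorithm.

    Runs from the identity plus seeded random starts and keeps the lowest
    criterion value.  For a single factor the rotation is the identity.
    """
    A = np.asarray(loadings, dtype=float)
    p, m = A.shape
    if m == 1:
        ev = np.array([np.sum(A**2) / p])
        f, _ = _geomin_criterion(A, epsilon)
        return EFASolution(A.copy(), np.eye(1), f, ev)
    rng = np.random.default_rng(seed)
    best = None
    starts = [np.eye(m)]
    for _ in range(max(0, n_starts - 1)):
        M = rng.normal(size=(m, m))
        starts.append(M / np.linalg.norm(M, axis=0, keepdims=True))
    for T0 in starts:
        sol = _gpf_oblique(A, T0, epsilon, max_iter, tol)
        if best is None or sol[2] < best[2]:
            best = sol
    L, Phi, f, converged = best
    if not converged:
        raise RuntimeError(f"geomin rotation failed to converge (criterion {f:.6g})")
    # sign convention: each factor's dominant loading positive
    signs = np.sign(L[np.argmax(np.abs(L), axis=0), np.arange(m)])
    signs[signs == 0] = 1.0
    L = L * signs[None, :]
    Phi = Phi * np.outer(signs, signs)
    ev = np.sum(L**2, axis=0) / p
    return EFASolution(L, Phi, f, ev, converged=converged)


def _gpf_oblique(A, T0, eps, max_iter, tol):
    """Gradient projection for oblique rotation (Bernaards & Jennrich)."""
    T = T0.copy()
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _geomin_criterion(L, eps)
    G = -((L.T @ Gq) @ Ti).T
    al = 1.0
    converged = False
    for _ in range(max_iter):
        Gp = G - T * np.sum(T * G, axis=0, keepdims=True)
        s = np.linalg.norm(Gp)
        if s < tol:
            converged = True
            break
        al *= 2.0
        for _ in range(60):
            X = T - al * Gp
            X = X / np.linalg.norm(X, axis=0, keepdims=True)
            Ti_t = np.linalg.inv(X)
            Lt = A @ Ti_t.T
            ft, Gq_t = _geomin_criterion(Lt, eps)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        T, Ti, L, f, Gq = X, Ti_t, Lt, ft, Gq_t
        G = -((L.T @ Gq) @ Ti).T
    Phi = T.T @ T
    return L, Phi, f, converged


def assign_items(loadings: np.ndarray, cutoff: float = 0.25) -> tuple[dict[int, list[int]], list[int]]:
    """Assign every item to each factor where |loading| >= cutoff.

    Returns (factor -> item indices, unassigned item indices).  Ties at
    exactly the cutoff are included.
    """
    L = np.asarray(loadings)
    p, m = L.shape
    structure: dict[int, list[int]] = {f: [] for f in range(m)}
    unassigned = []
    for i in range(p):
        hits = np.flatnonzero(np.abs(L[i]) >= cutoff)
        if hits.size == 0:
            unassigned.append(i)
        for f in hits:
            structure[int(f)].append(i)
    return structure, unassigned


# ---------------------------------------------------------------------------
# Second-order CFA (ULS on the correlation matrix, ML-form chi-square)

@dataclass
class FitIndices:
    chi2: float
    df: int
    cfi: float
    tli: float
    rmsea: float
    rmsea_ci: tuple[float, float]


@dataclass
class CFAEstimates:
    loadings: np.ndarray            # standardized first-order loadings (p, m)
    second_order: np.ndarray        # gamma_f, (m,)
    uniquenesses: np.ndarray        # (p,)
    sigma: np.ndarray               # model-implied correlation matrix
    structure: dict[int, list[int]]


def _cfa_unpack(params, structure, p, m):
    idx = 0
    L = np.zeros((p, m))
    for f in range(m):
        for i in structure[f]:
            L[i, f] = params[idx]
            idx += 1
    gamma = params[idx: idx + m]
    idx += m
    theta = params[idx: idx + p]
    return L, gamma, theta


def cfa_second_order(
    R: np.ndarray, structure: dict[int, list[int]], N: int
) -> tuple[CFAEstimates, FitIndices]:
    """Second-order CFA: items -> first-order factors -> one general factor.

    First-order factors are standardized with correlation matrix
    ``gamma gamma' + diag(1 - gamma^2)`` induced by the general factor.
    Estimated by minimising the ULS discrepancy over all unique elements
    of ``R``; chi-square is the ML discrepancy at the ULS solution times
    (N - 1), compared against the independence baseline.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    m = len(structure)
    for f, items in structure.items():
        if len(items) < 2:
            raise ValueError(f"first-order factor {f} has fewer than 2 indicators")
    n_load = sum(len(v) for v in structure.values())

    iu = np.triu_indices(p)

    def implied(params):
        L, gamma, theta = _cfa_unpack(params, structure, p, m)
        g = np.clip(gamma, -0.999, 0.999)
        Phi = np.outer(g, g) + np.diag(1.0 - g**2)
        S = L @ Phi @ L.T + np.diag(np.clip(theta, 1e-3, None))
        return S

    def resid(params):
        S = implied(params)
        return (R - S)[iu]

    x0 = np.concatenate([
        np.full(n_load, 0.6), np.full(m, 0.7), np.full(p, 0.5),
    ])
    lb = np.concatenate([np.full(n_load, -1.5), np.full(m, -0.999), np.full(p, 1e-3)])
    ub = np.concatenate([np.full(n_load, 1.5), np.full(m, 0.999), np.full(p, 1.0)])
    res = optimize.least_squares(resid, x0, bounds=(lb, ub), xtol=1e-10, ftol=1e-12)
    if not res.success and res.cost > 1e-4:
        raise RuntimeError(f"second-order CFA did not converge: {res.message}")
    L, gamma, theta = _cfa_unpack(res.x, structure, p, m)
    gamma = np.clip(gamma, -0.999, 0.999)
    Sigma = implied(res.x)

    # sign convention: general factor loads positively; factor columns
    # dominated by positive loadings
    for f in range(m):
        col = L[:, f]
        if col[np.argmax(np.abs(col))] < 0:
            L[:, f] = -col
            gamma[f] = -gamma[f]
    if np.sum(gamma) < 0:
        gamma = -gamma

    d = np.sqrt(np.diag(Sigma))
    L_std = L / d[:, None]

    # ML-form chi-square at the ULS solution
    sign_m, logdet_S = np.linalg.slogdet(Sigma)
    sign_r, logdet_R = np.linalg.slogdet(R)
    if sign_m <= 0 or sign_r <= 0:
        raise RuntimeError("non-positive-definite matrix in chi-square evaluation")
    F_ml = logdet_S - logdet_R + np.trace(R @ np.linalg.inv(Sigma)) - p
    chi2_m = max((N - 1) * F_ml, 0.0)
    df_m = p * (p + 1) // 2 - (n_load + m + p)
    chi2_b = max(-(N - 1) * logdet_R + (N - 1) * (np.trace(R) - p), 0.0)
    df_b = p * (p - 1) // 2
    fi = fit_indices(chi2_m, df_m, chi2_b, df_b, N)
    est = CFAEstimates(
        loadings=L_std, second_order=gamma,
        uniquenesses=np.clip(theta, 1e-3, None), sigma=Sigma, structure=structure,
    )
    return est, fi


def fit_indices(chi2_m: float, df_m: int, chi2_b: float, df_b: int, N: int) -> FitIndices:
    """CFI, TLI and RMSEA (point and 90% CI) from model/baseline chi-squares."""
    if df_m <= 0 or df_b <= 0 or N <= 1:
        raise ValueError("df and N must be positive (N > 1)")
    num = max(chi2_m - df_m, 0.0)
    den = max(chi2_b - df_b, chi2_m - df_m, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den
    rb = chi2_b / df_b
    rm = chi2_m / df_m
    tli = 1.0 if rb <= 1.0 else (rb - rm) / (rb - 1.0)
    tli = float(np.clip(tli, 0.0, 1.0))
    cfi = float(np.clip(cfi, 0.0, 1.0))
    rmsea = float(np.sqrt(num / (df_m * (N - 1))))

    def _ncp_bound(target):
        # smallest/largest noncentrality with cdf(chi2; df, ncp) == target
        if chi2_m <= df_m:
            return 0.0
        f = lambda lam: ncx2.cdf(chi2_m, df_m, lam) - target
        hi = max(chi2_m * 2, 10.0)
        while f(hi) > 0 and hi < 1e8:
            hi *= 2
        if f(0) < target - 1:  # pragma: no cover - defensive
            return 0.0
        try:
            return float(optimize.brentq(f, 0.0, hi))
        except ValueError:
            return 0.0

    lo_ncp = _ncp_bound(0.95)
    hi_ncp = _ncp_bound(0.05)
    ci = (
        float(np.sqrt(lo_ncp / (df_m * (N - 1)))),
        float(np.sqrt(hi_ncp / (df_m * (N - 1)))),
    )
    ci = (min(ci[0], rmsea), max(ci[1], rmsea))
    return FitIndices(chi2=float(chi2_m), df=int(df_m), cfi=cfi, tli=tli,
                      rmsea=rmsea, rmsea_ci=ci)


def explained_variance(R: np.ndarray, n_factors: int) -> np.ndarray:
    """Proportion of total variance per retained principal component:
    eigenvalue / p for the first ``n_factors`` eigenvalues."""
    w = np.sort(np.linalg.eigvalsh(np.asarray(R, dtype=float)))[::-1]
    p = R.shape[0]
    return w[:n_factors] / p
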