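"""Sparse finite-mixture accelerated-failure-time survival modelling.

Stage 1 screens high-dimensional promoter-methylation covariates with
correlation-adjusted regression survival (CARS) scores adapted to right
censoring by inverse-probability-of-censoring (IPC) weighting. Stage 2 fits a
K-component mixture of log-normal AFT regressions by penalized EM: event
subjects contribute the normal density of log time, censored subjects the
survival function, and censored latent log-times are imputed by their
truncated-normal conditional moments inside each component. Sparsity comes
from a component-wise penalty n * pi_k * sum_j p_lambda(|beta_kj|) solved by
coordinate-descent soft-thresholding (local linear approximation for
SCAD/MCP); the order K is selected by BIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from numba import njit
from scipy import stats
from scipy.optimize import brentq
from scipy.special import log_ndtr, logsumexp
from sklearn.cluster import KMeans

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def _norm_logpdf(z):
    return -0.5 * z * z - _LOG_SQRT_2PI


def _norm_logsf(z):
    return log_ndtr(-z)

from .simulate import SurvivalDataset
from .types import ValidationError

__all__ = ["CARSScores", "cars_screen", "mixture_loglik", "EMConfig",
           "MixtureAFTFit", "fit_fm_aft", "select_order",
           "posterior_membership", "presmooth_density"]


# ------------------------------------------------------------- screening

@dataclass
class CARSScores:
    scores: np.ndarray
    threshold: float
    selected: np.ndarray          # indices, |selected| = ceil((1-q) d) within ties
    covariate_names: list


def _ipc_weights(time, status, g_floor: float = 0.2):
    """Inverse-probability-of-censoring weights from the Kaplan-Meier
    estimate of the censoring distribution; censored subjects get weight 0.

    The censoring-survival estimate is truncated below at ``g_floor`` (the
    usual IPCW stabilization) so late events cannot receive explosive
    weights.
    """
    km = KaplanMeierFitter()
    km.fit(time, event_observed=1 - status)
    g = km.survival_function_at_times(time * (1 - 1e-10)).to_numpy()
    g = np.clip(g, g_floor, None)
    w = status / g
    if w.sum() == 0:
        raise ValidationError("IPC weighting needs at least one event")
    return w / w.sum()


def _weighted_corr(X, y, w):
    mx = X.T @ w
    my = float(y @ w)
    Xc = X - mx
    yc = y - my
    cov = (Xc * w[:, None]).T @ yc
    vx = np.einsum("ij,i,ij->j", Xc, w, Xc)
    vy = float(yc @ (w * yc))
    return cov / np.sqrt(np.clip(vx * vy, 1e-300, None))


def _shrink_correlation(Z, R):
    """Schaefer-Strimmer shrinkage of the correlation matrix toward the
    identity, with the analytic intensity lambda* = sum Var(r_ij) / sum
    r_ij^2 over off-diagonal entries (estimated from the data products)."""
    n = Z.shape[0]
    Zs = Z * math.sqrt(n / (n - 1))
    P = Zs.T @ Zs / n                   # ~ r_ij
    P2 = (Zs ** 2).T @ (Zs ** 2) / n    # mean of squared products
    var_r = n / (n - 1) ** 2 * (P2 - P ** 2)
    off = ~np.eye(Z.shape[1], dtype=bool)
    denom = float(np.sum(R[off] ** 2))
    lam = 1.0 if denom == 0 else float(np.clip(np.sum(var_r[off]) / denom, 0.0, 1.0))
    Rs = (1.0 - lam) * R
    np.fill_diagonal(Rs, 1.0)
    return Rs


def cars_screen(data: SurvivalDataset, quantile: float = 0.95,
                shrink: bool = True) -> CARSScores:
    """Correlation-adjusted regression survival scores.

    The design is decorrelated by the inverse square root of the
    (Schaefer-Strimmer shrunk) correlation matrix — a Mahalanobis-type
    transform — and scores are
    the squared IPC-weighted correlations of the decorrelated covariates with
    log observed time. Covariates above the ``quantile`` of the score
    distribution (the top ceil((1-q) d) by rank) are selected.
    """
    X, d = data.X, data.d
    if d < 2:
        raise ValidationError("screening needs at least two covariates")
    w = _ipc_weights(data.time, data.status)
    r = _weighted_corr(X, data.log_time, w)

    sd = X.std(axis=0, ddof=1)
    Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    R = np.corrcoef(Z, rowvar=False)
    if shrink:
        R = _shrink_correlation(Z, R)
    vals, vecs = np.linalg.eigh(R)
    if not shrink and vals.min() < 1e-10:
        raise ValidationError(
            "correlation matrix is singular; rerun with shrink=True")
    inv_sqrt = vecs @ np.diag(1.0 / np.sqrt(np.clip(vals, 1e-12, None))) @ vecs.T
    omega = inv_sqrt @ r
    scores = omega ** 2

    k = max(1, int(math.ceil((1.0 - quantile) * d - 1e-9)))
    order = np.argsort(scores)[::-1]
    threshold = float(scores[order[k - 1]])
    selected = np.sort(order[:k])
    return CARSScores(scores=scores, threshold=threshold, selected=selected,
                      covariate_names=list(data.covariate_names))


# ---------------------------------------------------------- mixture AFT

@dataclass
class EMConfig:
    max_iter: int = 200
    tol: float = 1e-6             # relative change of the penalized objective
    zero_tol: float = 1e-5        # coefficients below this are set exactly to 0
    cd_iter: int = 25             # coordinate-descent sweeps per M-step
    n_starts: int = 2             # EM starts (k-means inits with distinct seeds)
    kmeans_restarts: int = 5
    min_component: float = 4.0    # minimum expected component occupancy
    max_restarts: int = 3
    sigma_floor: float = 0.05     # guards the unbounded-likelihood degeneracy
    scad_a: float = 3.7
    mcp_a: float = 3.0


@dataclass
class MixtureAFTFit:
    K: int
    pi: np.ndarray
    intercepts: np.ndarray
    betas: np.ndarray             # K x d, exact zeros for pruned effects
    sigmas: np.ndarray
    lambdas: np.ndarray
    loglik: float                 # observed-data, unpenalized
    bic: float
    tau: np.ndarray               # n x K posterior memberships
    labels: np.ndarray
    penalty: str
    converged: bool
    n_restarts: int = 0
    covariate_names: list = field(default_factory=list)

    @property
    def df(self) -> int:
        return int(np.sum(self.betas != 0) + 2 * self.K + (self.K - 1))

    def coefficient_table(self) -> pd.DataFrame:
        cols = {"coef": ["Intercept"] + list(self.covariate_names)}
        for k in range(self.K):
            cols[f"beta_{k+1}"] = np.concatenate(
                ([self.intercepts[k]], self.betas[k]))
        return pd.DataFrame(cols)


def _penalty_value(b_abs, lam, weights, kind, cfg: EMConfig):
    """p_lambda(|beta|) summed over coefficients (per component)."""
    if lam == 0:
        return 0.0
    if kind in ("lasso", "adaptive_lasso"):
        return float(np.sum(lam * weights * b_abs))
    if kind == "scad":
        a, l = cfg.scad_a, lam
        out = np.where(b_abs <= l, l * b_abs,
                       np.where(b_abs <= a * l,
                                (2 * a * l * b_abs - b_abs ** 2 - l ** 2) / (2 * (a - 1)),
                                l ** 2 * (a + 1) / 2))
        return float(out.sum())
    if kind == "mcp":
        a, l = cfg.mcp_a, lam
        out = np.where(b_abs <= a * l, l * b_abs - b_abs ** 2 / (2 * a),
                       a * l ** 2 / 2)
        return float(out.sum())
    raise ValidationError(f"unknown penalty {kind!r}")


def _penalty_deriv(b_abs, lam, weights, kind, cfg: EMConfig):
    """p'_lambda(|beta|), the LLA weight for the next coordinate-descent pass."""
    if lam == 0:
        return np.zeros_like(b_abs)
    if kind in ("lasso", "adaptive_lasso"):
        return lam * weights * np.ones_like(b_abs)
    if kind == "scad":
        a, l = cfg.scad_a, lam
        return np.where(b_abs <= l, l,
                        np.maximum(a * l - b_abs, 0.0) / (a - 1))
    if kind == "mcp":
        a, l = cfg.mcp_a, lam
        return np.maximum(l - b_abs / a, 0.0)
    raise ValidationError(f"unknown penalty {kind!r}")


def _component_logdens(data: SurvivalDataset, intercepts, betas, sigmas):
    """n x K matrix of log f^delta * S^(1-delta) on the log-time scale."""
    y = data.log_time
    mu = intercepts[None, :] + data.X @ betas.T
    z = (y[:, None] - mu) / sigmas[None, :]
    ev = data.status[:, None].astype(bool)
    out = np.where(ev, _norm_logpdf(z) - np.log(sigmas)[None, :],
                   _norm_logsf(z))
    return out, mu


def mixture_loglik(pi, intercepts, betas, sigmas, data: SurvivalDataset) -> float:
    """Observed-data log-likelihood of the censored log-normal mixture.

    Events contribute the normal density of log time (the constant 1/t
    Jacobian is dropped, shifting the value by an additive constant that does
    not depend on parameters); censored subjects contribute the normal
    survival function at their censoring log time.
    """
    pi = np.asarray(pi, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    if np.any(sigmas <= 0):
        raise ValidationError("sigmas must be positive")
    ld, _ = _component_logdens(data, np.asarray(intercepts, float),
                               np.atleast_2d(betas), sigmas)
    return float(np.sum(logsumexp(np.log(np.clip(pi, 1e-300, None))[None, :] + ld,
                                  axis=1)))


def _e_step(data, pi, intercepts, betas, sigmas):
    ld, mu = _component_logdens(data, intercepts, betas, sigmas)
    lw = np.log(np.clip(pi, 1e-300, None))[None, :] + ld
    ll = logsumexp(lw, axis=1)
    tau = np.exp(lw - ll[:, None])
    # truncated-normal conditional moments for censored latent log-times
    y = data.log_time
    z = (y[:, None] - mu) / sigmas[None, :]
    lam = np.exp(_norm_logpdf(z) - _norm_logsf(z))  # hazard of N(0,1)
    m1 = mu + sigmas[None, :] * lam
    v = sigmas[None, :] ** 2 * np.clip(1.0 + z * lam - lam ** 2, 1e-12, None)
    ev = data.status[:, None].astype(bool)
    zhat = np.where(ev, y[:, None], m1)
    vhat = np.where(ev, 0.0, v)
    return tau, zhat, vhat, float(ll.sum())


def _pi_update(tk, n, pen_k):
    """Maximize sum_k t_k log pi_k - n sum_k pi_k c_k on the simplex."""
    if np.allclose(pen_k, pen_k[0]):
        return tk / tk.sum()
    c = n * (pen_k - pen_k.min())

    def g(mu):
        return np.sum(tk / (mu + c)) - 1.0

    lo = 1e-12
    hi = tk.sum() + c.max() + 1.0
    while g(hi) > 0:
        hi *= 2
    mu = brentq(g, lo, hi)
    pi = tk / (mu + c)
    return pi / pi.sum()


@njit(cache=True)
def _cd_kernel(X, w, r, beta, b0, thr, denom, n_sweeps):
    """Penalized weighted least squares by cyclic coordinate descent with
    soft thresholding; residual ``r`` and ``beta`` are updated in place."""
    n, d = X.shape
    sw = 0.0
    for i in range(n):
        sw += w[i]
    for _ in range(n_sweeps):
        delta = 0.0
        acc = 0.0
        for i in range(n):
            acc += w[i] * r[i]
        shift = acc / sw
        if shift != 0.0:
            for i in range(n):
                r[i] -= shift
            b0 += shift
            delta = abs(shift)
        for j in range(d):
            if denom[j] <= 0.0:
                continue
            rho = denom[j] * beta[j]
            for i in range(n):
                rho += w[i] * X[i, j] * r[i]
            a = abs(rho) - thr[j]
            if a <= 0.0:
                bj = 0.0
            elif rho > 0.0:
                bj = a / denom[j]
            else:
                bj = -a / denom[j]
            diff = bj - beta[j]
            if diff != 0.0:
                for i in range(n):
                    r[i] -= X[i, j] * diff
                if abs(diff) > delta:
                    delta = abs(diff)
                beta[j] = bj
        if delta < 1e-8:
            break
    return b0


def _m_step(data, tau, zhat, vhat, pi, intercepts, betas, sigmas,
            lambdas, weights, penalty, cfg: EMConfig):
    X, n, d = data.X, data.n, data.d
    K = tau.shape[1]
    pen_k = np.array([
        _penalty_value(np.abs(betas[k]), lambdas[k], weights[k], penalty, cfg)
        for k in range(K)])
    pi = _pi_update(tau.sum(axis=0), n, pen_k)

    xsq = X ** 2
    for k in range(K):
        w = tau[:, k]
        sw = w.sum()
        z = zhat[:, k]
        beta = betas[k].copy()
        sig2 = sigmas[k] ** 2
        # LLA weights at the current coefficients
        omega = _penalty_deriv(np.abs(beta), lambdas[k], weights[k], penalty, cfg)
        r = z - intercepts[k] - X @ beta
        denom = w @ xsq              # per-coordinate curvature
        thr = n * pi[k] * sig2 * omega
        intercepts[k] = _cd_kernel(X, w, r, beta, float(intercepts[k]),
                                   thr, denom, cfg.cd_iter)
        beta[np.abs(beta) < cfg.zero_tol] = 0.0
        r = z - intercepts[k] - X @ beta
        betas[k] = beta
        sig2_new = (w @ (r ** 2) + w @ vhat[:, k]) / sw
        sigmas[k] = max(math.sqrt(max(sig2_new, 1e-12)), cfg.sigma_floor)
    return pi, intercepts, betas, sigmas


def _penalized_objective(data, pi, intercepts, betas, sigmas, lambdas,
                         weights, penalty, cfg):
    ll = mixture_loglik(pi, intercepts, betas, sigmas, data)
    pen = sum(pi[k] * _penalty_value(np.abs(betas[k]), lambdas[k], weights[k],
                                     penalty, cfg)
              for k in range(len(pi)))
    return ll - data.n * pen, ll


def _kmeans_init(data, K, seed, cfg):
    feats = np.column_stack([data.log_time, data.status.astype(float)])
    feats = (feats - feats.mean(axis=0)) / np.clip(feats.std(axis=0), 1e-12, None)
    if K == 1:
        return np.zeros(data.n, dtype=int)
    km = KMeans(n_clusters=K, n_init=cfg.kmeans_restarts, random_state=seed)
    labels = km.fit_predict(feats)
    # canonical: order clusters by mean log-time so starts are comparable
    means = [data.log_time[labels == k].mean() if np.any(labels == k) else np.inf
             for k in range(K)]
    order = np.argsort(means)
    remap = np.empty(K, dtype=int)
    remap[order] = np.arange(K)
    return remap[labels]


def _canonicalize(fit_tuple):
    """Order components by ascending intercept (component 1 = shortest survival)."""
    pi, b0, betas, sigmas, lambdas, tau = fit_tuple
    order = np.argsort(b0)
    return (pi[order], b0[order], betas[order], sigmas[order], lambdas[order],
            tau[:, order])


def _run_em(data, K, lambdas, weights, penalty, cfg, seed,
            init=None, track=None):
    rng = np.random.default_rng(seed)
    n, d = data.n, data.d
    n_restarts = 0
    attempt_seed = seed
    while True:
        if init is not None and n_restarts == 0:
            pi, b0, betas, sigmas = (x.copy() for x in init)
        else:
            labels = _kmeans_init(data, K, attempt_seed % (2**31 - 1), cfg)
            pi = np.full(K, 1.0 / K)
            b0 = np.empty(K)
            sigmas = np.empty(K)
            betas = np.zeros((K, d))
            for k in range(K):
                sel = labels == k
                if sel.sum() < 2:
                    sel = np.ones(n, dtype=bool)
                b0[k] = data.log_time[sel].mean()
                sigmas[k] = max(data.log_time[sel].std(), 0.2)
            jitter = rng.normal(0, 0.05 * (1 + n_restarts), K)
            b0 = b0 + jitter

        obj_prev = -np.inf
        converged = False
        empty = False
        for _ in range(cfg.max_iter):
            tau, zhat, vhat, _ = _e_step(data, pi, b0, betas, sigmas)
            if np.any(tau.sum(axis=0) < cfg.min_component):
                empty = True
                break
            pi, b0, betas, sigmas = _m_step(data, tau, zhat, vhat, pi, b0,
                                            betas, sigmas, lambdas, weights,
                                            penalty, cfg)
            obj, ll = _penalized_objective(data, pi, b0, betas, sigmas,
                                           lambdas, weights, penalty, cfg)
            if track is not None:
                track.append(obj)
            if obj_prev > -np.inf and abs(obj - obj_prev) <= cfg.tol * (abs(obj_prev) + 1):
                converged = True
                obj_prev = obj
                break
            obj_prev = obj
        if empty and n_restarts < cfg.max_restarts:
            n_restarts += 1
            attempt_seed = attempt_seed * 7919 + 13
            init = None
            continue
        break

    tau, _, _, ll = _e_step(data, pi, b0, betas, sigmas)
    pi, b0, betas, sigmas, lambdas_c, tau = _canonicalize(
        (pi, b0, betas, sigmas, np.asarray(lambdas, float), tau))
    ll = mixture_loglik(pi, b0, betas, sigmas, data)
    return dict(pi=pi, intercepts=b0, betas=betas, sigmas=sigmas,
                lambdas=lambdas_c, loglik=ll, tau=tau, converged=converged,
                n_restarts=n_restarts)


def _bic_from(res, data):
    df = int(np.sum(res["betas"] != 0) + 2 * len(res["pi"]) + (len(res["pi"]) - 1))
    return -2.0 * res["loglik"] + df * math.log(data.n)


def _adaptive_weights(data, K, penalty, cfg, seed):
    """Pilot (unpenalized) fit supplying adaptive-lasso weights."""
    d = data.d
    if penalty != "adaptive_lasso":
        return np.ones((K, d)), None
    zero_l = np.zeros(K)
    pilot = _run_em(data, K, zero_l, np.ones((K, d)), "lasso", cfg, seed)
    w = 1.0 / np.clip(np.abs(pilot["betas"]), 1e-3, None)
    init = (pilot["pi"], pilot["intercepts"], pilot["betas"], pilot["sigmas"])
    return w, init


DEFAULT_LAMBDA_GRID = tuple(np.geomspace(0.01, 0.5, 6))


def fit_fm_aft(data: SurvivalDataset, K: int, penalty: str = "adaptive_lasso",
               lambda_grid=DEFAULT_LAMBDA_GRID, em_config: EMConfig | None = None,
               seed: int = 0, refine_lambda: bool = True) -> MixtureAFTFit:
    """Penalized EM fit of the K-component censored log-normal AFT mixture.

    The tuning parameter is chosen on ``lambda_grid`` by BIC: first a common
    lambda across components, then (``refine_lambda``) one component-wise
    refinement sweep over the same grid. Multi-start k-means initialization;
    components are reported in ascending-intercept order.
    """
    if K < 1:
        raise ValidationError("K must be >= 1")
    if penalty not in ("lasso", "adaptive_lasso", "scad", "mcp"):
        raise ValidationError(f"unsupported penalty {penalty!r}")
    cfg = em_config or EMConfig()
    weights, warm = _adaptive_weights(data, K, penalty, cfg, seed)

    grid = [0.0] if not len(lambda_grid) else list(lambda_grid)
    best = None
    for lam in grid:
        lambdas = np.full(K, float(lam))
        cand = []
        for s in range(cfg.n_starts):
            res = _run_em(data, K, lambdas, weights, penalty, cfg,
                          seed + 1009 * s, init=warm if s == 0 else None)
            obj, _ = _penalized_objective(data, res["pi"], res["intercepts"],
                                          res["betas"], res["sigmas"], lambdas,
                                          weights, penalty, cfg)
            cand.append((obj, res))
        res = max(cand, key=lambda c: c[0])[1]
        bic = _bic_from(res, data)
        if best is None or bic < best[0]:
            best = (bic, lambdas, res)

    if refine_lambda and K > 1:
        bic_best, lambdas, res = best
        for k in range(K):
            for lam in grid:
                trial = lambdas.copy()
                trial[k] = float(lam)
                if np.allclose(trial, lambdas):
                    continue
                init = (res["pi"], res["intercepts"], res["betas"], res["sigmas"])
                r2 = _run_em(data, K, trial, weights, penalty, cfg, seed, init=init)
                b2 = _bic_from(r2, data)
                if b2 < bic_best:
                    bic_best, lambdas, res = b2, trial, r2
        best = (bic_best, lambdas, res)

    bic, lambdas, res = best
    return MixtureAFTFit(
        K=K, pi=res["pi"], intercepts=res["intercepts"], betas=res["betas"],
        sigmas=res["sigmas"], lambdas=res["lambdas"], loglik=res["loglik"],
        bic=bic, tau=res["tau"], labels=res["tau"].argmax(axis=1),
        penalty=penalty, converged=res["converged"],
        n_restarts=res["n_restarts"], covariate_names=list(data.covariate_names))


def select_order(data: SurvivalDataset, k_range=range(1, 8),
                 penalty: str = "adaptive_lasso", lambda_grid=DEFAULT_LAMBDA_GRID,
                 em_config: EMConfig | None = None, seed: int = 0):
    """Fit every order in ``k_range`` and return (best_K, {K: fit}).

    The order with the lowest BIC wins.
    """
    fits = {}
    for K in k_range:
        fits[K] = fit_fm_aft(data, K, penalty=penalty, lambda_grid=lambda_grid,
                             em_config=em_config, seed=seed)
    best_k = min(fits, key=lambda K: fits[K].bic)
    return best_k, fits


def posterior_membership(fit: MixtureAFTFit, data: SurvivalDataset):
    """Final-E-step memberships, hard labels, and per-status summaries."""
    tau, _, _, _ = _e_step(data, fit.pi, fit.intercepts, fit.betas, fit.sigmas)
    labels = tau.argmax(axis=1)
    rows = []
    for s, name in ((1, "event"), (0, "censored")):
        sel = data.status == s
        if sel.any():
            for k in range(fit.K):
                rows.append((name, k + 1, float(tau[sel, k].mean()),
                             int(np.sum(labels[sel] == k))))
    summary = pd.DataFrame(rows, columns=["status", "component",
                                          "mean_tau", "n_hard"])
    return tau, labels, summary


def presmooth_density(times, status, grid=None, bw: str | float = "scott"):
    """Censoring-aware kernel density of observed event times.

    Events are weighted by inverse probability of censoring; the result is
    renormalized to integrate to 1 on the grid.
    """
    times = np.asarray(times, dtype=float)
    status = np.asarray(status, dtype=np.int64)
    if times.shape[0] < 20:
        raise ValidationError("density estimate needs n >= 20")
    if status.sum() == 0:
        raise ValidationError("all observations censored; no density estimate")
    w = _ipc_weights(times, status)
    ev = status == 1
    kde = stats.gaussian_kde(times[ev], weights=w[ev], bw_method=bw)
    if grid is None:
        grid = np.linspace(0.0, times.max() * 1.2, 512)
    dens = kde(grid)
    area = np.trapezoid(dens, grid)
    return grid, dens / area
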