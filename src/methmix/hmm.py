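"""Penalized trans-dimensional HMM smoothing of per-sample methylation levels.

One chain per sample: hidden states ``s_l`` index K latent methylation levels
``theta_1 < ... < theta_K``; the methylated read count at site ``l`` is
Binomial(depth, theta_{s_l}). The chain jointly samples the order K (via a
reversible-jump split-merge move), the parameters (conjugate Gibbs updates)
and the hidden path (forward-filtering backward-sampling). Two penalties
steer the order: neighbouring propensities closer than ``collapse_tol`` are
merged deterministically (over-fit control), and the split-proposal weight is
boosted when the within-state binomial deviance exceeds a parametric
bootstrap reference (under-fit control). Missing sites contribute emission
factor 1, so smoothing never drops partially observed positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, xlogy

from ._hmm_kernels import ffbs, forward_loglik, state_posteriors
from .types import (HMMHyper, HMMParameterState, MCMCConfig, MethylationPanel,
                    SmoothedProfile, ValidationError)

__all__ = [
    "complete_data_loglik", "marginal_loglik", "gibbs_sweep",
    "split_merge_move", "apply_penalties", "smooth_sample", "smooth_panel",
    "transition_counts", "forward_posteriors",
]


# ---------------------------------------------------------------- utilities

def _obs_mask(y, m, missing):
    if missing is None:
        return np.ones(y.shape[0], dtype=bool)
    return ~np.asarray(missing, dtype=bool)


def _log_emission(y, m, obs, thetas, with_binom=False):
    """(L, K) log emission matrix; missing rows are identically 0."""
    th = np.clip(thetas, 1e-300, 1 - 1e-16)
    le = np.zeros((y.shape[0], th.shape[0]))
    yo = y[obs].astype(float)
    mo = m[obs].astype(float)
    le[obs] = yo[:, None] * np.log(th)[None, :] + (mo - yo)[:, None] * np.log1p(-th)[None, :]
    if with_binom:
        le[obs] += (gammaln(mo + 1) - gammaln(yo + 1) - gammaln(mo - yo + 1))[:, None]
    return le


def _scaled_emission(y, m, obs, thetas, with_binom=False):
    le = _log_emission(y, m, obs, thetas, with_binom=with_binom)
    scale = le.max(axis=1)
    return np.exp(le - scale[:, None]), scale


def transition_counts(states, K):
    """(K+1) x K count matrix; row 0 is the initial-state indicator."""
    n = np.zeros((K + 1, K), dtype=np.int64)
    n[0, states[0]] = 1
    if states.shape[0] > 1:
        np.add.at(n, (states[:-1] + 1, states[1:]), 1)
    return n


def _check_states(states, K):
    states = np.asarray(states, dtype=np.int64)
    if states.size and (states.min() < 0 or states.max() >= K):
        raise ValidationError("state path contains labels outside 0..K-1")
    return states


def _log_dirichlet(x, alpha):
    x = np.clip(np.asarray(x, dtype=float), 1e-300, None)
    alpha = np.asarray(alpha, dtype=float)
    return (gammaln(alpha.sum()) - gammaln(alpha).sum()
            + np.sum((alpha - 1) * np.log(x)))


def _log_beta_pdf(x, a, b):
    return ((a - 1) * math.log(x) + (b - 1) * math.log1p(-x)
            + gammaln(a + b) - gammaln(a) - gammaln(b))


def _sort_relabel_arrays(thetas, trans, states):
    """Canonical form: thetas ascending, states and trans permuted to match."""
    perm = np.argsort(thetas, kind="stable")
    if np.array_equal(perm, np.arange(thetas.shape[0])):
        return thetas, trans, states
    inv = np.empty_like(perm)
    inv[perm] = np.arange(thetas.shape[0])
    new_trans = np.empty_like(trans)
    new_trans[0] = trans[0][perm]
    new_trans[1:] = trans[1:][perm][:, perm]
    return thetas[perm], new_trans, inv[states]


# ---------------------------------------------------------- likelihoods

def complete_data_loglik(params: HMMParameterState, states, y, m, missing=None) -> float:
    """Joint log-likelihood of counts and a given hidden path.

    Product of binomial emissions over observed sites (missing sites
    contribute factor 1) times the initial/transition probabilities of the
    path.
    """
    states = _check_states(states, params.K)
    y = np.asarray(y, dtype=np.int64)
    m = np.asarray(m, dtype=np.int64)
    obs = _obs_mask(y, m, missing)
    th = params.thetas[states[obs]]
    yo, mo = y[obs].astype(float), m[obs].astype(float)
    ll = float(np.sum(gammaln(mo + 1) - gammaln(yo + 1) - gammaln(mo - yo + 1)
                      + xlogy(yo, th) + xlogy(mo - yo, 1 - th)))
    n = transition_counts(states, params.K)
    with np.errstate(divide="ignore"):
        lt = np.where(n > 0, np.log(np.clip(params.trans, 1e-300, None)), 0.0)
    ll += float(np.sum(n * lt))
    return ll


def marginal_loglik(params: HMMParameterState, y, m, missing=None) -> float:
    """log p(y | params): forward algorithm marginalizing the hidden path.

    Missing sites pass probability through unchanged, so appending a fully
    missing site leaves the value fixed.
    """
    y = np.asarray(y, dtype=np.int64)
    m = np.asarray(m, dtype=np.int64)
    obs = _obs_mask(y, m, missing)
    emit, scale = _scaled_emission(y, m, obs, params.thetas, with_binom=True)
    return float(forward_loglik(emit, scale, params.trans[0].copy(),
                                params.trans[1:].copy()))


def forward_posteriors(params: HMMParameterState, y, m, missing=None) -> np.ndarray:
    """Exact per-site state posteriors p(s_l | y) via forward-backward."""
    y = np.asarray(y, dtype=np.int64)
    m = np.asarray(m, dtype=np.int64)
    obs = _obs_mask(y, m, missing)
    emit, _ = _scaled_emission(y, m, obs, params.thetas)
    return state_posteriors(emit, params.trans[0].copy(), params.trans[1:].copy())


# ---------------------------------------------------------------- Gibbs

def gibbs_sweep(params: HMMParameterState, states, y, m, rng, missing=None,
                resample_states=True):
    """One conjugate sweep: theta | s, trans | s, then s | theta, trans (FFBS),
    finishing with the ascending-theta relabelling."""
    states = _check_states(states, params.K)
    y = np.asarray(y, dtype=np.int64)
    m = np.asarray(m, dtype=np.int64)
    obs = _obs_mask(y, m, missing)
    K, hyper = params.K, params.hyper

    s_obs = states[obs]
    ty = np.bincount(s_obs, weights=y[obs], minlength=K)
    tm = np.bincount(s_obs, weights=m[obs], minlength=K)
    thetas = rng.beta(hyper.alpha + ty, hyper.beta + (tm - ty))
    thetas = np.clip(thetas, 1e-12, 1 - 1e-12)

    counts = transition_counts(states, K)
    trans = np.empty((K + 1, K))
    for r in range(K + 1):
        trans[r] = rng.dirichlet(hyper.gamma + counts[r])
    trans = np.clip(trans, 1e-300, None)
    trans /= trans.sum(axis=1, keepdims=True)

    if resample_states:
        emit, _ = _scaled_emission(y, m, obs, thetas)
        states = ffbs(emit, trans[0].copy(), trans[1:].copy(), rng.random(y.shape[0]))
    thetas, trans, states = _sort_relabel_arrays(thetas, trans, states)
    return HMMParameterState(K, thetas, trans, hyper), states


# ------------------------------------------------------------ split-merge

def _split_umax(thetas, j):
    """Largest admissible split half-width for state j: half the gap to each
    neighbouring theta (so the ascending order is preserved), clipped so both
    offspring stay inside (0,1)."""
    K = thetas.shape[0]
    left = (thetas[j] - thetas[j - 1]) / 2.0 if j > 0 else np.inf
    right = (thetas[j + 1] - thetas[j]) / 2.0 if j < K - 1 else np.inf
    return float(min(left, right, thetas[j], 1.0 - thetas[j]))


def _log_trans_proposal(trans, states, K, gamma):
    """log density of drawing ``trans`` from its Dirichlet full conditional
    given the path ``states`` (rows are independent)."""
    counts = transition_counts(states, K)
    return sum(_log_dirichlet(trans[r], gamma + counts[r]) for r in range(K + 1))


def _log_prior(params: HMMParameterState):
    h = params.hyper
    lp = gammaln(params.K + 1)  # ordered-theta factor K!
    lp += sum(_log_beta_pdf(t, h.alpha, h.beta) for t in params.thetas)
    flat = np.full(params.K, h.gamma)
    lp += sum(_log_dirichlet(params.trans[r], flat) for r in range(params.K + 1))
    return float(lp)


def _alloc_logprobs(y, m, obs, theta_lo, theta_hi):
    """Per-site log allocation probabilities between two offspring states.

    Sites are assigned to the offspring with probability proportional to the
    binomial emission under each theta (missing sites: 1/2 each); returns
    (log p_lo, log p_hi) vectors over all sites.
    """
    th = np.clip(np.array([theta_lo, theta_hi]), 1e-12, 1 - 1e-12)
    le = np.zeros((y.shape[0], 2))
    yo = y[obs].astype(float)
    mo = m[obs].astype(float)
    le[obs] = yo[:, None] * np.log(th)[None, :] + (mo - yo)[:, None] * np.log1p(-th)[None, :]
    mx = le.max(axis=1, keepdims=True)
    le -= mx + np.log(np.exp(le - mx).sum(axis=1, keepdims=True))
    return le[:, 0], le[:, 1]


def _move_probs(K, k_max, split_boost):
    w_split = split_boost if K < k_max else 0.0
    w_merge = 1.0 if K > 1 else 0.0
    tot = w_split + w_merge
    if tot == 0.0:
        return 0.0, 0.0
    return w_split / tot, w_merge / tot


def split_merge_move(params: HMMParameterState, states, y, m, config: MCMCConfig,
                     rng, missing=None, split_boost=1.0):
    """One reversible-jump order move.

    Split: a uniformly chosen state's theta becomes ``theta -+ u`` with
    ``u ~ Uniform(0, min-gap/2)``, its sites are reallocated to the two
    offspring with probability proportional to their binomial emissions
    (reducing to Bernoulli(1/2) as u -> 0), and transition rows for the K+1
    model are drawn from their Dirichlet full conditional. Merge: a uniformly
    chosen adjacent-in-theta pair is merged to its midpoint (the exact
    reverse map; its 1/(K-1) choice probability enters the proposal ratio). The Metropolis-Hastings
    ratio combines the complete-data likelihoods, the ordered priors, both
    proposal densities and the |d(theta-u, theta+u)/d(theta, u)| = 2 Jacobian.
    Rejected moves leave the inputs unchanged.
    """
    states = _check_states(states, params.K)
    y = np.asarray(y, dtype=np.int64)
    m = np.asarray(m, dtype=np.int64)
    obs = _obs_mask(y, m, missing)
    K, hyper = params.K, params.hyper
    gamma = hyper.gamma
    p_split, p_merge = _move_probs(K, hyper.k_max, split_boost)
    if p_split == 0.0 and p_merge == 0.0:
        return params, states, False, "none"

    ll_old = complete_data_loglik(params, states, y, m, missing)
    lp_old = _log_prior(params)

    if rng.random() < p_split:
        move = "split"
        j = int(rng.integers(K))
        u_max = _split_umax(params.thetas, j)
        u = float(rng.uniform(0.0, u_max))
        if u <= 0.0 or u >= u_max:
            return params, states, False, move
        thetas_new = np.empty(K + 1)
        thetas_new[:j] = params.thetas[:j]
        thetas_new[j] = params.thetas[j] - u
        thetas_new[j + 1] = params.thetas[j] + u
        thetas_new[j + 2:] = params.thetas[j + 1:]
        in_j = states == j
        lp_lo, lp_hi = _alloc_logprobs(y, m, obs, thetas_new[j], thetas_new[j + 1])
        pick_hi = rng.random(y.shape[0]) < np.exp(lp_hi)
        states_new = np.where(states > j, states + 1, states)
        states_new[in_j] = j + pick_hi[in_j]
        log_alloc = float(np.sum(np.where(pick_hi, lp_hi, lp_lo)[in_j]))

        counts_new = transition_counts(states_new, K + 1)
        trans_new = np.empty((K + 2, K + 1))
        for r in range(K + 2):
            trans_new[r] = rng.dirichlet(gamma + counts_new[r])
        trans_new = np.clip(trans_new, 1e-300, None)
        trans_new /= trans_new.sum(axis=1, keepdims=True)
        prop = HMMParameterState(K + 1, thetas_new, trans_new, hyper)

        _, p_merge_rev = _move_probs(K + 1, hyper.k_max, split_boost)
        if p_merge_rev == 0.0:
            return params, states, False, move

        ll_new = complete_data_loglik(prop, states_new, y, m, missing)
        lp_new = _log_prior(prop)
        log_q_fwd = (math.log(p_split) - math.log(K) - math.log(u_max)
                     + log_alloc
                     + _log_trans_proposal(trans_new, states_new, K + 1, gamma))
        # reverse merge picks our pair uniformly among the K adjacent pairs
        log_q_rev = (math.log(p_merge_rev) - math.log(K)
                     + _log_trans_proposal(params.trans, states, K, gamma))
        log_rho = (ll_new - ll_old) + (lp_new - lp_old) + (log_q_rev - log_q_fwd) \
            + math.log(2.0)
    else:
        move = "merge"
        gaps = np.diff(params.thetas)
        i = int(rng.integers(K - 1))   # adjacent pair, uniformly
        u_rev = float(gaps[i]) / 2.0
        thetas_new = np.delete(params.thetas, i + 1)
        thetas_new[i] = (params.thetas[i] + params.thetas[i + 1]) / 2.0
        u_max_rev = _split_umax(thetas_new, i)
        if not (0.0 < u_rev < u_max_rev):
            return params, states, False, move  # reverse split impossible
        merged = (states == i) | (states == i + 1)
        lp_lo, lp_hi = _alloc_logprobs(y, m, obs, params.thetas[i],
                                       params.thetas[i + 1])
        log_alloc_rev = float(np.sum(
            np.where(states == i + 1, lp_hi, lp_lo)[merged]))
        states_new = np.where(states > i + 1, states - 1, states)
        states_new[merged] = i

        counts_new = transition_counts(states_new, K - 1)
        trans_new = np.empty((K, K - 1))
        for r in range(K):
            trans_new[r] = rng.dirichlet(gamma + counts_new[r])
        trans_new = np.clip(trans_new, 1e-300, None)
        trans_new /= trans_new.sum(axis=1, keepdims=True)
        prop = HMMParameterState(K - 1, thetas_new, trans_new, hyper)

        p_split_rev, _ = _move_probs(K - 1, hyper.k_max, split_boost)
        if p_split_rev == 0.0:
            return params, states, False, move
        ll_new = complete_data_loglik(prop, states_new, y, m, missing)
        lp_new = _log_prior(prop)
        log_q_fwd = (math.log(p_merge) - math.log(K - 1)
                     + _log_trans_proposal(trans_new, states_new, K - 1, gamma))
        log_q_rev = (math.log(p_split_rev) - math.log(K - 1) - math.log(u_max_rev)
                     + log_alloc_rev
                     + _log_trans_proposal(params.trans, states, K, gamma))
        log_rho = (ll_new - ll_old) + (lp_new - lp_old) + (log_q_rev - log_q_fwd) \
            - math.log(2.0)

    if math.log(max(rng.random(), 1e-300)) < log_rho:
        return prop, states_new, True, move
    return params, states, False, move


# --------------------------------------------------------------- penalties

def _merge_pair(params: HMMParameterState, states, i, weights=None):
    """Deterministically merge states i and i+1 (occupancy-weighted theta)."""
    K = params.K
    occ = np.bincount(states, minlength=K).astype(float) if weights is None else weights
    w1, w2 = occ[i], occ[i + 1]
    if w1 + w2 == 0:
        w1 = w2 = 1.0
    theta_m = (w1 * params.thetas[i] + w2 * params.thetas[i + 1]) / (w1 + w2)
    thetas = np.delete(params.thetas, i + 1)
    thetas[i] = theta_m
    # columns: sum mass into the merged state; rows i,i+1: occupancy-weighted mean
    T = params.trans
    cols = np.delete(np.arange(K), i + 1)
    newT = np.empty((K, K - 1))
    rows_keep = [0] + [r for r in range(1, K + 1) if r - 1 != i + 1]
    for out_r, r in enumerate(rows_keep):
        row = T[r].copy()
        row[i] += row[i + 1]
        if r - 1 == i:  # outgoing row of the merged state
            row2 = T[i + 2].copy()
            row2[i] += row2[i + 1]
            row = (w1 * row + w2 * row2) / (w1 + w2)
        newT[out_r] = row[cols]
    newT = np.clip(newT, 1e-300, None)
    newT /= newT.sum(axis=1, keepdims=True)
    states_new = np.where(states > i + 1, states - 1, states)
    states_new[states == i + 1] = i
    return HMMParameterState(K - 1, thetas, newT, params.hyper), states_new


def _binom_deviance(yo, mo, mu):
    """2 * sum[ y log(y/mu) + (m-y) log((m-y)/(m-mu)) ] with 0 log 0 = 0.

    mu is the fitted mean m*theta; zero-depth entries contribute 0.
    """
    return 2.0 * np.sum(xlogy(yo, yo) - xlogy(yo, mu)
                        + xlogy(mo - yo, mo - yo) - xlogy(mo - yo, mo - mu),
                        axis=-1)


def _state_deviance(params, states, y, m, obs):
    th = np.clip(params.thetas[states[obs]], 1e-12, 1 - 1e-12)
    yo = y[obs].astype(float)
    mo = m[obs].astype(float)
    return float(_binom_deviance(yo, mo, mo * th))


def _deviance_reference(params, states, y, m, obs, config: MCMCConfig, rng):
    """Parametric-bootstrap null quantile of the within-state deviance."""
    th = np.clip(params.thetas[states[obs]], 1e-12, 1 - 1e-12)
    mo = m[obs].astype(np.int64)
    B = config.deviance_bootstrap
    yb = rng.binomial(mo[None, :], th[None, :], size=(B, mo.shape[0])).astype(float)
    mu = (mo.astype(float) * th)[None, :]
    d = _binom_deviance(yb, mo.astype(float)[None, :], mu)
    return float(np.quantile(d, config.deviance_quantile))


def apply_penalties(params: HMMParameterState, states, y, m, config: MCMCConfig,
                    rng, missing=None, compute_boost=True):
    """Apply the two order penalties.

    Over-fit control: any adjacent theta pair closer than ``collapse_tol`` is
    merged deterministically. Under-fit control: returns a multiplicative
    split-proposal boost (``underfit_penalty_weight``) when the within-state
    binomial deviance exceeds the ``deviance_quantile`` of its parametric
    bootstrap null; 1.0 otherwise.
    """
    states = _check_states(states, params.K)
    y = np.asarray(y, dtype=np.int64)
    m = np.asarray(m, dtype=np.int64)
    obs = _obs_mask(y, m, missing)

    while params.K > 1:
        gaps = np.diff(params.thetas)
        i = int(np.argmin(gaps))
        if gaps[i] >= config.collapse_tol:
            break
        params, states = _merge_pair(params, states, i)

    boost = 1.0
    if compute_boost and obs.any():
        dev = _state_deviance(params, states, y, m, obs)
        ref = _deviance_reference(params, states, y, m, obs, config, rng)
        if dev > ref:
            boost = config.underfit_penalty_weight
    return params, states, boost


# --------------------------------------------------------------- smoothing

def _init_chain(y, m, obs, hyper: HMMHyper, config: MCMCConfig):
    """Start rich and let the penalties prune: empirical-ratio quantiles give
    up to six initial states (well-separated ones only); merging spurious
    states is far easier for the sampler than splitting new ones out."""
    ratios = (y[obs] + 0.5) / (m[obs] + 1.0)
    K0 = min(hyper.k_max, 6)
    qs = np.quantile(ratios, (np.arange(K0) + 0.5) / K0)
    thetas = [float(np.clip(qs[0], 1e-4, 1 - 1e-4))]
    for q in qs[1:]:
        q = float(np.clip(q, 1e-4, 1 - 1e-4))
        if q - thetas[-1] >= max(config.collapse_tol, 0.02):
            thetas.append(q)
    thetas = np.asarray(thetas)
    K = thetas.shape[0]
    trans = np.full((K + 1, K), 0.2 / max(K - 1, 1))
    trans[:, :] = np.where(np.eye(K + 1, K, k=-1, dtype=bool), 0.8, trans)
    trans[0] = 1.0 / K
    trans /= trans.sum(axis=1, keepdims=True)
    fill = (np.abs((np.where(obs, y, 0) + 0.5) / (np.where(obs, m, 1) + 1.0)
                   - thetas[:, None])).argmin(axis=0)
    states = np.where(obs, fill, K // 2).astype(np.int64)
    return HMMParameterState(K, thetas, trans, hyper), states


@dataclass
class ChainResult:
    fitted: np.ndarray
    order_trace: np.ndarray
    acceptance_rate: float
    n_moves: int


def smooth_sample(y_col, m_col, missing_col, positions, config: MCMCConfig,
                  hyper: HMMHyper | None = None) -> ChainResult:
    """Run the full RJ-MCMC on one sample's columns and return the
    posterior-mean methylation level per position (defined at missing sites
    through the hidden path) plus the retained order trace."""
    y = np.asarray(y_col, dtype=np.int64)
    m = np.asarray(m_col, dtype=np.int64)
    missing = None if missing_col is None else np.asarray(missing_col, dtype=bool)
    obs = _obs_mask(y, m, missing)
    if not obs.any():
        raise ValidationError("cannot smooth a sample with every position missing")
    hyper = hyper or HMMHyper()
    rng = np.random.default_rng(config.seed)
    params, states = _init_chain(y, m, obs, hyper, config)

    L = y.shape[0]
    fitted_sum = np.zeros(L)
    order_trace = []
    n_acc = n_moves = n_saved = 0
    boost = 1.0
    for it in range(config.n_iter):
        params, states = gibbs_sweep(params, states, y, m, rng, missing)
        compute = (it % config.boost_every) == 0
        params, states, b = apply_penalties(params, states, y, m, config, rng,
                                            missing, compute_boost=compute)
        if compute:
            boost = b
        params, states, accepted, move = split_merge_move(
            params, states, y, m, config, rng, missing, split_boost=boost)
        if move != "none":
            n_moves += 1
            n_acc += accepted
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            fitted_sum += params.thetas[states]
            order_trace.append(params.K)
            n_saved += 1
    fitted = fitted_sum / n_saved
    rate = n_acc / n_moves if n_moves else 0.0
    return ChainResult(np.clip(fitted, 1e-12, 1 - 1e-12),
                       np.asarray(order_trace), rate, n_moves)


def sample_seed(master_seed: int, index: int) -> int:
    """Per-sample chain seed derived from the master seed by a fixed offset."""
    return int((master_seed * 100003 + 7919 * (index + 1)) % (2**31 - 1))


def smooth_panel(panel: MethylationPanel, config: MCMCConfig,
                 hyper: HMMHyper | None = None) -> SmoothedProfile:
    """Smooth every sample of a panel with an independent seeded chain."""
    fitted = np.empty((panel.n_positions, panel.n_samples))
    traces, rates = [], []
    for i in range(panel.n_samples):
        cfg = MCMCConfig(**{**config.__dict__, "seed": sample_seed(config.seed, i)})
        res = smooth_sample(panel.counts[:, i], panel.depths[:, i],
                            panel.missing_mask[:, i], panel.positions, cfg, hyper)
        fitted[:, i] = res.fitted
        traces.append(res.order_trace)
        rates.append(res.acceptance_rate)
    return SmoothedProfile(panel.chrom, panel.positions, fitted,
                           list(panel.sample_ids), list(panel.group_labels),
                           traces, rates)
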