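"""Hot inner loops of the HMM sampler (scaled forward pass and FFBS).

Emission matrices arrive row-scaled: ``emit[l, k]`` is the emission likelihood
of site ``l`` under state ``k`` divided by the row maximum, with the log of
that maximum carried separately so marginal likelihoods stay exact in log
space. Missing sites have all-ones emission rows (likelihood factor 1).
"""

import numpy as np
from numba import njit


@njit(cache=True)
def forward_loglik(emit, log_scale, init, trans):
    """log p(y) by the scaled forward recursion."""
    L, K = emit.shape
    alpha = init * emit[0]
    c = alpha.sum()
    ll = np.log(c) + log_scale[0]
    alpha = alpha / c
    for l in range(1, L):
        nxt = np.zeros(K)
        for k in range(K):
            acc = 0.0
            for j in range(K):
                acc += alpha[j] * trans[j, k]
            nxt[k] = acc * emit[l, k]
        c = nxt.sum()
        ll += np.log(c) + log_scale[l]
        alpha = nxt / c
    return ll


@njit(cache=True)
def ffbs(emit, init, trans, u):
    """Draw a hidden path from its exact posterior (forward filter, backward
    sample); ``u`` is a length-L vector of Uniform(0,1) draws."""
    L, K = emit.shape
    alphas = np.empty((L, K))
    alpha = init * emit[0]
    alpha = alpha / alpha.sum()
    alphas[0] = alpha
    for l in range(1, L):
        nxt = np.zeros(K)
        for k in range(K):
            acc = 0.0
            for j in range(K):
                acc += alpha[j] * trans[j, k]
            nxt[k] = acc * emit[l, k]
        alpha = nxt / nxt.sum()
        alphas[l] = alpha
    states = np.empty(L, dtype=np.int64)
    # final site
    w = alphas[L - 1]
    states[L - 1] = _sample_index(w, u[L - 1])
    for l in range(L - 2, -1, -1):
        w = alphas[l] * trans[:, states[l + 1]]
        states[l] = _sample_index(w / w.sum(), u[l])
    return states


@njit(cache=True)
def _sample_index(p, u):
    acc = 0.0
    for k in range(p.shape[0]):
        acc += p[k]
        if u <= acc:
            return k
    return p.shape[0] - 1


@njit(cache=True)
def state_posteriors(emit, init, trans):
    """Exact forward-backward marginal posteriors p(s_l = k | y), (L, K)."""
    L, K = emit.shape
    alphas = np.empty((L, K))
    alpha = init * emit[0]
    alpha = alpha / alpha.sum()
    alphas[0] = alpha
    for l in range(1, L):
        nxt = np.zeros(K)
        for k in range(K):
            acc = 0.0
            for j in range(K):
                acc += alpha[j] * trans[j, k]
            nxt[k] = acc * emit[l, k]
        alpha = nxt / nxt.sum()
        alphas[l] = alpha
    beta = np.ones(K)
    post = np.empty((L, K))
    post[L - 1] = alphas[L - 1]
    for l in range(L - 2, -1, -1):
        nxt = np.zeros(K)
        for j in range(K):
            acc = 0.0
            for k in range(K):
                acc += trans[j, k] * emit[l + 1, k] * beta[k]
            nxt[j] = acc
        beta = nxt / nxt.max()
        p = alphas[l] * beta
        post[l] = p / p.sum()
    return post
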