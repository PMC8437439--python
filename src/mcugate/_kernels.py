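"""Compiled inner loops for Markov-chain sampling and HMM recursions.

These are the only O(T) loops in the package that cannot be expressed as
vectorized numpy; everything else (emission densities, M-step statistics)
is done with array operations in the calling modules.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def sample_markov_chain(cum_trans, start_state, uniforms):
    """Sample a Markov state path.

    Parameters
    ----------
    cum_trans : (K, K) float64
        Row-wise cumulative sums of the transition matrix.
    start_state : int
        State at step 0.
    uniforms : (T-1,) float64
        Pre-drawn U(0,1) variates, one per transition.

    Returns
    -------
    (T,) int64 state path.
    """
    T = uniforms.shape[0] + 1
    K = cum_trans.shape[0]
    states = np.empty(T, dtype=np.int64)
    states[0] = start_state
    for t in range(1, T):
        u = uniforms[t - 1]
        row = cum_trans[states[t - 1]]
        s = K - 1
        for k in range(K):
            if u < row[k]:
                s = k
                break
        states[t] = s
    return states


@njit(cache=True)
def forward_scaled(emission, trans, init):
    """Scaled forward recursion.

    emission : (T, K) per-sample emission densities (not logs)
    Returns (alpha, c): scaled forward variables and per-step scaling
    factors; log-likelihood = sum(log(c)).
    """
    T, K = emission.shape
    alpha = np.empty((T, K))
    c = np.empty(T)
    tot = 0.0
    for k in range(K):
        alpha[0, k] = init[k] * emission[0, k]
        tot += alpha[0, k]
    c[0] = tot
    for k in range(K):
        alpha[0, k] /= tot
    for t in range(1, T):
        tot = 0.0
        for j in range(K):
            a = 0.0
            for i in range(K):
                a += alpha[t - 1, i] * trans[i, j]
            a *= emission[t, j]
            alpha[t, j] = a
            tot += a
        c[t] = tot
        for j in range(K):
            alpha[t, j] /= tot
    return alpha, c


@njit(cache=True)
def backward_scaled(emission, trans, c):
    """Scaled backward recursion matching :func:`forward_scaled`."""
    T, K = emission.shape
    beta = np.empty((T, K))
    for k in range(K):
        beta[T - 1, k] = 1.0
    for t in range(T - 2, -1, -1):
        for i in range(K):
            b = 0.0
            for j in range(K):
                b += trans[i, j] * emission[t + 1, j] * beta[t + 1, j]
            beta[t, i] = b / c[t + 1]
    return beta


@njit(cache=True)
def transition_counts(emission, trans, alpha, beta, c):
    """Expected transition counts xi summed over time (K x K)."""
    T, K = emission.shape
    xi = np.zeros((K, K))
    for t in range(T - 1):
        for i in range(K):
            for j in range(K):
                xi[i, j] += (
                    alpha[t, i]
                    * trans[i, j]
                    * emission[t + 1, j]
                    * beta[t + 1, j]
                    / c[t + 1]
                )
    return xi


@njit(cache=True)
def viterbi_path(log_emission, log_trans, log_init):
    """Most probable state path by the Viterbi algorithm (log domain)."""
    T, K = log_emission.shape
    delta = np.empty((T, K))
    psi = np.empty((T, K), dtype=np.int64)
    for k in range(K):
        delta[0, k] = log_init[k] + log_emission[0, k]
        psi[0, k] = 0
    for t in range(1, T):
        for j in range(K):
            best = -np.inf
            arg = 0
            for i in range(K):
                v = delta[t - 1, i] + log_trans[i, j]
                if v > best:
                    best = v
                    arg = i
            delta[t, j] = best + log_emission[t, j]
            psi[t, j] = arg
    path = np.empty(T, dtype=np.int64)
    best = -np.inf
    arg = 0
    for k in range(K):
        if delta[T - 1, k] > best:
            best = delta[T - 1, k]
            arg = k
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path
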