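"""Inner loops of the forward-backward and Viterbi recursions.

Plain-Python/NumPy implementations, JIT-compiled with numba when it is
importable. The numba path and the fallback execute the same code, so
results are identical; only speed differs.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


@njit(cache=True)
def forward_backward_scaled(pi, A, B):
    """Rabiner-scaled forward-backward for one observation sequence.

    Parameters: ``pi`` (K,), ``A`` (K, K) row-stochastic, ``B`` (K, T)
    strictly positive per-bin emission weights (any common per-column factor
    cancels; the caller accounts for it in the log-likelihood).

    Returns (gamma (K, T), xi_sum (K, K), log_norm) where ``gamma`` columns
    sum to 1, ``xi_sum`` is the sum over t of pairwise posteriors
    P(s_t = i, s_{t+1} = j | O), and ``log_norm`` is the sum of the log
    scaling constants (the log-likelihood up to the caller's factor).
    """
    K, T = B.shape
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = pi * B[:, 0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[:, t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    gamma = np.empty((K, T))
    gamma[:, T - 1] = alpha[T - 1]
    xi_sum = np.zeros((K, K))
    beta = np.ones(K)
    for t in range(T - 2, -1, -1):
        bb = B[:, t + 1] * beta / c[t + 1]
        for i in range(K):
            for j in range(K):
                xi_sum[i, j] += alpha[t, i] * A[i, j] * bb[j]
        beta = A @ bb
        gamma[:, t] = alpha[t] * beta
    return gamma, xi_sum, np.log(c).sum()


@njit(cache=True)
def viterbi_log(log_pi, log_A, log_B):
    """Max-probability path in log space; ties take the lowest state index."""
    K, T = log_B.shape
    delta = log_pi + log_B[:, 0]
    back = np.zeros((T, K), dtype=np.int64)
    for t in range(1, T):
        new = np.empty(K)
        for j in range(K):
            best, arg = delta[0] + log_A[0, j], 0
            for i in range(1, K):
                v = delta[i] + log_A[i, j]
                if v > best:
                    best, arg = v, i
            new[j] = best + log_B[j, t]
            back[t, j] = arg
        delta = new
    path = np.zeros(T, dtype=np.int64)
    best, arg = delta[0], 0
    for i in range(1, K):
        if delta[i] > best:
            best, arg = delta[i], i
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path
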