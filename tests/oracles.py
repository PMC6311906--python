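"""Independent brute-force oracles: explicit enumeration over all K^T hidden
paths of a tiny HMM. Deliberately naive and separate from the package's
forward-backward implementation."""

import itertools

import numpy as np


def path_probability(pi, A, E, obs, path):
    """Joint probability of (path, observations) for one sequence.

    ``obs`` is R x T binary, ``path`` a tuple of 0-based states."""
    p = pi[path[0]]
    for t in range(1, len(path)):
        p *= A[path[t - 1], path[t]]
    for t, k in enumerate(path):
        for r in range(obs.shape[0]):
            p *= E[k, r] if obs[r, t] else (1 - E[k, r])
    return p


def enumerate_loglik(pi, A, E, obs):
    K, T = len(pi), obs.shape[1]
    total = sum(path_probability(pi, A, E, obs, path)
                for path in itertools.product(range(K), repeat=T))
    return np.log(total)


def enumerate_posteriors(pi, A, E, obs):
    """K x T matrix of P(s_t = k | obs) by summing path probabilities."""
    K, T = len(pi), obs.shape[1]
    gamma = np.zeros((K, T))
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        p = path_probability(pi, A, E, obs, path)
        total += p
        for t, k in enumerate(path):
            gamma[k, t] += p
    return gamma / total


def enumerate_pairwise(pi, A, E, obs):
    """K x K summed pairwise posteriors P(s_t=i, s_{t+1}=j | obs)."""
    K, T = len(pi), obs.shape[1]
    xi = np.zeros((K, K))
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        p = path_probability(pi, A, E, obs, path)
        total += p
        for t in range(T - 1):
            xi[path[t], path[t + 1]] += p
    return xi / total


def enumerate_viterbi(pi, A, E, obs):
    """Most probable path, ties resolved to the lexicographically smallest
    path (matching lowest-state-index tie-breaking)."""
    K, T = len(pi), obs.shape[1]
    best, best_path = -1.0, None
    for path in itertools.product(range(K), repeat=T):
        p = path_probability(pi, A, E, obs, path)
        if p > best + 1e-15 * best:
            best, best_path = p, path
    return np.array(best_path)


def random_params(K, R, rng):
    pi = rng.dirichlet(np.ones(K))
    A = rng.dirichlet(np.ones(K), size=K)
    E = rng.uniform(0.05, 0.95, size=(K, R))
    return pi, A, E
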