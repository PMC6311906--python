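"""Model-size scores (BIC/AIC) and cross-model state robustness.

BIC and AIC are reported for a range of state counts K but are not used to
pick K automatically: on genome-scale data both decrease monotonically in K,
so the choice is left to inspection of the score table and of the emission
matrices. Robustness of a state across refits is measured by its recovery
score: the maximum Pearson correlation between its emission vector and any
state of another model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .hmm import HMMParams


@dataclass(frozen=True)
class ModelScore:
    K: int
    loglik: float
    n_parameters: int
    bic: float
    aic: float
    n_bins: int


def n_parameters(K: int, N: int, M: int) -> int:
    """Free parameters of a K-state model over N cells and M marks:
    (K-1) initial + K(K-1) transition + K*N*M emission."""
    if K < 1 or N < 1 or M < 1:
        raise ValueError("K, N, M must be positive")
    return (K - 1) + K * (K - 1) + K * N * M


def bic(loglik: float, n_bins: int, n_params: int) -> float:
    """ln(#bins) * #parameters - 2 * loglik (natural-log likelihood)."""
    if n_bins < 1 or n_params < 0:
        raise ValueError("invalid n_bins or n_params")
    return math.log(n_bins) * n_params - 2.0 * loglik


def aic(loglik: float, n_params: int) -> float:
    """2 * #parameters - 2 * loglik."""
    if n_params < 0:
        raise ValueError("invalid n_params")
    return 2.0 * n_params - 2.0 * loglik


def model_score(K: int, loglik: float, n_bins: int, N: int, M: int) -> ModelScore:
    p = n_parameters(K, N, M)
    return ModelScore(K, loglik, p, bic(loglik, n_bins, p), aic(loglik, p),
                      n_bins)


def recovery_score(state_emissions: np.ndarray, other: HMMParams) -> float:
    """Max Pearson correlation of one emission vector over the other model's
    states, in [-1, 1]. Constant vectors correlate as 0."""
    v = np.asarray(state_emissions, dtype=np.float64)
    best = -1.0
    for k in range(other.K):
        best = max(best, _pearson(v, other.E[k]))
    return best


def recovery_matrix(model: HMMParams, others: Sequence[HMMParams]) -> np.ndarray:
    """K x len(others) matrix of recovery scores of each state of ``model``."""
    return np.array([[recovery_score(model.E[k], H) for H in others]
                     for k in range(model.K)])


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        return 0.0
    return float(np.clip(xc @ yc / (nx * ny), -1.0, 1.0))


def observation_space_size(N: int, s: int, M: int) -> int:
    """Number of distinct observation columns: (sum_{i<=s} C(N, i))^M.

    Exact big-integer arithmetic; grows to ~3.4e16 already for N=9, s=2,
    M=10, which is why emissions are modeled as independent Bernoullis
    rather than one parameter per observation.
    """
    if N < 1 or M < 1 or not 1 <= s <= N:
        raise ValueError("need N >= 1, M >= 1, 1 <= s <= N")
    return sum(math.comb(N, i) for i in range(1, s + 1)) ** M


def write_recovery_matrix(matrix: np.ndarray, state_names: Sequence[str],
                          model_names: Sequence[str], path) -> None:
    """TSV of recovery scores, states (rows) x comparison models (columns)."""
    matrix = np.asarray(matrix)
    if matrix.shape != (len(state_names), len(model_names)):
        raise ValueError("matrix shape inconsistent with names")
    with open(path, "w") as fh:
        fh.write("state\t" + "\t".join(model_names) + "\n")
        for name, row in zip(state_names, matrix):
            fh.write(name + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def write_score_table(scores: Sequence[ModelScore], path) -> None:
    with open(path, "w") as fh:
        fh.write("K\tloglik\tn_params\tBIC\tAIC\tn_bins\n")
        for sc in scores:
            fh.write(f"{sc.K}\t{sc.loglik:.6f}\t{sc.n_parameters}"
                     f"\t{sc.bic:.6f}\t{sc.aic:.6f}\t{sc.n_bins}\n")
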