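"""Multivariate Bernoulli hidden Markov model over stacked specificity tracks.

Each genome bin carries a binary vector of R cell-mark observations; state k
emits observation r with probability ``p[k, r]`` independently across r.
Chromosomes are independent sequences sharing one parameter set: the
likelihood factorizes over chromosomes, each starting from the initial
distribution pi and evolving by the transition matrix A.

Training is expectation-maximization (Baum-Welch). Batch mode re-estimates
from the sufficient statistics of all chromosomes each iteration and has the
usual monotone-likelihood guarantee; incremental mode (Neal-Hinton)
re-estimates after every chromosome's E-step by replacing that chromosome's
previous statistic contribution, which converges faster in passes but
without the per-pass monotonicity guarantee.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._kernels import forward_backward_scaled, viterbi_log
from .genome import GenomeBins
from .specificity import ObservationMatrix

logger = logging.getLogger(__name__)

EPS_PROB = 1e-6          # clamp for Bernoulli emission probabilities
EMISSION_PSEUDOCOUNT = 1e-2
DEFAULT_MAX_ITER = 300
DEFAULT_TOL = 1e-6

MODEL_FORMAT = "csrehmm-model"
MODEL_VERSION = 1


@dataclass
class HMMParams:
    """pi (K,), A (K, K) row-stochastic, E (K, R) Bernoulli emission matrix."""

    pi: np.ndarray
    A: np.ndarray
    E: np.ndarray
    row_labels: Optional[Tuple[Tuple[str, str], ...]] = None

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=np.float64)
        self.A = np.asarray(self.A, dtype=np.float64)
        self.E = np.asarray(self.E, dtype=np.float64)
        if self.row_labels is not None:
            self.row_labels = tuple((a, b) for a, b in self.row_labels)
        self.validate()

    @property
    def K(self) -> int:
        return self.E.shape[0]

    @property
    def R(self) -> int:
        return self.E.shape[1]

    def validate(self, tol: float = 1e-9) -> None:
        K, R = self.E.shape
        if self.pi.shape != (K,) or self.A.shape != (K, K):
            raise ValueError("inconsistent parameter shapes")
        if abs(self.pi.sum() - 1.0) > tol or (self.pi < 0).any():
            raise ValueError("pi is not a probability simplex")
        if np.abs(self.A.sum(axis=1) - 1.0).max() > tol or (self.A < 0).any():
            raise ValueError("A is not row-stochastic")
        if (self.E < EPS_PROB - 1e-15).any() or (self.E > 1 - EPS_PROB + 1e-15).any():
            raise ValueError(f"emissions must lie in [{EPS_PROB}, {1 - EPS_PROB}]")

    def permuted(self, perm: Sequence[int]) -> "HMMParams":
        """Relabel states by ``perm`` (new state i = old state perm[i])."""
        p = np.asarray(perm)
        return HMMParams(self.pi[p], self.A[np.ix_(p, p)], self.E[p],
                         self.row_labels)

    def save(self, path) -> None:
        doc = {
            "format": MODEL_FORMAT, "version": MODEL_VERSION,
            "K": self.K, "R": self.R,
            "row_labels": [list(x) for x in self.row_labels] if self.row_labels else None,
            "pi": self.pi.tolist(), "A": self.A.tolist(), "E": self.E.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def load(cls, path) -> "HMMParams":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != MODEL_FORMAT:
            raise ValueError(f"{path}: not a {MODEL_FORMAT} file")
        labels = doc.get("row_labels")
        return cls(np.array(doc["pi"]), np.array(doc["A"]), np.array(doc["E"]),
                   tuple(tuple(x) for x in labels) if labels else None)


@dataclass
class StatePath:
    """Per-chromosome decoded state labels (1-based, in [1..K])."""

    states: Dict[str, np.ndarray]
    posterior: Optional[Dict[str, np.ndarray]] = None  # K x T_c per chrom

    def concatenated(self, bins: GenomeBins) -> np.ndarray:
        return np.concatenate([self.states[c] for c in bins.chrom_order])


@dataclass
class EMTrace:
    log_likelihoods: List[float]
    converged: bool
    mode: str
    n_iter: int = 0
    seed: Optional[int] = None

    def __post_init__(self):
        self.n_iter = len(self.log_likelihoods)


# ---------------------------------------------------------------------------
# Emission weights

def _log_frame_prob(E: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """K x T log emission probabilities for a binary R x T block."""
    logE = np.log(E)
    log1mE = np.log1p(-E)
    Of = obs.astype(np.float64)
    return (logE - log1mE) @ Of + log1mE.sum(axis=1, keepdims=True)


def _scaled_frame_prob(E: np.ndarray, obs: np.ndarray) -> Tuple[np.ndarray, float]:
    """Per-column max-normalized emission weights and the log of the factor."""
    logB = _log_frame_prob(E, obs)
    shift = logB.max(axis=0)
    return np.exp(logB - shift[None, :]), float(shift.sum())


# ---------------------------------------------------------------------------
# Likelihood / E-step

def forward_backward(obs_seq: np.ndarray, params: HMMParams
                     ) -> Tuple[np.ndarray, np.ndarray, float]:
    """Posteriors, summed pairwise expectations, and log-likelihood for one
    chromosome's R x T_c binary block."""
    obs_seq = np.atleast_2d(obs_seq)
    if obs_seq.shape[0] != params.R:
        raise ValueError(f"observation rows {obs_seq.shape[0]} != R {params.R}")
    B, log_shift = _scaled_frame_prob(params.E, obs_seq)
    gamma, xi_sum, log_norm = forward_backward_scaled(
        params.pi, params.A, np.ascontiguousarray(B))
    return gamma, xi_sum, log_norm + log_shift


def log_likelihood(O: ObservationMatrix, bins: GenomeBins,
                   params: HMMParams) -> float:
    """Total log-likelihood; factorizes as a sum over chromosomes."""
    if O.R != params.R:
        raise ValueError(f"O has {O.R} rows but model expects R={params.R}")
    total = 0.0
    for chrom in bins.chrom_order:
        _, _, ll = forward_backward(O.chrom_block(bins, chrom), params)
        total += ll
    return total


# ---------------------------------------------------------------------------
# Initialization

def init_random(K: int, R: int, seed: int,
                row_labels=None) -> HMMParams:
    """Random start: emissions uniform in (0.1, 0.9), pi and A rows Dirichlet(1)."""
    rng = np.random.default_rng(seed)
    E = rng.uniform(0.1, 0.9, size=(K, R))
    pi = rng.dirichlet(np.ones(K))
    A = rng.dirichlet(np.ones(K), size=K)
    return HMMParams(pi, A, E, row_labels)


def _binary_entropy(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -(p * np.log(p) + (1 - p) * np.log1p(-p))


def init_entropy(O: ObservationMatrix, bins: GenomeBins, K: int) -> HMMParams:
    """Deterministic entropy-splitting initialization.

    Starting from one cluster of all bins, repeatedly split the cluster
    carrying the most total information -- cluster size times the binary
    entropy of its R feature means -- on its highest-entropy feature, until
    K clusters exist or no cluster is separable. Size weighting keeps the
    procedure from re-splitting small, already-homogeneous clusters while a
    dominant mixed cluster remains. Emissions are the cluster feature means;
    pi and A come from the induced hard genome labeling. Ties break on the
    lowest feature or cluster index, so the result is reproducible and
    comparable across K.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    Of = O.matrix
    T = Of.shape[1]
    clusters: List[np.ndarray] = [np.arange(T)]
    while len(clusters) < K:
        best_c, best_h, best_feats = -1, -np.inf, None
        for ci, idx in enumerate(clusters):
            if idx.size < 2:
                continue
            means = Of[:, idx].mean(axis=1)
            h = _binary_entropy(means)
            h[(means <= 0) | (means >= 1)] = 0.0
            total = idx.size * h.sum()
            if total > best_h + 1e-15:
                best_c, best_h, best_feats = ci, total, h
        if best_c < 0 or best_h <= 0:
            break  # nothing separable left
        feat = int(np.argmax(best_feats))  # argmax takes the lowest index on ties
        idx = clusters[best_c]
        on = idx[Of[feat, idx] == 1]
        off = idx[Of[feat, idx] == 0]
        if on.size == 0 or off.size == 0:
            break
        clusters[best_c] = on
        clusters.append(off)
    E = np.empty((K, O.R))
    labels = np.zeros(T, dtype=np.int64)
    for ci, idx in enumerate(clusters):
        E[ci] = Of[:, idx].mean(axis=1)
        labels[idx] = ci
    if len(clusters) < K:
        logger.warning("init_entropy: only %d separable clusters for K=%d; "
                       "remaining states start at the global mean",
                       len(clusters), K)
        gm = Of.mean(axis=1)
        for k in range(len(clusters), K):
            E[k] = gm + 1e-3 * k
    E = np.clip(E, EPS_PROB, 1 - EPS_PROB)

    pc = 1e-2
    pi_counts = np.full(K, pc)
    A_counts = np.full((K, K), pc)
    for chrom in bins.chrom_order:
        lab = labels[bins.chrom_slice(chrom)]
        pi_counts[lab[0]] += 1
        np.add.at(A_counts, (lab[:-1], lab[1:]), 1)
    pi = pi_counts / pi_counts.sum()
    A = A_counts / A_counts.sum(axis=1, keepdims=True)
    return HMMParams(pi, A, E, O.row_labels)


# ---------------------------------------------------------------------------
# EM

def _m_step(pi_num, A_num, e_num, gamma_sum, K):
    pi = pi_num / pi_num.sum()
    rowsum = A_num.sum(axis=1, keepdims=True)
    A = np.where(rowsum > 0, A_num / np.where(rowsum == 0, 1, rowsum), 1.0 / K)
    pc = EMISSION_PSEUDOCOUNT
    E = (e_num + pc) / (gamma_sum[:, None] + 2 * pc)
    E = np.clip(E, EPS_PROB, 1 - EPS_PROB)
    return pi, A / A.sum(axis=1, keepdims=True), E


def _chrom_stats(obs, params):
    gamma, xi_sum, ll = forward_backward(obs, params)
    return {
        "pi": gamma[:, 0].copy(),
        "A": xi_sum,
        "e": gamma @ obs.T.astype(np.float64),
        "g": gamma.sum(axis=1),
        "ll": ll,
    }


def em_fit(O: ObservationMatrix, bins: GenomeBins, init: HMMParams,
           mode: str = "incremental", max_iter: int = DEFAULT_MAX_ITER,
           tol: float = DEFAULT_TOL) -> Tuple[HMMParams, EMTrace]:
    """Fit by EM from ``init``.

    ``batch``: full Baum-Welch sweep per iteration (monotone log-likelihood).
    ``incremental``: after each chromosome's E-step, its previous sufficient
    statistics are replaced and parameters re-estimated immediately; one
    iteration is one pass over chromosomes in input order.

    Stops when the relative log-likelihood change drops below ``tol`` or
    after ``max_iter`` iterations.
    """
    if mode not in ("batch", "incremental"):
        raise ValueError(f"unknown mode {mode!r}")
    init.validate()
    params = HMMParams(init.pi.copy(), init.A.copy(), init.E.copy(),
                       init.row_labels or O.row_labels)
    chroms = list(bins.chrom_order)
    blocks = {c: np.ascontiguousarray(O.chrom_block(bins, c)) for c in chroms}

    lls: List[float] = []
    converged = False
    stats: Dict[str, dict] = {}
    for it in range(max_iter):
        ll_iter = 0.0
        if mode == "batch":
            K = params.K
            pi_num = np.zeros(K)
            A_num = np.zeros((K, K))
            e_num = np.zeros((K, params.R))
            gamma_sum = np.zeros(K)
            for c in chroms:
                st = _chrom_stats(blocks[c], params)
                pi_num += st["pi"]
                A_num += st["A"]
                e_num += st["e"]
                gamma_sum += st["g"]
                ll_iter += st["ll"]
            pi, A, E = _m_step(pi_num, A_num, e_num, gamma_sum, K)
            params = HMMParams(pi, A, E, params.row_labels)
        else:
            for c in chroms:
                stats[c] = _chrom_stats(blocks[c], params)
                ll_iter += stats[c]["ll"]
                pi_num = sum(s["pi"] for s in stats.values())
                A_num = sum(s["A"] for s in stats.values())
                e_num = sum(s["e"] for s in stats.values())
                gamma_sum = sum(s["g"] for s in stats.values())
                pi, A, E = _m_step(pi_num, A_num, e_num, gamma_sum, params.K)
                params = HMMParams(pi, A, E, params.row_labels)
        if not np.isfinite(ll_iter):
            raise FloatingPointError(
                f"non-finite log-likelihood at iteration {it}")
        lls.append(ll_iter)
        if it > 0 and abs(lls[-1] - lls[-2]) <= tol * abs(lls[-2]):
            converged = True
            break
    return params, EMTrace(lls, converged, mode)


# ---------------------------------------------------------------------------
# Decoding

def decode(O: ObservationMatrix, bins: GenomeBins, params: HMMParams,
           method: str = "posterior", keep_posterior: bool = False) -> StatePath:
    """Per-bin state labels (1-based).

    ``posterior``: argmax of the smoothed forward-backward posterior per bin.
    ``viterbi``: single most probable path. Ties resolve to the lowest state
    index under both methods.
    """
    if method not in ("posterior", "viterbi"):
        raise ValueError(f"unknown decoding method {method!r}")
    states: Dict[str, np.ndarray] = {}
    posts: Dict[str, np.ndarray] = {}
    with np.errstate(divide="ignore"):
        log_pi = np.log(params.pi)
        log_A = np.log(params.A)
    for chrom in bins.chrom_order:
        block = np.ascontiguousarray(O.chrom_block(bins, chrom))
        if method == "posterior":
            gamma, _, _ = forward_backward(block, params)
            states[chrom] = gamma.argmax(axis=0).astype(np.int64) + 1
            if keep_posterior:
                posts[chrom] = gamma
        else:
            logB = _log_frame_prob(params.E, block)
            states[chrom] = viterbi_log(log_pi, log_A,
                                        np.ascontiguousarray(logB)) + 1
    return StatePath(states, posts if keep_posterior else None)
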