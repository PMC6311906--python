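"""Synthetic multi-cell-type epigenomes with planted specific states.

The generator draws a hidden state path per chromosome from a Markov chain
in which one background state dominates (~80% of the genome) and each
specific state forms short islands (geometric segment lengths, mean 5 bins
~ 1 kb by default, near the sub-kilobase scale of real cell type-specific
elements). Peak calls are Bernoulli draws per (cell, mark) from the planted
emission probabilities (foreground 0.9, background 0.05), so the real
specificity transform, HMM training and CSRE extraction can run end to end.
Background co-occurrence across more than ``s`` cells arises naturally from
the 0.05 rate and exercises the column-zeroing path.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .genome import GenomeBins, PeakMatrix, ReadRecord
from .hmm import HMMParams, StatePath
from .specificity import ObservationMatrix, specificity_transform, stack_observations
from .states import CSRE, SpecificState, classify_states, extract_csres


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic epigenome.

    ``planted`` maps a 1-based state index to its specific (cell, mark)
    index pairs; states without an entry are background. The constraint
    that no state plants more than ``s`` cells per mark keeps planted
    signal visible to the specificity transform.
    """

    n_cells: int = 4
    n_marks: int = 3
    n_states: int = 4
    s: int = 2
    chrom_lengths: Dict[str, int] = field(
        default_factory=lambda: {"chrS1": 5_000_000, "chrS2": 5_000_000})
    bin_size: int = 200
    planted: Dict[int, List[Tuple[int, int]]] = field(
        default_factory=lambda: {2: [(0, 0)],
                                 3: [(1, 1), (1, 2)],
                                 4: [(2, 2), (3, 2)]})
    p_fg: float = 0.9
    p_bg: float = 0.05
    mean_segment_bins: float = 5.0
    background_mean_segment_bins: float = 20.0
    mu_fg: float = 50.0
    mu_bg: float = 0.5
    seed: int = 1

    def __post_init__(self):
        if not (0 < self.p_bg < self.p_fg < 1):
            raise ValueError("need 0 < p_bg < p_fg < 1")
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        for k, pairs in self.planted.items():
            if not 1 <= k <= self.n_states:
                raise ValueError(f"planted state {k} outside [1, {self.n_states}]")
            per_mark: Dict[int, Set[int]] = {}
            for cell, mark in pairs:
                if not (0 <= cell < self.n_cells and 0 <= mark < self.n_marks):
                    raise ValueError(f"planted pair {(cell, mark)} out of range")
                per_mark.setdefault(mark, set()).add(cell)
            if any(len(cells) > self.s for cells in per_mark.values()):
                raise ValueError(f"state {k} plants more than s={self.s} "
                                 "cells for one mark")

    @property
    def cell_names(self) -> Tuple[str, ...]:
        return tuple(f"cell{i + 1}" for i in range(self.n_cells))

    @property
    def mark_names(self) -> Tuple[str, ...]:
        return tuple(f"mark{j + 1}" for j in range(self.n_marks))

    @property
    def row_labels(self) -> Tuple[Tuple[str, str], ...]:
        return tuple((m, c) for m in self.mark_names for c in self.cell_names)

    def bins(self) -> GenomeBins:
        return GenomeBins.from_chrom_sizes(self.chrom_lengths, self.bin_size)


def true_params(config: SimulationConfig) -> HMMParams:
    """Ground-truth HMM parameters implied by the planted design.

    Emissions: p_fg on planted pairs, p_bg elsewhere. Transitions: each
    state is a geometric island (stay probability 1 - 1/mean length);
    specific states return to the background, the background moves uniformly
    to the specific states. pi is the stationary distribution.
    """
    K, N, M = config.n_states, config.n_cells, config.n_marks
    R = N * M
    E = np.full((K, R), config.p_bg)
    for k, pairs in config.planted.items():
        for cell, mark in pairs:
            E[k - 1, mark * N + cell] = config.p_fg
    specific = sorted(config.planted)
    background = [k for k in range(1, K + 1) if k not in config.planted]
    A = np.zeros((K, K))
    for k in range(1, K + 1):
        mean = (config.background_mean_segment_bins if k in background
                else config.mean_segment_bins)
        stay = 1.0 - 1.0 / mean
        A[k - 1, k - 1] = stay
        if k in background:
            targets = specific or background
        else:
            targets = background or specific
        targets = [t for t in targets if t != k] or [k]
        for t in targets:
            A[k - 1, t - 1] += (1.0 - stay) / len(targets)
    A /= A.sum(axis=1, keepdims=True)
    # stationary distribution: left eigenvector of A for eigenvalue 1
    w, v = np.linalg.eig(A.T)
    pi = np.real(v[:, np.argmin(np.abs(w - 1))])
    pi = np.abs(pi) / np.abs(pi).sum()
    return HMMParams(pi, A, E, config.row_labels)


def simulate_state_path(config: SimulationConfig,
                        params: Optional[HMMParams] = None,
                        seed: Optional[int] = None) -> StatePath:
    """Markov-chain state path per chromosome (1-based labels)."""
    params = params or true_params(config)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    bins = config.bins()
    cum_pi = np.cumsum(params.pi)
    cum_A = np.cumsum(params.A, axis=1)
    states: Dict[str, np.ndarray] = {}
    for chrom in bins.chrom_order:
        Tc = bins.n_bins(chrom)
        u = rng.random(Tc)
        path = np.empty(Tc, dtype=np.int64)
        state = int(np.searchsorted(cum_pi, u[0], side="right"))
        path[0] = state
        for t in range(1, Tc):
            state = int(np.searchsorted(cum_A[state], u[t], side="right"))
            path[t] = state
        states[chrom] = path + 1
    return StatePath(states)


def simulate_peak_matrices(config: SimulationConfig, truth: StatePath,
                           seed: Optional[int] = None) -> List[PeakMatrix]:
    """Bernoulli peak calls per (cell, mark) conditioned on the true path."""
    params = true_params(config)
    bins = config.bins()
    rng = np.random.default_rng(
        (config.seed if seed is None else seed) + 1_000_003)
    path0 = truth.concatenated(bins) - 1
    probs = params.E[path0, :]  # T x R
    draws = (rng.random(probs.shape) < probs).astype(np.uint8)
    N = config.n_cells
    out = []
    for m, mark in enumerate(config.mark_names):
        out.append(PeakMatrix(mark, config.cell_names,
                              draws[:, m * N:(m + 1) * N].T))
    return out


def simulate_observations(params: HMMParams, bins: GenomeBins, seed: int
                          ) -> Tuple[ObservationMatrix, StatePath]:
    """Draw a path and R x T Bernoulli observations directly from ``params``.

    Bypasses the peak/specificity stage; used to study the estimator under
    exactly the model's own generative assumptions.
    """
    rng = np.random.default_rng(seed)
    cum_pi = np.cumsum(params.pi)
    cum_A = np.cumsum(params.A, axis=1)
    states: Dict[str, np.ndarray] = {}
    blocks = []
    for chrom in bins.chrom_order:
        Tc = bins.n_bins(chrom)
        u = rng.random(Tc)
        path = np.empty(Tc, dtype=np.int64)
        s = int(np.searchsorted(cum_pi, u[0], side="right"))
        path[0] = s
        for t in range(1, Tc):
            s = int(np.searchsorted(cum_A[s], u[t], side="right"))
            path[t] = s
        states[chrom] = path + 1
        probs = params.E[path, :]  # Tc x R
        blocks.append((rng.random(probs.shape) < probs).astype(np.uint8).T)
    labels = params.row_labels or tuple(
        ("obs", f"r{r + 1}") for r in range(params.R))
    return ObservationMatrix(np.hstack(blocks), labels), StatePath(states)


def stack_from_peaks(peak_matrices: Sequence[PeakMatrix], s: int
                     ) -> ObservationMatrix:
    """Convenience: specificity transform + mark-major stack."""
    return stack_observations([specificity_transform(P, s)
                               for P in peak_matrices])


def simulate_reads(config: SimulationConfig,
                   peak_matrices: Sequence[PeakMatrix],
                   seed: Optional[int] = None
                   ) -> Dict[Tuple[str, str], List[ReadRecord]]:
    """Read-level emission: Poisson(mu_fg) reads per peak bin, Poisson(mu_bg)
    per background bin, 5' ends uniform within the bin, random strand."""
    bins = config.bins()
    rng = np.random.default_rng(
        (config.seed if seed is None else seed) + 2_000_039)
    out: Dict[Tuple[str, str], List[ReadRecord]] = {}
    starts = np.array([bins.bin_to_locus(i)[1] for i in range(bins.T)])
    chroms = np.array([bins.bin_to_locus(i)[0] for i in range(bins.T)])
    for P in peak_matrices:
        for i, cell in enumerate(P.cell_order):
            rates = np.where(P.matrix[i] == 1, config.mu_fg, config.mu_bg)
            counts = rng.poisson(rates)
            reads: List[ReadRecord] = []
            for b in np.flatnonzero(counts):
                chrom = str(chroms[b])
                size = bins.chrom_sizes[chrom]
                width = min(bins.bin_size, size - starts[b])
                offs = rng.integers(0, width, size=counts[b])
                strands = rng.random(counts[b]) < 0.5
                for o, plus in zip(offs, strands):
                    reads.append(ReadRecord(chrom, int(starts[b] + o),
                                            "+" if plus else "-"))
            out[(cell, P.mark)] = reads
    return out


# ---------------------------------------------------------------------------
# Companion data for the annotation stage

@dataclass
class SimulatedCompanions:
    genes: list                      # GeneModel
    expression: pd.DataFrame         # genes x cell types
    peaks_by_cell: Dict[str, List[Tuple[str, int, int]]]
    gene_sets: Dict[str, Set[str]]
    universe: Set[str]
    proximal_by_state: Dict[str, Set[str]]
    truth_csres: List[CSRE]
    specific_states: List[SpecificState]


def simulate_companions(config: SimulationConfig, truth: StatePath,
                        seed: Optional[int] = None,
                        genes_per_state: int = 5,
                        n_decoy_terms: int = 5) -> SimulatedCompanions:
    """Toy gene models, expression, per-cell peaks and gene sets tied to the
    planted CSREs.

    Proximal genes are placed inside CSRE runs longer than 3 kb (their whole
    body is covered, so they satisfy the contiguous-3-kb rule by
    construction); distal genes sit in long background runs. Expression of a
    proximal gene is elevated in the cells of its state; the gene set
    collection contains one term per planted state (its proximal genes) plus
    random decoys.
    """
    from .annotation import GeneModel

    bins = config.bins()
    params = true_params(config)
    specific = classify_states(params, p0=0.3)
    truth_csres = extract_csres(truth, specific, bins)
    rng = np.random.default_rng(
        (config.seed if seed is None else seed) + 3_000_017)

    name_to_cells = {s.name: s.cells for s in specific if s.combinations}
    genes: List[GeneModel] = []
    proximal_by_state: Dict[str, Set[str]] = {n: set() for n in name_to_cells}
    gid = 0
    body = 3000  # gene-body length; fully covered runs satisfy the 3-kb rule
    for state_name in sorted(name_to_cells):
        long_runs = [c for c in truth_csres
                     if c.state_name == state_name and c.length >= body + 400]
        for run in long_runs[:genes_per_state]:
            gid += 1
            g = GeneModel(f"NM_{gid:06d}", f"GENE{gid}", run.chrom, "+",
                          run.start + 200, run.start + 200 + body,
                          [(run.start + 200, run.start + 200 + body)])
            genes.append(g)
            proximal_by_state[state_name].add(g.gene)

    # distal genes in long background runs, away from any CSRE
    bg_states = [k for k in range(1, config.n_states + 1)
                 if k not in config.planted]
    n_distal = max(10, gid)
    placed = 0
    for chrom in bins.chrom_order:
        lab = truth.states[chrom]
        change = np.flatnonzero(np.diff(lab)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [lab.size]))
        for lo, hi in zip(starts, ends):
            if placed >= n_distal:
                break
            if int(lab[lo]) in bg_states and (hi - lo) * config.bin_size > 30000:
                gid += 1
                mid = (lo + hi) // 2 * config.bin_size
                genes.append(GeneModel(f"NM_{gid:06d}", f"GENE{gid}", chrom,
                                       "+", mid, mid + body,
                                       [(mid, mid + body)]))
                placed += 1

    universe = {g.gene for g in genes}
    expr = pd.DataFrame(
        5.0 + rng.normal(0, 0.5, size=(len(genes), config.n_cells)),
        index=[g.gene for g in genes], columns=list(config.cell_names))
    cell_index = {c: i for i, c in enumerate(config.cell_names)}
    for state_name, gene_set in proximal_by_state.items():
        for cell in name_to_cells[state_name]:
            expr.loc[sorted(gene_set), config.cell_names[cell_index[cell]]] += 3.0

    peaks_by_cell: Dict[str, List[Tuple[str, int, int]]] = {
        c: [] for c in config.cell_names}
    for c in truth_csres:
        for cell in c.cells:
            peaks_by_cell[cell].append((c.chrom, c.start, c.end))

    gene_sets: Dict[str, Set[str]] = {
        f"TERM_{name}": set(g) for name, g in proximal_by_state.items() if g}
    uni_sorted = sorted(universe)
    for d in range(n_decoy_terms):
        size = min(len(uni_sorted), int(rng.integers(5, 16)))
        gene_sets[f"DECOY_{d + 1}"] = set(
            rng.choice(uni_sorted, size=size, replace=False))

    return SimulatedCompanions(genes, expr, peaks_by_cell, gene_sets,
                               universe, proximal_by_state, truth_csres,
                               specific)
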