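"""Specific-state identification and CSRE extraction.

A state is *specific* when at least one of its cell-mark emission
probabilities stands out: probabilities are sorted decreasingly, the largest
consecutive gap defines a state-specific cutoff p_s, and a combination is
specific iff its probability is >= p_s and strictly above the absolute floor
p_0 (0.3 by default). Maximal runs of bins decoded to a specific state are
emitted as cell type-specific regulatory elements (CSREs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .genome import GenomeBins
from .hmm import HMMParams, StatePath

logger = logging.getLogger(__name__)

DEFAULT_P0 = 0.3


@dataclass(frozen=True)
class SpecificCombination:
    """One cell-mark pair whose emission probability passes p_s and p_0."""

    cell: str
    mark: str
    probability: float


@dataclass
class SpecificState:
    state_index: int  # 1-based
    combinations: List[SpecificCombination]
    p_s: float
    name: str = ""
    contains_wce: bool = False

    @property
    def cells(self) -> Tuple[str, ...]:
        return tuple(sorted({c.cell for c in self.combinations}))


@dataclass(frozen=True)
class CSRE:
    """Maximal run of consecutive bins assigned to one specific state."""

    chrom: str
    start: int
    end: int
    state_name: str
    cells: Tuple[str, ...]

    @property
    def length(self) -> int:
        return self.end - self.start


def specific_combinations(emission_row: np.ndarray,
                          row_labels: Sequence[Tuple[str, str]],
                          p0: float = DEFAULT_P0
                          ) -> Tuple[List[SpecificCombination], float]:
    """Max-gap rule: cutoff p_s = value above the largest consecutive drop.

    With all-equal rows every gap is 0; the earliest gap wins, so p_s is the
    maximum and the p_0 floor alone decides. Returns (combinations, p_s);
    the list may be empty.
    """
    q = np.asarray(emission_row, dtype=np.float64)
    if q.size < 2:
        raise ValueError("need at least two cell-mark combinations")
    order = np.argsort(-q, kind="stable")
    qs = q[order]
    gaps = qs[:-1] - qs[1:]
    jstar = int(np.argmax(gaps))  # ties -> smallest j (fewer combinations)
    p_s = float(qs[jstar])
    combos = [
        SpecificCombination(cell=row_labels[r][1], mark=row_labels[r][0],
                            probability=float(q[r]))
        for r in range(q.size) if q[r] >= p_s and q[r] > p0
    ]
    combos.sort(key=lambda c: -c.probability)
    return combos, p_s


def classify_states(params: HMMParams,
                    row_labels: Optional[Sequence[Tuple[str, str]]] = None,
                    p0: float = DEFAULT_P0,
                    control_mark: str = "WCE") -> List[SpecificState]:
    """Apply the p_s/p_0 rule to every state and name the specific ones.

    Names are the sorted unique cell ids of a state's combinations joined by
    '_', with an ordinal suffix (by ascending state index) distinguishing
    states that share a cell-id set. Non-specific states get a 'Non' name.
    """
    labels = row_labels or params.row_labels
    if labels is None:
        raise ValueError("row_labels required (not stored in params)")
    out: List[SpecificState] = []
    for k in range(params.K):
        combos, p_s = specific_combinations(params.E[k], labels, p0)
        st = SpecificState(state_index=k + 1, combinations=combos, p_s=p_s)
        st.contains_wce = any(c.mark == control_mark for c in combos)
        out.append(st)
    counters: Dict[Tuple[str, ...], int] = {}
    for st in out:
        if st.combinations:
            key = st.cells
            counters[key] = counters.get(key, 0) + 1
            st.name = "_".join(key) + f"_{counters[key]}"
        else:
            st.name = f"Non_{st.state_index}"
    return out


def extract_csres(path: StatePath, specific: Sequence[SpecificState],
                  bins: GenomeBins) -> List[CSRE]:
    """Run-length encode the decoded path and emit specific-state runs."""
    by_index = {s.state_index: s for s in specific if s.combinations}
    out: List[CSRE] = []
    bs = bins.bin_size
    for chrom in bins.chrom_order:
        lab = np.asarray(path.states[chrom])
        if lab.size != bins.n_bins(chrom):
            raise ValueError(f"path length mismatch on {chrom}")
        # run boundaries wherever the label changes
        change = np.flatnonzero(np.diff(lab)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [lab.size]))
        size = bins.chrom_sizes[chrom]
        for lo, hi in zip(starts, ends):
            st = by_index.get(int(lab[lo]))
            if st is None:
                continue
            out.append(CSRE(chrom, lo * bs, min(hi * bs, size),
                            st.name, st.cells))
    out.sort(key=lambda c: (c.chrom, c.start))
    return out


def csre_summary(csres: Sequence[CSRE]) -> Dict[str, Dict[str, float]]:
    """Per-state count, median length (bp) and total bp covered."""
    by_state: Dict[str, List[int]] = {}
    for c in csres:
        by_state.setdefault(c.state_name, []).append(c.length)
    return {
        name: {
            "count": len(lens),
            "median_length": float(np.median(lens)),
            "bp_covered": int(sum(lens)),
        }
        for name, lens in sorted(by_state.items())
    }


def write_csres_bed(csres: Sequence[CSRE], path, bed9: bool = False) -> None:
    """BED4 (name = state name) or BED9 with a stable per-state color."""
    names = sorted({c.state_name for c in csres})
    palette = _state_colors(names)
    with open(path, "w") as fh:
        for c in sorted(csres, key=lambda x: (x.chrom, x.start)):
            if bed9:
                rgb = palette[c.state_name]
                fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.state_name}"
                         f"\t0\t.\t{c.start}\t{c.end}\t{rgb}\n")
            else:
                fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.state_name}\n")


def _state_colors(names: Sequence[str]) -> Dict[str, str]:
    colors = {}
    for i, name in enumerate(names):
        # deterministic spread around the hue wheel
        h = (i * 0.618033988749895) % 1.0
        r, g, b = _hsv_to_rgb(h, 0.65, 0.9)
        colors[name] = f"{r},{g},{b}"
    return colors


def _hsv_to_rgb(h: float, s: float, v: float) -> Tuple[int, int, int]:
    import colorsys
    r, g, b = colorsys.hsv_to_rgb(h, s, v)
    return int(r * 255), int(g * 255), int(b * 255)


def write_emission_table(params: HMMParams, states: Sequence[SpecificState],
                         path) -> None:
    """TSV heat-map table: states x cell-mark columns, '*' flags specifics."""
    labels = params.row_labels or ()
    cols = [f"{m}:{c}" for m, c in labels]
    flagged = {(s.state_index, (c.mark, c.cell))
               for s in states for c in s.combinations}
    name_of = {s.state_index: s.name for s in states}
    with open(path, "w") as fh:
        fh.write("state\tname\t" + "\t".join(cols) + "\n")
        for k in range(params.K):
            cells = []
            for r, lab in enumerate(labels):
                star = "*" if (k + 1, lab) in flagged else ""
                cells.append(f"{params.E[k, r]:.4f}{star}")
            fh.write(f"{k + 1}\t{name_of.get(k + 1, '')}\t" + "\t".join(cells) + "\n")
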