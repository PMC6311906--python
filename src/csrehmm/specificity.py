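"""Specificity transform and observation stacking.

A bin is informative about cell-type specificity only when few cell types
share a peak there: for each mark, columns where more than ``s`` cell types
have a peak are zeroed, and the per-mark specificity matrices are stacked
mark-major into the R x T binary observation matrix the HMM is trained on
(R = M marks x N cells).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .genome import GenomeBins, PeakMatrix
from . import io as _io

DEFAULT_S = 2


@dataclass
class SpecificityMatrix:
    """Per-mark binary N x T matrix keeping only columns with <= s peak cells."""

    mark: str
    cell_order: Tuple[str, ...]
    matrix: np.ndarray
    s: int

    def __post_init__(self):
        self.cell_order = tuple(self.cell_order)
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)


@dataclass
class ObservationMatrix:
    """Stacked R x T binary observations; rows are (mark, cell) pairs, mark-major."""

    matrix: np.ndarray  # uint8, R x T
    row_labels: Tuple[Tuple[str, str], ...]  # (mark, cell)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        self.row_labels = tuple((m, c) for m, c in self.row_labels)
        if self.matrix.shape[0] != len(self.row_labels):
            raise ValueError("row_labels length must equal row count")

    @property
    def R(self) -> int:
        return self.matrix.shape[0]

    @property
    def T(self) -> int:
        return self.matrix.shape[1]

    def chrom_block(self, bins: GenomeBins, chrom: str) -> np.ndarray:
        return self.matrix[:, bins.chrom_slice(chrom)]

    def label_strings(self) -> List[str]:
        return [f"{m}:{c}" for m, c in self.row_labels]


def specificity_transform(P: PeakMatrix, s: int = DEFAULT_S) -> SpecificityMatrix:
    """Zero every column of the peak matrix shared by more than ``s`` cells.

    Columns whose peak count is at most ``s`` are copied unchanged, so the
    transform is idempotent.
    """
    N = P.n_cells
    if not 1 <= s <= N:
        raise ValueError(f"s must be in [1, {N}], got {s}")
    keep = P.matrix.sum(axis=0) <= s
    S = np.where(keep[None, :], P.matrix, 0).astype(np.uint8)
    return SpecificityMatrix(P.mark, P.cell_order, S, s)


def stack_observations(S_list: Sequence[SpecificityMatrix]) -> ObservationMatrix:
    """Vertically stack per-mark specificity matrices, mark-major."""
    if not S_list:
        raise ValueError("no specificity matrices to stack")
    first = S_list[0]
    for S in S_list[1:]:
        if S.cell_order != first.cell_order:
            raise ValueError(f"cell order of mark {S.mark!r} differs from "
                             f"mark {first.mark!r}")
        if S.matrix.shape != first.matrix.shape:
            raise ValueError(f"bin count of mark {S.mark!r} differs from "
                             f"mark {first.mark!r}")
    labels = [(S.mark, cell) for S in S_list for cell in S.cell_order]
    return ObservationMatrix(np.vstack([S.matrix for S in S_list]), labels)


def unstack_observations(O: ObservationMatrix) -> List[SpecificityMatrix]:
    """Recover the per-mark specificity matrices from a stacked O."""
    marks: List[str] = []
    for m, _ in O.row_labels:
        if m not in marks:
            marks.append(m)
    out = []
    for mark in marks:
        rows = [i for i, (m, _) in enumerate(O.row_labels) if m == mark]
        cells = tuple(O.row_labels[i][1] for i in rows)
        out.append(SpecificityMatrix(mark, cells, O.matrix[rows], s=len(cells)))
    return out


def write_observations(O: ObservationMatrix, bins: GenomeBins, directory,
                       name: str = "observations") -> List[str]:
    """Serialize O to the binarized text dialect, one file per chromosome."""
    import os
    paths = []
    for chrom in bins.chrom_order:
        path = os.path.join(str(directory), f"{name}_{chrom}_binary.txt")
        _io.write_binarized(path, name, chrom, O.label_strings(),
                            O.chrom_block(bins, chrom).T)
        paths.append(path)
    return paths


def read_observations(paths: Sequence[str], bins: GenomeBins) -> ObservationMatrix:
    """Load a serialized observation matrix (files in any chromosome order)."""
    blocks: Dict[str, np.ndarray] = {}
    labels = None
    for path in paths:
        _, chrom, labs, mat = _io.read_binarized(path)
        if labels is None:
            labels = labs
        elif labs != labels:
            raise ValueError(f"{path}: row labels differ between chromosomes")
        blocks[chrom] = mat.T
    missing = [c for c in bins.chrom_order if c not in blocks]
    if missing:
        raise ValueError(f"missing chromosomes: {missing}")
    matrix = np.hstack([blocks[c] for c in bins.chrom_order])
    row_labels = [tuple(l.split(":", 1)) for l in labels]
    return ObservationMatrix(matrix, row_labels)
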