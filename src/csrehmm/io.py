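"""Readers and writers for the on-disk formats the pipeline consumes.

All genomic coordinates are 0-based half-open (BED convention). The
binarized interchange dialect is the two-header-line text format used by
chromatin-state tools: line 1 is ``<name><TAB><chrom>``, line 2 the
tab-separated column labels, then one 0/1 row per bin.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, Iterator, List, Sequence, Tuple

import numpy as np

from .genome import GenomeBins, ReadRecord

logger = logging.getLogger(__name__)


def read_chrom_sizes(path) -> Dict[str, int]:
    """Two-column TSV: chromosome name, size in bp."""
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected 'chrom<TAB>size'")
            sizes[parts[0]] = int(parts[1])
    if not sizes:
        raise ValueError(f"{path}: empty chromosome-sizes file")
    return sizes


def read_bed_intervals(path, min_fields: int = 3
                       ) -> List[Tuple[str, int, int, List[str]]]:
    """Parse BED records as (chrom, start, end, extra_fields)."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < min_fields:
                raise ValueError(f"{path}:{ln}: fewer than {min_fields} fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from exc
            if start < 0 or end < start:
                raise ValueError(f"{path}:{ln}: invalid interval [{start},{end})")
            out.append((parts[0], start, end, parts[3:]))
    return out


def read_reads_bed(path) -> Iterator[ReadRecord]:
    """Aligned reads from BED6 (strand in column 6) or chrom/pos/strand TSV.

    For BED records the 5' position is ``start`` on the plus strand and
    ``end - 1`` on the minus strand.
    """
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) >= 6 and parts[5] in ("+", "-"):
                chrom, start, end, strand = parts[0], int(parts[1]), int(parts[2]), parts[5]
                pos = start if strand == "+" else end - 1
            elif len(parts) == 3 and parts[2] in ("+", "-"):
                chrom, pos, strand = parts[0], int(parts[1]), parts[2]
            else:
                raise ValueError(f"{path}:{ln}: unrecognized read record")
            yield ReadRecord(chrom, pos, strand)


def rasterize_intervals(intervals: Iterable[Tuple[str, int, int]],
                        bins: GenomeBins) -> np.ndarray:
    """Binary length-T vector: bin = 1 iff any interval overlaps it >= 1 bp."""
    vec = np.zeros(bins.T, dtype=np.uint8)
    bs = bins.bin_size
    for chrom, start, end, *_ in intervals:
        if chrom not in bins.chrom_sizes:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if end <= start:
            continue
        off = bins.offsets[chrom]
        last = min((end - 1) // bs, bins.n_bins(chrom) - 1)
        vec[off + start // bs: off + last + 1] = 1
    return vec


def read_peaks_bed(path, bins: GenomeBins) -> np.ndarray:
    """BED peaks rasterized to the bin grid (>= 1 bp overlap rule)."""
    return rasterize_intervals(
        [(c, s, e) for c, s, e, _ in read_bed_intervals(path)], bins)


def binary_vector_to_intervals(vec: np.ndarray, bins: GenomeBins
                               ) -> List[Tuple[str, int, int]]:
    """Merge consecutive 1-bins into maximal bp intervals."""
    out = []
    for chrom in bins.chrom_order:
        sub = np.asarray(vec[bins.chrom_slice(chrom)], dtype=np.int8)
        if sub.size == 0:
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([0], sub, [0]))))
        size, bs = bins.chrom_sizes[chrom], bins.bin_size
        for lo, hi in edges.reshape(-1, 2):
            out.append((chrom, lo * bs, min(hi * bs, size)))
    return out


def write_bed(records: Sequence[tuple], path) -> None:
    """Write BED records (tuples of 3+ fields), sorted by (chrom, start)."""
    recs = sorted(records, key=lambda r: (r[0], int(r[1]), int(r[2])))
    with open(path, "w") as fh:
        for r in recs:
            fh.write("\t".join(str(x) for x in r) + "\n")


# ---------------------------------------------------------------------------
# Binarized text interchange (one file per chromosome)

def write_binarized(path, name: str, chrom: str, labels: Sequence[str],
                    matrix: np.ndarray) -> None:
    """Write a T_c x L 0/1 table with the two-line header dialect."""
    matrix = np.asarray(matrix, dtype=np.uint8)
    if matrix.ndim != 2 or matrix.shape[1] != len(labels):
        raise ValueError("matrix shape inconsistent with labels")
    with open(path, "w") as fh:
        fh.write(f"{name}\t{chrom}\n")
        fh.write("\t".join(labels) + "\n")
        for row in matrix:
            fh.write("\t".join("1" if x else "0" for x in row) + "\n")


def read_binarized(path) -> Tuple[str, str, List[str], np.ndarray]:
    """Inverse of :func:`write_binarized`; bit-exact round-trip."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != 2:
            raise ValueError(f"{path}:1: expected 'name<TAB>chrom'")
        name, chrom = header
        labels = fh.readline().rstrip("\n").split("\t")
        rows = []
        for ln, line in enumerate(fh, 3):
            parts = line.rstrip("\n").split("\t")
            if parts == [""]:
                continue
            if len(parts) != len(labels):
                raise ValueError(f"{path}:{ln}: expected {len(labels)} columns")
            rows.append([int(x) for x in parts])
    matrix = np.asarray(rows, dtype=np.uint8)
    if matrix.size and matrix.max() > 1:
        raise ValueError(f"{path}: non-binary entries")
    return name, chrom, labels, matrix
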