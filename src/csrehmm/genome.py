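"""Genome binning, read ingestion, and peak calling.

The genome is tiled with fixed-width non-overlapping bins (200 bp by
default), the resolution at which all downstream matrices are defined.
Aligned reads are extended from their 5' end, assigned to the bin holding
the extended fragment's midpoint, and peaks are called per track against a
Poisson background whose rate is the genome-wide mean bin count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Sequence, Tuple

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_BIN_SIZE = 200
DEFAULT_PEAK_ALPHA = 1e-4
DEFAULT_SIGNAL_THRESHOLD = 2.0


@dataclass(frozen=True)
class GenomeBins:
    """Fixed tiling of a genome into non-overlapping, 0-based half-open bins.

    Bins tile each chromosome left to right; the last bin of a chromosome may
    be shorter than ``bin_size``. Global bin indices are chromosome-major in
    ``chrom_order``.
    """

    chrom_order: Tuple[str, ...]
    chrom_sizes: Dict[str, int]
    bin_size: int = DEFAULT_BIN_SIZE

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        missing = [c for c in self.chrom_order if c not in self.chrom_sizes]
        if missing:
            raise ValueError(f"chromosomes without sizes: {missing}")
        for c in self.chrom_order:
            if self.chrom_sizes[c] <= 0:
                raise ValueError(f"non-positive size for chromosome {c}")
        object.__setattr__(self, "chrom_order", tuple(self.chrom_order))

    @classmethod
    def from_chrom_sizes(cls, sizes: Dict[str, int] | Sequence[Tuple[str, int]],
                         bin_size: int = DEFAULT_BIN_SIZE) -> "GenomeBins":
        items = list(sizes.items()) if isinstance(sizes, dict) else list(sizes)
        return cls(chrom_order=tuple(c for c, _ in items),
                   chrom_sizes={c: int(s) for c, s in items},
                   bin_size=bin_size)

    def n_bins(self, chrom: str) -> int:
        return -(-self.chrom_sizes[chrom] // self.bin_size)  # ceil div

    @property
    def T_c(self) -> Dict[str, int]:
        return {c: self.n_bins(c) for c in self.chrom_order}

    @property
    def T(self) -> int:
        return sum(self.n_bins(c) for c in self.chrom_order)

    @property
    def offsets(self) -> Dict[str, int]:
        """Global column offset of each chromosome's first bin."""
        out, acc = {}, 0
        for c in self.chrom_order:
            out[c] = acc
            acc += self.n_bins(c)
        return out

    def chrom_slice(self, chrom: str) -> slice:
        off = self.offsets[chrom]
        return slice(off, off + self.n_bins(chrom))

    def locus_to_bin(self, chrom: str, pos: int) -> int:
        """Global bin index of base pair ``pos`` on ``chrom``."""
        if not 0 <= pos < self.chrom_sizes[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        return self.offsets[chrom] + pos // self.bin_size

    def bin_to_locus(self, index: int) -> Tuple[str, int]:
        """Inverse of :meth:`locus_to_bin`: (chrom, start_bp) of a bin."""
        if index < 0 or index >= self.T:
            raise IndexError(index)
        for c in self.chrom_order:
            n = self.n_bins(c)
            if index < n:
                return c, index * self.bin_size
            index -= n
        raise IndexError(index)  # pragma: no cover

    def bin_interval(self, index: int) -> Tuple[str, int, int]:
        chrom, start = self.bin_to_locus(index)
        end = min(start + self.bin_size, self.chrom_sizes[chrom])
        return chrom, start, end


@dataclass(frozen=True)
class ReadRecord:
    """A single aligned read: chromosome, 5' position (bp) and strand."""

    chrom: str
    five_prime_pos: int
    strand: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.five_prime_pos < 0:
            raise ValueError("negative read position")


@dataclass
class BinnedTrack:
    """One (cell, mark) track of per-bin values aligned to a GenomeBins."""

    cell: str
    mark: str
    data: Dict[str, np.ndarray]

    @classmethod
    def zeros(cls, cell: str, mark: str, bins: GenomeBins,
              dtype=np.float64) -> "BinnedTrack":
        return cls(cell, mark,
                   {c: np.zeros(bins.n_bins(c), dtype=dtype)
                    for c in bins.chrom_order})

    def values(self, bins: GenomeBins) -> np.ndarray:
        """Concatenated length-T vector in the bins' chromosome order."""
        return np.concatenate([self.data[c] for c in bins.chrom_order])

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def __iadd__(self, other: "BinnedTrack") -> "BinnedTrack":
        for c, v in other.data.items():
            self.data[c] = self.data[c] + v
        return self


@dataclass
class PeakMatrix:
    """Binary N (cells) x T (bins) peak calls for one mark."""

    mark: str
    cell_order: Tuple[str, ...]
    matrix: np.ndarray  # uint8, N x T

    def __post_init__(self):
        self.cell_order = tuple(self.cell_order)
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.cell_order):
            raise ValueError("matrix shape inconsistent with cell_order")
        if self.matrix.size and self.matrix.max() > 1:
            raise ValueError("peak matrix must be binary")

    @property
    def n_cells(self) -> int:
        return len(self.cell_order)

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]


def bin_reads(reads: Iterable[ReadRecord], bins: GenomeBins,
              ext_len: int = 200, cell: str = "", mark: str = "") -> BinnedTrack:
    """Assign extended reads to bins by fragment midpoint.

    Each read is extended ``ext_len`` bp from its 5' end toward 3' (leftward
    for minus-strand reads), clipped to the chromosome, and adds one count to
    the bin containing the midpoint of the extended interval. Reads on
    chromosomes absent from ``bins`` are rejected with a warning count.
    """
    track = BinnedTrack.zeros(cell, mark, bins, dtype=np.int64)
    rejected = 0
    for read in reads:
        if read.chrom not in bins.chrom_sizes:
            rejected += 1
            continue
        size = bins.chrom_sizes[read.chrom]
        if read.five_prime_pos < 0:
            raise ValueError("negative read position")
        if read.strand == "+":
            start, end = read.five_prime_pos, read.five_prime_pos + ext_len
        else:
            start, end = read.five_prime_pos - ext_len, read.five_prime_pos
        start, end = max(start, 0), min(end, size)
        if end <= start:  # fully off-chromosome after clipping
            rejected += 1
            continue
        mid = (start + end) // 2
        track.data[read.chrom][min(mid, size - 1) // bins.bin_size] += 1
    if rejected:
        logger.warning("bin_reads: rejected %d read(s) (unknown chromosome "
                       "or empty extension)", rejected)
    return track


def poisson_peak_threshold(lam: float, alpha: float = DEFAULT_PEAK_ALPHA) -> int:
    """Smallest count c with P(X >= c) < alpha under X ~ Poisson(lam)."""
    if lam <= 0:
        return 1
    c = int(stats.poisson.isf(alpha, lam))  # bracket, then verify exactly
    while stats.poisson.sf(c - 1, lam) >= alpha:
        c += 1
    while c > 1 and stats.poisson.sf(c - 2, lam) < alpha:
        c -= 1
    return c


def call_peaks_poisson(track: BinnedTrack, bins: GenomeBins,
                       alpha: float = DEFAULT_PEAK_ALPHA
                       ) -> Tuple[np.ndarray, float, int]:
    """Call peak bins against a Poisson background.

    The background rate lambda is the mean count over all T bins of the
    track; a bin is a peak iff its count reaches the smallest c* whose
    Poisson upper-tail probability drops below ``alpha``. Returns the binary
    length-T vector together with (lambda, c*).
    """
    counts = track.values(bins)
    if counts.size == 0:
        raise ValueError("empty track")
    lam = float(counts.mean())
    if lam == 0:
        logger.warning("call_peaks_poisson: all-zero track (%s/%s); "
                       "no peaks called", track.cell, track.mark)
        return np.zeros(counts.size, dtype=np.uint8), 0.0, 0
    cstar = poisson_peak_threshold(lam, alpha)
    return (counts >= cstar).astype(np.uint8), lam, cstar


def binarize_signal(track: BinnedTrack, bins: GenomeBins,
                    threshold: float = DEFAULT_SIGNAL_THRESHOLD) -> np.ndarray:
    """Binarize a real-valued signal track: 1 iff signal >= threshold.

    NaN values count as 0 signal (logged). The boundary is inclusive.
    """
    signal = track.values(bins).astype(np.float64)
    n_nan = int(np.isnan(signal).sum())
    if n_nan:
        logger.warning("binarize_signal: %d NaN bin(s) treated as 0", n_nan)
        signal = np.nan_to_num(signal, nan=0.0)
    return (signal >= threshold).astype(np.uint8)


def average_signal_to_bins(intervals: Iterable[Tuple[str, int, int, float]],
                           bins: GenomeBins, cell: str = "",
                           mark: str = "") -> BinnedTrack:
    """Length-weighted mean of interval values per bin (bedGraph -> track).

    Uncovered base pairs contribute 0; overlapping input intervals sum their
    contributions. Each bin is divided by its actual width (the last bin of a
    chromosome may be short).
    """
    track = BinnedTrack.zeros(cell, mark, bins)
    bs = bins.bin_size
    for chrom, start, end, value in intervals:
        if chrom not in bins.chrom_sizes:
            raise ValueError(f"unknown chromosome {chrom!r}")
        size = bins.chrom_sizes[chrom]
        if start < 0 or end > size or end <= start:
            raise ValueError(f"interval [{start},{end}) outside {chrom}")
        vec = track.data[chrom]
        for b in range(start // bs, (end - 1) // bs + 1):
            lo, hi = max(start, b * bs), min(end, (b + 1) * bs)
            vec[b] += (hi - lo) * value
    for chrom in bins.chrom_order:
        size = bins.chrom_sizes[chrom]
        widths = np.full(bins.n_bins(chrom), bs, dtype=np.float64)
        widths[-1] = size - (bins.n_bins(chrom) - 1) * bs
        track.data[chrom] /= widths
    return track


def merge_tracks(tracks: Sequence[BinnedTrack]) -> BinnedTrack:
    """Sum replicate count tracks before peak calling."""
    if not tracks:
        raise ValueError("no tracks to merge")
    out = BinnedTrack(tracks[0].cell, tracks[0].mark,
                      {c: v.copy() for c, v in tracks[0].data.items()})
    for t in tracks[1:]:
        out += t
    return out
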