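"""Downstream characterization of CSREs.

Covers genomic-feature assignment (promoter > 5'UTR > 3'UTR > exon > intron
> intergenic), proximal-gene calling (a contiguous >= 3 kb stretch of a
gene's promoter-plus-body covered by one state's CSREs), TSS distances with
matched random controls, peak-overlap enrichment with a permutation null,
expression normalization and specificity z-scores, and Fisher/BH gene-set
enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import GenomeBins
from .states import CSRE

logger = logging.getLogger(__name__)

PROMOTER_FLANK = 2000
PROXIMAL_RUN_BP = 3000
FEATURE_PRIORITY = ("promoter", "utr5", "utr3", "exon", "intron", "intergenic")


# ---------------------------------------------------------------------------
# Interval arithmetic (0-based half-open throughout)

def merge_intervals(intervals: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Union of intervals; overlapping or abutting pieces are merged."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: List[Tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract_intervals(keep: Iterable[Tuple[int, int]],
                       remove: Iterable[Tuple[int, int]]
                       ) -> List[Tuple[int, int]]:
    """Base-pair subtraction keep \\ remove on one chromosome."""
    rem = merge_intervals(remove)
    out: List[Tuple[int, int]] = []
    for s, e in merge_intervals(keep):
        cur = s
        for rs, re in rem:
            if re <= cur or rs >= e:
                continue
            if rs > cur:
                out.append((cur, rs))
            cur = max(cur, re)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


# ---------------------------------------------------------------------------
# Gene models

@dataclass
class GeneModel:
    """One transcript with derived genomic features.

    Coordinates are 0-based half-open; ``exons`` are sorted and disjoint.
    ``cds`` is the coding span (None for non-coding transcripts, which then
    contribute no UTR intervals).
    """

    transcript_id: str
    gene: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: List[Tuple[int, int]]
    cds: Optional[Tuple[int, int]] = None

    def __post_init__(self):
        self.exons = merge_intervals(self.exons)
        if not self.exons:
            self.exons = [(self.start, self.end)]
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def tss(self) -> int:
        """Strand-aware transcription start site (bp of the first base)."""
        return self.start if self.strand == "+" else self.end - 1

    def promoter(self, flank: int = PROMOTER_FLANK) -> Tuple[int, int]:
        """Within ``flank`` bp of the TSS, inclusive, rendered half-open."""
        return max(0, self.tss - flank), self.tss + flank + 1

    @property
    def introns(self) -> List[Tuple[int, int]]:
        return [(self.exons[i][1], self.exons[i + 1][0])
                for i in range(len(self.exons) - 1)
                if self.exons[i + 1][0] > self.exons[i][1]]

    def _utr(self, which: str) -> List[Tuple[int, int]]:
        if self.cds is None:
            return []
        cs, ce = self.cds
        before = [(max(s, 0), min(e, cs)) for s, e in self.exons if s < cs]
        after = [(max(s, ce), e) for s, e in self.exons if e > ce]
        before = [(s, e) for s, e in before if e > s]
        after = [(s, e) for s, e in after if e > s]
        if self.strand == "+":
            return before if which == "utr5" else after
        return after if which == "utr5" else before

    @property
    def utr5(self) -> List[Tuple[int, int]]:
        return self._utr("utr5")

    @property
    def utr3(self) -> List[Tuple[int, int]]:
        return self._utr("utr3")


def read_gtf(path) -> List[GeneModel]:
    """GeneModels from a GTF: exon and CDS features grouped by transcript_id."""
    import gffutils

    exons: Dict[str, List[Tuple[int, int]]] = {}
    cds: Dict[str, List[Tuple[int, int]]] = {}
    meta: Dict[str, Tuple[str, str, str]] = {}
    for f in gffutils.DataIterator(str(path)):
        if f.featuretype not in ("exon", "CDS"):
            continue
        tid = f.attributes.get("transcript_id", [None])[0]
        if tid is None:
            raise ValueError(f"{path}: {f.featuretype} without transcript_id")
        gene = (f.attributes.get("gene_name") or
                f.attributes.get("gene_id") or [tid])[0]
        meta.setdefault(tid, (gene, f.seqid, f.strand))
        iv = (f.start - 1, f.end)  # GTF is 1-based inclusive
        (exons if f.featuretype == "exon" else cds).setdefault(tid, []).append(iv)
    out = []
    for tid, (gene, chrom, strand) in meta.items():
        ex = merge_intervals(exons.get(tid, []))
        if not ex:
            ex = merge_intervals(cds.get(tid, []))
        cspan = None
        if tid in cds:
            cc = merge_intervals(cds[tid])
            cspan = (cc[0][0], cc[-1][1])
        out.append(GeneModel(tid, gene, chrom, strand,
                             ex[0][0], ex[-1][1], ex, cspan))
    return out


def read_bed12(path) -> List[GeneModel]:
    """GeneModels from BED12 (blocks = exons, thick span = CDS)."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            p = line.split("\t")
            if len(p) < 12:
                raise ValueError(f"{path}:{ln}: BED12 needs 12 fields")
            chrom, start, end, name = p[0], int(p[1]), int(p[2]), p[3]
            strand = p[5]
            thick = (int(p[6]), int(p[7]))
            sizes = [int(x) for x in p[10].rstrip(",").split(",")]
            starts = [int(x) for x in p[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + sz) for o, sz in zip(starts, sizes)]
            cds = thick if thick[1] > thick[0] else None
            out.append(GeneModel(name, name.split(".")[0], chrom, strand,
                                 start, end, exons, cds))
    return out


def filter_transcripts(genes: Sequence[GeneModel],
                       prefix: Optional[str] = None) -> List[GeneModel]:
    """Keep transcripts whose id starts with ``prefix`` (e.g. 'NM_')."""
    if prefix is None:
        return list(genes)
    return [g for g in genes if g.transcript_id.startswith(prefix)]


# ---------------------------------------------------------------------------
# Feature assignment

class FeatureIndex:
    """Per-chromosome interval trees of the five annotated feature classes."""

    def __init__(self, genes: Sequence[GeneModel],
                 promoter_flank: int = PROMOTER_FLANK):
        self.trees: Dict[str, Dict[str, IntervalTree]] = {
            f: {} for f in FEATURE_PRIORITY[:-1]}
        for g in genes:
            self._add("promoter", g.chrom, [g.promoter(promoter_flank)])
            self._add("utr5", g.chrom, g.utr5)
            self._add("utr3", g.chrom, g.utr3)
            self._add("exon", g.chrom, g.exons)
            self._add("intron", g.chrom, g.introns)

    def _add(self, feat: str, chrom: str, ivs: Iterable[Tuple[int, int]]):
        tree = self.trees[feat].setdefault(chrom, IntervalTree())
        for s, e in ivs:
            if e > s:
                tree.addi(s, e)

    def overlaps(self, feat: str, chrom: str, start: int, end: int) -> bool:
        tree = self.trees[feat].get(chrom)
        return bool(tree is not None and tree.overlap(start, end))


def assign_feature(csre: CSRE, index: FeatureIndex) -> str:
    """Highest-priority feature class the CSRE overlaps by >= 1 bp."""
    for feat in FEATURE_PRIORITY[:-1]:
        if index.overlaps(feat, csre.chrom, csre.start, csre.end):
            return feat
    return "intergenic"


def feature_distribution(csres: Sequence[CSRE], index: FeatureIndex
                         ) -> Dict[str, int]:
    """Counts per feature class; every CSRE lands in exactly one class."""
    counts = {f: 0 for f in FEATURE_PRIORITY}
    for c in csres:
        counts[assign_feature(c, index)] += 1
    return counts


# ---------------------------------------------------------------------------
# Proximal genes

def proximal_genes(csres: Sequence[CSRE], genes: Sequence[GeneModel],
                   min_run: int = PROXIMAL_RUN_BP,
                   promoter_flank: int = PROMOTER_FLANK) -> Set[str]:
    """Genes with a contiguous >= ``min_run`` bp of promoter-plus-body
    covered by the given (single-state) CSREs. Gene level: any transcript
    qualifies the gene."""
    cov: Dict[str, List[Tuple[int, int]]] = {}
    for c in csres:
        cov.setdefault(c.chrom, []).append((c.start, c.end))
    cov = {chrom: merge_intervals(ivs) for chrom, ivs in cov.items()}
    hits: Set[str] = set()
    for g in genes:
        if g.gene in hits or g.chrom not in cov:
            continue
        ps, pe = g.promoter(promoter_flank)
        lo, hi = min(ps, g.start), max(pe, g.end)
        for s, e in cov[g.chrom]:
            if s >= hi:
                break
            if min(e, hi) - max(s, lo) >= min_run:
                hits.add(g.gene)
                break
    return hits


# ---------------------------------------------------------------------------
# TSS distances

def nearest_tss_distances(csres: Sequence[CSRE], genes: Sequence[GeneModel],
                          chrom_sizes: Dict[str, int], n_random: int = 1,
                          seed: int = 0) -> Tuple[np.ndarray, np.ndarray]:
    """Edge distance of each CSRE to its nearest TSS, plus matched controls.

    Controls are placed uniformly on the CSRE's own chromosome with the same
    length (one control per CSRE per ``n_random`` round). CSREs on
    chromosomes without any TSS are skipped with a log message.
    """
    tss_by_chrom: Dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, [])
    for g in genes:
        tss_by_chrom[g.chrom].append(g.tss)
    tss_by_chrom = {c: np.unique(v) for c, v in tss_by_chrom.items()}

    rng = np.random.default_rng(seed)
    true_d: List[int] = []
    ctrl_d: List[int] = []
    skipped = 0
    for c in csres:
        tss = tss_by_chrom.get(c.chrom)
        if tss is None or tss.size == 0:
            skipped += 1
            continue
        true_d.append(_edge_distance(tss, c.start, c.end))
        size = chrom_sizes[c.chrom]
        span = max(size - c.length, 0)
        for _ in range(n_random):
            s = int(rng.integers(0, span + 1))
            ctrl_d.append(_edge_distance(tss, s, s + c.length))
    if skipped:
        logger.warning("nearest_tss_distances: skipped %d CSRE(s) on "
                       "chromosomes without a TSS", skipped)
    return np.asarray(true_d), np.asarray(ctrl_d)


def _edge_distance(tss_sorted: np.ndarray, start: int, end: int) -> int:
    i = int(np.searchsorted(tss_sorted, start))
    best = np.inf
    if i < tss_sorted.size:
        t = int(tss_sorted[i])
        best = 0 if t < end else t - (end - 1)
    if i > 0:
        best = min(best, start - int(tss_sorted[i - 1]))
    return int(best)


# ---------------------------------------------------------------------------
# Peak-overlap enrichment

@dataclass
class EnrichmentResult:
    observed: int
    null_counts: np.ndarray
    empirical_p: float
    wilcoxon_p: float
    seed: int

    @property
    def n_sim(self) -> int:
        return len(self.null_counts)


def overlap_enrichment(csres: Sequence[CSRE],
                       peaks: Sequence[Tuple[str, int, int]],
                       chrom_sizes: Dict[str, int], n_sim: int = 1000,
                       seed: int = 0) -> EnrichmentResult:
    """Observed vs. permutation-null counts of CSREs overlapping any peak.

    The null repositions every CSRE uniformly on its own chromosome with its
    length preserved, ``n_sim`` times. Reports the empirical enrichment
    p-value (1 + #{null >= observed}) / (n_sim + 1) and a one-sample
    Wilcoxon signed-rank p of the null counts against the observed value
    (alternative: null below observed)."""
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    merged: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, s, e, *_ in peaks:
        by_chrom.setdefault(chrom, []).append((s, e))
    for chrom, ivs in by_chrom.items():
        m = merge_intervals(ivs)
        merged[chrom] = (np.array([x[0] for x in m]),
                         np.array([x[1] for x in m]))

    def count(starts_by_chrom: Dict[str, np.ndarray],
              lens_by_chrom: Dict[str, np.ndarray]) -> int:
        total = 0
        for chrom, starts in starts_by_chrom.items():
            if chrom not in merged:
                continue
            ps, pe = merged[chrom]
            ends = starts + lens_by_chrom[chrom]
            idx = np.searchsorted(ps, ends, side="left") - 1
            ok = (idx >= 0) & (pe[np.maximum(idx, 0)] > starts)
            total += int(ok.sum())
        return total

    cs_by_chrom: Dict[str, np.ndarray] = {}
    lens_by_chrom: Dict[str, np.ndarray] = {}
    for chrom in {c.chrom for c in csres}:
        sub = [c for c in csres if c.chrom == chrom]
        cs_by_chrom[chrom] = np.array([c.start for c in sub])
        lens_by_chrom[chrom] = np.array([c.length for c in sub])
    observed = count(cs_by_chrom, lens_by_chrom)

    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_sim, dtype=np.int64)
    fixed_logged = False
    for i in range(n_sim):
        sim_starts = {}
        for chrom, lens in lens_by_chrom.items():
            size = chrom_sizes[chrom]
            span = size - lens
            if (span < 0).any() and not fixed_logged:
                logger.warning("overlap_enrichment: CSRE longer than its "
                               "chromosome kept in place")
                fixed_logged = True
            hi = np.maximum(span, 0) + 1
            sim_starts[chrom] = np.where(
                span < 0, cs_by_chrom[chrom],
                rng.integers(0, hi))
        null_counts[i] = count(sim_starts, lens_by_chrom)

    empirical_p = (1 + int((null_counts >= observed).sum())) / (n_sim + 1)
    diffs = null_counts - observed
    if np.all(diffs == 0):
        logger.warning("overlap_enrichment: degenerate null (all counts "
                       "equal observed); Wilcoxon p set to 1")
        wp = 1.0
    else:
        wp = float(stats.wilcoxon(diffs, alternative="less",
                                  zero_method="wilcox").pvalue)
    return EnrichmentResult(observed, null_counts, empirical_p, wp, seed)


# ---------------------------------------------------------------------------
# Expression

def quantile_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Standard quantile normalization across columns.

    After normalization all columns share the same sorted value vector (the
    per-rank mean over columns); tied values within a column receive the
    mean of their rank range. Idempotent.
    """
    X = expr.to_numpy(dtype=np.float64)
    mu = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        ranked = np.empty_like(mu)
        ranked[order] = mu
        # average over tie groups so equal inputs stay equal
        sorted_vals = col[order]
        i = 0
        while i < len(sorted_vals):
            k = i
            while k + 1 < len(sorted_vals) and sorted_vals[k + 1] == sorted_vals[i]:
                k += 1
            if k > i:
                ranked[order[i:k + 1]] = mu[i:k + 1].mean()
            i = k + 1
        out[:, j] = ranked
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def specificity_zscores(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scores across cell types (sample sd, ddof=1).

    High positive values flag specifically high expression in a cell type.
    Constant genes get all-zero rows (logged).
    """
    X = expr.to_numpy(dtype=np.float64)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    const = (sd == 0).ravel()
    if const.any():
        logger.warning("specificity_zscores: %d constant gene(s) set to 0",
                       int(const.sum()))
    Z = np.where(sd == 0, 0.0, (X - mean) / np.where(sd == 0, 1.0, sd))
    return pd.DataFrame(Z, index=expr.index, columns=expr.columns)


def compare_groups(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when both samples have <= 8 untied values; otherwise
    the normal approximation with tie correction and continuity."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    no_ties = len(np.unique(np.concatenate([a, b]))) == a.size + b.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# Gene sets

@dataclass
class GeneSetCollection:
    terms: Dict[str, Set[str]]
    universe: Set[str]

    def __post_init__(self):
        self.universe = set(self.universe)
        self.terms = {t: set(g) & self.universe for t, g in self.terms.items()}


def read_gmt(path, universe: Optional[Iterable[str]] = None) -> GeneSetCollection:
    """GMT: term <TAB> description <TAB> gene1 <TAB> gene2 ..."""
    terms: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                if line.strip():
                    raise ValueError(f"{path}:{ln}: GMT needs >= 3 fields")
                continue
            terms[parts[0]] = {g for g in parts[2:] if g}
    uni = set(universe) if universe is not None else set().union(*terms.values())
    return GeneSetCollection(terms, uni)


def enrichment_pvalue(n_overlap: int, n_query: int, n_term: int,
                      n_universe: int) -> float:
    """One-sided (enrichment) Fisher exact p for a query/term overlap."""
    if not (0 <= n_overlap <= min(n_query, n_term) and
            max(n_query, n_term) <= n_universe):
        raise ValueError("inconsistent contingency counts")
    table = [[n_overlap, n_query - n_overlap],
             [n_term - n_overlap, n_universe - n_query - n_term + n_overlap]]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def gene_set_enrichment(query: Iterable[str], sets: GeneSetCollection,
                        min_size: int = 5, max_size: int = 500) -> pd.DataFrame:
    """One-sided Fisher exact enrichment per term, BH-corrected per query.

    Terms outside [min_size, max_size] genes (after universe intersection)
    are dropped; query genes outside the universe are dropped with a log."""
    q = set(query)
    outside = q - sets.universe
    if outside:
        logger.warning("gene_set_enrichment: %d query gene(s) outside the "
                       "universe dropped", len(outside))
        q &= sets.universe
    rows = []
    U, nq = len(sets.universe), len(q)
    for term, genes in sorted(sets.terms.items()):
        nt = len(genes)
        if not min_size <= nt <= max_size:
            continue
        a = len(q & genes)
        p = enrichment_pvalue(a, nq, nt, U)
        rows.append((term, nt, a, ",".join(sorted(q & genes)), p))
    if not rows:
        return pd.DataFrame(columns=["term", "term_size", "overlap",
                                     "overlap_genes", "p", "q"])
    df = pd.DataFrame(rows, columns=["term", "term_size", "overlap",
                                     "overlap_genes", "p"])
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df.sort_values("p", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Cell-specific peaks

def cell_specific_peaks(peaks_by_cell: Dict[str, Sequence[Tuple[str, int, int]]]
                        ) -> Dict[str, List[Tuple[str, int, int]]]:
    """Per cell, the base pairs of its peaks not covered by any other cell."""
    out: Dict[str, List[Tuple[str, int, int]]] = {}
    for cell, own in peaks_by_cell.items():
        others: Dict[str, List[Tuple[int, int]]] = {}
        for other_cell, ivs in peaks_by_cell.items():
            if other_cell == cell:
                continue
            for chrom, s, e, *_ in ivs:
                others.setdefault(chrom, []).append((s, e))
        result: List[Tuple[str, int, int]] = []
        own_by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, s, e, *_ in own:
            own_by_chrom.setdefault(chrom, []).append((s, e))
        for chrom in sorted(own_by_chrom):
            for s, e in subtract_intervals(own_by_chrom[chrom],
                                           others.get(chrom, [])):
                result.append((chrom, s, e))
        out[cell] = result
    return out
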