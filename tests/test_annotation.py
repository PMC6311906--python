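import numpy as np
import pandas as pd
import pytest
from scipy import stats

import csrehmm as ch
from csrehmm import annotation as ann
from csrehmm.states import CSRE


def _csre(chrom, start, end, name="H1_1", cells=("H1",)):
    return CSRE(chrom, start, end, name, cells)


@pytest.fixture(scope="module")
def toy_gene():
    """One plus-strand coding transcript: tx [10000, 20000), two exons,
    CDS [12000, 18000)."""
    return ann.GeneModel("NM_000001", "GENE1", "chr1", "+", 10000, 20000,
                         exons=[(10000, 13000), (16000, 20000)],
                         cds=(12000, 18000))


@pytest.fixture(scope="module")
def toy_index(toy_gene):
    return ann.FeatureIndex([toy_gene])


class TestGeneModel:
    def test_derived_features_plus_strand(self, toy_gene):
        assert toy_gene.tss == 10000
        assert toy_gene.promoter() == (8000, 12001)
        assert toy_gene.utr5 == [(10000, 12000)]
        assert toy_gene.utr3 == [(18000, 20000)]
        assert toy_gene.introns == [(13000, 16000)]

    def test_minus_strand_tss_and_utrs(self):
        g = ann.GeneModel("NM_2", "G2", "chr1", "-", 1000, 5000,
                          exons=[(1000, 2000), (4000, 5000)],
                          cds=(1500, 4500))
        assert g.tss == 4999
        assert g.promoter() == (2999, 7000)
        assert g.utr5 == [(4500, 5000)]
        assert g.utr3 == [(1000, 1500)]

    def test_noncoding_has_no_utrs(self):
        g = ann.GeneModel("NR_1", "G3", "chr1", "+", 0, 1000, [(0, 1000)])
        assert g.utr5 == [] and g.utr3 == []


class TestAssignFeature:
    def test_priority_promoter_beats_intron(self, toy_index):
        # overlaps the promoter (ends 12001) and the intron via a long span
        c = _csre("chr1", 11800, 14000)
        assert ann.assign_feature(c, toy_index) == "promoter"

    def test_intergenic_when_nothing_overlaps(self, toy_index):
        assert ann.assign_feature(_csre("chr1", 50000, 50400),
                                  toy_index) == "intergenic"

    @pytest.mark.parametrize("start,end,expected", [
        (12200, 12400, "exon"),     # coding exon past the 5'UTR
        (14000, 15000, "intron"),
        (16500, 17000, "exon"),
        (18500, 19000, "utr3"),
        (8200, 8400, "promoter"),
    ])
    def test_single_feature_cases(self, toy_index, start, end, expected):
        assert ann.assign_feature(_csre("chr1", start, end),
                                  toy_index) == expected

    def test_assignment_is_total(self, toy_index):
        rng = np.random.default_rng(0)
        csres = [_csre("chr1", int(s), int(s) + 400)
                 for s in rng.integers(0, 60000, 50)]
        dist = ann.feature_distribution(csres, toy_index)
        assert sum(dist.values()) == len(csres)


class TestProximalGenes:
    def test_single_long_csre_qualifies(self, toy_gene):
        assert ann.proximal_genes([_csre("chr1", 10000, 13400)],
                                  [toy_gene]) == {"GENE1"}

    def test_gapped_coverage_excluded(self, toy_gene):
        csres = [_csre("chr1", 10000, 12000), _csre("chr1", 12200, 14200)]
        assert ann.proximal_genes(csres, [toy_gene]) == set()

    def test_no_csres_on_chromosome_excluded(self, toy_gene):
        assert ann.proximal_genes([_csre("chr2", 0, 5000)], [toy_gene]) == set()

    def test_promoter_counts_toward_run(self, toy_gene):
        # [8000, 11000) covers 2000 bp promoter + 1000 bp body contiguously
        assert ann.proximal_genes([_csre("chr1", 8000, 11000)],
                                  [toy_gene]) == {"GENE1"}

    def test_monotone_in_coverage(self, toy_gene):
        base = [_csre("chr1", 10000, 13400)]
        more = base + [_csre("chr1", 40000, 40400)]
        assert ann.proximal_genes(base, [toy_gene]) <= \
            ann.proximal_genes(more, [toy_gene])


class TestTssDistances:
    SIZES = {"chr1": 100000}

    def _genes(self, *tss):
        return [ann.GeneModel(f"NM_{i}", f"G{i}", "chr1", "+", t, t + 1000,
                              [(t, t + 1000)]) for i, t in enumerate(tss)]

    def test_edge_distance(self):
        true, _ = ann.nearest_tss_distances(
            [_csre("chr1", 6000, 6600)], self._genes(5000), self.SIZES, seed=0)
        assert true.tolist() == [1000]

    def test_minimum_over_sides(self):
        true, _ = ann.nearest_tss_distances(
            [_csre("chr1", 4000, 4200)], self._genes(0, 10000),
            self.SIZES, seed=0)
        assert true.tolist() == [4000]

    def test_controls_seeded_and_matched(self):
        csres = [_csre("chr1", 6000, 6600)]
        genes = self._genes(5000)
        _, c1 = ann.nearest_tss_distances(csres, genes, self.SIZES,
                                          n_random=5, seed=42)
        _, c2 = ann.nearest_tss_distances(csres, genes, self.SIZES,
                                          n_random=5, seed=42)
        assert np.array_equal(c1, c2) and len(c1) == 5

    def test_chromosome_without_tss_skipped(self, caplog):
        with caplog.at_level("WARNING"):
            true, _ = ann.nearest_tss_distances(
                [_csre("chr2", 0, 600)], self._genes(5000),
                {"chr1": 100000, "chr2": 100000}, seed=0)
        assert len(true) == 0


class TestOverlapEnrichment:
    SIZES = {"chr1": 200000}

    def test_no_peaks(self):
        res = ann.overlap_enrichment([_csre("chr1", 0, 600)], [], self.SIZES,
                                     n_sim=50, seed=1)
        assert res.observed == 0 and res.empirical_p == 1.0

    def test_saturated_peaks_degenerate(self, caplog):
        csres = [_csre("chr1", 1000, 1600), _csre("chr1", 5000, 5400)]
        with caplog.at_level("WARNING"):
            res = ann.overlap_enrichment(csres, [("chr1", 0, 200000)],
                                         self.SIZES, n_sim=50, seed=1)
        assert res.observed == 2
        assert (res.null_counts == 2).all()
        assert res.empirical_p == 1.0 and res.wilcoxon_p == 1.0

    def test_exact_cover_minimal_p(self):
        """Peaks covering exactly the CSREs on a long chromosome: random
        placement almost never hits them all, so p ~ 1/(n_sim+1)."""
        rng = np.random.default_rng(3)
        csres = [_csre("chr1", int(s), int(s) + 400)
                 for s in rng.choice(np.arange(0, 199000, 1000), 20,
                                     replace=False)]
        peaks = [(c.chrom, c.start, c.end) for c in csres]
        res = ann.overlap_enrichment(csres, peaks, self.SIZES,
                                     n_sim=200, seed=7)
        assert res.observed == 20
        assert res.empirical_p == pytest.approx(1 / 201, abs=0.02)
        assert res.wilcoxon_p < 1e-10

    def test_null_p_superuniform(self):
        """Under the null generator itself the empirical p-value is valid
        (super-uniform) at the 5% level across seeded replicates."""
        rng = np.random.default_rng(11)
        peaks = [("chr1", int(s), int(s) + 300)
                 for s in rng.choice(np.arange(0, 199000, 600), 60,
                                     replace=False)]
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            starts = rng.integers(0, 199600, size=8)
            csres = [_csre("chr1", int(s), int(s) + 400) for s in starts]
            res = ann.overlap_enrichment(csres, peaks, self.SIZES,
                                         n_sim=99, seed=rep)
            hits += res.empirical_p <= 0.05
        # binomial(200, 0.05) 3-sigma upper bound
        assert hits <= 0.05 * n_rep + 3 * np.sqrt(n_rep * 0.05 * 0.95)


class TestExpression:
    def test_quantile_normalize_hand_example(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        out = ann.quantile_normalize(df)
        assert out["a"].tolist() == [2.0, 3.0]
        assert out["b"].tolist() == [2.0, 3.0]

    def test_columns_share_sorted_vector_and_idempotent(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(50, 4)))
        out = ann.quantile_normalize(df)
        ref = np.sort(out.iloc[:, 0].to_numpy())
        for j in range(1, 4):
            np.testing.assert_allclose(np.sort(out.iloc[:, j]), ref)
        again = ann.quantile_normalize(out)
        np.testing.assert_allclose(again.to_numpy(), out.to_numpy(),
                                   atol=1e-12)

    def test_identical_columns_unchanged(self):
        df = pd.DataFrame({"a": [5.0, 1.0, 3.0], "b": [5.0, 1.0, 3.0]})
        out = ann.quantile_normalize(df)
        np.testing.assert_allclose(out.to_numpy(), df.to_numpy())

    def test_ties_share_rank_mean(self):
        df = pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 4.0]})
        out = ann.quantile_normalize(df)
        assert out["a"].tolist() == [2.0, 2.0]  # mean of rank means 1.5, 2.5

    def test_zscores(self):
        df = pd.DataFrame({"x": [1.0, 5.0], "y": [2.0, 5.0], "z": [3.0, 5.0]})
        z = ann.specificity_zscores(df)
        np.testing.assert_allclose(z.iloc[0], [-1, 0, 1])
        np.testing.assert_allclose(z.iloc[1], [0, 0, 0])  # constant gene
        assert abs(z.sum(axis=1)).max() < 1e-12


class TestCompareGroups:
    def test_exact_minimal_overlap(self):
        assert ann.compare_groups([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=10), rng.normal(1.0, 1.0, size=12)
        assert ann.compare_groups(a, b) == pytest.approx(
            ann.compare_groups(b, a))

    def test_identical_samples_p_one(self):
        assert ann.compare_groups([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)


class TestGeneSetEnrichment:
    def _sets(self, terms, universe):
        return ann.GeneSetCollection(terms, universe)

    def test_perfect_term_hypergeometric(self):
        universe = {f"g{i}" for i in range(10)}
        term = {f"g{i}" for i in range(5)}
        sets = self._sets({"T": term}, universe)
        df = ann.gene_set_enrichment(term, sets)
        assert df.loc[0, "p"] == pytest.approx(1 / 252, rel=1e-9)

    def test_small_terms_excluded(self):
        universe = {f"g{i}" for i in range(10)}
        sets = self._sets({"small": {"g0", "g1", "g2", "g3"}}, universe)
        assert len(ann.gene_set_enrichment({"g0", "g1"}, sets)) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_hypergeometric_tail_oracle(self, seed):
        """Fisher one-sided p equals the hypergeometric upper tail for
        random tables with universe <= 30 (checked over the full tail)."""
        rng = np.random.default_rng(seed)
        U = int(rng.integers(12, 31))
        universe = {f"g{i}" for i in range(U)}
        nt = int(rng.integers(5, min(U, 20) + 1))
        term = set(rng.choice(sorted(universe), nt, replace=False))
        nq = int(rng.integers(1, U + 1))
        query = set(rng.choice(sorted(universe), nq, replace=False))
        df = ann.gene_set_enrichment(query, self._sets({"T": term}, universe))
        a = len(query & term)
        expected = sum(
            stats.hypergeom.pmf(k, U, nt, nq)
            for k in range(a, min(nt, nq) + 1))
        assert df.loc[0, "p"] == pytest.approx(expected, rel=1e-8)

    def test_bh_step_up_hand_example(self):
        universe = {f"g{i}" for i in range(40)}
        terms = {f"T{i}": set(list(sorted(universe))[i * 6:(i + 1) * 6])
                 for i in range(3)}
        df = ann.gene_set_enrichment(set(list(sorted(universe))[:8]),
                                     self._sets(terms, universe))
        ps = df["p"].to_numpy()
        expected_q = np.minimum.accumulate(
            (ps * len(ps) / (np.arange(len(ps)) + 1))[::-1])[::-1]
        np.testing.assert_allclose(df["q"].to_numpy(), expected_q)

    def test_empty_query(self):
        universe = {f"g{i}" for i in range(10)}
        sets = self._sets({"T": set(list(universe)[:5])}, universe)
        df = ann.gene_set_enrichment(set(), sets)
        assert (df["overlap"] == 0).all()


class TestCellSpecificPeaks:
    def test_single_cell_unchanged(self):
        peaks = {"A": [("chr1", 0, 300)]}
        assert ann.cell_specific_peaks(peaks)["A"] == [("chr1", 0, 300)]

    def test_identical_peaks_cancel(self):
        peaks = {"A": [("chr1", 0, 300)], "B": [("chr1", 0, 300)]}
        out = ann.cell_specific_peaks(peaks)
        assert out["A"] == [] and out["B"] == []

    def test_partial_subtraction(self):
        peaks = {"A": [("chr1", 0, 300)], "B": [("chr1", 100, 200)]}
        out = ann.cell_specific_peaks(peaks)
        assert out["A"] == [("chr1", 0, 100), ("chr1", 200, 300)]
        assert out["B"] == []


class TestIntervalArithmetic:
    def test_merge_handles_abutting_and_overlap(self):
        assert ann.merge_intervals([(0, 10), (10, 20), (30, 40), (35, 50)]) \
            == [(0, 20), (30, 50)]

    def test_subtract_empty_remove(self):
        assert ann.subtract_intervals([(5, 15)], []) == [(5, 15)]

    def test_subtract_splits(self):
        assert ann.subtract_intervals([(0, 100)], [(20, 30), (50, 60)]) \
            == [(0, 20), (30, 50), (60, 100)]
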