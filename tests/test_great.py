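"""Regulatory domains and binomial / hypergeometric term enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from hmcblocks.great import (
    GeneModel,
    bh_fdr,
    binomial_region_test,
    build_regulatory_domains,
    hypergeometric_gene_test,
    rank_terms,
    term_enrichment_table,
)
from hmcblocks.intervals import Genome, GenomicInterval, IntervalSet


def gene(gid, chrom, strand, tss, start, end):
    return GeneModel(gid, chrom, strand, tss, start, end)


class TestRegulatoryDomains:
    def test_lone_plus_strand_gene(self):
        genome = Genome([("chr1", 10_000_000)])
        g = gene("g1", "chr1", "+", 2_000_000, 2_000_000, 2_010_000)
        d = build_regulatory_domains([g], genome)[0]
        assert (d.basal.start, d.basal.end) == (1_995_000, 2_001_000)
        assert (d.extended.start, d.extended.end) == (995_000, 3_001_000)

    def test_two_gene_extension_stops_at_neighbour_basal(self):
        genome = Genome([("chr1", 300_000)])
        ga = gene("gA", "chr1", "+", 100_000, 100_000, 110_000)
        gb = gene("gB", "chr1", "+", 200_000, 200_000, 210_000)
        da, db = build_regulatory_domains([ga, gb], genome)
        assert (da.extended.start, da.extended.end) == (0, 195_000)
        assert (db.extended.start, db.extended.end) == (101_000, 300_000)

    def test_minus_strand_basal_mirrors_orientation(self):
        genome = Genome([("chr1", 10_000_000)])
        g = gene("g1", "chr1", "-", 2_000_000, 1_990_000, 2_000_000)
        d = build_regulatory_domains([g], genome)[0]
        # upstream of a minus-strand gene lies to the right of its TSS
        assert (d.basal.start, d.basal.end) == (1_999_000, 2_005_000)

    def test_duplicate_gene_ids_rejected(self):
        genome = Genome([("chr1", 1_000_000)])
        g = gene("g1", "chr1", "+", 500_000, 500_000, 510_000)
        with pytest.raises(ValueError, match="duplicate"):
            build_regulatory_domains([g, g], genome)

    def test_extensions_never_invade_basal_domains(self):
        genome = Genome([("chr1", 2_000_000)])
        rng = np.random.default_rng(73)
        tss = np.sort(rng.choice(np.arange(20_000, 1_980_000, 10_000), 30, replace=False))
        genes = [
            gene(f"g{i}", "chr1", "+" if i % 2 else "-", int(t), int(t) - 5_000, int(t) + 5_000)
            for i, t in enumerate(tss)
        ]
        domains = build_regulatory_domains(genes, genome)
        for d in domains:
            assert d.extended.start <= d.basal.start <= d.basal.end <= d.extended.end
            ext = IntervalSet.from_intervals([d.extended])
            for other in domains:
                if other.gene_id == d.gene_id:
                    continue
                if ext.overlap_bp(other.basal) > 0:
                    # an extension may only touch a basal it already overlapped
                    own = IntervalSet.from_intervals([d.basal])
                    assert own.overlap_bp(other.basal) > 0


def exhaustive_binom_upper(n, k, p):
    return sum(math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1))


class TestBinomialRegionTest:
    def genome(self):
        return Genome([("chr1", 1000)])

    def regions(self, *mids):
        return IntervalSet.from_pairs(("chr1", m - 5, m + 5) for m in mids)

    def test_three_of_three_in_half_genome(self):
        domains = IntervalSet.from_pairs([("chr1", 0, 500)])
        p, fold = binomial_region_test(self.regions(100, 200, 300), domains, self.genome())
        assert p == pytest.approx(0.125)
        assert fold == pytest.approx(2.0)

    def test_zero_hits_give_p_one(self):
        domains = IntervalSet.from_pairs([("chr1", 0, 500)])
        p, fold = binomial_region_test(self.regions(600, 700), domains, self.genome())
        assert p == pytest.approx(1.0)
        assert fold == 0.0

    def test_whole_genome_domain(self):
        domains = IntervalSet.from_pairs([("chr1", 0, 1000)])
        p, fold = binomial_region_test(self.regions(100, 900), domains, self.genome())
        assert p == pytest.approx(1.0)
        assert fold == pytest.approx(1.0)

    @pytest.mark.parametrize("n,k,p0", [(4, 2, 0.25), (6, 5, 0.5), (10, 3, 0.1), (8, 0, 0.3)])
    def test_matches_exhaustive_enumeration(self, n, k, p0):
        # place k midpoints inside a domain of fraction p0, n-k outside
        genome = Genome([("chr1", 1000)])
        domains = IntervalSet.from_pairs([("chr1", 0, int(1000 * p0))])
        inside = [int(1000 * p0 * (i + 1) / (k + 1)) for i in range(k)]
        outside = [int(1000 * p0) + 1 + 40 * i for i in range(n - k)]
        regions = self.regions(*(inside + outside))
        p, fold = binomial_region_test(regions, domains, genome)
        assert p == pytest.approx(exhaustive_binom_upper(n, k, p0), rel=1e-9)

    def test_any_overlap_assignment_flag(self):
        genome = self.genome()
        domains = IntervalSet.from_pairs([("chr1", 0, 100)])
        regions = IntervalSet.from_pairs([("chr1", 90, 300)])  # midpoint outside
        p_mid, _ = binomial_region_test(regions, domains, genome)
        p_any, _ = binomial_region_test(regions, domains, genome, assignment="any")
        assert p_mid == 1.0 and p_any < 1.0


def exhaustive_hypergeom_upper(N, K, n, k):
    num = sum(math.comb(K, j) * math.comb(N - K, n - j) for j in range(k, min(K, n) + 1))
    return num / math.comb(N, n)


class TestHypergeometricGeneTest:
    def test_all_hits_in_term(self):
        universe = set(range(10))
        term = set(range(5))
        hits = {0, 1, 2}
        p, fold = hypergeometric_gene_test(hits, term, universe)
        assert p == pytest.approx(1 / 12)
        assert fold == pytest.approx(2.0)

    def test_term_equals_universe(self):
        u = set(range(8))
        p, fold = hypergeometric_gene_test({1, 2}, u, u)
        assert p == pytest.approx(1.0)
        assert fold == pytest.approx(1.0)

    def test_no_overlap_gives_p_one_fold_zero(self):
        p, fold = hypergeometric_gene_test({0, 1}, {5, 6}, set(range(10)))
        assert p == pytest.approx(1.0)
        assert fold == 0.0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            hypergeometric_gene_test(set(), set(), set())

    @pytest.mark.parametrize("N,K,n", [(10, 4, 3), (12, 6, 5), (9, 2, 4)])
    def test_matches_combinatorial_enumeration(self, N, K, n):
        universe = set(range(N))
        term = set(range(K))
        for k in range(0, min(K, n) + 1):
            hits = set(range(k)) | set(range(K, K + n - k))
            p, _ = hypergeometric_gene_test(hits, term, universe)
            assert p == pytest.approx(exhaustive_hypergeom_upper(N, K, n, k), rel=1e-9)


class TestFdrAndRanking:
    def test_bh_hand_applied_examples(self):
        assert bh_fdr([0.01]) == pytest.approx([0.01])
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])
        # step-up with distinct adjustments
        assert bh_fdr([0.001, 0.04, 0.9]) == pytest.approx([0.003, 0.06, 0.9])

    def test_bh_q_dominates_p_and_is_monotone(self):
        rng = np.random.default_rng(79)
        ps = rng.random(50)
        qs = bh_fdr(ps)
        assert (qs >= ps - 1e-12).all()
        order = np.argsort(ps)
        assert (np.diff(qs[order]) >= -1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_rank_terms_sorting_ties_and_oracle(self):
        rng = np.random.default_rng(83)
        df = pd.DataFrame(
            {
                "term_id": [f"T{i:03d}" for i in range(100)],
                "binom_raw_p": np.round(rng.random(100), 2),  # force ties
            }
        )
        top = rank_terms(df, top_n=10)
        full = df.sort_values(["binom_raw_p", "term_id"]).reset_index(drop=True)
        assert list(top["term_id"]) == list(full["term_id"][:10])


class TestTermTable:
    def test_planted_term_scores_best(self):
        genome = Genome([("chr1", 500_000)])
        genes = [
            gene(f"g{i}", "chr1", "+", 20_000 + 40_000 * i,
                 20_000 + 40_000 * i, 30_000 + 40_000 * i)
            for i in range(10)
        ]
        # regions piled on genes 0-2; term A = those genes, term B = others
        regions = IntervalSet.from_pairs(
            ("chr1", 21_000 + 40_000 * i + 200 * j, 21_400 + 40_000 * i + 200 * j)
            for i in range(3)
            for j in range(4)
        )
        terms = pd.DataFrame(
            [("A", "hit term", f"g{i}") for i in range(3)]
            + [("B", "background", f"g{i}") for i in range(3, 10)],
            columns=["term_id", "term_name", "gene_id"],
        )
        table = term_enrichment_table(regions, genes, terms, genome)
        ranked = rank_terms(table, top_n=2)
        assert ranked["term_id"].iloc[0] == "A"
        row = table[table.term_id == "A"].iloc[0]
        assert row.binom_fold > 1
        assert row.binom_fdr_q >= row.binom_raw_p
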