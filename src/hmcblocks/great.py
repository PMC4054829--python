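"""Regulatory-domain construction and term enrichment tests.

Each gene gets a *basal* regulatory domain around its TSS (5 kb upstream,
1 kb downstream by default, strand-oriented) and an *extended* domain that
grows from the basal domain in both directions until the nearest
neighbouring gene's basal domain, the chromosome end, or a 1 Mb cap —
whichever comes first.  Basal domains are never invaded by a neighbour's
extension, but extended domains of adjacent genes may overlap.

Two term-enrichment tests mirror the region-based/gene-based pair used by
genomic-region annotation tools:

* binomial region test — each query region is reduced to its midpoint;
  the number of midpoints landing in a term's (normalized) regulatory
  domains is tested against Binomial(n_regions, domain fraction of genome);
* hypergeometric gene test — genes hit by at least one region midpoint,
  drawn against the term's gene membership within the gene universe.

Raw p-values are corrected per test family with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .blocks import BlockSet
from .intervals import Genome, GenomicInterval, IntervalSet

__all__ = [
    "GeneModel",
    "RegulatoryDomain",
    "TermEnrichmentRow",
    "build_regulatory_domains",
    "binomial_region_test",
    "hypergeometric_gene_test",
    "bh_fdr",
    "term_enrichment_table",
    "rank_terms",
    "read_gene_models",
    "read_terms",
]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    tss: int
    start: int  # gene body, half-open
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not (self.start <= self.tss <= self.end):
            raise ValueError(f"gene {self.gene_id}: TSS outside gene body")

    @property
    def body(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass(frozen=True)
class RegulatoryDomain:
    gene_id: str
    basal: GenomicInterval
    extended: GenomicInterval


@dataclass
class TermEnrichmentRow:
    term_id: str
    term_name: str
    binom_raw_p: float
    binom_fdr_q: float
    binom_fold: float
    hyper_fdr_q: float
    hyper_fold: float


def _basal_span(
    gene: GeneModel, genome: Genome, basal_up: int, basal_down: int
) -> tuple[int, int]:
    L = genome.lengths[gene.chrom]
    if gene.strand == "+":
        s, e = gene.tss - basal_up, gene.tss + basal_down
    else:
        s, e = gene.tss - basal_down, gene.tss + basal_up
    return max(0, s), min(L, max(e, s + 1))


def build_regulatory_domains(
    genes: list[GeneModel],
    genome: Genome,
    basal_up: int = 5000,
    basal_down: int = 1000,
    max_ext: int = 1_000_000,
) -> list[RegulatoryDomain]:
    """Basal-plus-extension regulatory domains for every gene.

    Extension on each side stops at the nearest other gene's basal domain
    boundary, the chromosome end, or ``max_ext`` bp beyond the basal domain.
    """
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene ids")
    for g in genes:
        if g.chrom not in genome:
            raise ValueError(f"gene {g.gene_id}: chromosome {g.chrom!r} undeclared")
        if g.tss > genome.lengths[g.chrom]:
            raise ValueError(f"gene {g.gene_id}: TSS beyond chromosome end")
    domains: dict[str, RegulatoryDomain] = {}
    by_chrom: dict[str, list[tuple[int, int, GeneModel]]] = {}
    for g in genes:
        bs, be = _basal_span(g, genome, basal_up, basal_down)
        by_chrom.setdefault(g.chrom, []).append((bs, be, g))
    for chrom, items in by_chrom.items():
        L = genome.lengths[chrom]
        items.sort(key=lambda t: (t[0], t[1], t[2].gene_id))
        n = len(items)
        # running max of basal ends to the left, min of basal starts to the right
        for i, (bs, be, g) in enumerate(items):
            prev_end = max((items[j][1] for j in range(i)), default=0)
            next_start = min((items[j][0] for j in range(i + 1, n)), default=L)
            left = max(bs - max_ext, 0, min(prev_end, bs))
            right = min(be + max_ext, L, max(next_start, be))
            domains[g.gene_id] = RegulatoryDomain(
                g.gene_id,
                GenomicInterval(chrom, bs, be),
                GenomicInterval(chrom, left, right),
            )
    return [domains[g.gene_id] for g in genes]


def _midpoints(regions) -> list[GenomicInterval]:
    if isinstance(regions, BlockSet):
        return [b.interval for b in regions.blocks]
    if isinstance(regions, IntervalSet):
        return list(regions)
    return list(regions)


def binomial_region_test(
    regions,
    term_domains: IntervalSet,
    genome: Genome,
    assignment: str = "midpoint",
) -> tuple[float, float]:
    """Binomial test of region midpoints against the domain genome fraction.

    Returns (raw_p, fold) with fold = k / (n * p0).  With
    ``assignment='any'`` a region counts as a hit if any of its bases
    overlaps the domains instead of its midpoint.
    """
    intervals = _midpoints(regions)
    n = len(intervals)
    if n == 0:
        raise ValueError("no query regions")
    domains = IntervalSet.from_intervals(term_domains)  # normalize defensively
    p0 = domains.total_length / genome.size
    if assignment == "midpoint":
        k = sum(
            1
            for iv in intervals
            if bool(domains.contains_points(iv.chrom, np.array([iv.midpoint()]))[0])
        )
    elif assignment == "any":
        k = sum(1 for iv in intervals if domains.overlap_bp(iv) > 0)
    else:
        raise ValueError(f"unknown assignment mode {assignment!r}")
    if p0 == 0:
        if k > 0:
            raise ValueError("regions hit term domains of zero size (annotation inconsistency)")
        return 1.0, 0.0
    raw_p = float(stats.binom.sf(k - 1, n, p0))
    fold = k / (n * p0)
    return raw_p, fold


def hypergeometric_gene_test(
    hit_genes: set, term_genes: set, universe: set
) -> tuple[float, float]:
    """Over-representation of term genes among the hit genes.

    Returns (raw_p, fold) for the hypergeometric upper tail with
    N=|universe|, K=|term|, n=|hits|, k=|hits intersect term|.
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not hit_genes <= universe or not term_genes <= universe:
        raise ValueError("hit/term genes must be subsets of the universe")
    N, K, n = len(universe), len(term_genes), len(hit_genes)
    k = len(hit_genes & term_genes)
    if n == 0 or K == 0:
        return 1.0, 0.0
    raw_p = float(stats.hypergeom.sf(k - 1, N, K, n))
    fold = (k / n) / (K / N)
    return raw_p, fold


def bh_fdr(raw_ps) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    ps = np.asarray(list(raw_ps), dtype=float)
    if len(ps) == 0:
        return ps
    if ((ps < 0) | (ps > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(ps, method="fdr_bh")[1]


def term_enrichment_table(
    regions,
    genes: list[GeneModel],
    terms: pd.DataFrame,
    genome: Genome,
    basal_up: int = 5000,
    basal_down: int = 1000,
    max_ext: int = 1_000_000,
    assignment: str = "midpoint",
) -> pd.DataFrame:
    """Score every term with the binomial and hypergeometric tests.

    ``terms`` needs columns term_id, term_name, gene_id.  Returns one row
    per term with both raw and BH-corrected statistics.
    """
    domains = build_regulatory_domains(genes, genome, basal_up, basal_down, max_ext)
    dom_by_gene = {d.gene_id: d for d in domains}
    universe = {g.gene_id for g in genes}
    intervals = _midpoints(regions)
    # genes hit by >= 1 region midpoint (in their extended domain)
    hit_genes: set[str] = set()
    for d in domains:
        ext = IntervalSet.from_intervals([d.extended])
        for iv in intervals:
            if assignment == "midpoint":
                if bool(ext.contains_points(iv.chrom, np.array([iv.midpoint()]))[0]):
                    hit_genes.add(d.gene_id)
                    break
            else:
                if ext.overlap_bp(iv) > 0:
                    hit_genes.add(d.gene_id)
                    break
    rows = []
    for term_id, sub in terms.groupby("term_id", sort=True):
        term_genes = set(sub["gene_id"]) & universe
        term_name = str(sub["term_name"].iloc[0])
        term_dom = IntervalSet.from_intervals(
            dom_by_gene[g].extended for g in sorted(term_genes)
        )
        if term_dom.total_length == 0:
            continue
        binom_p, binom_fold = binomial_region_test(
            regions, term_dom, genome, assignment=assignment
        )
        hyper_p, hyper_fold = hypergeometric_gene_test(hit_genes, term_genes, universe)
        rows.append((str(term_id), term_name, binom_p, binom_fold, hyper_p, hyper_fold))
    df = pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "binom_raw_p", "binom_fold",
                 "hyper_raw_p", "hyper_fold"],
    )
    if len(df):
        df["binom_fdr_q"] = bh_fdr(df["binom_raw_p"])
        df["hyper_fdr_q"] = bh_fdr(df["hyper_raw_p"])
    else:
        df["binom_fdr_q"] = []
        df["hyper_fdr_q"] = []
    return df[
        ["term_id", "term_name", "binom_raw_p", "binom_fdr_q", "binom_fold",
         "hyper_fdr_q", "hyper_fold"]
    ]


def rank_terms(rows: pd.DataFrame, top_n: int = 10) -> pd.DataFrame:
    """Top terms sorted by raw binomial p, ties broken by term_id."""
    return (
        rows.sort_values(["binom_raw_p", "term_id"], kind="mergesort")
        .head(top_n)
        .reset_index(drop=True)
    )


def read_gene_models(path) -> list[GeneModel]:
    """Read gene models from TSV: gene_id, chrom, strand, tss, body_start, body_end."""
    df = pd.read_csv(path, sep="\t")
    return [
        GeneModel(str(r.gene_id), str(r.chrom), str(r.strand), int(r.tss),
                  int(r.body_start), int(r.body_end))
        for r in df.itertuples()
    ]


def write_gene_models(genes: list[GeneModel], path) -> None:
    pd.DataFrame(
        [(g.gene_id, g.chrom, g.strand, g.tss, g.start, g.end) for g in genes],
        columns=["gene_id", "chrom", "strand", "tss", "body_start", "body_end"],
    ).to_csv(path, sep="\t", index=False)


def read_terms(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"term_id", "term_name", "gene_id"}
    if not needed <= set(df.columns):
        raise ValueError(f"terms file must have columns {sorted(needed)}")
    return df
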