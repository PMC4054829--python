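"""Enrichment of block sets in genomic features against a random-placement null.

The statistic is base-pair weighted fold enrichment

    fold = (observed block bp in feature / total block bp) / feature_fraction

where feature_fraction is the feature's share of the genome; 1 is the
reference rate of a uniformly placed block set.  The permutation null
re-places every block, length preserved, uniformly in the genome
(chromosome chosen with probability proportional to its length among
chromosomes long enough to hold the block; start uniform within the
chromosome; placed blocks may overlap each other).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .blocks import BlockSet
from .intervals import Genome, GenomicInterval, IntervalSet

__all__ = [
    "FeatureTrack",
    "EnrichmentResult",
    "analytic_enrichment",
    "permutation_enrichment",
    "chromosome_representation",
    "expression_class_enrichment",
    "developmental_group_enrichment",
    "cgi_shores",
]


@dataclass
class FeatureTrack:
    name: str
    regions: IntervalSet


@dataclass
class EnrichmentResult:
    feature: str
    observed_bp: int
    expected_bp: float
    block_bp: int
    feature_fraction: float
    fold: float
    null_p: float | None = None
    n_perm: int | None = None
    seed: int | None = None
    perm_sd: float | None = None  # spread of one permutation's overlap bp


def _blocks_iset(blocks) -> IntervalSet:
    return blocks.intervals if isinstance(blocks, BlockSet) else blocks


def cgi_shores(cgi: IntervalSet, genome: Genome, flank: int = 2000) -> IntervalSet:
    """Standard CpG-island shores: ``flank`` bp on each side of an island,
    excluding the islands themselves, clipped to chromosome bounds."""
    flanks = []
    for iv in cgi:
        L = genome.lengths[iv.chrom]
        if iv.start > 0:
            flanks.append(GenomicInterval(iv.chrom, max(0, iv.start - flank), iv.start))
        if iv.end < L:
            flanks.append(GenomicInterval(iv.chrom, iv.end, min(L, iv.end + flank)))
    return IntervalSet.from_intervals(flanks).subtract(cgi)


def analytic_enrichment(blocks, feature: FeatureTrack | IntervalSet, genome: Genome,
                        name: str | None = None) -> EnrichmentResult:
    """Closed-form fold enrichment of a block set in one feature track."""
    if isinstance(feature, FeatureTrack):
        name = name or feature.name
        feat = feature.regions
    else:
        name = name or "feature"
        feat = feature
    iset = _blocks_iset(blocks)
    block_bp = iset.total_length
    feat_bp = feat.total_length
    if block_bp == 0:
        raise ValueError(f"empty block set for feature {name!r}")
    if feat_bp == 0:
        raise ValueError(f"empty feature track {name!r}")
    feature_fraction = feat_bp / genome.size
    observed = iset.intersect(feat).total_length
    expected = block_bp * feature_fraction
    fold = (observed / block_bp) / feature_fraction
    return EnrichmentResult(name, observed, expected, block_bp, feature_fraction, fold)


def _random_placement_overlap(
    lengths: np.ndarray,
    chrom_names: list[str],
    chrom_lengths: np.ndarray,
    feat: IntervalSet,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Summed feature-overlap bp of length-preserving random placements.

    Per-block overlaps are summed with multiplicity (placed blocks may
    overlap each other), so the expectation stays linear in block bp.
    """
    n_blocks = len(lengths)
    perm_bp = np.zeros(n_perm, dtype=np.int64)
    feat_arrays = {c: feat.array(c) for c in chrom_names}
    for b, length in enumerate(lengths):
        fits = chrom_lengths >= length
        if not fits.any():
            raise ValueError(f"block of length {length} exceeds every chromosome")
        probs = np.where(fits, chrom_lengths, 0).astype(float)
        probs /= probs.sum()
        chrom_idx = rng.choice(len(chrom_names), size=n_perm, p=probs)
        starts = np.floor(
            rng.random(n_perm) * (chrom_lengths[chrom_idx] - length + 1)
        ).astype(np.int64)
        for ci in np.unique(chrom_idx):
            mask = chrom_idx == ci
            cov = feat.coverage_between(
                chrom_names[ci], starts[mask], starts[mask] + length
            )
            perm_bp[mask] += cov
    return perm_bp


def permutation_enrichment(
    blocks,
    feature: FeatureTrack | IntervalSet,
    genome: Genome,
    n_perm: int = 1000,
    seed: int = 0,
    name: str | None = None,
) -> EnrichmentResult:
    """Empirical fold and two-sided p-value against the random-placement null.

    fold = observed bp / mean permuted bp;
    null_p uses the (r + 1)/(n + 1) empirical estimator, two-sided.
    Deterministic for a given seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    analytic = analytic_enrichment(blocks, feature, genome, name=name)
    feat = feature.regions if isinstance(feature, FeatureTrack) else feature
    iset = _blocks_iset(blocks)
    lengths = np.array([iv.length for iv in iset], dtype=np.int64)
    chrom_names = [c for c, _ in genome.chromosomes]
    chrom_lengths = np.array([l for _, l in genome.chromosomes], dtype=np.int64)
    rng = np.random.default_rng(seed)
    perm_bp = _random_placement_overlap(
        lengths, chrom_names, chrom_lengths, feat, n_perm, rng
    )
    mean_perm = float(perm_bp.mean())
    observed = analytic.observed_bp
    fold = observed / mean_perm if mean_perm > 0 else float("inf")
    r_hi = int((perm_bp >= observed).sum())
    r_lo = int((perm_bp <= observed).sum())
    null_p = min(1.0, 2.0 * min(r_hi + 1, r_lo + 1) / (n_perm + 1))
    return EnrichmentResult(
        analytic.feature,
        observed,
        mean_perm,
        analytic.block_bp,
        analytic.feature_fraction,
        fold,
        null_p=null_p,
        n_perm=n_perm,
        seed=seed,
        perm_sd=float(perm_bp.std(ddof=1)),
    )


def permutation_fold_se(result: EnrichmentResult) -> float:
    """Monte-Carlo standard error of a permutation fold estimate (delta method)."""
    if result.perm_sd is None or result.n_perm is None:
        raise ValueError("result carries no permutation information")
    return result.observed_bp * result.perm_sd / (
        np.sqrt(result.n_perm) * result.expected_bp**2
    )


def chromosome_representation(blocks, genome: Genome) -> pd.DataFrame:
    """Per-chromosome fold: block bp share relative to chromosome size share."""
    iset = _blocks_iset(blocks)
    block_bp = iset.total_length
    if block_bp == 0:
        raise ValueError("empty block set")
    rows = []
    for chrom, length in genome.chromosomes:
        on_chrom = int(
            (iset.array(chrom)[:, 1] - iset.array(chrom)[:, 0]).sum()
        )
        expected_share = length / genome.size
        fold = (on_chrom / block_bp) / expected_share
        rows.append((chrom, length, on_chrom, fold))
    return pd.DataFrame(rows, columns=["chrom", "chrom_bp", "block_bp", "fold"])


def _class_enrichment(
    blocks,
    labels: Mapping[str, str],
    gene_bodies: Mapping[str, GenomicInterval],
    order: list[str] | None = None,
) -> dict[str, float]:
    iset = _blocks_iset(blocks)
    classes: dict[str, list[GenomicInterval]] = {}
    for gene, label in labels.items():
        if gene not in gene_bodies:
            continue
        classes.setdefault(label, []).append(gene_bodies[gene])
    class_sets = {c: IntervalSet.from_intervals(ivs) for c, ivs in classes.items()}
    all_bodies = IntervalSet.from_intervals(
        gene_bodies[g] for g in labels if g in gene_bodies
    )
    all_bp = all_bodies.total_length
    blocks_in_all = iset.intersect(all_bodies).total_length
    folds: dict[str, float] = {}
    keys = order if order is not None else sorted(class_sets)
    for cls in keys:
        if cls not in class_sets:
            continue
        cls_bp = class_sets[cls].total_length
        if cls_bp == 0:
            warnings.warn(f"class {cls!r} has zero gene-body bp; omitted")
            continue
        obs = iset.intersect(class_sets[cls]).total_length
        if blocks_in_all == 0:
            folds[cls] = 0.0
            continue
        folds[cls] = (obs / blocks_in_all) / (cls_bp / all_bp)
    return folds


def expression_class_enrichment(
    blocks,
    gene_classes: Mapping[str, str],
    gene_bodies: Mapping[str, GenomicInterval],
) -> dict[str, float]:
    """Fold enrichment of blocks in low/intermediate/high expression classes.

    The reference space is the union of all analyzed gene bodies, so a
    uniformly distributed genic block set has fold 1 in every class.
    """
    return _class_enrichment(
        blocks, gene_classes, gene_bodies, order=["silent", "low", "intermediate", "high"]
    )


def developmental_group_enrichment(
    cohort_only_blocks,
    groups: Mapping[str, str],
    gene_bodies: Mapping[str, GenomicInterval],
) -> dict[str, float]:
    """Fold enrichment of cohort-only blocks in developmental gene groups I-V."""
    labels = {g: lab for g, lab in groups.items() if lab != "unassigned"}
    return _class_enrichment(
        cohort_only_blocks, labels, gene_bodies, order=["I", "II", "III", "IV", "V"]
    )
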