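"""Synthetic cohort hydroxymethylome datasets with known ground truth.

The generator emulates the statistical structure of a two-cohort (fetal
and adult liver) 5hmC profiling study on a toy genome, so that every
pipeline stage can be exercised against planted truth:

* a declared genome (default 3 chromosomes x 1 Mb) with non-overlapping
  gene models and independent feature tracks (CpG islands with derived
  shores, enhancers, repeats, miRNA and lncRNA genes);
* cohort-shared and cohort-exclusive planted 5hmC blocks, each detected
  independently per sample with a configurable probability and emitted as
  a boundary-jittered peak, plus sample-unique noise peaks whose placement
  is biased toward or away from features (CGI/genic enrichment, repeat
  depletion);
* an expression matrix with genes planted into developmental groups I-V
  (silent in one cohort, >= fold-biased, or non-developmental) under
  log-normal sample noise;
* a gene-set table in which one term's genes host the fetal-exclusive
  planted blocks;
* TAB-Seq C/T counts drawn binomially from planted per-site (5hmC, 5mC)
  levels in one fetal-specific and one adult-specific validation interval.

Everything is deterministic for a given config seed; per-stage generators
derive their streams from the master seed with fixed offsets.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from bisect import bisect_left, insort
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blocks import PeakSet
from .enrichment import FeatureTrack, cgi_shores
from .expression import ExpressionMatrix, classify_levels
from .great import GeneModel, write_gene_models
from .intervals import Genome, GenomicInterval, IntervalSet, write_bed

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "SimulatedDataset",
    "generate_genome",
    "generate_cohort_peaks",
    "generate_expression",
    "generate_terms",
    "generate_tabseq",
    "simulate_dataset",
    "write_dataset",
    "block_recovery",
]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults mirror the study design
    at toy scale (two cohorts of 8 and 7 samples)."""

    seed: int = 0
    n_chroms: int = 3
    chrom_length: int = 1_000_000
    n_fetal_samples: int = 8
    n_adult_samples: int = 7
    # planted consensus blocks and per-sample peaks
    n_blocks_per_cohort: int = 150
    frac_shared: float = 0.3
    block_length: tuple = (600, 1800)
    detection_prob: float = 0.6
    jitter: int = 50
    noise_peaks_per_sample: int = 15
    noise_length: tuple = (600, 1800)
    read_mean: float = 50.0
    read_dispersion: float = 5.0
    min_block_gap: int = 250
    cohort_gene_bias: float = 0.5
    # feature tracks
    n_genes: int = 300
    gene_length: tuple = (1500, 4500)
    n_cgi: int = 90
    cgi_length: tuple = (500, 1500)
    n_enhancers: int = 100
    enhancer_length: tuple = (500, 1500)
    n_repeats: int = 300
    repeat_length: tuple = (200, 1000)
    n_mirna: int = 30
    mirna_length: tuple = (80, 120)
    n_lncrna: int = 40
    lncrna_length: tuple = (1000, 3000)
    shore_flank: int = 2000
    placement_bias: dict = field(
        default_factory=lambda: {"cgi": 6.0, "refseq_genes": 2.0, "repeats": 0.1}
    )
    # expression
    group_sizes: dict = field(
        default_factory=lambda: {"I": 12, "II": 21, "III": 231, "IV": 28, "V": 8}
    )
    silent_level: float = 0.1
    silent_threshold: float = 1.0
    expr_base_range: tuple = (4.0, 64.0)
    dev_fold: float = 3.0
    expr_sigma: float = 0.2
    # gene sets
    n_terms: int = 20
    term_size: int = 15
    # TAB-Seq validation
    tabseq_depth: int = 500
    tabseq_samples_per_cohort: int = 4

    def __post_init__(self) -> None:
        if not (0 <= self.detection_prob <= 1 and 0 <= self.frac_shared <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if any(v < 0 for v in self.placement_bias.values()):
            raise ValueError("bias multipliers must be >= 0")
        if sum(self.group_sizes.values()) > self.n_genes:
            raise ValueError("group sizes exceed the number of genes")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ValueError(f"unknown simulation options: {sorted(unknown)}")
        d = dict(d)
        for key in ("block_length", "noise_length", "gene_length", "cgi_length",
                    "enhancer_length", "repeat_length", "mirna_length",
                    "lncrna_length", "expr_base_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class TruthTable:
    """Ground truth consistent with the emitted files."""

    gene_order: list = field(default_factory=list)
    gene_groups: dict = field(default_factory=dict)
    gene_levels: dict = field(default_factory=dict)  # cohort -> gene -> level
    planted_blocks: dict = field(default_factory=dict)  # label -> [(c, s, e)]
    host_genes: dict = field(default_factory=dict)  # cohort -> [gene ids]
    enriched_term: str | None = None
    feature_bias: dict = field(default_factory=dict)
    tabseq_intervals: dict = field(default_factory=dict)
    tabseq_truth: list = field(default_factory=list)

    def planted(self, label: str) -> IntervalSet:
        return IntervalSet.from_pairs(self.planted_blocks.get(label, []))

    def cohort_planted(self, cohort: str) -> IntervalSet:
        """All blocks a cohort should exhibit: shared plus cohort-only."""
        return self.planted("shared").union(self.planted(f"{cohort}_only"))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: Genome
    features: dict
    genes: list
    truth: TruthTable
    peak_sets: dict  # cohort -> list[PeakSet]
    expression: ExpressionMatrix
    terms: pd.DataFrame
    tabseq: pd.DataFrame


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stage])


def _sample_length(rng, length_range) -> int:
    lo, hi = length_range
    return int(rng.integers(lo, hi + 1))


class _Occupancy:
    """Per-chromosome sorted occupied spans, for non-overlap placement."""

    def __init__(self):
        self.spans: dict[str, list[tuple[int, int]]] = {}

    def clear_of(self, chrom: str, start: int, end: int, gap: int = 0) -> bool:
        spans = self.spans.get(chrom, [])
        i = bisect_left(spans, (start, start))
        for j in (i - 1, i):
            if 0 <= j < len(spans):
                s, e = spans[j]
                if start < e + gap and s < end + gap:
                    return False
        return True

    def add(self, chrom: str, start: int, end: int) -> None:
        insort(self.spans.setdefault(chrom, []), (start, end))


def _place_track(
    rng, genome: Genome, n: int, length_range, occupancy: _Occupancy | None = None,
    gap: int = 0, max_tries_per: int = 500,
) -> list[GenomicInterval]:
    own = occupancy or _Occupancy()
    chrom_names = genome.names
    chrom_lengths = np.array([genome.lengths[c] for c in chrom_names], dtype=float)
    probs = chrom_lengths / chrom_lengths.sum()
    out = []
    for _ in range(n):
        placed = False
        for _try in range(max_tries_per):
            length = _sample_length(rng, length_range)
            ci = int(rng.choice(len(chrom_names), p=probs))
            L = genome.lengths[chrom_names[ci]]
            if length > L:
                continue
            start = int(rng.integers(0, L - length + 1))
            if own.clear_of(chrom_names[ci], start, start + length, gap):
                own.add(chrom_names[ci], start, start + length)
                out.append(GenomicInterval(chrom_names[ci], start, start + length))
                placed = True
                break
        if not placed:
            raise ValueError(
                "infeasible feature density: could not place a non-overlapping "
                f"interval of length range {length_range}"
            )
    return out


def generate_genome(
    config: SimulationConfig,
) -> tuple[Genome, dict, list[GeneModel]]:
    """Toy genome, feature tracks and gene models, deterministic under seed."""
    rng = _rng(config, 1)
    genome = Genome(
        [(f"chr{i + 1}", config.chrom_length) for i in range(config.n_chroms)]
    )
    gene_ivs = _place_track(
        rng, genome, config.n_genes, config.gene_length, gap=100
    )
    genes = []
    for i, iv in enumerate(gene_ivs):
        strand = "+" if rng.random() < 0.5 else "-"
        tss = iv.start if strand == "+" else iv.end
        genes.append(
            GeneModel(f"gene_{i:04d}", iv.chrom, strand, tss, iv.start, iv.end)
        )
    tracks = {
        "refseq_genes": IntervalSet.from_intervals(gene_ivs),
        "mirna": IntervalSet.from_intervals(
            _place_track(rng, genome, config.n_mirna, config.mirna_length)
        ),
        "lncrna": IntervalSet.from_intervals(
            _place_track(rng, genome, config.n_lncrna, config.lncrna_length)
        ),
        "enhancers": IntervalSet.from_intervals(
            _place_track(rng, genome, config.n_enhancers, config.enhancer_length)
        ),
        "cgi": IntervalSet.from_intervals(
            _place_track(rng, genome, config.n_cgi, config.cgi_length)
        ),
        "repeats": IntervalSet.from_intervals(
            _place_track(rng, genome, config.n_repeats, config.repeat_length)
        ),
    }
    tracks["cgi_shores"] = cgi_shores(tracks["cgi"], genome, config.shore_flank)
    features = {name: FeatureTrack(name, regions) for name, regions in tracks.items()}
    return genome, features, genes


def assign_gene_groups(config: SimulationConfig, genes: list[GeneModel]) -> dict:
    """Plant developmental group labels I-V; any remainder is group III."""
    rng = _rng(config, 2)
    ids = [g.gene_id for g in genes]
    perm = list(rng.permutation(ids))
    groups: dict[str, str] = {}
    pos = 0
    for label in ("I", "II", "III", "IV", "V"):
        size = int(config.group_sizes.get(label, 0))
        for g in perm[pos : pos + size]:
            groups[g] = label
        pos += size
    for g in perm[pos:]:
        groups[g] = "III"
    return groups


def _bias_weight(iv: GenomicInterval, features: dict, bias: dict) -> float:
    """Placement weight of a candidate interval under the feature biases.

    Each bias multiplier acts on the fraction of the interval's footprint
    covered by the feature (``bias ** overlap_fraction``), so the planted
    effect applies to the base-pair-weighted occupancy that downstream
    enrichment statistics measure, not just to a single anchor point.
    """
    w = 1.0
    for name, mult in bias.items():
        track = features.get(name)
        if track is None or mult == 1.0:
            continue
        frac = track.regions.overlap_bp(iv) / iv.length
        if frac > 0:
            w *= float(mult) ** frac
    return w


def _biased_place(
    rng, genome: Genome, length: int, features: dict, bias: dict,
    occupancy: _Occupancy | None = None, gap: int = 0, max_tries: int = 2000,
) -> GenomicInterval:
    chrom_names = genome.names
    chrom_lengths = np.array([genome.lengths[c] for c in chrom_names], dtype=float)
    probs = chrom_lengths / chrom_lengths.sum()
    w_max = max(1.0, math.prod(max(1.0, b) for b in bias.values())) if bias else 1.0
    for _ in range(max_tries):
        ci = int(rng.choice(len(chrom_names), p=probs))
        L = genome.lengths[chrom_names[ci]]
        if length > L:
            continue
        start = int(rng.integers(0, L - length + 1))
        iv = GenomicInterval(chrom_names[ci], start, start + length)
        if occupancy is not None and not occupancy.clear_of(
            iv.chrom, iv.start, iv.end, gap
        ):
            continue
        w = _bias_weight(iv, features, bias)
        if rng.random() * w_max < w:
            if occupancy is not None:
                occupancy.add(iv.chrom, iv.start, iv.end)
            return iv
    raise ValueError("could not place interval under the configured biases")


def generate_cohort_peaks(
    config: SimulationConfig,
    genome: Genome,
    features: dict,
    genes: list[GeneModel],
    truth: TruthTable,
) -> dict:
    """Plant blocks, then emit per-sample peak sets with noise.

    Cohort-exclusive blocks are preferentially placed inside the bodies of
    that cohort's developmentally biased genes (groups I/II for fetal-only,
    IV/V for adult-only), emulating the coupling between developmental
    hydroxymethylation and developmental transcription.
    """
    rng = _rng(config, 3)
    n_shared = int(round(config.frac_shared * config.n_blocks_per_cohort))
    n_only = config.n_blocks_per_cohort - n_shared
    gene_by_id = {g.gene_id: g for g in genes}
    targets = {
        "fetal": sorted(
            g for g, lab in truth.gene_groups.items() if lab in ("I", "II")
        ),
        "adult": sorted(
            g for g, lab in truth.gene_groups.items() if lab in ("IV", "V")
        ),
    }
    occupancy = _Occupancy()
    gap = config.min_block_gap

    def place_global() -> GenomicInterval:
        length = _sample_length(rng, config.block_length)
        return _biased_place(
            rng, genome, length, features, config.placement_bias, occupancy, gap
        )

    def place_in_gene(gene: GeneModel) -> GenomicInterval | None:
        body_len = gene.end - gene.start
        length = min(_sample_length(rng, config.block_length), body_len)
        for _ in range(50):
            start = gene.start + int(rng.integers(0, body_len - length + 1))
            if occupancy.clear_of(gene.chrom, start, start + length, gap):
                occupancy.add(gene.chrom, start, start + length)
                return GenomicInterval(gene.chrom, start, start + length)
        return None

    planted: dict[str, list[GenomicInterval]] = {
        "shared": [],
        "fetal_only": [],
        "adult_only": [],
    }
    hosts: dict[str, list[str]] = {"fetal": [], "adult": []}
    for _ in range(n_shared):
        planted["shared"].append(place_global())
    for cohort in ("fetal", "adult"):
        for _ in range(n_only):
            iv = None
            if targets[cohort] and rng.random() < config.cohort_gene_bias:
                gid = targets[cohort][int(rng.integers(0, len(targets[cohort])))]
                iv = place_in_gene(gene_by_id[gid])
                if iv is not None:
                    hosts[cohort].append(gid)
            if iv is None:
                iv = place_global()
            planted[f"{cohort}_only"].append(iv)
    truth.planted_blocks = {
        label: [(iv.chrom, iv.start, iv.end) for iv in ivs]
        for label, ivs in planted.items()
    }
    truth.host_genes = {c: sorted(set(h)) for c, h in hosts.items()}
    truth.feature_bias = dict(config.placement_bias)

    def jittered(iv: GenomicInterval) -> GenomicInterval:
        j = config.jitter
        if j == 0:
            return iv
        L = genome.lengths[iv.chrom]
        s = iv.start + int(rng.integers(-j, j + 1))
        e = iv.end + int(rng.integers(-j, j + 1))
        s = max(0, s)
        e = min(L, e)
        if e <= s:  # pathological jitter on a tiny block; keep the original
            return iv
        return GenomicInterval(iv.chrom, s, e)

    def read_count() -> int:
        r = config.read_dispersion
        p = r / (r + config.read_mean)
        return int(rng.negative_binomial(r, p)) + 1

    cohort_sizes = {"fetal": config.n_fetal_samples, "adult": config.n_adult_samples}
    peak_sets: dict[str, list[PeakSet]] = {}
    for cohort in ("fetal", "adult"):
        cohort_blocks = planted["shared"] + planted[f"{cohort}_only"]
        sets = []
        for s_idx in range(cohort_sizes[cohort]):
            intervals: list[GenomicInterval] = []
            reads: list[int] = []
            for block in cohort_blocks:
                if rng.random() < config.detection_prob:
                    intervals.append(jittered(block))
                    reads.append(read_count())
            for _ in range(config.noise_peaks_per_sample):
                length = _sample_length(rng, config.noise_length)
                intervals.append(
                    _biased_place(
                        rng, genome, length, features, config.placement_bias
                    )
                )
                reads.append(read_count())
            sets.append(
                PeakSet.from_raw(
                    f"{cohort}_{s_idx + 1:02d}", cohort, intervals, reads, genome
                )
            )
        peak_sets[cohort] = sets
    return peak_sets


def generate_expression(
    config: SimulationConfig, truth: TruthTable
) -> ExpressionMatrix:
    """Expression matrix realizing the planted groups under log-normal noise."""
    rng = _rng(config, 4)
    gene_ids = truth.gene_order
    lo, hi = config.expr_base_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(gene_ids)))
    f_mean = np.empty(len(gene_ids))
    a_mean = np.empty(len(gene_ids))
    for i, g in enumerate(gene_ids):
        grp = truth.gene_groups[g]
        b = base[i]
        if grp == "I":
            f_mean[i], a_mean[i] = b, config.silent_level
        elif grp == "II":
            f_mean[i], a_mean[i] = config.dev_fold * b, b
        elif grp == "IV":
            f_mean[i], a_mean[i] = b, config.dev_fold * b
        elif grp == "V":
            f_mean[i], a_mean[i] = config.silent_level, b
        else:
            f_mean[i], a_mean[i] = b, b
    samples = [f"fetal_{i + 1:02d}" for i in range(config.n_fetal_samples)] + [
        f"adult_{i + 1:02d}" for i in range(config.n_adult_samples)
    ]
    cohorts = {s: ("fetal" if s.startswith("fetal") else "adult") for s in samples}
    cols = {}
    for s in samples:
        mean = f_mean if cohorts[s] == "fetal" else a_mean
        noise = np.exp(rng.normal(0.0, config.expr_sigma, size=len(gene_ids)))
        cols[s] = mean * noise
    values = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    expr = ExpressionMatrix(values, cohorts)
    # planted level classes follow from the noiseless cohort means
    truth.gene_levels = {
        "fetal": classify_levels(
            pd.Series(f_mean, index=gene_ids), config.silent_threshold
        ).to_dict(),
        "adult": classify_levels(
            pd.Series(a_mean, index=gene_ids), config.silent_threshold
        ).to_dict(),
    }
    return expr


def generate_terms(config: SimulationConfig, truth: TruthTable) -> pd.DataFrame:
    """Gene-set table; term T000 collects hosts of fetal-exclusive blocks."""
    rng = _rng(config, 5)
    gene_ids = list(truth.gene_order)
    rows = []
    hosts = list(truth.host_genes.get("fetal", []))
    fallback = sorted(
        g for g, lab in truth.gene_groups.items() if lab in ("I", "II")
    )
    members = hosts[: config.term_size]
    for g in fallback:
        if len(members) >= config.term_size:
            break
        if g not in members:
            members.append(g)
    if members:
        truth.enriched_term = "T000"
        for g in sorted(members):
            rows.append(("T000", "planted_target_pathway", g))
    for t in range(1, config.n_terms):
        chosen = rng.choice(
            len(gene_ids), size=min(config.term_size, len(gene_ids)), replace=False
        )
        for gi in sorted(chosen):
            rows.append((f"T{t:03d}", f"random_pathway_{t:03d}", gene_ids[gi]))
    return pd.DataFrame(rows, columns=["term_id", "term_name", "gene_id"])


def generate_tabseq(config: SimulationConfig, truth: TruthTable) -> pd.DataFrame:
    """Binomially sampled TAB-Seq counts for two validation intervals.

    One interval sits in a fetal-exclusive planted block (4 CpGs, high
    5hmC in fetal samples only) and one in an adult-exclusive block
    (7 CpGs, high 5hmC in adult samples only).
    """
    rng = _rng(config, 6)
    specs = []
    for cohort, n_cpg, label in (("fetal", 4, "fetal_specific"),
                                 ("adult", 7, "adult_specific")):
        blocks = truth.planted_blocks.get(f"{cohort}_only", [])
        if blocks:
            chrom, start, end = blocks[0]
            specs.append((label, cohort, chrom, int(start), int(end), n_cpg))
    truth.tabseq_intervals = {
        label: {"cohort": cohort, "chrom": chrom, "start": start, "end": end}
        for label, cohort, chrom, start, end, _ in specs
    }
    samples = [
        (f"fetal_{i + 1:02d}", "fetal")
        for i in range(min(config.tabseq_samples_per_cohort, config.n_fetal_samples))
    ] + [
        (f"adult_{i + 1:02d}", "adult")
        for i in range(min(config.tabseq_samples_per_cohort, config.n_adult_samples))
    ]
    rows = []
    truth_rows = []
    depth = config.tabseq_depth
    for label, home_cohort, chrom, start, end, n_cpg in specs:
        positions = np.linspace(start + 10, end - 10, n_cpg).astype(int)
        for sample_id, cohort in samples:
            if cohort == home_cohort:
                h_sample = rng.uniform(0.2, 0.35) if cohort == "fetal" else rng.uniform(0.45, 0.6)
            else:
                h_sample = rng.uniform(0.0, 0.04)
            m_sample = rng.uniform(0.2, 0.4)
            for pos in positions:
                h, m = float(h_sample), float(m_sample)
                ox_c = int(rng.binomial(depth, h))
                bs_c = int(rng.binomial(depth, min(1.0, h + m)))
                rows.append(
                    (sample_id, cohort, label, chrom, int(pos), ox_c, depth - ox_c,
                     bs_c, depth - bs_c)
                )
                truth_rows.append(
                    {"sample_id": sample_id, "interval_id": label, "chrom": chrom,
                     "pos": int(pos), "h": h, "m": m}
                )
    truth.tabseq_truth = truth_rows
    return pd.DataFrame(
        rows,
        columns=["sample_id", "cohort", "interval_id", "chrom", "pos",
                 "ox_c", "ox_t", "bs_c", "bs_t"],
    )


def simulate_dataset(config: SimulationConfig | None = None, **overrides) -> SimulatedDataset:
    """Run all generators in dependency order and return the full dataset."""
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = dataclasses.replace(config, **overrides)
    genome, features, genes = generate_genome(config)
    truth = TruthTable(gene_order=[g.gene_id for g in genes])
    truth.gene_groups = assign_gene_groups(config, genes)
    peak_sets = generate_cohort_peaks(config, genome, features, genes, truth)
    expression = generate_expression(config, truth)
    terms = generate_terms(config, truth)
    tabseq = generate_tabseq(config, truth)
    return SimulatedDataset(
        config, genome, features, genes, truth, peak_sets, expression, terms, tabseq
    )


def write_dataset(ds: SimulatedDataset, out_dir) -> dict:
    """Write every artifact as plain-text files consumable by the CLI.

    Returns a dict of the paths written.
    """
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    feat_dir = os.path.join(out_dir, "features")
    peak_dir = os.path.join(out_dir, "peaks")
    os.makedirs(feat_dir, exist_ok=True)
    os.makedirs(peak_dir, exist_ok=True)
    paths: dict[str, object] = {}
    genome_path = os.path.join(out_dir, "genome.tsv")
    ds.genome.to_tsv(genome_path)
    paths["genome"] = genome_path
    for name, track in ds.features.items():
        p = os.path.join(feat_dir, f"{name}.bed")
        write_bed(track.regions, p)
        paths.setdefault("features", {})[name] = p  # type: ignore[union-attr]
    genes_path = os.path.join(out_dir, "genes.tsv")
    write_gene_models(ds.genes, genes_path)
    paths["genes"] = genes_path
    manifest_path = os.path.join(out_dir, "manifest.tsv")
    with open(manifest_path, "w") as fh:
        for cohort in ("fetal", "adult"):
            for ps in ds.peak_sets[cohort]:
                bed = os.path.join(peak_dir, f"{ps.sample_id}.bed")
                write_bed(list(ps.peaks), bed, scores=list(ps.reads))
                fh.write(f"{ps.sample_id}\t{cohort}\t{bed}\n")
    paths["manifest"] = manifest_path
    expr_path = os.path.join(out_dir, "expression.tsv")
    ds.expression.to_tsv(expr_path)
    paths["expression"] = expr_path
    expr_manifest = os.path.join(out_dir, "expression_samples.tsv")
    with open(expr_manifest, "w") as fh:
        for s, c in ds.expression.cohorts.items():
            fh.write(f"{s}\t{c}\n")
    paths["expression_samples"] = expr_manifest
    terms_path = os.path.join(out_dir, "terms.tsv")
    ds.terms.to_csv(terms_path, sep="\t", index=False)
    paths["terms"] = terms_path
    tabseq_path = os.path.join(out_dir, "tabseq.tsv")
    ds.tabseq.to_csv(tabseq_path, sep="\t", index=False)
    paths["tabseq"] = tabseq_path
    truth_path = os.path.join(out_dir, "truth.json")
    ds.truth.to_json(truth_path)
    paths["truth"] = truth_path
    return paths


def block_recovery(called: IntervalSet, planted: IntervalSet) -> dict:
    """Base-level sensitivity and precision of called blocks vs planted truth."""
    inter = called.intersect(planted).total_length
    return {
        "sensitivity": inter / planted.total_length if planted.total_length else 0.0,
        "precision": inter / called.total_length if called.total_length else 0.0,
        "called_bp": called.total_length,
        "planted_bp": planted.total_length,
    }
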