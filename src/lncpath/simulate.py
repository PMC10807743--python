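"""Synthetic data with planted structure for every pipeline stage.

The generator emulates a skin-disease / cytokine-stimulation RNA-Seq
compendium at desk scale: a gene catalog of protein-coding genes and
lncRNAs laid out without overlap on synthetic chromosomes; a latent-factor
negative-binomial count model in which each cytokine pathway has a
per-sample activity that is shifted in its stimulated condition, loads on
that pathway's member genes and planted lncRNAs, and thereby induces both
gene-gene correlation (what the classifier learns) and condition
differential expression (what the DE stage tests); transcript sequences
with cluster-specific enriched 6-mers; GMT gene sets; and uniform interval
tracks with recorded nearest-gene distances.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .catalog import GeneCatalog, GeneRecord, GenomicInterval
from .de import ExpressionMatrix

__all__ = [
    "PathwaySpec",
    "SimulationConfig",
    "GroundTruth",
    "simulate_catalog",
    "simulate_target_catalog",
    "simulate_expression",
    "simulate_sequences",
    "simulate_gene_sets",
    "simulate_intervals",
    "standard_benchmark_config",
]


@dataclass
class PathwaySpec:
    name: str
    n_members: int
    n_planted_lncrna: int
    # fraction of planted lncRNAs given a negative loading, emulating
    # lncRNAs anticorrelated with their pathway
    negative_fraction: float = 0.0


@dataclass
class SimulationConfig:
    n_protein_coding: int = 2000
    n_lncrna: int = 500
    pathways: list[PathwaySpec] = field(default_factory=list)
    n_samples_per_condition: int = 20
    conditions: list[str] | None = None   # default: <pathway>_stim/_unstim per pathway
    effect_size: float = 2.0              # loading on log2 scale
    activity_shift: float = 2.0           # latent activity shift in active conditions
    dispersion: float = 0.2               # NB dispersion (var = m + d*m^2)
    baseline_log_mean_range: tuple[float, float] = (3.0, 9.0)
    lncrna_baseline_offset: float = -2.0  # lncRNAs express lower than coding genes
    gene_length_range: tuple[int, int] = (200, 2000)
    intergenic_gap: int = 5000
    chromosome_length: int = 30_000_000
    n_chromosomes: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_protein_coding < 0 or self.n_lncrna < 0:
            raise ValueError("gene counts must be >= 0")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        total_members = sum(p.n_members for p in self.pathways)
        if total_members > self.n_protein_coding:
            raise ValueError("pathway members exceed protein-coding genes")
        total_planted = sum(p.n_planted_lncrna for p in self.pathways)
        if total_planted > self.n_lncrna:
            raise ValueError("planted lncRNAs exceed lncRNA count")

    def condition_labels(self) -> list[str]:
        if self.conditions is not None:
            return list(self.conditions)
        labels = []
        for p in self.pathways:
            labels += [f"{p.name}_stim", f"{p.name}_unstim"]
        return labels or ["control"]

    def active_conditions(self, pathway: str) -> set[str]:
        """Conditions where a pathway's latent activity is shifted: its own
        stimulated condition plus any 'lesional' condition."""
        return {
            c for c in self.condition_labels()
            if c == f"{pathway}_stim" or "lesional" in c
        }


@dataclass
class GroundTruth:
    pathway_members: dict[str, set[str]] = field(default_factory=dict)
    planted_lncrnas: dict[str, set[str]] = field(default_factory=dict)
    planted_signs: dict[str, dict[str, int]] = field(default_factory=dict)
    de_genes: dict[str, dict[str, float]] = field(default_factory=dict)
    sequence_clusters: dict[int, dict] = field(default_factory=dict)
    mark_distances: dict[str, float] = field(default_factory=dict)


def _layout_genes(ids, biotypes, cfg: SimulationConfig, rng) -> GeneCatalog:
    catalog = GeneCatalog()
    chrom_i, cursor = 0, 1
    for gid, bt in zip(ids, biotypes):
        length = int(rng.integers(*cfg.gene_length_range))
        n_exons = int(rng.integers(1, 4))
        if cursor + 3 * length > cfg.chromosome_length:
            chrom_i += 1
            cursor = 1
            if chrom_i >= cfg.n_chromosomes:
                raise ValueError(
                    "infeasible layout: too many genes for the configured chromosomes"
                )
        chrom = f"chr{chrom_i + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = cursor
        exon_len = max(50, length // n_exons)
        for _ in range(n_exons):
            exons.append(GenomicInterval(chrom, pos, pos + exon_len - 1, strand))
            pos += exon_len + int(rng.integers(100, 500))  # intron
        catalog.add(GeneRecord(gene_id=gid, biotype=bt, exons=exons, source="sim"))
        cursor = pos + cfg.intergenic_gap
    return catalog


def simulate_catalog(config: SimulationConfig) -> tuple[GeneCatalog, GroundTruth]:
    """Non-overlapping genes on synthetic chromosomes, with pathway members
    and planted lncRNAs assigned in the ground truth."""
    rng = np.random.default_rng(config.seed)
    pc_ids = [f"PC{i:05d}" for i in range(config.n_protein_coding)]
    lnc_ids = [f"LNC{i:05d}" for i in range(config.n_lncrna)]
    ids = pc_ids + lnc_ids
    biotypes = ["protein_coding"] * len(pc_ids) + ["lncRNA"] * len(lnc_ids)
    catalog = _layout_genes(ids, biotypes, config, rng)

    truth = GroundTruth()
    pc_pool = list(pc_ids)
    lnc_pool = list(lnc_ids)
    rng.shuffle(pc_pool)
    rng.shuffle(lnc_pool)
    for spec in config.pathways:
        members = set(pc_pool[: spec.n_members])
        pc_pool = pc_pool[spec.n_members:]
        planted = set(lnc_pool[: spec.n_planted_lncrna])
        lnc_pool = lnc_pool[spec.n_planted_lncrna:]
        truth.pathway_members[spec.name] = members
        truth.planted_lncrnas[spec.name] = planted
        n_neg = int(round(spec.negative_fraction * len(planted)))
        planted_sorted = sorted(planted)
        signs = {g: (-1 if i < n_neg else 1) for i, g in enumerate(planted_sorted)}
        truth.planted_signs[spec.name] = signs
    return catalog, truth


def simulate_target_catalog(
    catalog: GeneCatalog, n_overlapping: int, n_clear: int, seed: int = 0
) -> GeneCatalog:
    """A second catalog for merge testing: ``n_overlapping`` decoys that
    each overlap an exon of an existing gene, plus ``n_clear`` genes placed
    beyond all existing ones."""
    rng = np.random.default_rng(seed)
    target = GeneCatalog()
    victims = rng.choice(len(catalog.genes), size=n_overlapping, replace=False)
    for i, vi in enumerate(victims):
        victim = catalog.genes[int(vi)]
        e = victim.exons[0]
        mid = (e.start + e.end) // 2
        target.add(
            GeneRecord(
                gene_id=f"DECOY{i:04d}",
                biotype="lncRNA",
                exons=[GenomicInterval(e.chromosome, max(1, mid - 100), mid + 100, e.strand)],
                source="sim_target",
            )
        )
    # clear genes: placed past the maximum occupied coordinate per chromosome
    max_end: dict[str, int] = {}
    for g in catalog.genes:
        s = g.span
        max_end[s.chromosome] = max(max_end.get(s.chromosome, 0), s.end)
    chroms = sorted(max_end)
    for i in range(n_clear):
        chrom = chroms[i % len(chroms)]
        start = max_end[chrom] + 10_000
        target.add(
            GeneRecord(
                gene_id=f"CLEAR{i:04d}",
                biotype="lncRNA",
                exons=[GenomicInterval(chrom, start, start + 500, "+")],
                source="sim_target",
            )
        )
        max_end[chrom] = start + 500
    return target


def simulate_expression(
    catalog: GeneCatalog, truth: GroundTruth, config: SimulationConfig
) -> ExpressionMatrix:
    """Latent-factor negative-binomial counts.

    Pathway p's activity a_{p,j} is N(shift, 1) in p's active conditions and
    N(0, 1) elsewhere; gene g has log2 mean b_g + lambda_g * a_{p,j} with
    lambda_g = +/- effect_size for members and planted lncRNAs, 0 otherwise.
    Counts ~ NB via a gamma-Poisson mixture with the configured dispersion.
    Updates ``truth.de_genes`` with the true log2 fold changes for each
    pathway's stim:unstim contrast.
    """
    rng = np.random.default_rng(config.seed + 1)
    gene_ids = catalog.gene_ids()
    biotype = {g.gene_id: g.biotype for g in catalog.genes}
    for name, members in truth.pathway_members.items():
        missing = (members | truth.planted_lncrnas.get(name, set())) - set(gene_ids)
        if missing:
            raise ValueError(f"truth references unknown genes: {sorted(missing)[:5]}")

    conditions = config.condition_labels()
    n_per = config.n_samples_per_condition
    sample_ids, sample_cond = [], []
    for cond in conditions:
        for i in range(n_per):
            sample_ids.append(f"S_{cond}_{i:03d}")
            sample_cond.append(cond)
    n_samples = len(sample_ids)

    pathway_names = [p.name for p in config.pathways]
    activity = np.zeros((len(pathway_names), n_samples))
    for pi, name in enumerate(pathway_names):
        active = config.active_conditions(name)
        shift = np.array([config.activity_shift if c in active else 0.0
                          for c in sample_cond])
        activity[pi] = shift + rng.standard_normal(n_samples)

    lo, hi = config.baseline_log_mean_range
    baseline = rng.uniform(lo, hi, size=len(gene_ids))
    loading = np.zeros(len(gene_ids))
    pathway_of = np.full(len(gene_ids), -1)
    idx = {g: i for i, g in enumerate(gene_ids)}
    for pi, name in enumerate(pathway_names):
        for g in truth.pathway_members[name]:
            loading[idx[g]] = config.effect_size
            pathway_of[idx[g]] = pi
        signs = truth.planted_signs.get(name, {})
        for g in truth.planted_lncrnas.get(name, set()):
            loading[idx[g]] = config.effect_size * signs.get(g, 1)
            pathway_of[idx[g]] = pi
    for i, g in enumerate(gene_ids):
        if biotype[g] != "protein_coding":
            baseline[i] += config.lncrna_baseline_offset

    if pathway_names:
        log2_mu = baseline[:, None] + np.where(
            pathway_of[:, None] >= 0,
            loading[:, None] * activity[np.maximum(pathway_of, 0)],
            0.0,
        )
    else:
        log2_mu = np.broadcast_to(baseline[:, None], (len(gene_ids), n_samples)).copy()
    mu = np.exp2(log2_mu)
    if config.dispersion > 0:
        shape = 1.0 / config.dispersion
        lam = rng.gamma(shape, mu / shape)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(np.int64)

    meta = pd.DataFrame(
        {
            "condition": sample_cond,
            "group": sample_cond,
            "sex": rng.choice(["F", "M"], size=n_samples),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    matrix = ExpressionMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                            columns=sample_ids),
        sample_metadata=meta,
    )

    for name in pathway_names:
        contrast = f"{name}_stim:{name}_unstim"
        if f"{name}_stim" in conditions and f"{name}_unstim" in conditions:
            affected = {}
            signs = truth.planted_signs.get(name, {})
            for g in truth.pathway_members[name]:
                affected[g] = config.effect_size * config.activity_shift
            for g in truth.planted_lncrnas.get(name, set()):
                affected[g] = config.effect_size * config.activity_shift * signs.get(g, 1)
            truth.de_genes[contrast] = affected
    return matrix


def simulate_sequences(
    truth: GroundTruth,
    n_clusters: int = 3,
    motifs_per_cluster: int = 50,
    length: int = 2000,
    enrichment: float = 8.0,
    n_per_cluster: int = 60,
    k: int = 6,
    seed: int = 0,
) -> dict[str, str]:
    """Transcript sequences with cluster-specific enriched k-mers.

    Background is i.i.d. uniform ACGT; each cluster's motifs are implanted
    so their expected occurrence rate is ``enrichment`` times the uniform
    background rate.  Updates ``truth.sequence_clusters``.
    """
    if enrichment < 1:
        raise ValueError("enrichment must be >= 1")
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    all_kmers_needed = n_clusters * motifs_per_cluster
    motif_idx = rng.choice(4**k, size=all_kmers_needed, replace=False)

    def idx_to_kmer(i: int) -> str:
        s = []
        for _ in range(k):
            s.append("ACGT"[i % 4])
            i //= 4
        return "".join(reversed(s))

    windows = length - k + 1
    background_rate = windows / 4**k  # expected occurrences per motif
    extra = (enrichment - 1.0) * background_rate

    sequences: dict[str, str] = {}
    for c in range(n_clusters):
        motifs = [idx_to_kmer(int(m))
                  for m in motif_idx[c * motifs_per_cluster:(c + 1) * motifs_per_cluster]]
        members = []
        for t in range(n_per_cluster):
            tid = f"TX_C{c}_{t:03d}"
            seq = rng.choice(alphabet, size=length)
            for motif in motifs:
                n_insert = rng.poisson(extra)
                if n_insert:
                    starts = rng.integers(0, length - k + 1, size=n_insert)
                    mb = np.frombuffer(motif.encode(), dtype="S1")
                    for s0 in starts:
                        seq[s0:s0 + k] = mb
            sequences[tid] = b"".join(seq).decode()
            members.append(tid)
        truth.sequence_clusters[c] = {"transcripts": set(members), "motifs": motifs}
    return sequences


def simulate_gene_sets(truth: GroundTruth) -> dict[str, set[str]]:
    """Pathway gene sets: exactly the protein-coding members from truth."""
    return {name: set(m) for name, m in truth.pathway_members.items()}


def simulate_intervals(
    catalog: GeneCatalog, n_marks: int, seed: int = 0, mark_length: int = 500
) -> tuple[list[GenomicInterval], GroundTruth]:
    """Uniformly placed interval marks with brute-force nearest-mark
    distances per gene recorded in a fresh GroundTruth."""
    rng = np.random.default_rng(seed)
    spans = [g.span for g in catalog.genes]
    chroms = sorted({s.chromosome for s in spans})
    extent = {c: max(s.end for s in spans if s.chromosome == c) for c in chroms}
    marks = []
    for _ in range(n_marks):
        c = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(1, max(2, extent[c])))
        marks.append(GenomicInterval(c, start, start + mark_length - 1))
    truth = GroundTruth()
    for g in catalog.genes:
        s = g.span
        best = float("inf")
        for m in marks:
            if m.chromosome != s.chromosome:
                continue
            if s.start <= m.end and m.start <= s.end:
                best = 0.0
                break
            if m.start > s.end:
                best = min(best, m.start - s.end - 1)
            else:
                best = min(best, s.start - m.end - 1)
        truth.mark_distances[g.gene_id] = best
    return marks, truth


def standard_benchmark_config(seed: int = 0) -> SimulationConfig:
    """The canonical synthetic benchmark: 2000 protein-coding + 500 lncRNA
    genes, three pathways of 120/200/300 members with 50 planted lncRNAs
    each, effect size 2, 20 samples in each of the 6 stim/unstim
    conditions (120 samples)."""
    return SimulationConfig(
        n_protein_coding=2000,
        n_lncrna=500,
        pathways=[
            PathwaySpec("IFNG", 120, 50),
            PathwaySpec("IL4", 200, 50),
            PathwaySpec("TNF", 300, 50),
        ],
        n_samples_per_condition=20,
        effect_size=2.0,
        seed=seed,
    )


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
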