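"""Gene catalogs: GTF parsing, exon-overlap testing and catalog merging.

A comprehensive lncRNA catalog is built by merging annotation sources
(e.g. a reference annotation, a body-map atlas and tissue-expressed
transcripts).  The merge rule is deliberately conservative: a target gene
is added only if none of its exons overlaps any exon already in the
reference, so each source can only contribute genes occupying genuinely
unannotated exonic space.  Coordinates follow the GTF convention
throughout: 1-based, closed intervals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "GeneRecord",
    "GeneCatalog",
    "MergeReport",
    "GtfParseError",
    "parse_gtf",
    "write_gtf",
    "exons_overlap",
    "merge_catalogs",
    "sequential_merge",
]

BIOTYPES = ("protein_coding", "lncRNA", "pseudogene", "short_ncRNA", "other")

_SHORT_NCRNA = {
    "miRNA", "snRNA", "snoRNA", "rRNA", "tRNA", "scaRNA", "sRNA",
    "scRNA", "misc_RNA", "ribozyme", "vault_RNA", "Mt_rRNA", "Mt_tRNA",
}
_LNC_ALIASES = {"lncRNA", "lincRNA", "antisense", "antisense_RNA",
                "sense_intronic", "sense_overlapping", "processed_transcript",
                "3prime_overlapping_ncRNA", "bidirectional_promoter_lncRNA",
                "macro_lncRNA", "non_coding"}


def map_biotype(raw: str | None) -> str:
    """Collapse an annotation biotype string to the five-way scheme."""
    if raw is None:
        return "other"
    if raw == "protein_coding":
        return "protein_coding"
    if raw in _LNC_ALIASES:
        return "lncRNA"
    if "pseudogene" in raw:
        return "pseudogene"
    if raw in _SHORT_NCRNA:
        return "short_ncRNA"
    return "other"


@dataclass(frozen=True)
class GenomicInterval:
    """1-based closed interval on a chromosome strand."""

    chromosome: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chromosome:
            raise ValueError("chromosome must be non-empty")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end {self.end} < start {self.start}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of + - . , got {self.strand!r}")

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass
class GeneRecord:
    gene_id: str
    biotype: str
    exons: list[GenomicInterval]
    gene_name: str = ""
    source: str = ""

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        chroms = {e.chromosome for e in self.exons}
        if len(chroms) > 1:
            raise ValueError(f"gene {self.gene_id} has exons on multiple chromosomes: {chroms}")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")

    @property
    def span(self) -> GenomicInterval:
        """Hull of the exons."""
        e0 = self.exons[0]
        return GenomicInterval(
            e0.chromosome,
            min(e.start for e in self.exons),
            max(e.end for e in self.exons),
            e0.strand,
        )


class GeneCatalog:
    """A set of gene records with a per-chromosome exon interval index."""

    def __init__(self, genes: list[GeneRecord] | None = None):
        self.genes: list[GeneRecord] = []
        self._by_id: dict[str, GeneRecord] = {}
        self._index: dict[str, IntervalTree] = {}
        for g in genes or []:
            self.add(g)

    def add(self, gene: GeneRecord) -> None:
        if gene.gene_id in self._by_id:
            raise ValueError(f"duplicate gene_id {gene.gene_id!r}")
        self.genes.append(gene)
        self._by_id[gene.gene_id] = gene
        for e in gene.exons:
            # interval trees are half-open; closed [s, e] -> [s, e+1)
            self._index.setdefault(e.chromosome, IntervalTree()).addi(
                e.start, e.end + 1, gene
            )

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def by_biotype(self, biotype: str) -> list[GeneRecord]:
        return [g for g in self.genes if g.biotype == biotype]

    def overlapping_genes(self, gene: GeneRecord, same_strand: bool = False) -> list[GeneRecord]:
        """Genes of this catalog with >= 1 base of exonic overlap with `gene`."""
        hits: dict[str, GeneRecord] = {}
        for e in gene.exons:
            tree = self._index.get(e.chromosome)
            if tree is None:
                continue
            for iv in tree.overlap(e.start, e.end + 1):
                other: GeneRecord = iv.data
                if same_strand and other.span.strand != e.strand:
                    continue
                hits.setdefault(other.gene_id, other)
        return sorted(hits.values(), key=lambda g: (g.span.start, g.gene_id))


@dataclass
class MergeReport:
    n_reference: int
    n_candidates: int
    n_added: int
    n_excluded: int
    excluded_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        assert self.n_added + self.n_excluded == self.n_candidates


class GtfParseError(ValueError):
    pass


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def parse_gtf(path, source: str | None = None) -> GeneCatalog:
    """Read a GTF file into a GeneCatalog.

    One record per distinct ``gene_id``; exons come from feature rows of
    type ``exon`` (duplicates deduplicated, transcript structure collapsed
    to the gene-level exon union).  A gene with only a ``gene`` row gets a
    single exon equal to that row's span.  Biotype is taken from the
    ``gene_type``/``gene_biotype`` attribute and collapsed to the five-way
    scheme; unknowns map to ``other``.
    """
    path = str(path)
    label = source if source is not None else path
    exons: dict[str, set[GenomicInterval]] = {}
    spans: dict[str, GenomicInterval] = {}
    biotypes: dict[str, str] = {}
    names: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GtfParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = cols
            try:
                ivl = GenomicInterval(chrom, int(start), int(end),
                                      strand if strand in "+-" else ".")
            except ValueError as exc:
                raise GtfParseError(f"{path}:{lineno}: {exc}") from exc
            ad = _parse_attributes(attrs)
            gid = ad.get("gene_id")
            if not gid:
                raise GtfParseError(f"{path}:{lineno}: missing gene_id attribute")
            if gid not in exons:
                exons[gid] = set()
                order.append(gid)
            bt = ad.get("gene_type") or ad.get("gene_biotype")
            if bt and gid not in biotypes:
                biotypes[gid] = map_biotype(bt)
            if "gene_name" in ad and gid not in names:
                names[gid] = ad["gene_name"]
            if feature == "exon":
                exons[gid].add(ivl)
            elif feature == "gene":
                spans[gid] = ivl
    catalog = GeneCatalog()
    for gid in order:
        ex = sorted(exons[gid], key=lambda e: (e.start, e.end))
        if not ex:
            if gid not in spans:
                # rows existed (e.g. transcript/CDS only) but no exon/gene span
                raise GtfParseError(f"{path}: gene {gid} has no exon or gene rows")
            ex = [spans[gid]]
        catalog.add(
            GeneRecord(
                gene_id=gid,
                biotype=biotypes.get(gid, "other"),
                exons=ex,
                gene_name=names.get(gid, ""),
                source=label,
            )
        )
    return catalog


def write_gtf(catalog: GeneCatalog, path) -> None:
    """Write a catalog as GTF (gene row plus one row per exon).

    ``parse_gtf(write_gtf(c))`` reproduces gene ids, biotypes and exon
    coordinates.
    """
    with open(str(path), "w") as fh:
        fh.write("##provider: lncpath\n")
        for g in catalog.genes:
            span = g.span
            attrs = f'gene_id "{g.gene_id}"; gene_type "{g.biotype}";'
            if g.gene_name:
                attrs += f' gene_name "{g.gene_name}";'
            src = g.source or "lncpath"
            fh.write(
                f"{span.chromosome}\t{src}\tgene\t{span.start}\t{span.end}\t.\t{span.strand}\t.\t{attrs}\n"
            )
            for e in g.exons:
                fh.write(
                    f"{e.chromosome}\t{src}\texon\t{e.start}\t{e.end}\t.\t{e.strand}\t.\t{attrs}\n"
                )


def exons_overlap(a: GeneRecord, b: GeneRecord, same_strand: bool = False) -> bool:
    """True iff some exon of ``a`` and some exon of ``b`` share >= 1 base on
    the same chromosome (strand ignored unless ``same_strand``)."""
    for ea in a.exons:
        for eb in b.exons:
            if same_strand and ea.strand != eb.strand:
                continue
            if ea.overlaps(eb):
                return True
    return False


def merge_catalogs(
    reference: GeneCatalog, target: GeneCatalog, same_strand: bool = False
) -> tuple[GeneCatalog, MergeReport]:
    """Add to ``reference`` every target gene with no exonic overlap against
    the reference.

    Target genes are tested against the original reference only, never
    against each other: two mutually overlapping target genes that both
    miss the reference are both added.
    """
    collisions = [gid for gid in target.gene_ids() if gid in reference]
    if collisions:
        raise ValueError(f"gene_id collision between catalogs: {collisions[:5]}")
    merged = GeneCatalog(list(reference.genes))
    excluded: list[tuple[str, str]] = []
    added = 0
    for g in target.genes:
        hits = reference.overlapping_genes(g, same_strand=same_strand)
        if hits:
            excluded.append((g.gene_id, hits[0].gene_id))
        else:
            merged.add(g)
            added += 1
    report = MergeReport(
        n_reference=len(reference),
        n_candidates=len(target),
        n_added=added,
        n_excluded=len(excluded),
        excluded_pairs=excluded,
    )
    return merged, report


def sequential_merge(
    catalogs: list[GeneCatalog], same_strand: bool = False
) -> tuple[GeneCatalog, list[MergeReport]]:
    """Left fold of merge_catalogs over an ordered list of catalogs.

    Order matters whenever later sources overlap each other; the caller
    owns the ordering (reference first).
    """
    if not catalogs:
        raise ValueError("need at least one catalog")
    merged = catalogs[0]
    reports: list[MergeReport] = []
    for target in catalogs[1:]:
        merged, rep = merge_catalogs(merged, target, same_strand=same_strand)
        reports.append(rep)
    return merged, reports
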