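"""Readers and writers for the text formats the pipeline exchanges:
GMT gene sets, BED intervals, TSV count matrices and FASTA sequences."""

from __future__ import annotations

import json

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .catalog import GenomicInterval
from .de import ExpressionMatrix
from .simulate import GroundTruth

__all__ = [
    "read_gmt", "write_gmt",
    "read_bed", "write_bed",
    "read_expression", "write_expression",
    "read_fasta", "write_fasta",
    "write_ground_truth", "read_ground_truth",
]


def read_gmt(path) -> dict[str, set[str]]:
    """GMT: one gene set per line — name, description, member ids (tabs)."""
    sets: dict[str, set[str]] = {}
    with open(str(path)) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 id")
            sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(gene_sets: dict[str, set[str]], path, description: str = "lncpath") -> None:
    with open(str(path), "w") as fh:
        for name in gene_sets:
            members = "\t".join(sorted(gene_sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def read_bed(path) -> list[GenomicInterval]:
    """BED (0-based half-open) to 1-based closed intervals."""
    out = []
    with open(str(path)) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
            out.append(GenomicInterval(chrom, start + 1, end, strand))
    return out


def write_bed(intervals: list[GenomicInterval], path) -> None:
    with open(str(path), "w") as fh:
        for i, iv in enumerate(intervals):
            fh.write(f"{iv.chromosome}\t{iv.start - 1}\t{iv.end}\tmark{i}\t0\t{iv.strand if iv.strand != '.' else '+'}\n")


def read_expression(counts_path, metadata_path) -> ExpressionMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    return ExpressionMatrix(counts=counts, sample_metadata=meta.loc[counts.columns])


def write_expression(matrix: ExpressionMatrix, counts_path, metadata_path) -> None:
    matrix.counts.to_csv(counts_path, sep="\t")
    matrix.sample_metadata.to_csv(metadata_path, sep="\t")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=tid, description="") for tid, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "pathway_members": {k: sorted(v) for k, v in truth.pathway_members.items()},
        "planted_lncrnas": {k: sorted(v) for k, v in truth.planted_lncrnas.items()},
        "planted_signs": truth.planted_signs,
        "de_genes": truth.de_genes,
        "sequence_clusters": {
            str(k): {"transcripts": sorted(v["transcripts"]), "motifs": v["motifs"]}
            for k, v in truth.sequence_clusters.items()
        },
        "mark_distances": {
            k: (None if v == float("inf") else v) for k, v in truth.mark_distances.items()
        },
    }
    with open(str(path), "w") as fh:
        json.dump(payload, fh, indent=1)


def read_ground_truth(path) -> GroundTruth:
    with open(str(path)) as fh:
        payload = json.load(fh)
    truth = GroundTruth()
    truth.pathway_members = {k: set(v) for k, v in payload["pathway_members"].items()}
    truth.planted_lncrnas = {k: set(v) for k, v in payload["planted_lncrnas"].items()}
    truth.planted_signs = payload.get("planted_signs", {})
    truth.de_genes = payload.get("de_genes", {})
    truth.sequence_clusters = {
        int(k): {"transcripts": set(v["transcripts"]), "motifs": v["motifs"]}
        for k, v in payload.get("sequence_clusters", {}).items()
    }
    truth.mark_distances = {
        k: (float("inf") if v is None else v)
        for k, v in payload.get("mark_distances", {}).items()
    }
    return truth
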