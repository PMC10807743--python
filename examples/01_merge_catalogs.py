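"""Merge gene catalogs by exon overlap.

Builds a tiny reference catalog and a target catalog in which one gene
overlaps a reference exon and one sits in clear space, then merges them.
Only the non-overlapping gene is added; the report names each exclusion
and the reference gene responsible.
"""

from lncpath.catalog import GeneCatalog, GeneRecord, GenomicInterval, merge_catalogs


def gene(gid, chrom, exons, biotype="lncRNA"):
    return GeneRecord(
        gene_id=gid, biotype=biotype,
        exons=[GenomicInterval(chrom, s, e, "+") for s, e in exons],
    )


reference = GeneCatalog([
    gene("REF_A", "chr1", [(1_000, 1_400), (2_000, 2_300)], biotype="protein_coding"),
    gene("REF_B", "chr2", [(5_000, 5_800)]),
])
target = GeneCatalog([
    gene("TGT_overlapping", "chr1", [(2_250, 2_600)]),   # shares bases with REF_A's 2nd exon
    gene("TGT_intronic", "chr1", [(1_500, 1_900)]),      # inside REF_A's intron: no exon overlap
    gene("TGT_clear", "chr2", [(9_000, 9_500)]),
])

merged, report = merge_catalogs(reference, target)

print(f"reference genes: {report.n_reference}, candidates: {report.n_candidates}")
print(f"added: {report.n_added}, excluded: {report.n_excluded}")
for tgt_id, ref_id in report.excluded_pairs:
    print(f"  excluded {tgt_id} (exon overlap with {ref_id})")
print("merged catalog:", ", ".join(merged.gene_ids()))
# The intronic gene survives: the merge tests exon overlap, not span overlap,
# so genes nested in another gene's intron are kept as distinct annotations.
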