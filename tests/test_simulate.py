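"""Synthetic-data generator: determinism, layout, planted signal and the
consistency of ground truth with the emitted artifacts."""

import numpy as np
import pytest

from lncpath.catalog import merge_catalogs, write_gtf, parse_gtf
from lncpath.de import log_cpm
from lncpath.simulate import (
    PathwaySpec,
    SimulationConfig,
    simulate_catalog,
    simulate_expression,
    simulate_gene_sets,
    simulate_intervals,
    simulate_sequences,
    simulate_target_catalog,
)
from lncpath.stats import nearest_feature_distance
from lncpath.kmer import count_kmers, kmer_labels
from oracles import exons_overlap_bruteforce


def _small_cfg(**kw):
    defaults = dict(
        n_protein_coding=100, n_lncrna=30,
        pathways=[PathwaySpec("P", 20, 10)],
        n_samples_per_condition=10, seed=1,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestCatalogSimulation:
    def test_genes_mutually_nonoverlapping(self):
        catalog, _ = simulate_catalog(_small_cfg())
        genes = catalog.genes
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                assert not exons_overlap_bruteforce(genes[i], genes[j])

    def test_same_seed_identical_gtf_bytes(self, tmp_path):
        for name in ("a", "b"):
            catalog, _ = simulate_catalog(_small_cfg())
            write_gtf(catalog, tmp_path / f"{name}.gtf")
        assert (tmp_path / "a.gtf").read_bytes() == (tmp_path / "b.gtf").read_bytes()

    def test_truth_ids_exist_in_catalog(self):
        catalog, truth = simulate_catalog(_small_cfg())
        ids = set(catalog.gene_ids())
        for members in truth.pathway_members.values():
            assert members <= ids
        for planted in truth.planted_lncrnas.values():
            assert planted <= ids

    def test_decoys_excluded_and_clear_added_by_merge(self):
        catalog, _ = simulate_catalog(_small_cfg())
        target = simulate_target_catalog(catalog, n_overlapping=5, n_clear=7, seed=3)
        merged, report = merge_catalogs(catalog, target)
        assert report.n_excluded == 5
        assert report.n_added == 7
        assert {p[0] for p in report.excluded_pairs} == {f"DECOY{i:04d}" for i in range(5)}

    def test_infeasible_layout_rejected(self):
        cfg = _small_cfg(n_protein_coding=5000, chromosome_length=100_000, n_chromosomes=1)
        with pytest.raises(ValueError, match="infeasible"):
            simulate_catalog(cfg)


class TestExpressionSimulation:
    def test_same_seed_identical_counts(self):
        cfg = _small_cfg()
        c1, t1 = simulate_catalog(cfg)
        m1 = simulate_expression(c1, t1, cfg)
        c2, t2 = simulate_catalog(cfg)
        m2 = simulate_expression(c2, t2, cfg)
        assert m1.counts.equals(m2.counts)

    def test_null_effect_gives_no_condition_correlation(self):
        cfg = _small_cfg(n_protein_coding=300, n_lncrna=0, effect_size=0.0,
                         n_samples_per_condition=100,
                         pathways=[PathwaySpec("P", 30, 0)])
        catalog, truth = simulate_catalog(cfg)
        m = simulate_expression(catalog, truth, cfg)
        lc = log_cpm(m)
        stim = (m.sample_metadata["condition"] == "P_stim").to_numpy().astype(float)
        rs = np.array([np.corrcoef(lc.iloc[i], stim)[0, 1] for i in range(lc.shape[0])])
        assert np.mean(np.abs(rs) < 0.2) >= 0.95

    def test_planted_genes_track_pathway_activity(self):
        cfg = _small_cfg(
            n_protein_coding=300, n_lncrna=80,
            pathways=[PathwaySpec("P", 30, 20)],
            n_samples_per_condition=100, effect_size=2.0, dispersion=0.01,
        )
        catalog, truth = simulate_catalog(cfg)
        m = simulate_expression(catalog, truth, cfg)
        lc = np.log2(m.counts + 0.5)
        members = sorted(truth.pathway_members["P"])
        proxy = lc.loc[members].mean(axis=0)  # near-noiseless activity readout
        for g in sorted(truth.planted_lncrnas["P"]):
            assert np.corrcoef(lc.loc[g], proxy)[0, 1] > 0.8

    def test_negative_fraction_plants_anticorrelated_lncrnas(self):
        cfg = _small_cfg(
            n_protein_coding=300, n_lncrna=80,
            pathways=[PathwaySpec("P", 30, 20, negative_fraction=0.5)],
            n_samples_per_condition=60, effect_size=2.0, dispersion=0.01,
        )
        catalog, truth = simulate_catalog(cfg)
        m = simulate_expression(catalog, truth, cfg)
        lc = np.log2(m.counts + 0.5)
        proxy = lc.loc[sorted(truth.pathway_members["P"])].mean(axis=0)
        signs = truth.planted_signs["P"]
        for g, sign in signs.items():
            r = np.corrcoef(lc.loc[g], proxy)[0, 1]
            assert np.sign(r) == sign

    def test_lncrna_baselines_lower(self):
        cfg = _small_cfg(n_protein_coding=200, n_lncrna=200, pathways=[])
        catalog, truth = simulate_catalog(cfg)
        m = simulate_expression(catalog, truth, cfg)
        pc_mean = m.counts.iloc[:200].mean(axis=1).median()
        lnc_mean = m.counts.iloc[200:].mean(axis=1).median()
        assert lnc_mean < pc_mean


class TestSequenceSimulation:
    def test_enriched_kmers_occur_above_background(self):
        from lncpath.simulate import GroundTruth
        truth = GroundTruth()
        seqs = simulate_sequences(truth, n_clusters=2, motifs_per_cluster=5,
                                  length=2000, enrichment=8.0, n_per_cluster=20, seed=4)
        labels = kmer_labels(6)
        for c, info in truth.sequence_clusters.items():
            members = sorted(info["transcripts"])
            counts = sum(count_kmers(seqs[t], 6) for t in members)
            total_windows = counts.sum()
            background = total_windows / 4**6
            for motif in info["motifs"]:
                assert counts[labels.index(motif)] >= 4 * background

    def test_null_enrichment_gives_uniform_sequences(self):
        from lncpath.simulate import GroundTruth
        truth = GroundTruth()
        seqs = simulate_sequences(truth, n_clusters=2, motifs_per_cluster=5,
                                  length=2000, enrichment=1.0, n_per_cluster=10, seed=4)
        labels = kmer_labels(6)
        counts = sum(count_kmers(s, 6) for s in seqs.values())
        planted = [labels.index(m) for info in truth.sequence_clusters.values()
                   for m in info["motifs"]]
        background = counts.sum() / 4**6
        # planted motifs are not inflated when enrichment is 1
        assert counts[planted].mean() < 2 * background

    def test_same_seed_identical_fasta(self, tmp_path):
        from lncpath.simulate import GroundTruth
        from lncpath.io import write_fasta
        for name in ("a", "b"):
            truth = GroundTruth()
            seqs = simulate_sequences(truth, n_clusters=1, motifs_per_cluster=3,
                                      length=500, enrichment=4.0, n_per_cluster=5, seed=7)
            write_fasta(seqs, tmp_path / f"{name}.fa")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()


class TestGeneSetsAndIntervals:
    def test_gene_sets_match_truth_exactly(self):
        catalog, truth = simulate_catalog(_small_cfg())
        sets = simulate_gene_sets(truth)
        assert sets == truth.pathway_members

    def test_gmt_round_trip(self, tmp_path):
        from lncpath.io import read_gmt, write_gmt
        catalog, truth = simulate_catalog(_small_cfg())
        sets = simulate_gene_sets(truth)
        write_gmt(sets, tmp_path / "s.gmt")
        assert read_gmt(tmp_path / "s.gmt") == sets

    def test_recorded_distances_match_module_computation(self):
        catalog, _ = simulate_catalog(_small_cfg())
        marks, truth = simulate_intervals(catalog, n_marks=50, seed=2)
        computed = nearest_feature_distance(catalog.genes, marks)
        assert computed == truth.mark_distances

    def test_mark_inside_gene_has_distance_zero(self):
        catalog, _ = simulate_catalog(_small_cfg())
        g = catalog.genes[0]
        from lncpath.catalog import GenomicInterval
        mark = GenomicInterval(g.span.chromosome, g.span.start, g.span.start + 10)
        d = nearest_feature_distance([g], [mark])
        assert d[g.gene_id] == 0
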