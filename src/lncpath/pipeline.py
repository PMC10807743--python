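"""End-to-end orchestration: simulate -> merge -> DE -> predict -> k-mer ->
enrich, from one config, with per-stage seeds and a reproducibility
manifest.

The global seed is fanned out to per-stage seeds by stable hashing of the
stage name, so adding a stage never perturbs earlier stages' randomness.
Each stage writes its outputs before the next starts; a failure aborts with
the failing stage named and leaves a FAILED marker beside the partial
outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import catalog as cat
from . import de as de_mod
from . import io as io_mod
from . import kmer as kmer_mod
from . import predict as pred_mod
from . import simulate as sim_mod
from .kmer import enrichment_table

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "stage_seed", "load_config"]

STAGES = ("simulate", "merge", "de", "predict", "kmer", "enrich")


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    # synthetic mode: if set, stage inputs are generated rather than read
    simulate: dict | None = None
    # file inputs (used when simulate is None)
    gtfs: list[str] = field(default_factory=list)
    counts: str | None = None
    metadata: str | None = None
    gene_sets: str | None = None
    fasta: str | None = None
    # stage parameters (defaults mirror the published analysis)
    contrasts: list[str] = field(default_factory=list)  # "groupA:groupB"
    covariates: list[str] = field(default_factory=list)
    lfc_threshold: float = 1.0
    fdr_threshold: float = 0.05
    n_trials: int = 100
    n_trees: int = 100
    folds: int = 10
    kmer_k: int = 6
    adjacency_threshold: float = 0.13
    same_strand_only: bool = False
    resume: bool = False

    def validate(self) -> None:
        if self.simulate is None:
            for path in [*self.gtfs, self.counts, self.metadata, self.gene_sets]:
                if path is None:
                    raise ValueError("non-synthetic runs need gtfs, counts, metadata and gene_sets")
                if not Path(path).exists():
                    raise ValueError(f"input file not found: {path}")
            if self.fasta is not None and not Path(self.fasta).exists():
                raise ValueError(f"input file not found: {self.fasta}")


def load_config(path) -> PipelineConfig:
    with open(str(path)) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig(**data)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, outputs: list[Path], elapsed: float) -> None:
        self.stages[stage] = {
            "outputs": {
                str(p.name): hashlib.sha256(p.read_bytes()).hexdigest() for p in outputs
            },
            "seconds": round(elapsed, 3),
        }

    def write(self, path) -> None:
        with open(str(path), "w") as fh:
            json.dump({"config_hash": self.config_hash, "seed": self.seed,
                       "stages": self.stages}, fh, indent=1)


def _config_hash(config: PipelineConfig) -> str:
    from dataclasses import asdict
    return hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> RunManifest:
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_config_hash(config), seed=config.seed)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    state: dict = {}
    try:
        for stage in STAGES:
            t0 = time.monotonic()
            outputs = _run_stage(stage, config, state, outdir)
            manifest.record(stage, outputs, time.monotonic() - t0)
    except Exception as exc:
        failed_marker.write_text(f"stage failed: {exc}\n")
        raise RuntimeError(f"pipeline failed in stage: {exc}") from exc
    manifest.write(outdir / "manifest.json")
    return manifest


def _outputs_exist(paths: list[Path]) -> bool:
    return all(p.exists() for p in paths)


def _run_stage(stage: str, config: PipelineConfig, state: dict, outdir: Path) -> list[Path]:
    seed = stage_seed(config.seed, stage)
    fn = {
        "simulate": _stage_simulate,
        "merge": _stage_merge,
        "de": _stage_de,
        "predict": _stage_predict,
        "kmer": _stage_kmer,
        "enrich": _stage_enrich,
    }[stage]
    try:
        return fn(config, state, outdir, seed)
    except Exception as exc:
        raise RuntimeError(f"{stage}: {exc}") from exc


def _stage_simulate(config, state, outdir: Path, seed: int) -> list[Path]:
    if config.simulate is None:
        state["catalog"] = None
        return []
    sim = dict(config.simulate)
    pathways = [sim_mod.PathwaySpec(**p) for p in sim.pop("pathways", [])]
    seq_opts = sim.pop("sequences", {})
    n_target_overlap = sim.pop("n_target_overlapping", 0)
    n_target_clear = sim.pop("n_target_clear", 0)
    cfg = sim_mod.SimulationConfig(pathways=pathways, seed=seed, **sim)
    catalog, truth = sim_mod.simulate_catalog(cfg)
    matrix = sim_mod.simulate_expression(catalog, truth, cfg)
    sequences = sim_mod.simulate_sequences(truth, seed=seed + 1, **seq_opts)
    gene_sets = sim_mod.simulate_gene_sets(truth)

    paths = {
        "reference_gtf": outdir / "reference.gtf",
        "target_gtf": outdir / "target.gtf",
        "counts": outdir / "counts.tsv",
        "metadata": outdir / "metadata.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "fasta": outdir / "transcripts.fa",
        "truth": outdir / "truth.json",
    }
    cat.write_gtf(catalog, paths["reference_gtf"])
    target = sim_mod.simulate_target_catalog(
        catalog, n_target_overlap, n_target_clear, seed=seed + 2
    )
    cat.write_gtf(target, paths["target_gtf"])
    io_mod.write_expression(matrix, paths["counts"], paths["metadata"])
    io_mod.write_gmt(gene_sets, paths["gene_sets"])
    io_mod.write_fasta(sequences, paths["fasta"])
    io_mod.write_ground_truth(truth, paths["truth"])

    state.update(catalog=catalog, target=target, matrix=matrix,
                 gene_sets=gene_sets, sequences=sequences, truth=truth,
                 sim_cfg=cfg)
    return list(paths.values())


def _stage_merge(config, state, outdir: Path, seed: int) -> list[Path]:
    if config.simulate is not None:
        catalogs = [state["catalog"], state["target"]]
    else:
        catalogs = [cat.parse_gtf(p) for p in config.gtfs]
    merged, reports = cat.sequential_merge(catalogs, same_strand=config.same_strand_only)
    out_gtf = outdir / "merged.gtf"
    out_rep = outdir / "merge_report.tsv"
    cat.write_gtf(merged, out_gtf)
    with open(out_rep, "w") as fh:
        fh.write("step\tn_reference\tn_candidates\tn_added\tn_excluded\n")
        for i, r in enumerate(reports):
            fh.write(f"{i}\t{r.n_reference}\t{r.n_candidates}\t{r.n_added}\t{r.n_excluded}\n")
    state["merged"] = merged
    return [out_gtf, out_rep]


def _stage_de(config, state, outdir: Path, seed: int) -> list[Path]:
    if config.simulate is not None:
        matrix = state["matrix"]
        contrasts = config.contrasts or [
            f"{p.name}_stim:{p.name}_unstim" for p in state["sim_cfg"].pathways
        ]
    else:
        matrix = io_mod.read_expression(config.counts, config.metadata)
        contrasts = config.contrasts
        state["matrix"] = matrix
    tables = []
    for c in contrasts:
        a, b = c.split(":")
        tables.append(
            de_mod.differential_expression(
                matrix, (a, b), covariates=config.covariates,
                lfc_threshold=config.lfc_threshold, fdr_threshold=config.fdr_threshold,
            )
        )
    out = outdir / "de.tsv"
    if tables:
        import pandas as pd
        pd.concat(tables).to_csv(out, sep="\t", index=False)
    else:
        out.write_text("gene_id\tcontrast\tlogFC\tpvalue\tfdr\tis_de\tdirection\n")
    state["de_tables"] = tables
    return [out]


def _stage_predict(config, state, outdir: Path, seed: int) -> list[Path]:
    import pandas as pd
    matrix = state["matrix"]
    merged = state.get("merged") or state.get("catalog")
    gene_sets = state.get("gene_sets") or io_mod.read_gmt(config.gene_sets)
    features = pred_mod.build_feature_table(matrix)
    # restrict to genes present in the (merged) catalog
    keep = [g for g in features.index if g in merged]
    features = features.loc[keep]
    rows, cv_rows = [], []
    predictions = {}
    for i, (name, members) in enumerate(sorted(gene_sets.items())):
        labels = pred_mod.PULabels.from_catalog(merged, members & set(features.index))
        cv = pred_mod.cross_validate(
            features, labels, classifier="balanced_rf", k=config.folds,
            seed=seed + 7 * i,
        )
        cv_rows.append({"pathway": name, "pooled_auroc": cv.pooled_auroc,
                        **{f"fold_{j}": a for j, a in enumerate(cv.fold_aurocs)}})
        pred = pred_mod.predict_pathway(
            features, labels, pathway=name, n_trials=config.n_trials,
            n_trees=config.n_trees, base_seed=seed + 1000 * i,
        )
        predictions[name] = pred
        rows.append(pred.to_frame())
    out_pred = outdir / "predictions.tsv"
    out_cv = outdir / "cv.tsv"
    pd.concat(rows).to_csv(out_pred, sep="\t", index=False)
    pd.DataFrame(cv_rows).to_csv(out_cv, sep="\t", index=False)
    state["predictions"] = predictions
    return [out_pred, out_cv]


def _stage_kmer(config, state, outdir: Path, seed: int) -> list[Path]:
    sequences = state.get("sequences")
    if sequences is None:
        if config.fasta is None:
            return []
        sequences = io_mod.read_fasta(config.fasta)
    profiles = kmer_mod.profile_matrix(sequences, k=config.kmer_k)
    kmer_mod.standardize_profiles(profiles)
    graph = kmer_mod.build_adjacency(profiles, threshold=config.adjacency_threshold)
    assignment = kmer_mod.detect_communities(graph, seed=seed,
                                             threshold=config.adjacency_threshold)
    out = outdir / "kmer_clusters.tsv"
    with open(out, "w") as fh:
        fh.write("transcript_id\tcluster\n")
        for t in profiles.transcript_ids:
            fh.write(f"{t}\t{assignment.membership[t]}\n")
    state["kmer_assignment"] = assignment
    return [out]


def _stage_enrich(config, state, outdir: Path, seed: int) -> list[Path]:
    import pandas as pd
    outputs = []
    tables = state.get("de_tables") or []
    if len(tables) >= 2:
        universe = set(tables[0]["gene_id"])
        results = de_mod.pairwise_shared_de(tables, universe)
        rows = [{"pair": "|".join(r.label), "odds_ratio": r.odds_ratio,
                 "p_value": r.p_value, "p_adjusted": r.p_adjusted} for r in results]
        out = outdir / "shared_de_enrichment.tsv"
        pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
        outputs.append(out)
    assignment = state.get("kmer_assignment")
    truth = state.get("truth")
    if assignment is not None and truth is not None and truth.sequence_clusters:
        # on synthetic runs, use the planted clusters as 'predicted' sets to
        # exercise the enrichment path end to end
        predicted = {f"cluster_{c}": info["transcripts"]
                     for c, info in truth.sequence_clusters.items()}
        results = kmer_mod.cluster_enrichment(assignment, predicted)
        out = outdir / "kmer_enrichment.tsv"
        enrichment_table(results).to_csv(out, sep="\t", index=False)
        outputs.append(out)
    return outputs
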