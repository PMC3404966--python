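"""End-to-end pipeline: filter -> scan -> FDR -> network -> hubs -> validation.

All randomness flows from one top-level seed through named substreams
(scan, randomized scan, seed shuffles, GO control) recorded in the JSON run
manifest, so two runs with the same configuration produce byte-identical
tables.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import scan_all_pairs
from .enrichment import enrich_all, target_sets
from .io import PairedExpressionSet, read_annotation, read_fasta
from .network import build_network, detect_hubs
from .seeds import count_matches, enrichment_table, extract_seed_matches, seed_enrichment

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_full_pipeline"]

# fixed order gives each stage a stable seed substream
_SUBSTREAMS = ("scan", "randomized_scan", "seed_shuffles", "go_control")


@dataclasses.dataclass
class PipelineConfig:
    mirna_path: str
    mrna_path: str
    out_dir: str
    seed: int = 0
    n_permutations: int = 1000
    n_null_shuffles: int = 100
    fdr_q: float = 0.02
    hub_rule: str = "scaled_max"
    apply_iqr_filter: bool = True
    abundance_quantile: float | None = None
    utr_fasta: str | None = None
    mature_fasta: str | None = None
    annotation_path: str | None = None
    n_seed_shuffles: int = 1000
    go_p_threshold: float = 0.001
    n_jobs: int = 1


def _scores_frame(scores) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.mirna_id, s.gene_id, s.coefficient, s.best_intercept, s.pvalue,
             s.qvalue, s.significant)
            for s in scores
        ],
        columns=["mirna_id", "gene_id", "coefficient", "best_intercept",
                 "pvalue", "qvalue", "significant"],
    )


def run_full_pipeline(config: PipelineConfig | dict) -> dict:
    """Run every stage and write the result tables plus a run manifest.

    Returns the manifest dict.  Any stage error aborts with the stage name
    and removes the partial outputs already written.
    """
    if isinstance(config, dict):
        config = PipelineConfig(**config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    streams = dict(zip(_SUBSTREAMS, np.random.SeedSequence(config.seed).spawn(len(_SUBSTREAMS))))
    written: list[Path] = []
    manifest: dict = {
        "package": "mirantag",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "parameters": dataclasses.asdict(config),
        "stages": {},
    }

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = out_dir / name
        frame.to_csv(path, sep="\t", index=False, float_format="%.8g")
        written.append(path)

    stage = "load"
    try:
        expr = PairedExpressionSet.from_files(config.mirna_path, config.mrna_path)

        stage = "filter"
        if config.apply_iqr_filter:
            expr = expr.filtered(config.abundance_quantile)
        manifest["stages"]["filter"] = {
            "mirnas": int(expr.mirna_matrix.shape[0]),
            "genes": int(expr.mrna_matrix.shape[0]),
            "samples": len(expr.sample_ids),
        }

        stage = "scan"
        scores = scan_all_pairs(
            expr,
            n_permutations=config.n_permutations,
            n_null_shuffles=config.n_null_shuffles,
            rng=streams["scan"],
            fdr_q=config.fdr_q,
            n_jobs=config.n_jobs,
        )
        emit("pairs.tsv", _scores_frame(scores))
        manifest["stages"]["scan"] = {"pairs": len(scores)}

        stage = "network"
        edges = build_network(scores, config.fdr_q)
        emit("edges.tsv", edges)
        manifest["stages"]["network"] = {"edges": len(edges)}

        stage = "hubs"
        # randomized twin: one global sample shuffle of the mRNA matrix breaks
        # the pairing while preserving each matrix's internal structure
        rand_rng = np.random.default_rng(streams["randomized_scan"])
        perm = rand_rng.permutation(len(expr.sample_ids))
        shuffled_mrna = expr.mrna_matrix.iloc[:, perm]
        shuffled_mrna.columns = expr.mrna_matrix.columns
        shuffled = PairedExpressionSet(expr.mirna_matrix, shuffled_mrna)
        rand_scores = scan_all_pairs(
            shuffled,
            n_permutations=config.n_permutations,
            n_null_shuffles=config.n_null_shuffles,
            rng=streams["randomized_scan"],
            fdr_q=config.fdr_q,
            n_jobs=config.n_jobs,
        )
        rand_edges = build_network(rand_scores, config.fdr_q)
        emit("randomized_edges.tsv", rand_edges)
        hubs = detect_hubs(edges, rand_edges, rule=config.hub_rule)
        emit("hubs.tsv", hubs)
        manifest["stages"]["hubs"] = {
            "randomized_edges": len(rand_edges),
            "mirna_hubs": int(((hubs["node_class"] == "miRNA") & hubs["is_hub"]).sum())
            if not hubs.empty else 0,
            "gene_hubs": int(((hubs["node_class"] == "gene") & hubs["is_hub"]).sum())
            if not hubs.empty else 0,
        }

        stage = "seed_enrichment"
        seed_hit_pairs: set[tuple[str, str]] | None = None
        if config.utr_fasta and config.mature_fasta and len(edges) > 0:
            mature = read_fasta(config.mature_fasta)
            utrs = read_fasta(config.utr_fasta)
            results = seed_enrichment(
                edges, mature, utrs,
                n_shuffles=config.n_seed_shuffles,
                rng=np.random.default_rng(streams["seed_shuffles"]),
            )
            emit("seed_enrichment.tsv", enrichment_table(results))
            manifest["stages"]["seed_enrichment"] = {
                "tested_edges": int(edges["gene_id"].isin(utrs).sum())
            }
            seed_hit_pairs = set()
            for row in edges.itertuples(index=False):
                if row.mirna_id in mature and row.gene_id in utrs:
                    cat = extract_seed_matches(mature[row.mirna_id], mirna_id=row.mirna_id)
                    if any(count_matches(utrs[row.gene_id], cat, k) for k in (6, 7, 8)):
                        seed_hit_pairs.add((row.mirna_id, row.gene_id))
        else:
            logger.info("seed enrichment skipped (no FASTA inputs or empty network)")
            manifest["stages"]["seed_enrichment"] = "skipped"

        stage = "go_enrichment"
        if config.annotation_path and len(edges) > 0:
            annotation = read_annotation(config.annotation_path)
            universe = set(map(str, expr.mrna_matrix.index))
            table = enrich_all(
                target_sets(edges), annotation, universe, config.go_p_threshold
            )
            emit("go_enrichment.tsv", table)
            if seed_hit_pairs is not None:
                from .enrichment import combined_target_sets

                combined = combined_target_sets(edges, seed_hit_pairs)
                emit(
                    "go_enrichment_combined.tsv",
                    enrich_all(combined, annotation, universe, config.go_p_threshold),
                )
            manifest["stages"]["go_enrichment"] = {"tests": int(len(table))}
        else:
            logger.info("GO enrichment skipped (no annotation or empty network)")
            manifest["stages"]["go_enrichment"] = "skipped"

        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return manifest
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
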