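"""End-to-end orchestration: filter -> normalize -> STATIS -> dual-STATIS ->
bootstrap -> enrichment -> condition clustering, with deterministic outputs.

``run_pipeline`` executes the whole analysis for one normalization strategy
and writes every artifact through :mod:`statispy.io_formats`; with
``alt_normalization: true`` the control-normalized rerun lands in a second
subdirectory. A manifest (config hash, package version, seeds, the choices
behind every ambiguous knob) makes each run auditable.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Any

from . import __version__
from .condition_similarity import cluster_conditions, dendrogram_to_newick
from .config import config_hash
from .core import run_dual_statis, run_statis
from .enrichment import hypergeometric_enrichment
from .io_formats import (
    GeneSetCollection,
    TableCollection,
    read_expression_tables,
    read_gene_sets,
    write_results,
)
from .preprocessing import control_normalize, filter_informative_genes
from .significance import bootstrap_tables, significant_genes

logger = logging.getLogger(__name__)


class _StageTimer:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        status = "failed" if exc_type else "done"
        logger.info("stage %s: %s in %.2fs", self.name, status, dt)
        return False


def _analyse_one(
    collection: TableCollection,
    gene_sets: GeneSetCollection | None,
    cfg: dict[str, Any],
    out_dir: Path,
) -> dict[str, Any]:
    summary: dict[str, Any] = {}
    fcfg = cfg["filter"]
    report = None
    if fcfg["enabled"]:
        with _StageTimer("filter"):
            collection, report = filter_informative_genes(
                collection,
                fc_threshold=fcfg["fc_threshold"],
                min_fc_timepoints=fcfg["min_fc_timepoints"],
                cv_threshold=fcfg["cv_threshold"],
                cv_scope=fcfg["cv_scope"],
            )
        summary["n_genes_kept"] = report.n_kept
        summary["n_genes_input"] = report.n_input

    scfg = cfg["statis"]
    with _StageTimer("statis"):
        statis_res = run_statis(
            collection,
            n_components=scfg["n_components"],
            table_norm=cfg["table_norm"]["method"],
            weight_norm=scfg["weight_norm"],
        )
    with _StageTimer("dual-statis"):
        dual_res = run_dual_statis(
            collection,
            n_components=scfg["n_components"],
            table_norm=cfg["table_norm"]["method"],
        )

    with _StageTimer("cluster"):
        dend = cluster_conditions(
            statis_res.interstructure.rv_matrix, statis_res.table_ids
        )
        newick = dendrogram_to_newick(dend)

    bootstrap_res = None
    selected: list[str] = []
    bcfg = cfg["bootstrap"]
    if bcfg["enabled"]:
        with _StageTimer("bootstrap"):
            bootstrap_res = bootstrap_tables(
                statis_res,
                n_boot=bcfg["B"],
                seed=bcfg["seed"],
                basis=bcfg["basis"],
                alpha_level=bcfg["alpha_level"],
            )
            lists = significant_genes(
                bootstrap_res,
                alpha_level=bcfg["alpha_level"],
                union_components=tuple(bcfg["components_for_union"]),
            )
            selected = lists["union"]
        summary["n_significant_union"] = len(selected)

    enr = None
    ecfg = cfg["enrichment"]
    if ecfg["enabled"] and gene_sets is not None and bootstrap_res is not None:
        with _StageTimer("enrichment"):
            if ecfg["background"] == "custom_list":
                background = list(ecfg.get("background_list") or [])
            else:
                background = list(collection.gene_ids)
            enr = hypergeometric_enrichment(
                selected,
                background,
                gene_sets,
                fdr_cutoff=ecfg["fdr_cutoff"],
                min_set_size=ecfg["min_set_size"],
            )
        summary["n_enriched_sets"] = len(enr.enriched_ids)

    with _StageTimer("write"):
        write_results(
            out_dir,
            statis=statis_res,
            bootstrap=bootstrap_res,
            enrichment=enr,
            dendrogram_newick=newick,
            filter_report=report,
        )
        dual_dir = out_dir / "dual"
        write_results(dual_dir, statis=dual_res)
    summary["eigenvalues_top3"] = [float(v) for v in statis_res.decomposition.eigenvalues[:3]]
    return summary


def run_pipeline(cfg: dict[str, Any], out_dir: str | Path) -> dict[str, Any]:
    """Run the configured analysis; returns the manifest dictionary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    io = cfg["io"]
    with _StageTimer("read"):
        collection = read_expression_tables(
            io["tables"], control_id=io["control_id"], scale=io["scale"]
        )
        gene_sets = (
            read_gene_sets(io["gene_sets"], min_size=io["gene_sets_min_size"])
            if io.get("gene_sets")
            else None
        )

    manifest: dict[str, Any] = {
        "package": "statispy",
        "version": __version__,
        "config_hash": config_hash(cfg),
        "seeds": {"bootstrap": cfg["bootstrap"].get("seed")},
        "choices": {
            "weight_norm": cfg["statis"]["weight_norm"],
            "bootstrap_basis": cfg["bootstrap"]["basis"],
            "cv_scope": cfg["filter"]["cv_scope"],
            "table_norm": cfg["table_norm"]["method"],
        },
        "runs": {},
    }

    if cfg.get("alt_normalization"):
        manifest["runs"]["standard"] = _analyse_one(
            collection, gene_sets, cfg, out_dir / "standard"
        )
        with _StageTimer("control-normalize"):
            renorm = control_normalize(collection)
        manifest["runs"]["control_normalized"] = _analyse_one(
            renorm, gene_sets, cfg, out_dir / "control_normalized"
        )
    else:
        manifest["runs"]["standard"] = _analyse_one(collection, gene_sets, cfg, out_dir)

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
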