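"""End-to-end orchestration: filter → compare → network → null → enrich.

A single :class:`RunConfig` names every input, the analysis parameters and
one master seed; :func:`run_pipeline` executes the stages in order, writes
per-stage outputs under the output directory and a consolidated JSON report
(``report.json``) that embeds exactly the values written to disk. The
master seed deterministically spawns one child seed per randomized stage,
so runs with identical configs are byte-identical while stages stay
independently reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from . import io_formats, set_comparison
from .enrichment import run_enrichment
from .hit_filter import filter_hits
from .network_topology import induce_subgraph, resample_null, topology_report

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Inputs, parameters and seed of one full pipeline run."""

    detections: str  # TSV detection table → interactome A via the hit filter
    interactome_b: str  # TSV protein set: the second interactome to compare against
    edges: str  # TSV background PPI edge list
    gene_sets: str  # GMT collection for enrichment
    out_dir: str
    abundance_matrix: str | None = None  # optional proteins × regions TSV
    mapping: str | None = None  # optional source→target id mapping TSV
    count_rule: str = "ratio"
    fold_threshold: float = 4.0
    n_resamples: int = 1000
    universe: str = "background"  # "background" (interactome nodes) or a protein-set path
    seed: int = 0
    label_a: str = "A"
    label_b: str = "B"


def _stage_seeds(master: int, n: int) -> list[int]:
    # keep spawned seeds small, positive ints
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def _jsonable(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return (and write) the consolidated report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"tool_version": __version__, "config": asdict(config)}
    (null_seed,) = _stage_seeds(config.seed, 1)

    stage = "filter"
    try:
        detections = io_formats.read_detection_table(config.detections)
        filt = filter_hits(detections, count_rule=config.count_rule)
        interactome_a = filt.hits
        if config.mapping:
            mapping = io_formats.read_mapping(config.mapping)
            interactome_a = {mapping.get(p, p) for p in interactome_a}
        io_formats.write_protein_set(interactome_a, out / "interactome_a.tsv")
        report["filter"] = {
            "branch_counts": filt.branch_counts,
            "n_hits": len(interactome_a),
            "count_rule": config.count_rule,
        }

        stage = "compare"
        interactome_b = io_formats.read_protein_set(config.interactome_b)
        part = set_comparison.partition_sets(
            interactome_a, interactome_b, config.label_a, config.label_b
        )
        io_formats.write_protein_set(set(part.common), out / "common.tsv")
        io_formats.write_protein_set(set(part.specific_a), out / f"specific_{config.label_a}.tsv")
        io_formats.write_protein_set(set(part.specific_b), out / f"specific_{config.label_b}.tsv")
        report["compare"] = {
            "n_common": len(part.common),
            "n_specific_a": len(part.specific_a),
            "n_specific_b": len(part.specific_b),
            "pct_common_a": part.pct_common_a,
            "pct_common_b": part.pct_common_b,
            "pct_specific_a": part.pct_specific_a,
            "pct_specific_b": part.pct_specific_b,
        }

        stage = "regions"
        region_sets: dict[str, set[str]] | None = None
        if config.abundance_matrix:
            matrix = io_formats.read_abundance_matrix(config.abundance_matrix)
            rule = set_comparison.RegionEnrichmentRule(config.fold_threshold)
            region_sets = set_comparison.region_enriched_proteins(matrix, rule)
            io_formats.write_gmt(
                {
                    r: {"description": f">{config.fold_threshold}-fold region-enriched", "members": s}
                    for r, s in region_sets.items()
                },
                out / "region_enriched.gmt",
            )
            report["regions"] = {r: len(s) for r, s in region_sets.items()}

        stage = "network"
        edge_df = io_formats.read_edge_table(config.edges)
        background = nx.from_pandas_edgelist(edge_df, "protein_a", "protein_b")
        networks = {
            "common": set(part.common),
            f"specific_{config.label_a}": set(part.specific_a),
            f"specific_{config.label_b}": set(part.specific_b),
        }
        report["network"] = {}
        for name, proteins in networks.items():
            sub = induce_subgraph(proteins, background)
            top = topology_report(sub)
            edge_rows = sorted((min(u, v), max(u, v)) for u, v in sub.edges)
            io_formats.write_edge_table(
                pd.DataFrame(edge_rows, columns=["protein_a", "protein_b"]),
                out / f"network_{name}_edges.tsv",
            )
            report["network"][name] = {
                "n_nodes": top.n_nodes,
                "n_edges": top.n_edges,
                "n_orphans": top.n_orphans,
                "avg_path_length": top.avg_path_length,
                "alpha": top.alpha,
                "degree_histogram": {str(k): v for k, v in sorted(top.degree_histogram.items())},
            }

        stage = "null"
        null = resample_null(
            set(part.specific_a), background, n_resamples=config.n_resamples, seed=null_seed
        )
        report["null"] = {
            "query": f"specific_{config.label_a}",
            "observed_stat": null.observed_stat,
            "n_resamples": null.n_resamples,
            "n_smaller": null.n_smaller,
            "n_absent": null.n_absent,
            "empirical_p": null.empirical_p,
            "seed": null.seed,
        }

        stage = "enrich"
        if config.universe == "background":
            universe = set(background.nodes)
        else:
            universe = io_formats.read_protein_set(config.universe)
        collection = io_formats.read_gmt(config.gene_sets)
        results = run_enrichment(set(part.specific_a), collection, universe)
        report["enrichment"] = [
            {
                "set_name": r.set_name,
                "k": r.k,
                "m": r.m,
                "K": r.K,
                "N": r.N,
                "raw_p": r.raw_p,
                "adj_p": r.adj_p,
                "significant": r.significant,
            }
            for r in results
        ]
        pd.DataFrame(report["enrichment"]).to_csv(
            out / "enrichment.tsv", sep="\t", index=False, lineterminator="\n"
        )
    except Exception as exc:  # noqa: BLE001 - stage name is part of the contract
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "report.json").write_text(
        json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n"
    )
    logger.info("pipeline complete; report at %s", out / "report.json")
    return report
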