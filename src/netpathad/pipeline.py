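"""End-to-end orchestration: genes → enrichment → crosstalk → subnetwork → null.

``run_pipeline`` consumes a flat configuration mapping (or a YAML file of
one), runs the requested stages, writes every stage's tabular output under
the configured output directory, and returns a machine-readable report with
conserved record bookkeeping (records_in = records_out + records_dropped at
every filtering step).  Reruns with the same configuration and seed are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import crosstalk as ct
from . import io as npio
from . import steiner as st
from .datatypes import GeneSet, Interactome
from .enrichment import enrich
from .interactome import merge_interactomes, network_summary
from .nullmodel import NullEnsembleSpec, compare_to_null

log = logging.getLogger(__name__)

DEFAULTS: dict[str, Any] = {
    "seed": 17,
    "fdr": 0.05,
    "min_genes": 6,
    "min_shared": 2,
    "replicates": 1000,
    "densify": True,
    "null_statistics": ["clustering", "largest_component_fraction"],
    "stages": ["crosstalk"],
    "outdir": "results",
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_config(config: Mapping[str, Any] | str | Path) -> dict[str, Any]:
    if isinstance(config, (str, Path)):
        with open(config, "r", encoding="utf-8") as fh:
            config = yaml.safe_load(fh) or {}
    merged = dict(DEFAULTS)
    merged.update(config)
    return merged


def _load_genes(spec: str) -> GeneSet:
    if spec == "fixture:alzgset":
        return npio.load_disease_gene_fixture()
    return npio.read_gene_list(spec)


def run_pipeline(config: Mapping[str, Any] | str | Path) -> dict[str, Any]:
    """Run the configured stages; returns (and writes) the run report.

    Config keys: ``genes`` (path or ``fixture:alzgset``), ``gmt``,
    ``universe``, ``pathway_table_fixture`` (bool: take candidate sets from the
    packaged pathway table instead of running enrichment), ``network``
    (list of edge-list paths), ``stages`` (subset of enrich / crosstalk /
    subnet / nullcmp), thresholds ``fdr`` / ``min_genes`` / ``min_shared``
    / ``replicates``, ``densify``, ``seed``, ``outdir``.
    """
    cfg = _load_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(cfg["stages"])
    report: dict[str, Any] = {"config": {
        k: v for k, v in sorted(cfg.items()) if k != "stages"
    }, "stages": stages}

    candidate_sets: list[tuple[str, GeneSet]] = []

    if "enrich" in stages:
        try:
            report["enrich"] = _stage_enrich(cfg, outdir, candidate_sets)
        except Exception as e:  # noqa: BLE001 - stage surface
            raise PipelineError("enrich", e) from e

    if cfg.get("pathway_table_fixture"):
        fixture = npio.load_enrichment_table()
        candidate_sets = [
            (r.pathway_name, r.candidates)
            for r in fixture
            if r.p_bh < cfg["fdr"]
        ]
        report["fixture"] = {
            "records_in": len(fixture),
            "records_out": len(candidate_sets),
            "records_dropped": len(fixture) - len(candidate_sets),
        }

    subnet_result = None
    if "crosstalk" in stages:
        try:
            report["crosstalk"] = _stage_crosstalk(cfg, outdir, candidate_sets)
        except Exception as e:
            raise PipelineError("crosstalk", e) from e

    if "subnet" in stages:
        try:
            subnet_result, stage_report = _stage_subnet(cfg, outdir)
            report["subnet"] = stage_report
        except Exception as e:
            raise PipelineError("subnet", e) from e

    if "nullcmp" in stages:
        try:
            report["nullcmp"] = _stage_nullcmp(cfg, outdir, subnet_result)
        except Exception as e:
            raise PipelineError("nullcmp", e) from e

    report_path = outdir / "run_report.json"
    report_path.write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str) + "\n",
        encoding="utf-8",
    )
    return report


def _stage_enrich(cfg, outdir, candidate_sets) -> dict[str, Any]:
    query = _load_genes(cfg["genes"])
    db = npio.read_gmt(cfg["gmt"])
    universe = (
        npio.read_gene_list(cfg["universe"]) if cfg.get("universe") else None
    )
    results = enrich(query, db, universe=universe,
                     fdr_threshold=cfg["fdr"], keep_empty=True)
    nonzero = [r for r in results if r.k >= 1]
    significant = [r for r in nonzero if r.significant]
    npio.write_tsv(
        (
            {
                "pathway_id": r.pathway_id,
                "name": r.display_name,
                "k": r.k, "K": r.K, "n": r.n, "N": r.N,
                "overlap_genes": ",".join(sorted(r.overlap_genes.genes)),
                "p_raw": f"{r.p_raw:.6g}",
                "p_bh": f"{r.p_bh:.6g}",
                "significant": int(r.significant),
            }
            for r in nonzero
        ),
        outdir / "enrichment.tsv",
        ["pathway_id", "name", "k", "K", "n", "N", "overlap_genes",
         "p_raw", "p_bh", "significant"],
    )
    candidate_sets.extend((r.pathway_id, r.overlap_genes) for r in significant)
    for r in results:
        if r.k == 0:
            log.info("enrich: dropped %s (no overlap with query)", r.pathway_id)
    return {
        "records_in": len(results),
        "records_out": len(nonzero),
        "records_dropped": len(results) - len(nonzero),
        "significant": len(significant),
    }


def _stage_crosstalk(cfg, outdir, candidate_sets) -> dict[str, Any]:
    if not candidate_sets:
        raise ValueError(
            "crosstalk stage needs candidate sets (run enrich or set "
            "pathway_table_fixture: true)"
        )
    n_in = len(candidate_sets)
    n_size_ok = ct.size_filter_count(candidate_sets, cfg["min_genes"])
    net = ct.build_crosstalk(candidate_sets, min_genes=cfg["min_genes"],
                             min_shared=cfg["min_shared"])
    for pid, gs in candidate_sets:
        if len(gs) < cfg["min_genes"]:
            log.info("crosstalk: dropped %s (%d < %d candidates)",
                     pid, len(gs), cfg["min_genes"])
    npio.write_tsv(
        (
            {
                "pathway_a": e.pathway_a,
                "pathway_b": e.pathway_b,
                "n_shared": len(e.shared_genes),
                "shared_genes": ",".join(sorted(e.shared_genes.genes)),
                "jc": f"{e.jc:.6f}",
                "oc": f"{e.oc:.6f}",
                "score": f"{e.score:.6f}",
            }
            for e in net.edges
        ),
        outdir / "crosstalk_edges.tsv",
        ["pathway_a", "pathway_b", "n_shared", "shared_genes",
         "jc", "oc", "score"],
    )
    sizes = dict(
        (pid, len(gs)) for pid, gs in candidate_sets
    )
    npio.write_tsv(
        ({"pathway": p, "n_candidates": sizes[p]} for p in net.nodes),
        outdir / "crosstalk_nodes.tsv",
        ["pathway", "n_candidates"],
    )
    return {
        "records_in": n_in,
        "size_filtered": n_size_ok,
        "records_dropped": n_in - n_size_ok,
        "isolated_dropped": n_size_ok - net.n_nodes,
        "records_out": net.n_nodes,
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
    }


def _stage_subnet(cfg, outdir):
    paths = cfg["network"]
    if isinstance(paths, (str, Path)):
        paths = [paths]
    nets = [npio.read_edge_list(p) for p in paths]
    g = merge_interactomes(nets)
    seeds = _load_genes(cfg["genes"])
    tree = st.steiner_tree(g, seeds)
    result = st.densify(g, tree) if cfg["densify"] else tree
    seed_list, linker_list = st.classify_nodes(result, seeds)
    degree: dict[str, int] = {n: 0 for n in result.nodes}
    for a, b in result.edges:
        degree[a] += 1
        degree[b] += 1
    npio.write_tsv(
        (
            {"node": n,
             "role": "seed" if n in result.seed_nodes.genes else "linker",
             "degree_in_subnet": degree[n]}
            for n in sorted(result.nodes)
        ),
        outdir / "subnet_nodes.tsv",
        ["node", "role", "degree_in_subnet"],
    )
    npio.write_tsv(
        ({"node_a": a, "node_b": b} for a, b in sorted(result.edges)),
        outdir / "subnet_edges.tsv",
        ["node_a", "node_b"],
    )
    summary = network_summary(g)
    stage_report = {
        "interactome_nodes": summary.n_nodes,
        "interactome_edges": summary.n_edges,
        "records_in": len(seeds),
        "records_out": len(seed_list),
        "records_dropped": len(result.excluded_seeds),
        "n_nodes": result.n_nodes,
        "n_edges": result.n_edges,
        "n_linkers": len(linker_list),
        "seed_coverage": round(result.seed_coverage(seeds), 4),
        "densified": bool(cfg["densify"]),
    }
    return result, stage_report


def _stage_nullcmp(cfg, outdir, subnet_result) -> dict[str, Any]:
    if subnet_result is None:
        raise ValueError("nullcmp stage needs the subnet stage to run first")
    observed = Interactome(edges=subnet_result.edges,
                           nodes=subnet_result.nodes)
    spec = NullEnsembleSpec(
        n_nodes=observed.n_nodes,
        n_edges=observed.n_edges,
        n_replicates=cfg["replicates"],
        rng_seed=cfg["seed"],
    )
    comparisons = compare_to_null(observed, spec,
                                  statistics=cfg["null_statistics"])
    npio.write_tsv(
        (
            {
                "statistic": c.statistic,
                "observed": f"{c.observed:.6g}",
                "null_mean": f"{c.null_mean:.6g}",
                "null_sd": f"{c.null_sd:.6g}",
                "z": f"{c.z:.4g}",
                "p_empirical": f"{c.p_empirical:.6g}",
            }
            for c in comparisons
        ),
        outdir / "null_comparison.tsv",
        ["statistic", "observed", "null_mean", "null_sd", "z", "p_empirical"],
    )
    return {
        "replicates": cfg["replicates"],
        "z_scores": {c.statistic: round(c.z, 4) for c in comparisons},
        "p_empirical": {c.statistic: round(c.p_empirical, 6)
                        for c in comparisons},
    }
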