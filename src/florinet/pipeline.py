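"""End-to-end orchestration: simulate/load -> promoters -> scan -> DE -> TRNs -> diff.

A run is driven by one declarative config (YAML or dict). Every stage output
is written under the output directory; a manifest records the seed, the
echoed config, package version and sha256 checksums of all outputs, so two
runs with the same config and seed produce byte-identical artifacts and
manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .diff_network import compare_networks, enrich_families
from .expression_de import DEConfig, deg_set, test_differential_expression
from .io_formats import (
    CountMatrix,
    SequenceRecord,
    read_count_matrix,
    read_fasta,
    read_gene_sets,
    read_gff3_genes,
    read_meme_motifs,
    read_tf_map,
    write_edge_table,
    write_fasta,
)
from .motif_scan import build_scoring_model, scan_promoters
from .promoters import PromoterWindowConfig, extract_promoters
from .synthetic_data import GroundTruth, SyntheticConfig, generate_dataset
from .trn_build import TRN, TRNConfig, assemble_trn, compute_coexpression, deg_union

__all__ = ["run_pipeline", "edge_recovery_metrics", "site_recovery", "load_config"]

logger = logging.getLogger(__name__)

DEFAULT_COMPARISONS = [("C", "I"), ("C", "F")]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: pipeline config must be a mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def edge_recovery_metrics(trn: TRN, true_edges: set[tuple[str, str, str]]) -> dict[str, float]:
    """Precision/recall of recovered (tf, target) pairs and sign agreement."""
    found_pairs = {(r.tf, r.target): r.sign for r in trn.edges.itertuples(index=False)}
    true_pairs = {(tf, t): s for tf, t, s in true_edges}
    tp = set(found_pairs) & set(true_pairs)
    precision = len(tp) / len(found_pairs) if found_pairs else float("nan")
    recall = len(tp) / len(true_pairs) if true_pairs else float("nan")
    sign_ok = sum(1 for p in tp if found_pairs[p] == true_pairs[p])
    sign_agreement = sign_ok / len(tp) if tp else float("nan")
    return {
        "n_edges": len(found_pairs),
        "n_true": len(true_pairs),
        "n_recovered": len(tp),
        "precision": precision,
        "recall": recall,
        "sign_agreement": sign_agreement,
    }


def site_recovery(hits: pd.DataFrame, planted_sites, tf_map: Mapping[str, str]) -> float:
    """Fraction of planted promoter sites found at the exact offset and strand."""
    found = {
        (r.gene, r.motif, int(r.offset), r.strand) for r in hits.itertuples(index=False)
    }
    planted = {(g, m, int(o), s) for g, o, s, m in planted_sites}
    if not planted:
        return float("nan")
    return len(planted & found) / len(planted)


def run_pipeline(config: Mapping[str, Any], out_dir: str | Path, seed: int | None = None) -> dict:
    """Execute the full analysis; returns the aggregated run report (also
    written as report.json; manifest as manifest.json)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dict(config)
    manifest: dict[str, Any] = {"config": cfg, "version": __version__, "stages": []}
    stage = "configure"
    try:
        truth: GroundTruth | None = None
        if "simulate" in cfg:
            stage = "simulate"
            sim_kwargs = dict(cfg["simulate"] or {})
            if seed is not None:
                sim_kwargs["seed"] = seed
            sim_cfg = SyntheticConfig(**sim_kwargs)
            manifest["seed"] = sim_cfg.seed
            dataset = generate_dataset(sim_cfg)
            data_dir = out / "data"
            dataset.write(data_dir)
            genome, genes = dataset.genome, dataset.genes
            motifs, tf_map = dataset.motifs, dataset.tf_map
            counts, gene_sets, truth = dataset.counts, dataset.gene_sets, dataset.truth
            manifest["stages"].append({"stage": stage, "n_genes": len(genes)})
        else:
            stage = "load"
            for key in ("genome", "genes", "motifs", "tf_map", "counts", "conditions", "genesets"):
                if key not in cfg:
                    raise ValueError(f"pipeline config lacks required input path {key!r}")
                if not Path(cfg[key]).exists():
                    raise FileNotFoundError(f"input {key!r}: no such file {cfg[key]}")
            genome = read_fasta(cfg["genome"])
            genes = read_gff3_genes(cfg["genes"])
            motifs = read_meme_motifs(cfg["motifs"])
            tf_map = read_tf_map(cfg["tf_map"])
            counts = read_count_matrix(cfg["counts"], cfg["conditions"])
            gene_sets = read_gene_sets(cfg["genesets"])
            if "truth" in cfg and Path(cfg["truth"]).exists():
                truth = GroundTruth.from_json(cfg["truth"])
            manifest["seed"] = seed

        stage = "promoters"
        pw = cfg.get("promoter_window", {})
        window = PromoterWindowConfig(
            upstream=int(pw.get("upstream", 500)), downstream=int(pw.get("downstream", 100))
        )
        promoters = extract_promoters(genome, genes, window)
        write_fasta(
            [SequenceRecord(p.gene_id, p.sequence) for p in promoters],
            out / "promoters.fasta",
        )
        manifest["stages"].append({"stage": stage, "n_promoters": len(promoters)})

        stage = "scan"
        p_threshold = float(cfg.get("scan", {}).get("p_threshold", 1e-5))
        pseudocount = float(cfg.get("scan", {}).get("pseudocount", 0.1))
        models = [build_scoring_model(m, pseudocount=pseudocount) for m in motifs]
        hits = scan_promoters(promoters, models, p_threshold=p_threshold)
        hits.to_csv(out / "hits.tsv", sep="\t", index=False)
        manifest["stages"].append({"stage": stage, "n_hits": int(len(hits))})

        stage = "de"
        de_cfg_in = cfg.get("de", {})
        de_config = DEConfig(
            fc_threshold=float(de_cfg_in.get("fc_threshold", 2.0)),
            alpha=float(de_cfg_in.get("alpha", 0.05)),
            criterion=str(de_cfg_in.get("criterion", "fdr")),
        )
        de_tables: dict[str, pd.DataFrame] = {}
        for a, b in (("C", "I"), ("C", "F"), ("I", "F")):
            name = f"{b}-vs-{a}"
            table = test_differential_expression(counts, a, b, de_config)
            de_tables[name] = table
            table.to_csv(out / f"de_{name}.tsv", sep="\t", index_label="gene")
        deg_counts = {k: int(v["is_deg"].sum()) for k, v in de_tables.items()}
        manifest["stages"].append({"stage": stage, "deg_counts": deg_counts})

        stage = "trn"
        trn_cfg_in = cfg.get("trn", {})
        trn_config = TRNConfig(
            rho_threshold=float(trn_cfg_in.get("rho_threshold", 0.9)),
            rho_mode=str(trn_cfg_in.get("rho_mode", "absolute")),
            sample_scope=str(trn_cfg_in.get("sample_scope", "pair_conditions")),
        )
        floral = gene_sets.get("floral", set())
        deg_genes = deg_union(de_tables, ["I-vs-C", "F-vs-C"])
        comparisons = [tuple(c) for c in cfg.get("comparisons", DEFAULT_COMPARISONS)]
        trns: dict[str, TRN] = {}
        for a, b in comparisons:
            name = f"{a}-{b}"
            scope = (
                counts.samples_of(a, b)
                if trn_config.sample_scope == "pair_conditions"
                else counts.sample_ids
            )
            rho = compute_coexpression(counts, list(tf_map), scope)
            trn = assemble_trn(hits, rho, deg_genes, tf_map, floral, trn_config, comparison=name)
            trns[name] = trn
            write_edge_table(trn, out / f"trn_{name}.tsv")
        manifest["stages"].append(
            {
                "stage": stage,
                "sizes": {k: {"nodes": len(v.nodes), "edges": int(len(v.edges))} for k, v in trns.items()},
            }
        )

        stage = "diff"
        report: dict[str, Any] = {"deg_counts": deg_counts}
        if len(trns) >= 2:
            names = list(trns)
            comparison = compare_networks(trns[names[0]], trns[names[1]])
            families = {k: v for k, v in gene_sets.items() if k != "floral"}
            enrichment = enrich_families(comparison, families)
            enrichment.to_csv(out / "diff_report.tsv", sep="\t", index=False)
            report["networks"] = {
                k: {"nodes": len(v.nodes), "edges": int(len(v.edges))} for k, v in trns.items()
            }
            report["distinguishing_nodes"] = sorted(comparison.distinguishing_nodes)
            report["n_distinguishing"] = len(comparison.distinguishing_nodes)
            report["enrichment"] = enrichment.to_dict(orient="records")
        manifest["stages"].append({"stage": stage})

        if truth is not None:
            stage = "score"
            report["site_recovery"] = site_recovery(hits, truth.planted_sites, tf_map)
            score_trn = trns.get("C-F") or next(iter(trns.values()))
            report["edge_recovery"] = edge_recovery_metrics(score_trn, truth.true_edges)
            de_truth = truth.de_genes.get("F-vs-C", {})
            if de_truth:
                flagged = deg_set(de_tables["F-vs-C"])
                report["de_power_F_vs_C"] = len(flagged & set(de_truth)) / len(de_truth)
    except Exception as exc:  # record the failing stage before propagating
        manifest["error"] = {"stage": stage, "message": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
        raise

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    checksums = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest["checksums"] = checksums
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return report
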