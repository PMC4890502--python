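"""Configuration-driven orchestration of the full mining pipeline.

Stages run in method order: corpus parsing -> association extraction ->
gene-set enrichment -> network construction and hub calling ->
guilt-by-association prioritization. Every stage writes a self-describing
plain-text artifact (TSV / JSON / SIF / GraphML), and the run ends with a
JSON report collecting per-stage counts, realized thresholds (the computed
hub cutoff in particular), seeds and versions. Reports contain no
timestamps, so identical configuration yields byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any

import yaml

from . import __version__
from .corpus import (
    parse_corpus,
    publications_per_year,
    write_corpus_jsonl,
    write_year_counts_tsv,
)
from .enrichment import enrich, read_gmt, write_enrichment_tsv
from .mining import (
    DEFAULT_DISEASE_TERMS,
    aggregate_gene_counts,
    build_dictionary,
    extract_associations,
    read_gene_info_tsv,
    write_associations_tsv,
    write_gene_counts_tsv,
    write_review_queue_tsv,
)
from .network import (
    build_network,
    degree_distribution,
    detect_hubs,
    fit_power_law,
    induced_subgraph,
    load_interactions,
    write_degree_histogram_tsv,
    write_graphml,
    write_hubs_tsv,
    write_sif,
)
from .prioritize import score_candidates, select_candidates, write_candidates_tsv

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run", "load_config"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs, loadable from YAML."""

    corpus_path: str
    dictionary_path: str
    annotation_path: str
    interactions_path: str
    output_dir: str = "litmine_out"
    blacklist_path: str | None = None
    overrides_path: str | None = None
    disease_terms: set[str] = field(default_factory=lambda: set(DEFAULT_DISEASE_TERMS))
    alpha: float = 0.01
    sd_multiplier: float = 2.0
    min_connections: int | None = None
    seed: int = 0
    mine_titles: bool = False
    case_sensitive_short_upper: bool = True
    background_path: str | None = None  # default: annotation universe
    allowed_taxa: set[int] | None = None
    strict: bool = False

    def validate(self) -> None:
        for label, path in [
            ("corpus", self.corpus_path),
            ("dictionary", self.dictionary_path),
            ("annotation", self.annotation_path),
            ("interactions", self.interactions_path),
        ]:
            if not os.path.exists(path):
                raise PipelineError(f"startup validation: {label} file not found: {path}")
        if not (0.0 < self.alpha < 1.0):
            raise PipelineError("startup validation: alpha must be in (0, 1)")
        if self.sd_multiplier <= 0:
            raise PipelineError("startup validation: sd_multiplier must be > 0")
        if not self.disease_terms:
            raise PipelineError("startup validation: disease_terms must be non-empty")


def load_config(path: str) -> PipelineConfig:
    with open(path, encoding="utf-8") as handle:
        raw = yaml.safe_load(handle) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise PipelineError(f"unknown config keys: {sorted(unknown)}")
    if "disease_terms" in raw:
        raw["disease_terms"] = set(raw["disease_terms"])
    if raw.get("allowed_taxa") is not None:
        raw["allowed_taxa"] = set(raw["allowed_taxa"])
    return PipelineConfig(**raw)


def _stage(name: str):
    def decorator(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return wrapped

    return decorator


def run(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages; returns (and writes) the JSON run report."""
    config.validate()
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    report: dict[str, Any] = {
        "litmine_version": __version__,
        "seed": config.seed,
        "parameters": {
            "alpha": config.alpha,
            "sd_multiplier": config.sd_multiplier,
            "min_connections": config.min_connections,
            "disease_terms": sorted(config.disease_terms),
            "mine_titles": config.mine_titles,
            "case_sensitive_short_upper": config.case_sensitive_short_upper,
        },
    }

    articles = _run_corpus(config, out, report)
    associations, symbols = _run_mining(config, articles, out, report)
    study_genes = sorted({a.gene_id for a in associations})
    _run_enrichment(config, study_genes, out, report)
    network = _run_network(config, study_genes, symbols, out, report)
    _run_prioritization(config, network, study_genes, symbols, out, report)

    report_path = os.path.join(out, "run_report.json")
    with open(report_path, "w", encoding="utf-8") as handle:
        json.dump(report, handle, indent=1, sort_keys=True)
        handle.write("\n")
    logger.info("pipeline complete; report at %s", report_path)
    return report


@_stage("corpus")
def _run_corpus(config: PipelineConfig, out: str, report: dict) -> list:
    articles = parse_corpus(config.corpus_path)
    write_corpus_jsonl(articles, os.path.join(out, "corpus.jsonl"))
    counts = publications_per_year(articles)
    write_year_counts_tsv(counts, os.path.join(out, "publications_per_year.tsv"))
    report["corpus"] = {
        "n_articles": len(articles),
        "n_with_abstract": sum(1 for a in articles if a.abstract),
        "n_dated": max(counts.values()) if counts else 0,
    }
    return articles


@_stage("mining")
def _run_mining(config: PipelineConfig, articles, out: str, report: dict):
    records = read_gene_info_tsv(config.dictionary_path)
    blacklist: list[str] = []
    if config.blacklist_path:
        with open(config.blacklist_path, encoding="utf-8") as handle:
            blacklist = [line.strip() for line in handle if line.strip()]
    dictionary = build_dictionary(
        records, blacklist, case_sensitive_short_upper=config.case_sensitive_short_upper
    )
    overrides = None
    if config.overrides_path:
        overrides = {}
        with open(config.overrides_path, encoding="utf-8") as handle:
            for line in handle:
                if line.strip() and not line.startswith("#"):
                    surface, gene_id = line.rstrip("\n").split("\t")[:2]
                    overrides[surface] = int(gene_id)

    associations, queue = extract_associations(
        articles,
        dictionary,
        disease_terms=config.disease_terms,
        overrides=overrides,
        mine_titles=config.mine_titles,
    )
    counts = aggregate_gene_counts(associations)
    write_associations_tsv(associations, os.path.join(out, "associations.tsv"), dictionary.symbols)
    write_review_queue_tsv(queue, os.path.join(out, "review_queue.tsv"))
    write_gene_counts_tsv(counts, os.path.join(out, "gene_publication_counts.tsv"), dictionary.symbols)
    report["mining"] = {
        "n_associations": len(associations),
        "n_disease_genes": len(counts),
        "n_review_queue": len(queue),
        "dictionary_size": len(dictionary),
    }
    return associations, dict(dictionary.symbols)


@_stage("enrichment")
def _run_enrichment(config: PipelineConfig, study_genes, out: str, report: dict) -> None:
    gene_sets = read_gmt(config.annotation_path)
    if config.background_path:
        with open(config.background_path, encoding="utf-8") as handle:
            background = {int(line.strip()) for line in handle if line.strip()}
    else:
        background = set()
        for _, members in gene_sets.values():
            background |= members
    study = set(study_genes) & background
    dropped = len(study_genes) - len(study)
    if dropped:
        logger.warning("%d study genes absent from background dropped", dropped)
    results = enrich(study, gene_sets, background, alpha=config.alpha)
    write_enrichment_tsv(results, os.path.join(out, "enrichment.tsv"), alpha=config.alpha)
    report["enrichment"] = {
        "n_terms_tested": len(results),
        "n_significant": sum(1 for r in results if r.p_adj < config.alpha),
        "background_size": len(background),
        "study_size_in_background": len(study),
        "study_genes_dropped": dropped,
        "top_term": results[0].term_id if results else None,
    }


@_stage("network")
def _run_network(config: PipelineConfig, study_genes, symbols, out: str, report: dict):
    edges = load_interactions(
        config.interactions_path,
        allowed_taxa=config.allowed_taxa,
        strict=config.strict,
    )
    full = build_network(edges)
    disease_net = induced_subgraph(full, set(study_genes))
    target = disease_net if disease_net.n_nodes >= 3 else full

    dist = degree_distribution(target)
    try:
        fit = fit_power_law(dist)
        fit_block = {
            "exponent": fit.exponent,
            "r_squared": fit.r_squared,
            "fit_range": list(fit.fit_range),
        }
    except ValueError:
        fit_block = None
    hubs = detect_hubs(target, sd_multiplier=config.sd_multiplier)

    write_sif(target, os.path.join(out, "network.sif"))
    write_graphml(target, os.path.join(out, "network.graphml"))
    write_degree_histogram_tsv(dist, os.path.join(out, "degree_histogram.tsv"))
    write_hubs_tsv(hubs, target, os.path.join(out, "hubs.tsv"), symbols)
    report["network"] = {
        "n_input_edges": len(edges),
        "full_nodes": full.n_nodes,
        "full_edges": full.n_edges,
        "disease_nodes": disease_net.n_nodes,
        "disease_edges": disease_net.n_edges,
        "isolated_mapped_genes": len(disease_net.isolated_mapped),
        "mean_degree": hubs.mean_degree,
        "sd_degree": hubs.sd_degree,
        "hub_threshold": hubs.threshold,
        "n_hubs": len(hubs.hubs),
        "power_law": fit_block,
    }
    return full


@_stage("prioritization")
def _run_prioritization(config: PipelineConfig, full, study_genes, symbols, out: str, report: dict) -> None:
    scores = score_candidates(full, set(study_genes))
    write_candidates_tsv(scores, os.path.join(out, "candidates.tsv"), symbols)
    block: dict[str, Any] = {
        "n_candidates": len(scores),
        "max_connections": scores[0].connections if scores else 0,
    }
    if config.min_connections is not None:
        selected = select_candidates(scores, config.min_connections)
        write_candidates_tsv(
            selected, os.path.join(out, "candidates_selected.tsv"), symbols
        )
        block["n_selected"] = len(selected)
        block["min_connections"] = config.min_connections
    report["prioritization"] = block
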