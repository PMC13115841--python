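"""End-to-end orchestration: build-net -> diffuse -> extract -> annotate.

``analyze`` runs the core method in memory (interactome + seed list in,
selected top network and all annotations out); ``run_all`` is the file-based
pipeline driven by a YAML config that writes per-stage outputs plus a
machine-readable ``summary.json``. All randomness flows from one top-level
seed: stage s uses seed + fixed offset (diffusion +0, community detection
+1, meta-pathways +2), documented here so runs are exactly replayable.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from socionet import cartography, diffusion, enrichment, extraction, genomics
from socionet import interactome as inter_mod

logger = logging.getLogger(__name__)


def round_half_up_percent(k: int, total: int) -> int:
    """Percentage k/total rounded half-up to an integer."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(math.floor(100.0 * k / total + 0.5))


def overlap_report(
    list_a: Iterable[str], list_b: Iterable[str], universe: Iterable[str]
) -> tuple[int, int, float]:
    """(overlap size, percent of A, hypergeometric p) for two gene lists.

    Lists are intersected with the universe first (drops logged).
    """
    universe = set(universe)
    a = set(list_a)
    b = set(list_b)
    for name, s in (("A", a), ("B", b)):
        stray = s - universe
        if stray:
            logger.info("%d genes of list %s outside the universe", len(stray), name)
    a &= universe
    b &= universe
    if not a:
        raise ValueError("list A is empty after intersecting with the universe")
    k = len(a & b)
    percent = round_half_up_percent(k, len(a))
    p = enrichment.hypergeom_pvalue(k, len(b), len(a), len(universe))
    return k, percent, p


@dataclass
class PipelineConfig:
    """All inputs and thresholds of a full run (defaults = study values)."""

    links: str = ""
    mapping: str | None = None
    seeds: str = ""
    disease: str = ""
    deg: str | None = None
    pathways: str | None = None
    loci: str | None = None
    har: str | None = None
    out_dir: str = "socionet_out"

    excluded_channels: tuple[str, ...] = ("textmining",)
    high_threshold: int = 700
    medium_threshold: int = 400
    top_k_medium: int = 3
    alpha: float = 0.7
    epsilon: float = 50.0
    n_perm: int = 1000
    r_min: int = 50
    r_max: int = 500
    r_step: int = 10
    ora_fdr: float = 0.05
    band_fdr: float = 0.25
    window_bp: int = 500_000
    community_method: str = "multilevel"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "excluded_channels" in raw:
            raw["excluded_channels"] = tuple(raw["excluded_channels"])
        return cls(**raw)


@dataclass
class AnalysisResult:
    """In-memory results of the core method."""

    interactome: inter_mod.Interactome
    diffusion: diffusion.DiffusionResult
    candidates: list[extraction.CandidateNetwork]
    selected: extraction.CandidateNetwork
    partition: cartography.CommunityPartition
    profiles: pd.DataFrame = field(repr=False)


def analyze(
    inter: inter_mod.Interactome,
    seeds: Iterable[str],
    disease: Iterable[str],
    alpha: float = 0.7,
    epsilon: float = 50.0,
    n_perm: int = 1000,
    r_min: int = 50,
    r_max: int = 500,
    r_step: int = 10,
    community_method: str = "multilevel",
    seed: int = 0,
) -> AnalysisResult:
    """Diffusion, extraction and cartography on an in-memory interactome."""
    W = inter_mod.normalize_adjacency(inter)
    x0, dropped = diffusion.seed_vector(inter, seeds)
    if dropped:
        logger.info("%d seed genes absent from the interactome", len(dropped))
    result = diffusion.permutation_adjusted_index(
        W, inter.genes, x0, alpha=alpha, epsilon=epsilon, n_perm=n_perm, seed=seed
    )
    r_max_eff = min(r_max, inter.n_genes)
    cands = extraction.candidate_networks(
        result, inter, r_min=min(r_min, r_max_eff), r_max=r_max_eff, step=r_step
    )
    extraction.score_candidates(
        cands, result, inter, set(disease), seed=seed + 1
    )
    selected = extraction.select_top_network(cands)
    sub = cartography.graph_from_interactome(inter, selected.genes)
    partition = cartography.detect_communities(
        sub, method=community_method, seed=seed + 1
    )
    profiles = cartography.cartography_profiles(sub, partition.assignment)
    return AnalysisResult(
        interactome=inter,
        diffusion=result,
        candidates=cands,
        selected=selected,
        partition=partition,
        profiles=profiles,
    )


def _component_sizes(inter: inter_mod.Interactome, genes: list[str]) -> list[int]:
    sub = cartography.graph_from_interactome(inter, genes)
    return sorted(sub.connected_components().sizes(), reverse=True)


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage from files, write outputs and ``summary.json``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- build-net ---------------------------------------------------------
    logger.info("stage build-net: links=%s", config.links)
    if not Path(config.links).exists():
        raise FileNotFoundError(f"stage build-net: missing input {config.links}")
    links = inter_mod.read_links(config.links)
    links = inter_mod.recombine_frame(links, config.excluded_channels)
    mapping = (
        inter_mod.read_mapping(config.mapping) if config.mapping else None
    )
    inter = inter_mod.build_interactome(
        links,
        mapping=mapping,
        high_threshold=config.high_threshold,
        medium_threshold=config.medium_threshold,
        top_k_medium=config.top_k_medium,
    )
    logger.info(
        "interactome: %d genes, %d edges (high>=%d, medium>=%d top %d)",
        inter.n_genes, inter.n_edges, config.high_threshold,
        config.medium_threshold, config.top_k_medium,
    )
    inter_mod.write_edges(inter, out / "network.tsv")

    # --- diffuse / extract / cartography -----------------------------------
    seeds = genomics.read_gene_list(config.seeds)
    disease = genomics.read_gene_list(config.disease)
    logger.info(
        "stage diffuse: alpha=%s epsilon=%s n_perm=%d seed=%d",
        config.alpha, config.epsilon, config.n_perm, config.seed,
    )
    res = analyze(
        inter,
        seeds,
        disease,
        alpha=config.alpha,
        epsilon=config.epsilon,
        n_perm=config.n_perm,
        r_min=config.r_min,
        r_max=config.r_max,
        r_step=config.r_step,
        community_method=config.community_method,
        seed=config.seed,
    )
    diffusion.write_diffusion(res.diffusion, out / "diffusion.tsv")
    extraction.score_table(res.candidates).to_csv(
        out / "candidates.tsv", sep="\t", index=False
    )
    selected_genes = sorted(res.selected.genes)
    genomics.write_gene_list(selected_genes, out / "top_network_genes.txt")
    sub_edges = {
        pair: s
        for pair, s in inter.edges.items()
        if pair[0] in set(selected_genes) and pair[1] in set(selected_genes)
    }
    inter_mod.write_edges(
        inter_mod.Interactome(genes=tuple(selected_genes), edges=sub_edges),
        out / "top_network.tsv",
    )
    res.profiles.to_csv(out / "roles.tsv", sep="\t", index=False)

    summary: dict = {
        "interactome": {"n_genes": inter.n_genes, "n_links": inter.n_edges},
        "network": {
            "r": res.selected.r,
            "n_genes": len(selected_genes),
            "n_links": res.selected.n_links,
            "component_sizes": _component_sizes(inter, selected_genes),
            "n_communities": len(set(res.partition.assignment.values())),
            "modularity_Q": res.partition.q,
            "scores": {
                "modularity_Q": res.selected.modularity_q,
                "n_sig": res.selected.n_sig,
                "p_resampling": res.selected.p_resampling,
                "p_disease": res.selected.p_disease,
            },
        },
        "hubs": {
            role: sorted(res.profiles.loc[res.profiles["role"] == role, "gene"])
            for role in ("R5", "R6", "R7")
        },
        "thresholds": {
            "alpha": config.alpha,
            "epsilon": config.epsilon,
            "n_perm": config.n_perm,
            "high": config.high_threshold,
            "medium": config.medium_threshold,
            "top_k_medium": config.top_k_medium,
            "ora_fdr": config.ora_fdr,
            "band_fdr": config.band_fdr,
            "window_bp": config.window_bp,
            "seed": config.seed,
        },
    }

    k, pct, p = overlap_report(selected_genes, disease, inter.genes)
    summary["disease_overlap"] = {"k": k, "percent": pct, "p": p}
    if config.deg:
        deg = genomics.read_gene_list(config.deg)
        k, pct, p = overlap_report(selected_genes, deg, inter.genes)
        summary["deg_overlap"] = {"k": k, "percent": pct, "p": p}

    # --- enrich -------------------------------------------------------------
    if config.pathways:
        collection = enrichment.read_gmt(config.pathways)
        universe = set(inter.genes)
        ora = enrichment.pathway_ora(set(selected_genes), collection, universe)
        ora.to_csv(out / "ora.tsv", sep="\t", index=False)
        meta = enrichment.meta_pathways(
            ora, collection, universe=universe, fdr_max=config.ora_fdr,
            seed=config.seed + 2,
        )
        pd.DataFrame(
            sorted(meta.clusters.items()), columns=["pathway", "meta_pathway"]
        ).to_csv(out / "meta_pathways.tsv", sep="\t", index=False)
        summary["pathways"] = {
            "n_tested": int(len(ora)),
            "n_enriched": int((ora["fdr"] < config.ora_fdr).sum()),
            "meta_threshold": meta.threshold,
            "meta_modularity_Q": meta.pathway_network_q,
            "n_meta_pathways": len(set(meta.clusters.values())),
        }

    # --- genomics -----------------------------------------------------------
    if config.loci:
        loci = genomics.read_loci(config.loci)
        bands = genomics.band_enrichment(
            set(selected_genes), loci, set(inter.genes), fdr_max=config.band_fdr
        )
        bands.to_csv(out / "bands.tsv", sep="\t", index=False)
        pairs = genomics.linkage_neighbors(
            selected_genes, disease, loci, window_bp=config.window_bp
        )
        pairs.to_csv(out / "linkage.tsv", sep="\t", index=False)
        summary["genomics"] = {
            "n_bands_tested": int(len(bands)),
            "n_bands_enriched": int(bands["significant"].sum()) if len(bands) else 0,
            "n_linkage_pairs": int(len(pairs)),
        }
    if config.har:
        har = genomics.read_gene_list(config.har)
        report = genomics.har_overlap(selected_genes, har, disease)
        n_har, n_dis, n_new = report.counts
        summary["har"] = {
            "n_network_har": n_har,
            "n_har_disease": n_dis,
            "n_har_inferred": n_new,
        }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
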