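"""Synthetic benchmark inputs with a planted, recoverable seed module.

The generator emulates every pipeline input: a STRING-dialect links table
(per-channel subscores plus a combined score), a protein-to-gene mapping,
seed / disease / differential-expression / HAR gene lists, a pathway GMT,
and a gene loci table with cytobands. A module of genes is planted with
dense internal wiring on top of a scale-free-like background; seed genes are
enriched inside the module, the disease and DEG lists overlap it, pathways
are noisy copies of module subsets, and a configurable fraction of module
genes share one cytoband, so each downstream stage has a recoverable signal.

Defaults emulate the study conditions scaled to desk size: 500 genes with a
40-gene module wired at intra-module edge probability 0.3 (well above the
background density), seeds covering 60% of the module plus a background
seed rate near the real analysis' ~4%, and a disease list half inside the
module. The background is Barabasi-Albert (scale-free-like, closer to
interactome topology); an Erdos-Renyi background is used for calibration
nulls.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from socionet.enrichment import write_gmt
from socionet.genomics import write_gene_list, write_loci
from socionet.interactome import recombine_scores

LINK_CHANNELS = (
    "neighborhood",
    "fusion",
    "cooccurence",
    "coexpression",
    "experiments",
    "database",
    "textmining",
)


@dataclass
class BenchmarkConfig:
    """Knobs of the synthetic benchmark (all sampled from ``seed``)."""

    n_genes: int = 500
    background: str = "ba"  # "ba" (Barabasi-Albert) or "er" (Erdos-Renyi)
    ba_m: int = 2
    er_p: float = 0.02
    module_size: int = 40
    p_intra: float = 0.30  # intra-module edge probability, > background density
    n_seeds_in_module: int = 24
    n_seeds_background: int = 16
    disease_size: int = 30
    disease_in_module: int = 15
    deg_size: int = 50
    deg_in_module: int = 10
    n_pathways: int = 20
    n_module_pathways: int = 5
    pathway_size_range: tuple[int, int] = (5, 40)
    n_chromosomes: int = 5
    bands_per_chromosome: int = 4
    clustered_band_fraction: float = 0.5
    har_size: int = 25
    har_in_module: int = 8
    medium_edge_fraction: float = 0.3  # background edges scored 400-699
    noise_edge_fraction: float = 0.05  # extra sub-threshold edges to filter out
    seed: int = 1

    def validate(self) -> None:
        if not 0 < self.module_size < self.n_genes:
            raise ValueError("module size must be positive and < n_genes")
        for name in ("p_intra", "er_p", "clustered_band_fraction",
                     "medium_edge_fraction", "noise_edge_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_seeds_in_module > self.module_size:
            raise ValueError("more in-module seeds requested than module genes")
        if self.disease_in_module > min(self.disease_size, self.module_size):
            raise ValueError("disease/module overlap exceeds set size")
        if self.deg_in_module > min(self.deg_size, self.module_size):
            raise ValueError("deg/module overlap exceeds set size")
        if self.har_in_module > min(self.har_size, self.module_size):
            raise ValueError("har/module overlap exceeds set size")
        for name in ("n_genes", "disease_size", "deg_size", "har_size",
                     "n_pathways"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class BenchmarkTruth:
    """Ground truth of the generated benchmark."""

    module_genes: list[str]
    seed_genes: list[str]
    disease_genes: list[str]
    expected_band: str
    pathway_origin: dict[str, str]  # pathway name -> "module" | "background"


@dataclass
class Benchmark:
    """All generated inputs, in memory, plus the truth."""

    config: BenchmarkConfig
    links: pd.DataFrame = field(repr=False)
    mapping: dict[str, str] = field(repr=False)
    seeds: list[str]
    disease: list[str]
    deg: list[str]
    pathways: dict[str, set[str]] = field(repr=False)
    loci: pd.DataFrame = field(repr=False)
    har: list[str]
    truth: BenchmarkTruth

    def build_interactome(self):
        """Filtered analysis interactome (recombined scores, text mining
        excluded, retention rules applied)."""
        from socionet.interactome import build_interactome, recombine_frame

        df = recombine_frame(self.links).rename(
            columns={"protein1": "node_a", "protein2": "node_b"}
        )
        return build_interactome(df, mapping=self.mapping)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write every input in its pipeline file dialect; returns paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "links": out / "links.tsv",
            "mapping": out / "mapping.tsv",
            "seeds": out / "seeds.txt",
            "disease": out / "disease.txt",
            "deg": out / "deg.txt",
            "pathways": out / "pathways.gmt",
            "loci": out / "loci.tsv",
            "har": out / "har.txt",
            "truth": out / "truth.json",
        }
        self.links.to_csv(paths["links"], sep="\t", index=False)
        with open(paths["mapping"], "w") as fh:
            for prot in sorted(self.mapping):
                fh.write(f"{prot}\t{self.mapping[prot]}\n")
        write_gene_list(self.seeds, paths["seeds"])
        write_gene_list(self.disease, paths["disease"])
        write_gene_list(self.deg, paths["deg"])
        write_gmt(self.pathways, paths["pathways"])
        write_loci(self.loci, paths["loci"])
        write_gene_list(self.har, paths["har"])
        truth = asdict(self.truth)
        with open(paths["truth"], "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths


def _gene_name(i: int) -> str:
    return f"G{i:05d}"


def _protein_name(i: int) -> str:
    return f"P{i:05d}"


def _background_graph(config: BenchmarkConfig, rng: np.random.Generator) -> nx.Graph:
    gseed = int(rng.integers(2**31 - 1))
    if config.background == "ba":
        return nx.barabasi_albert_graph(config.n_genes, config.ba_m, seed=gseed)
    if config.background == "er":
        return nx.gnp_random_graph(config.n_genes, config.er_p, seed=gseed)
    raise ValueError(f"unknown background model {config.background!r}")


def _links_frame(
    edges_with_scores: list[tuple[int, int, int]], rng: np.random.Generator
) -> pd.DataFrame:
    """STRING-dialect links table; the 'experiments' channel carries the
    intended evidence (a single included channel recombines back to itself),
    'textmining' carries noise that must be excluded, and the shipped
    combined_score includes text mining (exercising the recombination)."""
    rows = []
    for u, v, score in edges_with_scores:
        tm = int(rng.integers(0, 901))
        chans = dict.fromkeys(LINK_CHANNELS, 0)
        chans["experiments"] = score
        chans["textmining"] = tm
        combined = recombine_scores(chans)
        rows.append(
            {"protein1": _protein_name(u), "protein2": _protein_name(v),
             **chans, "combined_score": combined}
        )
    df = pd.DataFrame(rows, columns=["protein1", "protein2", *LINK_CHANNELS,
                                     "combined_score"])
    return df.sort_values(["protein1", "protein2"], ignore_index=True)


def _sample_with_overlap(
    rng: np.random.Generator,
    module: np.ndarray,
    others: np.ndarray,
    total: int,
    in_module: int,
) -> np.ndarray:
    inside = rng.choice(module, size=in_module, replace=False)
    outside = rng.choice(others, size=total - in_module, replace=False)
    return np.concatenate([inside, outside])


def _make_loci(
    config: BenchmarkConfig,
    rng: np.random.Generator,
    genes: list[str],
    module: list[str],
) -> tuple[pd.DataFrame, str]:
    """Assign genes to chromosomes/bands; a fraction of module genes share
    one band. Each band spans a contiguous 10 Mb region; genes sit at 100 kb
    intervals from the band start (span 20 kb), so within-band neighbors fall
    inside a 0.5 cM window."""
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    bands = []
    for c_idx, chrom in enumerate(chroms):
        for b in range(config.bands_per_chromosome):
            arm = "p" if b < config.bands_per_chromosome / 2 else "q"
            bands.append((chrom, f"{chrom[3:]}{arm}{b + 1}1"))
    target_band_idx = int(rng.integers(len(bands)))
    target_chrom, target_band = bands[target_band_idx]

    n_clustered = int(round(config.clustered_band_fraction * len(module)))
    clustered = set(
        rng.choice(np.array(module), size=n_clustered, replace=False).tolist()
    )
    assignment: dict[str, int] = {}
    for g in genes:
        if g in clustered:
            assignment[g] = target_band_idx
        else:
            assignment[g] = int(rng.integers(len(bands)))

    band_span = 10_000_000
    counters = dict.fromkeys(range(len(bands)), 0)
    rows = []
    for g in genes:
        b_idx = assignment[g]
        chrom, band = bands[b_idx]
        local_band_idx = b_idx % config.bands_per_chromosome
        slot = counters[b_idx]
        counters[b_idx] += 1
        start = local_band_idx * band_span + slot * 100_000 + 1
        rows.append(
            {"gene": g, "chrom": chrom, "start": start, "end": start + 19_999,
             "band": band}
        )
    loci = pd.DataFrame(rows).sort_values("gene", ignore_index=True)
    return loci, target_band


def _make_pathways(
    config: BenchmarkConfig,
    rng: np.random.Generator,
    genes: list[str],
    module: list[str],
) -> tuple[dict[str, set[str]], dict[str, str]]:
    lo, hi = config.pathway_size_range
    if lo < 3 or hi > 200:
        raise ValueError("pathway sizes must stay within [3, 200]")
    pathways: dict[str, set[str]] = {}
    origin: dict[str, str] = {}
    gene_arr = np.array(genes)
    module_arr = np.array(module)
    for i in range(config.n_pathways):
        name = f"PW{i:03d}"
        size = int(rng.integers(lo, hi + 1))
        if i < config.n_module_pathways:
            core = min(max(3, int(round(size * 0.8))), len(module))
            members = set(rng.choice(module_arr, size=core, replace=False))
            n_noise = max(0, size - core)
            pool = np.array([g for g in genes if g not in members])
            members |= set(rng.choice(pool, size=n_noise, replace=False))
            origin[name] = "module"
        else:
            members = set(rng.choice(gene_arr, size=size, replace=False))
            origin[name] = "background"
        pathways[name] = members
    return pathways, origin


def generate_benchmark(config: BenchmarkConfig | None = None) -> Benchmark:
    """Generate all pipeline inputs with a planted module.

    Fully reproducible from ``config.seed``: the same config yields
    byte-identical files from :meth:`Benchmark.write`.
    """
    config = config or BenchmarkConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = [_gene_name(i) for i in range(n)]
    mapping = {_protein_name(i): genes[i] for i in range(n)}

    graph = _background_graph(config, rng)
    module_idx = np.sort(rng.choice(n, size=config.module_size, replace=False))
    module = [genes[i] for i in module_idx]
    for a_pos in range(config.module_size):
        for b_pos in range(a_pos + 1, config.module_size):
            if rng.random() < config.p_intra:
                graph.add_edge(int(module_idx[a_pos]), int(module_idx[b_pos]))

    module_set = set(module_idx.tolist())
    edges_scores: list[tuple[int, int, int]] = []
    for u, v in sorted(graph.edges()):
        u, v = (u, v) if u < v else (v, u)
        if u in module_set and v in module_set:
            score = int(rng.integers(700, 1001))
        elif rng.random() < config.medium_edge_fraction:
            score = int(rng.integers(400, 700))
        else:
            score = int(rng.integers(700, 1001))
        edges_scores.append((u, v, score))

    # sub-threshold noise edges the retention rules must discard
    n_noise = int(round(config.noise_edge_fraction * graph.number_of_edges()))
    existing = {(u, v) for u, v, _ in edges_scores}
    while n_noise > 0:
        u, v = sorted(rng.integers(0, n, size=2).tolist())
        if u == v or (u, v) in existing:
            continue
        existing.add((u, v))
        edges_scores.append((u, v, int(rng.integers(150, 400))))
        n_noise -= 1

    links = _links_frame(edges_scores, rng)

    others = np.array([g for g in genes if g not in set(module)])
    seeds = _sample_with_overlap(
        rng, np.array(module), others,
        config.n_seeds_in_module + config.n_seeds_background,
        config.n_seeds_in_module,
    ).tolist()
    disease = _sample_with_overlap(
        rng, np.array(module), others, config.disease_size,
        config.disease_in_module,
    ).tolist()
    deg = _sample_with_overlap(
        rng, np.array(module), others, config.deg_size, config.deg_in_module
    ).tolist()
    har = _sample_with_overlap(
        rng, np.array(module), others, config.har_size, config.har_in_module
    ).tolist()

    pathways, origin = _make_pathways(config, rng, genes, module)
    loci, expected_band = _make_loci(config, rng, genes, module)

    truth = BenchmarkTruth(
        module_genes=sorted(module),
        seed_genes=sorted(seeds),
        disease_genes=sorted(disease),
        expected_band=expected_band,
        pathway_origin=origin,
    )
    return Benchmark(
        config=config,
        links=links,
        mapping=mapping,
        seeds=sorted(seeds),
        disease=sorted(disease),
        deg=sorted(deg),
        pathways=pathways,
        loci=loci,
        har=sorted(har),
        truth=truth,
    )


def null_benchmark(config: BenchmarkConfig | None = None) -> Benchmark:
    """Benchmark with no planted structure, for calibration tests.

    Background is Erdos-Renyi by default, seeds are placed uniformly over
    all genes, and the disease/DEG/HAR lists are independent of the seeds.
    """
    config = config or BenchmarkConfig(background="er")
    null_cfg = BenchmarkConfig(**{**asdict(config)})
    null_cfg.p_intra = 0.0
    # uniform seed placement: module carries no extra edges and the sets are
    # drawn with expected (proportional) overlap so nothing marks the module
    total_seeds = config.n_seeds_in_module + config.n_seeds_background
    frac = config.module_size / config.n_genes
    null_cfg.n_seeds_in_module = int(round(total_seeds * frac))
    null_cfg.n_seeds_background = total_seeds - null_cfg.n_seeds_in_module
    null_cfg.disease_in_module = int(round(config.disease_size * frac))
    null_cfg.deg_in_module = int(round(config.deg_size * frac))
    null_cfg.har_in_module = int(round(config.har_size * frac))
    null_cfg.clustered_band_fraction = 0.0
    return generate_benchmark(null_cfg)
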