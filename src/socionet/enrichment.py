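"""Over-representation analysis and meta-pathway clustering.

Pathway enrichment is the upper-tail hypergeometric test with
Benjamini-Hochberg correction, after restricting each pathway to the
analysis universe and filtering by effective size (default 3-200 genes).
Enriched pathways are then summarized into meta-pathways: pathways become
nodes of a graph with an edge whenever their overlap coefficient
|A & B| / min(|A|, |B|) exceeds a threshold, the threshold is chosen to
maximize the fast-greedy modularity of that pathway graph, and the
fast-greedy communities at the chosen threshold are the meta-pathways.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import igraph as ig
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from socionet.cartography import detect_communities, graph_from_edges

logger = logging.getLogger(__name__)


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: universe size, K: annotated genes in the universe, n: query size,
    k: overlap. scipy evaluates the tail in log space, so the result is
    numerically stable for large N.
    """
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    if K > N or n > N or K < 0 or n < 0:
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDRs, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file (name <TAB> description <TAB> genes...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{i}: expected >=3 tab-separated fields")
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{i}: duplicate gene set name {name!r}")
            sets[name] = set(parts[2:])
    return sets


def write_gmt(
    sets: Mapping[str, Iterable[str]], path: str | Path, description: str = "na"
) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(set(sets[name])))
            fh.write(f"{name}\t{description}\t{genes}\n")


def pathway_ora(
    query: set[str],
    collection: Mapping[str, set[str]],
    universe: set[str],
    min_size: int = 3,
    max_size: int = 200,
) -> pd.DataFrame:
    """One hypergeometric test per size-eligible gene set.

    Pathways are intersected with the universe before the size filter, so
    the row count depends only on the collection and universe, not on the
    query. Columns: name, k, K, n, N, p, fdr, genes (overlap, '|'-joined).
    Rows sorted by p then name.
    """
    if not universe:
        raise ValueError("empty universe")
    stray = query - universe
    if stray:
        logger.info("%d query genes outside the universe were dropped", len(stray))
    query = query & universe
    N = len(universe)
    n = len(query)
    rows = []
    for name in sorted(collection):
        eff = collection[name] & universe
        if not (min_size <= len(eff) <= max_size):
            continue
        overlap = query & eff
        p = hypergeom_pvalue(len(overlap), len(eff), n, N)
        rows.append(
            {
                "name": name,
                "k": len(overlap),
                "K": len(eff),
                "n": n,
                "N": N,
                "p": p,
                "genes": "|".join(sorted(overlap)),
            }
        )
    df = pd.DataFrame(
        rows, columns=["name", "k", "K", "n", "N", "p", "genes"]
    )
    if len(df):
        df["fdr"] = bh_adjust(df["p"].to_numpy())
        df = df.sort_values(["p", "name"], ignore_index=True)
    else:
        df["fdr"] = pd.Series(dtype=float)
    return df[["name", "k", "K", "n", "N", "p", "fdr", "genes"]]


def overlap_coefficient(a: set[str], b: set[str]) -> float:
    """|A & B| / min(|A|, |B|), in [0, 1]."""
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))


@dataclass
class MetaPathwayResult:
    """Pathway graph at the selected overlap threshold with its clusters."""

    graph: ig.Graph
    threshold: float
    pathway_network_q: float
    clusters: dict[str, int]


DEFAULT_THRESHOLD_GRID = tuple(np.round(np.arange(0.05, 0.96, 0.05), 2))


def meta_pathways(
    enriched: pd.DataFrame,
    collection: Mapping[str, set[str]],
    universe: set[str] | None = None,
    min_network_genes: int = 3,
    fdr_max: float = 0.05,
    threshold_grid: Sequence[float] = DEFAULT_THRESHOLD_GRID,
    seed: int = 0,
) -> MetaPathwayResult:
    """Cluster enriched pathways into meta-pathways.

    Eligible pathways have at least ``min_network_genes`` query genes in the
    overlap and fdr < ``fdr_max``. For each threshold on the grid the graph
    has an edge between two pathways when their overlap coefficient exceeds
    the threshold; the threshold maximizing fast-greedy modularity (smallest
    on ties) defines the final clustering.
    """
    eligible = enriched[
        (enriched["k"] >= min_network_genes) & (enriched["fdr"] < fdr_max)
    ]["name"].tolist()
    sets = {
        name: (collection[name] & universe if universe else set(collection[name]))
        for name in eligible
    }
    if len(eligible) < 2:
        warnings.warn("fewer than 2 eligible pathways; trivial clustering")
        graph = graph_from_edges(eligible, [])
        return MetaPathwayResult(
            graph=graph,
            threshold=float(min(threshold_grid)),
            pathway_network_q=0.0,
            clusters={name: 0 for name in eligible},
        )
    pairs = [
        (a, b, overlap_coefficient(sets[a], sets[b]))
        for a, b in combinations(sorted(eligible), 2)
    ]
    best = None
    for thr in sorted(threshold_grid):
        edges = [(a, b) for a, b, oc in pairs if oc > thr]
        graph = graph_from_edges(eligible, edges)
        part = detect_communities(graph, method="fastgreedy", seed=seed)
        if best is None or part.q > best[2].q:
            best = (float(thr), graph, part)
    thr, graph, part = best
    return MetaPathwayResult(
        graph=graph,
        threshold=thr,
        pathway_network_q=part.q,
        clusters=dict(part.assignment),
    )
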