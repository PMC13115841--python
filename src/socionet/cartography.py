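"""Community detection and Guimera-Amaral functional cartography.

Genes of the selected network are partitioned into communities (multilevel
a.k.a. Louvain, or fast-greedy agglomeration) and classified by two
topological coordinates: the within-community degree z-score

    z_i = (kappa_i - mean_s(kappa)) / sd_s(kappa)

where kappa_i counts the links of gene i inside its own community s, and the
participation coefficient

    P_i = 1 - sum_s (k_is / k_i)^2,

which is 0 when all links stay inside one community and approaches 1 when
links spread evenly over many. Genes with z >= z_hub are hubs. The seven
roles follow the standard functional-cartography cuts: non-hubs are
ultra-peripheral (R1), peripheral (R2), connector (R3) or kinless (R4) by P;
hubs are provincial (R5), connector (R6) or kinless (R7).
"""

from __future__ import annotations

import random
from contextlib import contextmanager
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import igraph as ig
import numpy as np
import pandas as pd

from socionet.interactome import Interactome

ROLE_LABELS = {
    "R1": "ultra-peripheral",
    "R2": "peripheral",
    "R3": "non-hub connector",
    "R4": "non-hub kinless",
    "R5": "provincial hub",
    "R6": "connector hub",
    "R7": "kinless hub",
}


@dataclass
class CommunityPartition:
    """A community assignment with its modularity."""

    assignment: dict[str, int]
    method: str
    q: float


@dataclass(frozen=True)
class CartographyProfile:
    gene: str
    community: int
    z: float
    p: float
    role: str


@contextmanager
def _seeded_igraph_rng(seed: int):
    """python-igraph draws randomness from Python's ``random`` by default;
    swap in a seeded generator so community detection is reproducible."""
    ig.set_random_number_generator(random.Random(seed))
    try:
        yield
    finally:
        ig.set_random_number_generator(random)


def graph_from_edges(
    genes: Iterable[str], edges: Iterable[tuple[str, str]]
) -> ig.Graph:
    """Undirected igraph graph with gene names as the 'name' attribute."""
    genes = sorted(set(genes))
    index = {g: i for i, g in enumerate(genes)}
    g = ig.Graph(
        n=len(genes),
        edges=[(index[a], index[b]) for a, b in edges],
        directed=False,
    )
    g.vs["name"] = genes
    return g


def graph_from_interactome(
    interactome: Interactome, genes: Sequence[str] | None = None
) -> ig.Graph:
    """igraph view of an interactome, optionally induced on ``genes``."""
    if genes is None:
        return graph_from_edges(interactome.genes, interactome.edges.keys())
    keep = set(genes)
    edges = [(a, b) for (a, b) in interactome.edges if a in keep and b in keep]
    return graph_from_edges(keep, edges)


def modularity(graph: ig.Graph, partition: Mapping[str, int]) -> float:
    """Newman-Girvan modularity sum_c(e_c/m - (d_c/2m)^2); 0 if edgeless."""
    if graph.ecount() == 0:
        return 0.0
    membership = [partition[name] for name in graph.vs["name"]]
    return float(graph.modularity(membership))


def detect_communities(
    graph: ig.Graph, method: str = "multilevel", seed: int = 0
) -> CommunityPartition:
    """Community detection, deterministic given ``seed``.

    Disconnected components are never merged (merging components cannot
    increase modularity, and neither algorithm proposes such merges).
    """
    if graph.ecount() == 0:
        assignment = {name: i for i, name in enumerate(graph.vs["name"])}
        return CommunityPartition(assignment=assignment, method=method, q=0.0)
    with _seeded_igraph_rng(seed):
        if method == "multilevel":
            clustering = graph.community_multilevel()
        elif method == "fastgreedy":
            clustering = graph.community_fastgreedy().as_clustering()
        else:
            raise ValueError(f"unknown method {method!r}")
    assignment = dict(zip(graph.vs["name"], clustering.membership))
    return CommunityPartition(
        assignment=assignment, method=method, q=float(graph.modularity(clustering))
    )


def _role(z: float, p: float, z_hub, p_cuts_nonhub, p_cuts_hub) -> str:
    if z < z_hub:
        c1, c2, c3 = p_cuts_nonhub
        if p < c1:
            return "R1"
        if p < c2:
            return "R2"
        if p < c3:
            return "R3"
        return "R4"
    c1, c2 = p_cuts_hub
    if p < c1:
        return "R5"
    if p < c2:
        return "R6"
    return "R7"


def cartography_profiles(
    graph: ig.Graph,
    partition: Mapping[str, int],
    z_hub: float = 2.5,
    p_cuts_nonhub: tuple[float, float, float] = (0.05, 0.62, 0.80),
    p_cuts_hub: tuple[float, float] = (0.30, 0.75),
) -> pd.DataFrame:
    """Per-gene z, P and role; columns: gene, community, z, P, role.

    Isolated genes get z = 0, P = 0 and role R1. A community whose
    within-degree standard deviation is 0 gives z = 0 for its members.
    """
    names = list(graph.vs["name"])
    membership = np.array([partition[n] for n in names])
    n = len(names)
    comms = np.unique(membership)
    comm_pos = {c: i for i, c in enumerate(comms)}

    # k_is: links of gene i into each community
    k_is = np.zeros((n, len(comms)))
    for e in graph.es:
        a, b = e.tuple
        k_is[a, comm_pos[membership[b]]] += 1
        k_is[b, comm_pos[membership[a]]] += 1
    k = k_is.sum(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(k[:, None] > 0, k_is / np.maximum(k[:, None], 1), 0.0)
    p = np.where(k > 0, 1.0 - np.sum(frac**2, axis=1), 0.0)

    kappa = k_is[np.arange(n), [comm_pos[c] for c in membership]]
    z = np.zeros(n)
    for c in comms:
        mask = membership == c
        mu = kappa[mask].mean()
        sd = kappa[mask].std()  # population sd over the community's genes
        if sd > 0:
            z[mask] = (kappa[mask] - mu) / sd

    roles = [
        _role(z[i], p[i], z_hub, p_cuts_nonhub, p_cuts_hub) for i in range(n)
    ]
    return pd.DataFrame(
        {
            "gene": names,
            "community": membership,
            "z": z,
            "P": p,
            "role": roles,
        }
    ).sort_values("gene", ignore_index=True)
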