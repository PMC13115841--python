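"""Top-network extraction: sweep top-r subnetworks and pick the best.

The networks induced by the top r genes (r on a grid, by decreasing adjusted
smoothing index) are each scored on four criteria: modularity of the induced
subgraph, the number of genes with permutation p < 0.01, a network-resampling
p-value (how often the permuted rankings produce as many induced links among
their own top-r genes), and a hypergeometric enrichment p-value against a
disease gene set. The candidate with the best equal-weight rank aggregate of
the four criteria is the selected top network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from socionet.cartography import detect_communities, graph_from_interactome
from socionet.diffusion import DiffusionResult
from socionet.enrichment import hypergeom_pvalue
from socionet.interactome import Interactome


@dataclass
class CandidateNetwork:
    """A top-r induced subnetwork with its four extraction scores."""

    r: int
    gene_indices: np.ndarray = field(repr=False)
    genes: list[str]
    n_links: int
    modularity_q: float | None = None
    n_sig: int | None = None
    p_resampling: float | None = None
    p_disease: float | None = None
    composite_rank: float | None = None


class PermutationStore:
    """Link counts among the top-r genes of each permuted ranking.

    Wraps the per-permutation rankings produced during the permutation run
    and the interactome edge list. For a given r, an edge is inside a
    permutation's top-r network iff both endpoints rank above r, i.e. the
    larger of the two rank positions is < r; counts for a whole r grid are
    obtained in one pass per permutation.
    """

    def __init__(self, perm_rankings: np.ndarray, interactome: Interactome):
        if perm_rankings is None:
            raise ValueError("diffusion result was run with keep_rankings=False")
        self.n_perm, n = perm_rankings.shape
        u, v, _ = interactome.edge_arrays()
        # per permutation: sorted max-rank position of each edge
        self._sorted_maxpos = np.empty((self.n_perm, len(u)), dtype=np.int64)
        pos = np.empty(n, dtype=np.int64)
        for t in range(self.n_perm):
            pos[perm_rankings[t]] = np.arange(n)
            self._sorted_maxpos[t] = np.sort(np.maximum(pos[u], pos[v]))

    def link_counts(self, r_grid: Sequence[int]) -> np.ndarray:
        """(n_perm, len(r_grid)) array of induced link counts."""
        r = np.asarray(r_grid, dtype=np.int64)
        out = np.empty((self.n_perm, len(r)), dtype=np.int64)
        for t in range(self.n_perm):
            out[t] = np.searchsorted(self._sorted_maxpos[t], r, side="left")
        return out


def network_resampling_pvalue(
    r: int, observed_links: int, perm_store: PermutationStore
) -> float:
    """p = (1 + #{perm : links among its top-r >= observed}) / (n_perm + 1)."""
    counts = perm_store.link_counts([r])[:, 0]
    return float((1 + int(np.sum(counts >= observed_links))) / (perm_store.n_perm + 1))


def candidate_networks(
    result: DiffusionResult,
    interactome: Interactome,
    r_min: int = 50,
    r_max: int = 500,
    step: int = 10,
) -> list[CandidateNetwork]:
    """One candidate per r on the inclusive grid [r_min, r_max]."""
    if r_min > r_max:
        raise ValueError("r_min must be <= r_max")
    if r_max > interactome.n_genes:
        raise ValueError("r_max exceeds the number of interactome genes")
    cands = []
    for r in range(r_min, r_max + 1, step):
        idx = result.order[:r]
        cands.append(
            CandidateNetwork(
                r=r,
                gene_indices=idx,
                genes=[result.genes[i] for i in idx],
                n_links=interactome.induced_link_count(idx),
            )
        )
    return cands


def _induced_modularity(
    interactome: Interactome, gene_indices: np.ndarray, seed: int
) -> float:
    genes = [interactome.genes[i] for i in gene_indices]
    sub = graph_from_interactome(interactome, genes)
    if sub.ecount() == 0:
        return 0.0
    part = detect_communities(sub, method="multilevel", seed=seed)
    return part.q


def score_candidates(
    candidates: list[CandidateNetwork],
    result: DiffusionResult,
    interactome: Interactome,
    disease_genes: set[str],
    universe: set[str] | None = None,
    sig_level: float = 0.01,
    seed: int = 0,
) -> list[CandidateNetwork]:
    """Fill the four extraction scores of every candidate (in place).

    Disease enrichment is the upper-tail hypergeometric of the candidate's
    overlap with ``disease_genes`` against ``universe`` (default: all
    interactome genes).
    """
    if universe is None:
        universe = set(interactome.genes)
    disease = set(disease_genes) & universe
    if not disease:
        raise ValueError(
            "disease gene set is disjoint from the universe; background misconfigured"
        )
    store = PermutationStore(result.perm_rankings, interactome)
    perm_counts = store.link_counts([c.r for c in candidates])
    sig_ranked = np.cumsum(result.pi[result.order] < sig_level)
    n_universe = len(universe)
    for j, cand in enumerate(candidates):
        cand.modularity_q = _induced_modularity(
            interactome, cand.gene_indices, seed=seed
        )
        cand.n_sig = int(sig_ranked[cand.r - 1])
        cand.p_resampling = float(
            (1 + int(np.sum(perm_counts[:, j] >= cand.n_links)))
            / (store.n_perm + 1)
        )
        k = len(set(cand.genes) & disease)
        cand.p_disease = hypergeom_pvalue(
            k, len(disease), len(set(cand.genes) & universe), n_universe
        )
    return candidates


def select_top_network(candidates: list[CandidateNetwork]) -> CandidateNetwork:
    """Equal-weight rank aggregation of the four criteria.

    Each criterion is converted to a rank across candidates (higher Q, higher
    n_sig, lower resampling p and lower disease p are better); the composite
    is the sum of ranks, lower is better; ties go to the smaller r. The
    result is invariant to the order of ``candidates``.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    if any(
        c.modularity_q is None
        or c.n_sig is None
        or c.p_resampling is None
        or c.p_disease is None
        for c in candidates
    ):
        raise ValueError("all four scores must be populated before selection")
    q = np.array([c.modularity_q for c in candidates])
    nsig = np.array([c.n_sig for c in candidates])
    pres = np.array([c.p_resampling for c in candidates])
    pdis = np.array([c.p_disease for c in candidates])
    composite = (
        rankdata(-q, method="average")
        + rankdata(-nsig, method="average")
        + rankdata(pres, method="average")
        + rankdata(pdis, method="average")
    )
    for c, comp in zip(candidates, composite):
        c.composite_rank = float(comp)
    rs = np.array([c.r for c in candidates])
    best = np.lexsort((rs, composite))[0]
    return candidates[best]


def score_table(candidates: list[CandidateNetwork]) -> pd.DataFrame:
    """Per-candidate score table (one row per r)."""
    return pd.DataFrame(
        {
            "r": [c.r for c in candidates],
            "n_links": [c.n_links for c in candidates],
            "modularity_Q": [c.modularity_q for c in candidates],
            "n_sig": [c.n_sig for c in candidates],
            "p_resampling": [c.p_resampling for c in candidates],
            "p_disease": [c.p_disease for c in candidates],
            "composite_rank": [c.composite_rank for c in candidates],
        }
    )
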