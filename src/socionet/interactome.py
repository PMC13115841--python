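"""Interactome construction from STRING-style edge tables.

STRING distributes protein links with one confidence subscore per evidence
channel (neighborhood, fusion, co-occurrence, co-expression, experiments,
databases, text mining, ...) on a 0-1000 scale, plus a Bayesian combination
of all channels. This module recombines the channels while excluding chosen
ones (typically text mining), maps protein identifiers to gene identifiers,
and applies the edge-retention rule used for the sociability analysis: keep
every high-confidence edge (combined score >= 700) plus, per gene, its top
3 medium-confidence edges (score >= 400).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: Prior probability of a random protein pair interacting, as used by
#: STRING's published subscore-combination script.
STRING_PRIOR = 0.041

#: Channel columns of the ``protein.links.full`` dialect (non-transferred
#: plus transferred variants). Any column that is not an identifier or the
#: precomputed combination is treated as a channel when reading files.
_ID_COLUMNS = ("protein1", "protein2", "node1", "node2")
_COMBINED_COLUMNS = ("combined_score",)


@dataclass(frozen=True)
class EdgeRecord:
    """A single interaction record before gene mapping."""

    node_a: str
    node_b: str
    channel_scores: Mapping[str, int]
    combined: int


@dataclass
class Interactome:
    """Undirected gene-gene interaction graph with integer confidence scores.

    ``genes`` is lexicographically sorted; each edge is stored once with its
    endpoints order-normalized (``a < b``). Scores live on the 0-1000 scale.
    """

    genes: tuple[str, ...]
    edges: dict[tuple[str, str], int] = field(repr=False)

    def __post_init__(self) -> None:
        self.genes = tuple(sorted(set(self.genes)))
        self._index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index(self, gene: str) -> int:
        return self._index[gene]

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Edges as parallel index arrays (u, v, score)."""
        if not self.edges:
            z = np.empty(0, dtype=np.int64)
            return z, z.copy(), z.copy()
        pairs = sorted(self.edges.items())
        u = np.array([self._index[a] for (a, _), _ in pairs], dtype=np.int64)
        v = np.array([self._index[b] for (_, b), _ in pairs], dtype=np.int64)
        s = np.array([sc for _, sc in pairs], dtype=np.int64)
        return u, v, s

    def adjacency(self, weighting: str = "binary") -> sp.csr_matrix:
        """Symmetric adjacency matrix A (binary or score/1000 weights)."""
        if weighting not in ("binary", "score"):
            raise ValueError(f"unknown weighting {weighting!r}")
        n = self.n_genes
        u, v, s = self.edge_arrays()
        w = np.ones(len(u)) if weighting == "binary" else s / 1000.0
        a = sp.coo_matrix(
            (np.concatenate([w, w]), (np.concatenate([u, v]), np.concatenate([v, u]))),
            shape=(n, n),
        )
        return a.tocsr()

    def induced_link_count(self, gene_indices: np.ndarray) -> int:
        """Number of edges with both endpoints in ``gene_indices``."""
        mask = np.zeros(self.n_genes, dtype=bool)
        mask[gene_indices] = True
        u, v, _ = self.edge_arrays()
        return int(np.sum(mask[u] & mask[v]))


def recombine_scores(
    channel_scores: Mapping[str, int],
    excluded_channels: Iterable[str] = (),
    prior: float = STRING_PRIOR,
) -> int:
    """Combine per-channel STRING subscores into one confidence score.

    Each included channel score ``s`` (0-1000) is converted to a probability,
    the prior is removed, the de-priored probabilities are combined as
    ``1 - prod(1 - s')``, and the prior is added back:

        s' = max(0, (s/1000 - prior) / (1 - prior))
        c  = 1 - prod(1 - s')
        t  = c * (1 - prior) + prior

    Returns ``round(1000 * t)``. Channels named in ``excluded_channels`` are
    ignored, which is how text mining is dropped from the combination.
    """
    if not 0.0 < prior < 1.0:
        raise ValueError(f"prior must be in (0, 1), got {prior}")
    excluded = set(excluded_channels)
    one_minus = 1.0
    for channel, score in channel_scores.items():
        if score < 0 or score > 1000:
            raise ValueError(
                f"channel {channel!r} score {score} outside [0, 1000]"
            )
        if channel in excluded:
            continue
        deprior = max(0.0, (score / 1000.0 - prior) / (1.0 - prior))
        one_minus *= 1.0 - deprior
    combined = 1.0 - one_minus
    total = combined * (1.0 - prior) + prior
    return int(round(1000.0 * total))


def read_links(path: str | Path) -> pd.DataFrame:
    """Read a STRING ``protein.links.full``-dialect table.

    Whitespace- or tab-separated with a header row; gzip transparently
    supported. Returns a DataFrame whose first two columns are renamed to
    ``node_a``/``node_b``; remaining columns are channel subscores plus an
    optional ``combined_score``.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        df = pd.read_csv(fh, sep=r"\s+")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected >=3 columns, got {df.shape[1]}")
    cols = list(df.columns)
    df = df.rename(columns={cols[0]: "node_a", cols[1]: "node_b"})
    return df


def channel_columns(df: pd.DataFrame) -> list[str]:
    """Channel subscore columns of a links table."""
    skip = set(_ID_COLUMNS) | set(_COMBINED_COLUMNS) | {"node_a", "node_b"}
    return [c for c in df.columns if c not in skip]


def recombine_frame(
    df: pd.DataFrame,
    excluded_channels: Iterable[str] = ("textmining",),
    prior: float = STRING_PRIOR,
) -> pd.DataFrame:
    """Vectorized channel recombination over a links table.

    Returns a copy with a ``score`` column holding the recombined combined
    score with ``excluded_channels`` left out.
    """
    excluded = set(excluded_channels)
    chans = [c for c in channel_columns(df) if c not in excluded]
    vals = df[chans].to_numpy(dtype=float)
    if vals.size and (vals.min() < 0 or vals.max() > 1000):
        raise ValueError("channel score outside [0, 1000]")
    deprior = np.clip((vals / 1000.0 - prior) / (1.0 - prior), 0.0, None)
    combined = 1.0 - np.prod(1.0 - deprior, axis=1)
    total = combined * (1.0 - prior) + prior
    out = df.copy()
    out["score"] = np.rint(1000.0 * total).astype(int)
    return out


def build_interactome(
    edges: pd.DataFrame | Iterable[tuple[str, str, int]],
    mapping: Mapping[str, str] | None = None,
    high_threshold: int = 700,
    medium_threshold: int = 400,
    top_k_medium: int = 3,
    genes: Iterable[str] | None = None,
) -> Interactome:
    """Apply identifier mapping and the edge-retention rules.

    ``edges`` is a DataFrame with columns ``node_a``, ``node_b``, ``score``
    (or an iterable of such triples). Unmapped identifiers are dropped (with
    a logged count); self-loops after mapping are removed; duplicate gene
    pairs keep the maximum score. Retained edges are the union of

    * all edges with ``score >= high_threshold``, and
    * edges among the ``top_k_medium`` highest-scoring medium-confidence
      edges (``medium_threshold <= score < high_threshold``) of EITHER
      endpoint, ties broken by higher score then lexicographic partner id.

    ``genes`` optionally forces extra (possibly isolated) genes into the
    result; by default genes are the endpoints of retained edges.
    """
    if medium_threshold > high_threshold:
        raise ValueError("medium_threshold must be <= high_threshold")
    if isinstance(edges, pd.DataFrame):
        df = edges[["node_a", "node_b", "score"]].copy()
    else:
        df = pd.DataFrame(list(edges), columns=["node_a", "node_b", "score"])
    if df.empty:
        return Interactome(genes=tuple(genes or ()), edges={})
    if not np.issubdtype(df["score"].dtype, np.number):
        raise ValueError("scores must be numeric")
    if (df["score"] < 0).any() or (df["score"] > 1000).any():
        raise ValueError("edge score outside [0, 1000]")

    if mapping is not None:
        n0 = len(df)
        df["node_a"] = df["node_a"].map(mapping)
        df["node_b"] = df["node_b"].map(mapping)
        df = df.dropna(subset=["node_a", "node_b"])
        dropped = n0 - len(df)
        if dropped:
            logger.info("dropped %d records with unmapped identifiers", dropped)

    df = df[df["node_a"] != df["node_b"]]
    if df.empty:
        return Interactome(genes=tuple(genes or ()), edges={})

    # order-normalize pairs, then keep the maximum score per gene pair
    na = df["node_a"].astype(str).to_numpy()
    nb = df["node_b"].astype(str).to_numpy()
    swap = na > nb
    a = np.where(swap, nb, na)
    b = np.where(swap, na, nb)
    dedup = (
        pd.DataFrame({"a": a, "b": b, "score": df["score"].astype(int)})
        .groupby(["a", "b"], as_index=False)["score"]
        .max()
    )

    high = dedup[dedup["score"] >= high_threshold]
    medium = dedup[
        (dedup["score"] >= medium_threshold) & (dedup["score"] < high_threshold)
    ]

    keep = set(map(tuple, high[["a", "b"]].itertuples(index=False, name=None)))
    if not medium.empty and top_k_medium > 0:
        # per-endpoint view: one row per (gene, partner, score)
        long = pd.concat(
            [
                medium.rename(columns={"a": "gene", "b": "partner"}),
                medium.rename(columns={"b": "gene", "a": "partner"}),
            ],
            ignore_index=True,
        )
        long = long.sort_values(
            ["gene", "score", "partner"], ascending=[True, False, True]
        )
        top = long.groupby("gene", sort=False).head(top_k_medium)
        for gene, partner in top[["gene", "partner"]].itertuples(
            index=False, name=None
        ):
            keep.add((min(gene, partner), max(gene, partner)))

    score_of = {
        (r.a, r.b): int(r.score) for r in dedup.itertuples(index=False)
    }
    retained = {pair: score_of[pair] for pair in keep}
    gene_set = {g for pair in retained for g in pair}
    if genes is not None:
        gene_set |= set(genes)
    return Interactome(genes=tuple(gene_set), edges=retained)


def normalize_adjacency(
    interactome: Interactome, weighting: str = "binary"
) -> sp.csr_matrix:
    """Symmetrically normalized adjacency W = D^(-1/2) A D^(-1/2).

    Rows/columns of isolated genes are all zero (0/0 treated as 0). The
    spectral radius of W is at most 1.
    """
    a = interactome.adjacency(weighting=weighting)
    deg = np.asarray(a.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        dinv = 1.0 / np.sqrt(deg)
    dinv[~np.isfinite(dinv)] = 0.0
    d = sp.diags(dinv)
    return (d @ a @ d).tocsr()


def write_edges(interactome: Interactome, path: str | Path) -> None:
    """Write the canonical edge TSV (gene_a, gene_b, score), sorted."""
    with open(path, "w") as fh:
        for (a, b), s in sorted(interactome.edges.items()):
            fh.write(f"{a}\t{b}\t{s}\n")


def read_edges(path: str | Path) -> Interactome:
    """Read the canonical edge TSV written by :func:`write_edges`."""
    edges: dict[tuple[str, str], int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{i}: expected 3 fields, got {len(parts)}")
            a, b, s = parts
            edges[(min(a, b), max(a, b))] = int(s)
    genes = {g for pair in edges for g in pair}
    return Interactome(genes=tuple(genes), edges=edges)


def read_mapping(path: str | Path) -> dict[str, str]:
    """Read a two-column (protein id, gene id) TSV mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["protein", "gene"], dtype=str)
    return dict(zip(df["protein"], df["gene"]))
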