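"""Genomic context of network genes: cytobands, linkage windows, HAR overlap.

Band enrichment asks whether network genes cluster in particular cytogenetic
bands (one hypergeometric test per band, BH-corrected). Linkage neighbors are
genes whose genomic spans lie within a window of a network gene on the same
chromosome, with genetic distance approximated by the uniform conversion
1 cM ~ 1 Mb. HAR overlap intersects network genes with a list of genes under
human-accelerated-region control.

Note on the window: the source analyses state both "50,000 bp up/downstream"
and "within 0.5 cM" (= 500,000 bp under the 1 cM ~ 1 Mb rule); the two are
inconsistent, so the window is an explicit parameter defaulting to 500,000 bp.
Loci coordinates are 1-based inclusive; BED converters are provided.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from socionet.enrichment import bh_adjust, hypergeom_pvalue

logger = logging.getLogger(__name__)

BP_PER_CM = 1_000_000  # 1 cM ~ 1 Mb uniform conversion

LOCI_COLUMNS = ["gene", "chrom", "start", "end", "band"]


def read_loci(path: str | Path) -> pd.DataFrame:
    """Read a loci TSV (gene, chrom, start, end, band), 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str, "band": str})
    missing = set(LOCI_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if (df["start"] > df["end"]).any():
        raise ValueError(f"{path}: start > end for some loci")
    return df[LOCI_COLUMNS]


def write_loci(loci: pd.DataFrame, path: str | Path) -> None:
    loci[LOCI_COLUMNS].to_csv(path, sep="\t", index=False)


def loci_to_bed(loci: pd.DataFrame) -> pd.DataFrame:
    """1-based inclusive loci -> BED4+band (0-based, half-open)."""
    return pd.DataFrame(
        {
            "chrom": loci["chrom"],
            "start": loci["start"] - 1,
            "end": loci["end"],
            "name": loci["gene"],
            "band": loci["band"],
        }
    )


def bed_to_loci(bed: pd.DataFrame) -> pd.DataFrame:
    """BED4+band (0-based, half-open) -> 1-based inclusive loci."""
    return pd.DataFrame(
        {
            "gene": bed["name"],
            "chrom": bed["chrom"],
            "start": bed["start"] + 1,
            "end": bed["end"],
            "band": bed["band"],
        }
    )


def band_enrichment(
    network_genes: set[str],
    loci: pd.DataFrame,
    universe: set[str],
    fdr_max: float = 0.25,
) -> pd.DataFrame:
    """Per-band hypergeometric enrichment of network genes.

    Universe genes lacking a locus are excluded from N (count logged).
    Columns: band, k, K, n, N, p, fdr, significant, genes. Sorted by p then
    band.
    """
    annotated = loci[loci["gene"].isin(universe)]
    n_unannot = len(universe) - annotated["gene"].nunique()
    if n_unannot:
        logger.info("%d universe genes lack loci and were excluded", n_unannot)
    net = set(network_genes) & set(annotated["gene"])
    if not net:
        warnings.warn("no annotated network genes; empty enrichment table")
        return pd.DataFrame(
            columns=["band", "k", "K", "n", "N", "p", "fdr", "significant", "genes"]
        )
    N = annotated["gene"].nunique()
    n = len(net)
    rows = []
    for band, sub in annotated.groupby("band"):
        band_genes = set(sub["gene"])
        overlap = net & band_genes
        p = hypergeom_pvalue(len(overlap), len(band_genes), n, N)
        rows.append(
            {
                "band": band,
                "k": len(overlap),
                "K": len(band_genes),
                "n": n,
                "N": N,
                "p": p,
                "genes": "|".join(sorted(overlap)),
            }
        )
    df = pd.DataFrame(rows)
    df["fdr"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = df["fdr"] < fdr_max
    return df.sort_values(["p", "band"], ignore_index=True)[
        ["band", "k", "K", "n", "N", "p", "fdr", "significant", "genes"]
    ]


def _span_gap(s1: int, e1: int, s2: int, e2: int) -> int:
    """Gap in bp between two 1-based inclusive spans; 0 if they overlap."""
    return max(0, max(s1, s2) - min(e1, e2))


def linkage_neighbors(
    network_genes: Iterable[str],
    target_genes: Iterable[str],
    loci: pd.DataFrame,
    window_bp: int = 500_000,
) -> pd.DataFrame:
    """Target genes within ``window_bp`` of a network gene's span.

    A pair is emitted when the genes share a chromosome and the gap between
    their spans (0 if overlapping) is <= window_bp, boundary inclusive.
    Columns: network_gene, neighbor_gene, distance_bp, distance_cM; sorted
    by network gene then distance then neighbor.
    """
    by_gene = loci.set_index("gene")
    net = [g for g in sorted(set(network_genes)) if g in by_gene.index]
    targets = [g for g in sorted(set(target_genes)) if g in by_gene.index]
    rows = []
    for g in net:
        gl = by_gene.loc[g]
        for t in targets:
            if t == g:
                continue
            tl = by_gene.loc[t]
            if tl["chrom"] != gl["chrom"]:
                continue
            gap = _span_gap(
                int(gl["start"]), int(gl["end"]), int(tl["start"]), int(tl["end"])
            )
            if gap <= window_bp:
                rows.append(
                    {
                        "network_gene": g,
                        "neighbor_gene": t,
                        "distance_bp": gap,
                        "distance_cM": gap / BP_PER_CM,
                    }
                )
    df = pd.DataFrame(
        rows, columns=["network_gene", "neighbor_gene", "distance_bp", "distance_cM"]
    )
    if len(df):
        df = df.sort_values(
            ["network_gene", "distance_bp", "neighbor_gene"], ignore_index=True
        )
    return df


@dataclass(frozen=True)
class HarOverlap:
    """Set-algebra report of network genes under HAR control."""

    in_har: frozenset[str]
    in_har_and_disease: frozenset[str]
    in_har_not_disease: frozenset[str]

    @property
    def counts(self) -> tuple[int, int, int]:
        return (
            len(self.in_har),
            len(self.in_har_and_disease),
            len(self.in_har_not_disease),
        )


def har_overlap(
    network_genes: Iterable[str],
    har_genes: Iterable[str],
    disease_genes: Iterable[str],
) -> HarOverlap:
    """Intersect network genes with HAR-controlled and disease gene lists."""
    net = set(network_genes)
    har = set(har_genes)
    dis = set(disease_genes)
    in_har = net & har
    return HarOverlap(
        in_har=frozenset(in_har),
        in_har_and_disease=frozenset(in_har & dis),
        in_har_not_disease=frozenset(in_har - dis),
    )


def read_gene_list(path: str | Path) -> list[str]:
    """One-column gene list, blank lines and '#' comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(set(genes)):
            fh.write(f"{g}\n")
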