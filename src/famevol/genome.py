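"""Chromosome distribution, tandem-duplication clustering and
tandem/segmental classification of paralog pairs.

Tandem clusters follow the plant-family convention: genes on one chromosome
whose start-to-start distance is within a 200-kb window are chained by
single linkage, and chains of two or more genes form a cluster (so a
cluster's total span may exceed one window).
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .report import percentage
from .types import GeneModel, ParalogPair

DEFAULT_TANDEM_WINDOW = 200_000


@dataclass
class DuplicationCluster:
    chromosome: str
    members: list[str]  # gene ids ordered by start
    span: int

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("cluster needs >=2 members")


def chromosome_distribution(genes: list[GeneModel]) -> dict:
    """Per-chromosome gene counts and one-decimal percentages of placed genes."""
    placed = [g for g in genes if g.placed]
    unplaced = len(genes) - len(placed)
    counts: dict[str, int] = {}
    for g in placed:
        counts[g.chromosome] = counts.get(g.chromosome, 0) + 1
    table = pd.DataFrame(
        [
            {"chromosome": c, "count": n, "percent": percentage(n, len(placed))}
            for c, n in sorted(counts.items())
        ]
    )
    return {"table": table, "placed": len(placed), "unplaced": unplaced}


def tandem_clusters(
    genes: list[GeneModel], window: int = DEFAULT_TANDEM_WINDOW
) -> list[DuplicationCluster]:
    """Single-linkage chains of genes within ``window`` bp (start-to-start)."""
    if window < 0:
        raise ValueError("window must be nonnegative")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        if g.placed:
            by_chrom.setdefault(g.chromosome, []).append(g)
    clusters = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda g: (g.start, g.gene_id))
        chain = [ordered[0]]
        for g in ordered[1:]:
            if g.start - chain[-1].start <= window:
                chain.append(g)
            else:
                if len(chain) >= 2:
                    clusters.append(_mk_cluster(chrom, chain))
                chain = [g]
        if len(chain) >= 2:
            clusters.append(_mk_cluster(chrom, chain))
    return clusters


def _mk_cluster(chrom: str, chain: list[GeneModel]) -> DuplicationCluster:
    return DuplicationCluster(
        chromosome=chrom,
        members=[g.gene_id for g in chain],
        span=chain[-1].end - chain[0].start + 1,
    )


def clustered_gene_count(clusters: list[DuplicationCluster]) -> int:
    return sum(len(c.members) for c in clusters)


def classify_pairs(
    pairs: list[tuple[str, str]],
    genes: list[GeneModel],
    clusters: list[DuplicationCluster],
    segmental_evidence: set[tuple[str, str]] | None = None,
) -> list[ParalogPair]:
    """Assign each candidate pair exactly one duplication mode.

    "tandem" when both genes share a cluster; otherwise "segmental" when an
    external collinearity-evidence row covers the pair, or
    "segmental-candidate" under the no-evidence fallback.
    """
    known = {g.gene_id for g in genes}
    cluster_of: dict[str, int] = {}
    for k, c in enumerate(clusters):
        for gid in c.members:
            cluster_of[gid] = k
    evidence = {tuple(sorted(p)) for p in segmental_evidence or set()}
    out = []
    for a, b in pairs:
        if a == b:
            raise ValueError(f"pair of gene {a} with itself")
        for gid in (a, b):
            if gid not in known:
                raise ValueError(f"pair member {gid} missing from gene table")
        if a in cluster_of and cluster_of.get(a) == cluster_of.get(b):
            mode = "tandem"
        elif tuple(sorted((a, b))) in evidence:
            mode = "segmental"
        else:
            mode = "segmental-candidate"
        out.append(ParalogPair(gene_a=a, gene_b=b, mode=mode))
    return out


def duplication_summary(
    classified: list[ParalogPair], genes: list[GeneModel]
) -> dict:
    """Counts per mode plus the percentage of placed genes in non-tandem pairs."""
    placed = [g.gene_id for g in genes if g.placed]
    seg_genes = {
        gid
        for p in classified
        if p.mode in ("segmental", "segmental-candidate")
        for gid in (p.gene_a, p.gene_b)
        if gid in set(placed)
    }
    modes: dict[str, int] = {}
    for p in classified:
        modes[p.mode] = modes.get(p.mode, 0) + 1
    return {
        "pairs_by_mode": modes,
        "segmental_genes": len(seg_genes),
        "placed_genes": len(placed),
        "pct_segmental_genes": percentage(len(seg_genes), len(placed)) if placed else None,
    }
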