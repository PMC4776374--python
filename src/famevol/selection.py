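"""Two-population selection scan: per-SNP gene diversity (expected
heterozygosity), Fst (Weir & Cockerham 1984 theta-hat or Nei's GST),
threshold classification of loci, coding-effect annotation through gene
models, and per-gene / population summaries.

The wild-vs-cultivated contrast this supports: domestication reduces
diversity in the cultivated panel, and loci with Fst above a cutoff are
candidate artificial-selection targets.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .molevol import GENETIC_CODE
from .report import percentage
from .rounding import round_half_away
from .types import GeneModel, SelectionParams, SelectionResult, SnpLocus

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def gene_diversity(counts: dict[str, int], unbiased: bool = False) -> float:
    """Gene diversity H = 1 - sum p_i^2 from allele counts.

    ``unbiased`` applies Nei's small-sample factor n/(n-1), n the number of
    sampled allele copies.
    """
    n = sum(counts.values())
    if n < 1 or (unbiased and n < 2):
        raise ValueError("not enough sampled alleles")
    p = np.array(list(counts.values()), dtype=float) / n
    h = 1.0 - float((p**2).sum())
    return h * n / (n - 1) if unbiased else h


def _freqs(counts: dict[str, int], alleles: list[str]) -> tuple[np.ndarray, int]:
    n = sum(counts.values())
    return np.array([counts.get(a, 0) for a in alleles], float) / max(n, 1), n


def fst(
    counts_wild: dict[str, int],
    counts_cult: dict[str, int],
    estimator: str = "GST",
    het_wild: float | None = None,
    het_cult: float | None = None,
) -> float:
    """Differentiation between two populations from per-allele counts.

    GST: (Ht - Hs)/Ht with Hs the mean within-population diversity and Ht
    the diversity at the mean allele frequencies; 0 when Ht = 0.

    WC84: Weir & Cockerham's theta-hat summed over alleles.  Observed
    heterozygosity frequencies may be supplied per population; by default
    Hardy-Weinberg proportions 2p(1-p) are assumed.  Negative estimates are
    returned as-is.
    """
    n1, n2 = sum(counts_wild.values()), sum(counts_cult.values())
    if n1 < 1 or n2 < 1:
        raise ValueError("both populations need sampled alleles")
    alleles = sorted(set(counts_wild) | set(counts_cult))
    p1, _ = _freqs(counts_wild, alleles)
    p2, _ = _freqs(counts_cult, alleles)
    if estimator == "GST":
        hs = ((1 - (p1**2).sum()) + (1 - (p2**2).sum())) / 2
        pbar = (p1 + p2) / 2
        ht = 1 - float((pbar**2).sum())
        return float((ht - hs) / ht) if ht > 0 else 0.0
    if estimator != "WC84":
        raise ValueError(f"unknown estimator {estimator!r}")
    # theta-hat, two populations, allele-count formulation (r = 2)
    nd1, nd2 = n1 / 2, n2 / 2  # diploid individuals
    r = 2
    nbar = (nd1 + nd2) / r
    nc = (r * nbar - (nd1**2 + nd2**2) / (r * nbar)) / (r - 1)
    a_sum = b_sum = c_sum = 0.0
    for k, allele in enumerate(alleles):
        pb = (nd1 * p1[k] + nd2 * p2[k]) / (r * nbar)
        s2 = (nd1 * (p1[k] - pb) ** 2 + nd2 * (p2[k] - pb) ** 2) / ((r - 1) * nbar)
        if het_wild is None:
            h1 = 2 * p1[k] * (1 - p1[k])
        else:
            h1 = het_wild
        if het_cult is None:
            h2 = 2 * p2[k] * (1 - p2[k])
        else:
            h2 = het_cult
        hbar = (nd1 * h1 + nd2 * h2) / (r * nbar)
        if nbar > 1:
            a = (nbar / nc) * (
                s2 - (pb * (1 - pb) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pb * (1 - pb) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
        else:  # single diploid per population: use the asymptotic components
            a = (nbar / nc) * s2
            b = pb * (1 - pb) - (r - 1) / r * s2 - hbar / 2
        c = hbar / 2
        a_sum, b_sum, c_sum = a_sum + a, b_sum + b, c_sum + c
    denom = a_sum + b_sum + c_sum
    if denom == 0:
        return 0.0
    return min(float(a_sum / denom), 1.0)


def classify_loci(
    loci: list[SnpLocus],
    params: SelectionParams | None = None,
    effects: dict[str, str] | None = None,
) -> tuple[list[SelectionResult], dict]:
    """Classify every locus by Fst thresholds and summarise.

    Fst > fst_selected -> "selected"; Fst < fst_neutral -> "non-selected";
    the closed interval between -> "intermediate".
    """
    params = params or SelectionParams()
    effects = effects or {}
    results = []
    for loc in loci:
        h_w = gene_diversity(loc.counts_wild) if loc.counts_wild else 0.0
        h_c = gene_diversity(loc.counts_cult) if loc.counts_cult else 0.0
        f = fst(loc.counts_wild, loc.counts_cult, params.estimator)
        if f > params.fst_selected:
            cls = "selected"
        elif f < params.fst_neutral:
            cls = "non-selected"
        else:
            cls = "intermediate"
        results.append(
            SelectionResult(
                locus_id=loc.locus_id, gene_id=loc.gene_id,
                h_wild=h_w, h_cult=h_c, fst=f, cls=cls,
                effect=effects.get(loc.locus_id, loc.context if loc.context != "exon" else "outside"),
            )
        )
    n = len(results)
    by_class = {c: sum(r.cls == c for r in results) for c in ("selected", "intermediate", "non-selected")}
    selected = [r for r in results if r.cls == "selected"]
    per_gene: dict[str, int] = {}
    for r in selected:
        if r.gene_id:
            per_gene[r.gene_id] = per_gene.get(r.gene_id, 0) + 1
    summary = {
        "n_loci": n,
        "by_class": by_class,
        "pct_by_class": {c: percentage(k, n) for c, k in by_class.items()} if n else {},
        "selected_genes": len(per_gene),
        "selected_snps_per_gene": per_gene,
    }
    return results, summary


def annotate_effect(locus: SnpLocus, gene: GeneModel, cds_seq: str) -> str:
    """Coding effect of a single-nucleotide substitution.

    Maps the genomic position through the gene's CDS spans (respecting
    strand), substitutes the alternate allele into its codon and compares
    translations: synonymous / nonsynonymous; positions in introns are
    "intronic" and genic positions outside the CDS are "outside".
    """
    if len(locus.ref) != 1 or len(locus.alt) != 1:
        raise ValueError("only single-nucleotide alleles supported")
    pos = locus.position
    if not (gene.start <= pos <= gene.end):
        raise ValueError(f"position {pos} outside gene {gene.gene_id}")
    offset = None
    running = 0
    for a, b in gene.cds:
        if a <= pos <= b:
            offset = running + (pos - a)
            break
        running += b - a + 1
    if offset is None:
        in_exon = any(a <= pos <= b for a, b in gene.exons)
        return "outside" if in_exon else "intronic"
    total = gene.cds_length
    if gene.strand == "-":
        idx = total - 1 - offset
        alt = locus.alt.upper().translate(_COMPLEMENT)
        ref = locus.ref.upper().translate(_COMPLEMENT)
    else:
        idx = offset
        alt = locus.alt.upper()
        ref = locus.ref.upper()
    cds_seq = cds_seq.upper()
    if idx >= len(cds_seq):
        raise ValueError(f"CDS position {idx} beyond supplied sequence")
    if cds_seq[idx] != ref:
        raise ValueError(
            f"reference allele mismatch at {locus.locus_id}: "
            f"CDS has {cds_seq[idx]}, VCF says {ref}"
        )
    codon_start = 3 * (idx // 3)
    codon = cds_seq[codon_start : codon_start + 3]
    mutated = codon[: idx % 3] + alt + codon[idx % 3 + 1 :]
    return "synonymous" if GENETIC_CODE[mutated] == GENETIC_CODE[codon] else "nonsynonymous"


def diversity_report(results: list[SelectionResult]) -> dict:
    """Mean gene diversity per population (2 decimals) and width-0.1 histograms."""
    if not results:
        raise ValueError("no loci")
    h_w = np.array([r.h_wild for r in results])
    h_c = np.array([r.h_cult for r in results])
    edges = np.linspace(0, 1, 11)
    return {
        "mean_wild": round_half_away(float(h_w.mean()), 2),
        "mean_cult": round_half_away(float(h_c.mean()), 2),
        "hist_wild": np.histogram(h_w, bins=edges)[0].tolist(),
        "hist_cult": np.histogram(h_c, bins=edges)[0].tolist(),
        "bin_edges": edges.tolist(),
    }
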