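"""Family membership by domain criteria.

A candidate joins the roster iff its annotation table carries at least one
LRR domain and at least one kinase domain — the decisive criterion.  An
optional similarity prescreen (Smith-Waterman against reference family
proteins with a Karlin-Altschul E-value) mirrors the BLAST step such
surveys run before domain annotation, and a position-weight-matrix scanner
for the ~24-residue plant LRR repeat covers annotation-free inputs.
"""
from __future__ import annotations

import logging
import math
from collections import Counter

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .report import percentage
from .types import DomainAnnotation, FamilyMember, GeneModel

logger = logging.getLogger(__name__)

# Gapped Karlin-Altschul parameters for BLOSUM62 with gap open 11 / extend 1
KA_LAMBDA = 0.267
KA_K = 0.041


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def evalue(score: float, m: int, n: int) -> float:
    """Karlin-Altschul expect value for a local-alignment score."""
    return KA_K * m * n * math.exp(-KA_LAMBDA * score)


def prescreen_by_similarity(
    candidates: dict[str, str],
    queries: dict[str, str],
    evalue_threshold: float = 1e-6,
) -> dict[str, str]:
    """Keep candidates whose best local alignment against any query scores
    an E-value below the threshold; candidate order is preserved."""
    if evalue_threshold <= 0:
        raise ValueError("E-value threshold must be positive")
    if not queries:
        raise ValueError("query set is empty")
    if not candidates:
        raise ValueError("candidate set is empty")
    aligner = _local_aligner()
    kept = {}
    for cid, cseq in candidates.items():
        best = math.inf
        for qseq in queries.values():
            score = aligner.score(cseq, qseq)
            best = min(best, evalue(score, len(cseq), len(qseq)))
            if best < evalue_threshold:
                break
        if best < evalue_threshold:
            kept[cid] = cseq
    return kept


def filter_by_domains(
    candidates: dict[str, str],
    annotations: list[DomainAnnotation],
    collapse_identical_sequences: bool = True,
) -> list[FamilyMember]:
    """Apply the membership criterion: >=1 LRR and >=1 kinase annotation.

    Redundant entries (same gene id, or identical protein sequence when
    ``collapse_identical_sequences``) collapse to the lexicographically
    smallest id.  Annotation rows outside the protein raise, naming the row.
    """
    for ann in annotations:
        if ann.gene_id not in candidates:
            raise ValueError(f"annotation refers to unknown candidate {ann.gene_id}")
        plen = len(candidates[ann.gene_id])
        if ann.end > plen:
            raise ValueError(
                f"annotation {ann.gene_id}:{ann.domain_type}:{ann.start}-{ann.end} "
                f"exceeds protein length {plen}"
            )
    keep_ids = set(candidates)
    if collapse_identical_sequences:
        by_seq: dict[str, str] = {}
        for gid in sorted(candidates):
            seq = candidates[gid]
            if seq in by_seq:
                keep_ids.discard(gid)
            else:
                by_seq[seq] = gid
    counts: dict[str, Counter] = {}
    flags: dict[str, bool] = {}
    for ann in annotations:
        counts.setdefault(ann.gene_id, Counter())[ann.domain_type] += 1
        if ann.domain_type == "signal_peptide":
            flags[ann.gene_id] = True
    roster = []
    for gid in candidates:
        if gid not in keep_ids:
            continue
        c = counts.get(gid, Counter())
        if c["LRR"] >= 1 and c["kinase"] >= 1:
            roster.append(
                FamilyMember(
                    gene_id=gid,
                    protein_length=len(candidates[gid]),
                    n_lrr=c["LRR"],
                    n_kinase=c["kinase"],
                    n_tm=c["TM"],
                    has_signal_peptide=flags.get(gid, False),
                )
            )
    return roster


# -------------------------------------------------------------- LRR profile
#
# 24-column position-weight matrix for the plant extracellular LRR repeat
# LxxLxxLxLxxNxLxGxIPxxLxx: the bracketed residues are strongly conserved,
# 'x' columns are background.  Log-odds: conserved residue at p=0.6 vs a
# uniform 1/20 background; other residues at conserved columns share the
# remaining mass.

LRR_CONSENSUS_PATTERN = "LxxLxxLxLxxNxLxGxIPxxLxx"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_P_CONSERVED = 0.6
_BG = 1 / 20


def lrr_pwm() -> np.ndarray:
    """(24, 20) log-odds matrix over :data:`AMINO_ACIDS`."""
    pwm = np.zeros((len(LRR_CONSENSUS_PATTERN), len(AMINO_ACIDS)))
    for i, c in enumerate(LRR_CONSENSUS_PATTERN):
        if c == "x":
            continue
        other = (1 - _P_CONSERVED) / (len(AMINO_ACIDS) - 1)
        pwm[i, :] = math.log(other / _BG)
        pwm[i, AMINO_ACIDS.index(c)] = math.log(_P_CONSERVED / _BG)
    return pwm


def lrr_max_score() -> float:
    return float(lrr_pwm().max(axis=1).sum())


def lrr_most_probable_sequence() -> str:
    """Argmax residue per column; background columns break ties to 'A'."""
    pwm = lrr_pwm()
    return "".join(AMINO_ACIDS[int(i)] for i in pwm.argmax(axis=1))


def scan_lrr_motif(
    protein: str, pssm_threshold: float | None = None
) -> list[tuple[int, int, float]]:
    """Slide the LRR profile and return non-overlapping hits.

    Windows scoring >= threshold (default 60% of the maximum attainable
    score) are selected greedily by descending score (ties: leftmost) and
    returned as 1-based inclusive (start, end, score) sorted by start.
    """
    if not protein:
        raise ValueError("empty protein")
    pwm = lrr_pwm()
    w = pwm.shape[0]
    if pssm_threshold is None:
        pssm_threshold = 0.6 * lrr_max_score()
    idx = np.array([AMINO_ACIDS.find(a) for a in protein.upper()])
    scores = []
    for s in range(len(protein) - w + 1):
        window = idx[s : s + w]
        ok = window >= 0
        score = float(pwm[np.arange(w)[ok], window[ok]].sum())
        if score >= pssm_threshold:
            scores.append((s, score))
    chosen: list[tuple[int, int, float]] = []
    for s, score in sorted(scores, key=lambda t: (-t[1], t[0])):
        if all(s + w <= a - 1 or s > b - 1 for a, b, _ in chosen):
            chosen.append((s + 1, s + w, score))
    return sorted(chosen)


def summarize_family(
    roster: list[FamilyMember],
    gene_models: list[GeneModel] | None = None,
    subgroup_of: dict[str, str] | None = None,
) -> dict:
    """Per-subgroup member counts, protein-length range and signal-peptide
    percentage, plus the family-wide intron-count histogram."""
    if not roster:
        raise ValueError("empty roster")
    subgroup_of = subgroup_of or {}
    models = {g.gene_id: g for g in gene_models or []}
    rows = []
    for sub in sorted({subgroup_of.get(m.gene_id, m.subgroup or "unassigned") for m in roster}):
        members = [
            m for m in roster
            if subgroup_of.get(m.gene_id, m.subgroup or "unassigned") == sub
        ]
        with_sp = sum(m.has_signal_peptide for m in members)
        rows.append(
            {
                "subgroup": sub,
                "n_genes": len(members),
                "min_length": min(m.protein_length for m in members),
                "max_length": max(m.protein_length for m in members),
                "pct_signal_peptide": percentage(with_sp, len(members)),
            }
        )
    intron_hist: Counter = Counter()
    unplaced = 0
    for m in roster:
        model = models.get(m.gene_id)
        if model is None or not model.exons:
            unplaced += 1
            logger.warning("no gene model for %s; counted as unplaced", m.gene_id)
            continue
        intron_hist[model.n_introns] += 1
    return {
        "subgroups": pd.DataFrame(rows),
        "intron_histogram": dict(sorted(intron_hist.items())),
        "unplaced": unplaced,
        "n_members": len(roster),
    }
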