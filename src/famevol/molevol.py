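"""Pairwise Ka/Ks by the Nei-Gojobori (1986) counting method, with
Jukes-Cantor correction, molecular-clock dating of duplications, Ks
distribution binning and selective-regime categorisation.

Sites
-----
For each codon position the synonymous fraction is the share of the three
possible single-nucleotide changes that preserve the encoded amino acid;
changes producing a stop codon count as nonsynonymous.  A codon pair
contributes the average of the two codons' site counts, so S + N equals
three times the number of compared codons.

Differences
-----------
Codon pairs differing at several positions are resolved by averaging the
synonymous/nonsynonymous step counts over all orderings of the single
changes; orderings that pass through a stop codon are excluded (if every
ordering does, all are kept — this cannot arise for one or two differences
between sense codons of the standard code).

Distances
---------
pS = Sd/S and pN = Nd/N are Jukes-Cantor corrected,
Ks = -(3/4) ln(1 - (4/3) pS), and the duplication age follows the
synonymous clock T = Ks / (2 lambda).
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np

from .rounding import round_half_away
from .types import EvolParams, ParalogPair

BASES = "TCAG"

# standard genetic code, codon -> amino acid, '*' for stop
GENETIC_CODE = {
    t + c + a: aa
    for (t, c, a), aa in zip(
        ((b1, b2, b3) for b1 in BASES for b2 in BASES for b3 in BASES),
        "FFLLSSSSYY**CC*W"
        "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG",
    )
}
SENSE_CODONS = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")


def is_stop(codon: str) -> bool:
    return GENETIC_CODE[codon] == "*"


def translate_cds(cds: str) -> str:
    """Translate an ungapped CDS; raises on internal stop or ragged length."""
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    aas = []
    for i in range(0, len(cds), 3):
        aa = GENETIC_CODE[cds[i : i + 3].upper().replace("U", "T")]
        if aa == "*":
            if i == len(cds) - 3:
                break  # trailing stop tolerated
            raise ValueError(f"internal stop codon at codon {i // 3 + 1}")
        aas.append(aa)
    return "".join(aas)


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon."""
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if GENETIC_CODE[alt] == aa:  # stop != aa, hence nonsynonymous
                s += 1 / 3
    return s, 3.0 - s


@lru_cache(maxsize=None)
def pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences for one codon pair.

    Averages over orderings of the differing positions, skipping orderings
    whose intermediate codons are stops; falls back to all orderings when
    none survive.
    """
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diffs:
        return 0.0, 0.0
    surviving: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in permutations(diffs):
        cur = codon_a
        sd = nd = 0
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if is_stop(nxt) and nxt != codon_b:
                hit_stop = True
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt] and not is_stop(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if hit_stop else surviving).append((sd, nd))
    use = surviving or blocked
    return (
        float(np.mean([u[0] for u in use])),
        float(np.mean([u[1] for u in use])),
    )


@dataclass
class CodonAlignment:
    """Two aligned CDS rows of equal length divisible by 3.

    Codons containing a gap in either row are excluded from counting; the
    ungapped rows must translate without internal stop.
    """

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned rows differ in length")
        if len(self.seq_a) % 3:
            raise ValueError("alignment length not divisible by 3")
        for seq in (self.seq_a, self.seq_b):
            translate_cds(seq.replace("-", ""))  # raises on internal stop

    def comparable_codons(self) -> list[tuple[str, str]]:
        out = []
        for i in range(0, len(self.seq_a), 3):
            ca, cb = self.seq_a[i : i + 3], self.seq_b[i : i + 3]
            if "-" in ca or "-" in cb:
                continue
            out.append((ca.upper(), cb.upper()))
        return out


def backtranslate_align(
    prot_a: str, prot_b: str, cds_a: str, cds_b: str
) -> CodonAlignment:
    """Expand a pairwise protein alignment to codons (gaps become triple gaps)."""
    rows = []
    for prot, cds in ((prot_a, cds_a), (prot_b, cds_b)):
        ungapped = prot.replace("-", "")
        trans = translate_cds(cds)
        if trans != ungapped:
            for i, (x, y) in enumerate(zip(trans, ungapped)):
                if x != y:
                    raise ValueError(
                        f"CDS translation mismatch at codon {i + 1}: {x} vs {y}"
                    )
            raise ValueError(
                f"CDS/protein length mismatch: {len(trans)} vs {len(ungapped)} residues"
            )
        out, k = [], 0
        for aa in prot:
            if aa == "-":
                out.append("---")
            else:
                out.append(cds[3 * k : 3 * k + 3])
                k += 1
        rows.append("".join(out))
    return CodonAlignment(rows[0], rows[1])


def nei_gojobori(ca: CodonAlignment) -> ParalogPair:
    """Nei-Gojobori counts and Jukes-Cantor distances for one aligned pair.

    Returns a :class:`ParalogPair` (gene ids unset) carrying S, N, Sd, Nd,
    pS, pN, Ks, Ka and omega; ``saturated`` is set (and Ks/Ka left None)
    when a proportion reaches the 3/4 correction bound.
    """
    codons = ca.comparable_codons()
    if not codons:
        raise ValueError("no comparable codons in alignment")
    s_sites = n_sites = sd = nd = 0.0
    for c_a, c_b in codons:
        sa, na = codon_sites(c_a)
        sb, nb = codon_sites(c_b)
        s_sites += (sa + sb) / 2
        n_sites += (na + nb) / 2
        d_s, d_n = pathway_counts(c_a, c_b)
        sd += d_s
        nd += d_n
    ps = sd / s_sites if s_sites else 0.0
    pn = nd / n_sites if n_sites else 0.0
    pair = ParalogPair(
        gene_a="", gene_b="", s_sites=s_sites, n_sites=n_sites,
        sd=sd, nd=nd, ps=ps, pn=pn,
    )
    if ps >= 3 / 4 or pn >= 3 / 4:
        pair.saturated = True
        return pair
    pair.ks = -0.75 * float(np.log(1 - 4 * ps / 3)) + 0.0  # avoid -0.0
    pair.ka = -0.75 * float(np.log(1 - 4 * pn / 3)) + 0.0
    pair.omega = pair.ka / pair.ks if pair.ks > 0 else None
    return pair


def date_duplication(ks: float, params: EvolParams | None = None) -> float:
    """Duplication age in million years, T = Ks/(2 lambda), to one decimal."""
    params = params or EvolParams()
    if not (ks >= 0 and np.isfinite(ks)):
        raise ValueError("Ks must be finite and nonnegative")
    return round_half_away(ks / (2 * params.lambda_rate) / 1e6, 1)


def ks_histogram(
    pairs: list[ParalogPair], params: EvolParams | None = None
) -> tuple[np.ndarray, np.ndarray, list[tuple[float, float]]]:
    """Fixed-width Ks bins and peak (local-maximum) intervals.

    Bins are [0, w), [w, 2w), ... up to ks_max; saturated or out-of-range
    pairs are excluded.  A peak bin is strictly greater than both neighbours
    (boundary bins compare to their single neighbour).
    """
    params = params or EvolParams()
    n_bins = int(round(params.ks_max / params.ks_bin_width))
    edges = np.arange(n_bins + 1) * params.ks_bin_width
    values = [p.ks for p in pairs if p.ks is not None and 0 <= p.ks < params.ks_max]
    counts, _ = np.histogram(values, bins=edges)
    peaks = []
    for i, c in enumerate(counts):
        left = counts[i - 1] if i > 0 else -1
        right = counts[i + 1] if i < n_bins - 1 else -1
        if c > left and c > right and c > 0:
            peaks.append((float(edges[i]), float(edges[i + 1])))
    return edges, counts, peaks


def categorize_omega(
    pairs: list[ParalogPair], params: EvolParams | None = None
) -> dict[str, int]:
    """Counts of pairs with omega strictly below vs at-or-above the cutoff."""
    params = params or EvolParams()
    out = {"below": 0, "above": 0, "undefined": 0}
    for p in pairs:
        if p.omega is None:
            out["undefined"] += 1
        elif p.omega < params.omega_cutoff:
            out["below"] += 1
        else:
            out["above"] += 1
    return out
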