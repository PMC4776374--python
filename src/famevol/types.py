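"""Shared domain types for the gene-family evolution pipeline.

Coordinates are 1-based inclusive throughout (GFF3 convention), both on
chromosomes and on protein sequences.
"""
from __future__ import annotations

from dataclasses import dataclass, field


DOMAIN_TYPES = frozenset({"LRR", "kinase", "TM", "signal_peptide"})


@dataclass(frozen=True)
class DomainAnnotation:
    """A typed interval on a protein (e.g. one LRR repeat, the kinase domain)."""

    gene_id: str
    domain_type: str
    start: int
    end: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.domain_type not in DOMAIN_TYPES:
            raise ValueError(f"unknown domain_type {self.domain_type!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad interval {self.start}..{self.end} on {self.gene_id}")


@dataclass
class GeneModel:
    """A gene's placement and exon/CDS structure.

    ``exons`` and ``cds`` are ordered, disjoint (start, end) spans in genomic
    coordinates; ``cds`` spans are contained in exons.  ``chromosome`` may be
    the sentinel ``"unplaced"`` for scaffold-only genes.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        for spans in (self.exons, self.cds):
            for (a, b), (c, _) in zip(spans, spans[1:]):
                if not (a <= b < c):
                    raise ValueError(f"{self.gene_id}: spans not sorted/disjoint")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return max(len(self.exons) - 1, 0)

    @property
    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.cds)

    @property
    def placed(self) -> bool:
        return self.chromosome != "unplaced"


@dataclass
class FamilyMember:
    """A gene accepted into the family roster (>=1 LRR and >=1 kinase domain)."""

    gene_id: str
    protein_length: int
    n_lrr: int
    n_kinase: int
    n_tm: int = 0
    has_signal_peptide: bool = False
    intron_count: int | None = None
    group: str | None = None
    subgroup: str | None = None

    def __post_init__(self) -> None:
        if self.n_lrr < 1 or self.n_kinase < 1:
            raise ValueError(
                f"{self.gene_id}: family members need >=1 LRR and >=1 kinase domain"
            )
        if self.protein_length <= 0:
            raise ValueError(f"{self.gene_id}: nonpositive protein length")


@dataclass
class ParalogPair:
    """Two family members related by duplication, with divergence statistics.

    ``mode`` is "tandem", "segmental" (external collinearity evidence) or
    "segmental-candidate" (non-tandem, no evidence table).  Site/difference
    counts follow Nei & Gojobori (1986); ``ks``/``ka`` carry the Jukes-Cantor
    correction; ``age_my`` = Ks / (2 lambda) in million years.
    """

    gene_a: str
    gene_b: str
    mode: str | None = None
    s_sites: float | None = None
    n_sites: float | None = None
    sd: float | None = None
    nd: float | None = None
    ps: float | None = None
    pn: float | None = None
    ks: float | None = None
    ka: float | None = None
    omega: float | None = None
    age_my: float | None = None
    saturated: bool = False


@dataclass
class SnpLocus:
    """Per-population allele counts at one genomic position.

    ``counts_wild`` / ``counts_cult`` map allele (single base) to the number
    of observed allele copies; missing genotypes simply do not contribute.
    """

    locus_id: str
    chromosome: str
    position: int
    ref: str
    alt: str
    counts_wild: dict[str, int]
    counts_cult: dict[str, int]
    gene_id: str | None = None
    context: str = "outside"  # exon | intron | outside


@dataclass
class SelectionResult:
    """Diversity, differentiation and classification for one SNP locus."""

    locus_id: str
    gene_id: str | None
    h_wild: float
    h_cult: float
    fst: float
    cls: str  # selected | intermediate | non-selected
    effect: str  # synonymous | nonsynonymous | intronic | outside


@dataclass
class EvolParams:
    """Molecular-evolution constants.

    lambda_rate is the synonymous-clock rate in substitutions per synonymous
    site per year (soybean lineage value 6.1e-9); duplication age in years is
    T = Ks / (2 lambda).  Ks histogram bins have width ``ks_bin_width``
    anchored at 0 up to ``ks_max``.
    """

    lambda_rate: float = 6.1e-9
    omega_cutoff: float = 0.3
    ks_bin_width: float = 0.06
    ks_max: float = 1.02

    def __post_init__(self) -> None:
        for name in ("lambda_rate", "omega_cutoff", "ks_bin_width", "ks_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SelectionParams:
    """Fst classification thresholds and estimator choice.

    A locus is "selected" when Fst > fst_selected (strict) and "non-selected"
    when Fst < fst_neutral (strict); the closed interval between is
    "intermediate".
    """

    fst_selected: float = 0.45
    fst_neutral: float = 0.15
    estimator: str = "WC84"

    def __post_init__(self) -> None:
        if not (0 <= self.fst_neutral < self.fst_selected <= 1):
            raise ValueError("need 0 <= fst_neutral < fst_selected <= 1")
        if self.estimator not in ("WC84", "GST"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
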