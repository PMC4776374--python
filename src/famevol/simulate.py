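"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the study design of a genome-wide receptor-kinase
family survey: a proteome in which true family members carry both LRR and
kinase domains (decoys lack one or both), gene models laid out on
chromosomes with planted tandem clusters, paralog CDS pairs diverged by
exact planted synonymous/nonsynonymous edit counts, a tissue expression
atlas with planted dominant tissues and shared/contrasting duplicate
patterns, and a two-population diploid SNP panel drawn from planted allele
frequencies.  Every generator is a pure function of (config, seed); planted
quantities are recorded as truth and are recoverable by the downstream
modules.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io
from .family import AMINO_ACIDS, lrr_most_probable_sequence
from .molevol import GENETIC_CODE, SENSE_CODONS, codon_sites, is_stop
from .types import DomainAnnotation, GeneModel

GROUPS = ["I", "II", "III", "IV", "V", "VI", "VII",
          "VIII", "IX", "X", "XI", "XII", "XIII", "XIV"]
TISSUES = ["root", "root_hair", "nodule", "leaf", "stem",
           "flower", "SAM", "pod", "seed"]

KINASE_DOMAIN_LEN = 280
FAMILY_LENGTH_RANGE = (423, 1563)  # reported family protein-length range


# ------------------------------------------------------------------ config

def default_tandem_spec() -> list[tuple[str, int, int]]:
    """33 clusters totalling 94 genes (largest 10, smallest 2), cycled over
    chromosomes, with spacings varied below the 200-kb window."""
    sizes = [10] + [5] * 4 + [3] * 8 + [2] * 20
    spec = []
    for i, size in enumerate(sizes):
        chrom = f"Chr{i % 20 + 1:02d}"
        spacing = 60_000 + 10_000 * (i % 9)
        spec.append((chrom, size, spacing))
    return spec


def _canonical_codon_pool(l_codons: int) -> list[str]:
    reps = -(-l_codons // len(SENSE_CODONS))
    return (SENSE_CODONS * reps)[:l_codons]


def default_pair_spec(n_pairs: int = 160, l_codons: int = 300) -> list[tuple[int, int, int]]:
    """Planted (Sd*, Nd*, L) triples putting Ks at the two whole-genome
    duplication peaks (~0.15 and ~0.57, i.e. ~13 and ~59 MY at the soybean
    clock) with a 116:44 split of omega below/above 0.3."""
    pool = _canonical_codon_pool(l_codons)
    s0 = sum(codon_sites(c)[0] for c in pool)
    n0 = 3 * l_codons - s0
    rng = np.random.default_rng(777)  # fixed: the default spec is a constant
    n_recent = int(round(n_pairs * 0.55))
    kinds = []
    for i in range(n_pairs):
        recent = i < n_recent
        low_omega = (i % 4) != 3  # 3:1 within each age class -> ~72.5% low
        kinds.append((recent, low_omega))
    spec = []
    for recent, low_omega in kinds:
        ks = rng.uniform(0.135, 0.165) if recent else rng.uniform(0.555, 0.585)
        omega = rng.uniform(0.05, 0.25) if low_omega else rng.uniform(0.35, 0.55)
        ps = 0.75 * (1 - np.exp(-4 * ks / 3))
        ka = omega * ks
        pn = 0.75 * (1 - np.exp(-4 * ka / 3))
        spec.append((int(round(ps * s0)), int(round(pn * n0)), l_codons))
    return spec


def default_pop_spec(n_loci: int = 2000) -> "PopSpec":
    """Allele-frequency pairs whose parametric mean diversities are 0.36
    (wild) and 0.25 (cultivated), with 2 of every 25 loci planted as strong
    frequency contrasts (candidate selected loci)."""
    h_sel_wild, h_sel_cult = 0.18, 0.095  # p = 0.9 / 0.05
    base_wild = (25 * 0.36 - 2 * h_sel_wild) / 23
    base_cult = (25 * 0.25 - 2 * h_sel_cult) / 23
    spread = np.linspace(-0.09, 0.09, 23)

    def p_of_h(h: float) -> float:
        return (1 - np.sqrt(max(1 - 2 * h, 0.0))) / 2

    freqs = []
    for i in range(n_loci):
        k = i % 25
        if k < 2:
            freqs.append((0.9, 0.05))
        else:
            j = k - 2
            freqs.append((p_of_h(base_wild + spread[j]), p_of_h(base_cult + spread[j])))
    return PopSpec(freqs=freqs)


@dataclass
class PopSpec:
    """Per-locus (p_wild, p_cult) alternate-allele frequencies and diploid
    panel sizes (the resequencing-panel analogue: 21 wild, 35 cultivated)."""

    freqs: list[tuple[float, float]] = field(default_factory=lambda: default_pop_spec().freqs)
    n_wild: int = 21
    n_cult: int = 35

    def __post_init__(self) -> None:
        if self.n_wild < 1 or self.n_cult < 1:
            raise ValueError("sample sizes must be >= 1")
        for p_w, p_c in self.freqs:
            if not (0 <= p_w <= 1 and 0 <= p_c <= 1):
                raise ValueError("allele frequencies must lie in [0, 1]")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_family: int = 467
    n_decoy: int = 150
    n_chromosomes: int = 20
    chromosome_length: int = 50_000_000
    tandem_cluster_spec: list[tuple[str, int, int]] = field(default_factory=default_tandem_spec)
    duplicate_pair_spec: list[tuple[int, int, int]] = field(default_factory=default_pair_spec)
    n_tissues: int = 9
    specificity_fraction: float = 0.6
    pair_shared_fraction: float = 0.15
    n_shared_clusters: int = 7
    pop_spec: PopSpec = field(default_factory=PopSpec)
    tandem_window: int = 200_000
    n_unplaced: int = 3
    n_groups: int = 14

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])

    @property
    def tissue_names(self) -> list[str]:
        if self.n_tissues <= len(TISSUES):
            return TISSUES[: self.n_tissues]
        return TISSUES + [f"tissue{i}" for i in range(len(TISSUES), self.n_tissues)]

    @property
    def family_ids(self) -> list[str]:
        return [f"FAM{i + 1:04d}" for i in range(self.n_family)]

    @property
    def decoy_ids(self) -> list[str]:
        return [f"DEC{i + 1:04d}" for i in range(self.n_decoy)]


# ------------------------------------------------------------------ proteome

def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(AMINO_ACIDS))[rng.integers(0, 20, length)])


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = AMINO_ACIDS[rng.integers(0, 20)]
    return "".join(out)


def generate_proteome(config: SimulationConfig):
    """Proteins + domain annotation table + truth labels.

    Family members carry >=1 LRR and exactly one kinase domain; decoys cycle
    through three classes (LRR-only, kinase-only, neither).  Kinase domains
    are noisy copies of one consensus per phylogenetic group, so they double
    as the aligned input for tree building; per-group reference proteins
    ("AT-<group>") provide prescreen queries and labelled reference leaves.
    """
    rng = config.rng(1)
    groups = GROUPS[: config.n_groups]
    consensus = {g: _random_protein(rng, KINASE_DOMAIN_LEN) for g in groups}
    lrr_unit = lrr_most_probable_sequence()

    proteins: dict[str, str] = {}
    kinase_domains: dict[str, str] = {}
    annotations: list[DomainAnnotation] = []
    truth: dict[str, dict] = {}

    def plant_lrrs(seq: list[str], gid: str, start: int, n_lrr: int) -> None:
        for k in range(n_lrr):
            a = start + 24 * k
            unit = _mutate(lrr_unit, 0.03, rng)
            seq[a - 1 : a + 23] = list(unit)
            annotations.append(DomainAnnotation(gid, "LRR", a, a + 23, float(rng.uniform(1e-12, 1e-8))))

    for i, gid in enumerate(config.family_ids):
        group = groups[i % len(groups)]
        length = int(rng.integers(FAMILY_LENGTH_RANGE[0], FAMILY_LENGTH_RANGE[1] + 1))
        seq = list(_random_protein(rng, length))
        has_sp = rng.random() < 0.77
        if has_sp:
            annotations.append(DomainAnnotation(gid, "signal_peptide", 1, 25, 0.9))
        n_lrr = max(1, min((length - 340) // 24, 18))
        plant_lrrs(seq, gid, 30, n_lrr)
        kin_start = length - KINASE_DOMAIN_LEN + 1
        u = rng.random()
        n_tm = 0 if u < 0.05 else (2 if u < 0.49 else 1)
        tm_end = kin_start - 5
        for t in range(n_tm):
            a = tm_end - 23 * (t + 1) + 1 - 4 * t
            annotations.append(DomainAnnotation(gid, "TM", a, a + 22, 0.8))
        kd = _mutate(consensus[group], 0.05, rng)
        seq[kin_start - 1 : length] = list(kd)
        annotations.append(DomainAnnotation(gid, "kinase", kin_start, length, float(rng.uniform(1e-30, 1e-20))))
        proteins[gid] = "".join(seq)
        kinase_domains[gid] = kd
        truth[gid] = {"family": True, "group": group, "n_lrr": n_lrr,
                      "n_tm": n_tm, "signal_peptide": bool(has_sp)}

    for i, gid in enumerate(config.decoy_ids):
        cls = ("lrr_only", "kinase_only", "neither")[i % 3]
        length = int(rng.integers(300, 801))
        seq = list(_random_protein(rng, length))
        if cls == "lrr_only":
            n_lrr = max(1, min((length - 60) // 24, 8))
            plant_lrrs(seq, gid, 20, n_lrr)
        elif cls == "kinase_only":
            group = groups[i % len(groups)]
            kd = _mutate(consensus[group], 0.05, rng)
            a = length - KINASE_DOMAIN_LEN + 1
            if a < 1:
                seq = list(_random_protein(rng, KINASE_DOMAIN_LEN + 20))
                a = len(seq) - KINASE_DOMAIN_LEN + 1
            seq[a - 1 : a - 1 + KINASE_DOMAIN_LEN] = list(kd)
            annotations.append(DomainAnnotation(gid, "kinase", a, a + KINASE_DOMAIN_LEN - 1, 1e-25))
        proteins[gid] = "".join(seq)
        truth[gid] = {"family": False, "class": cls}

    references = {f"AT-{g}": _mutate(consensus[g], 0.05, rng) for g in groups}
    ref_groups = {name: name.split("-", 1)[1] for name in references}
    return {
        "proteins": proteins,
        "annotations": annotations,
        "kinase_domains": kinase_domains,
        "references": references,
        "ref_groups": ref_groups,
        "truth": truth,
    }


# ------------------------------------------------------------------ coordinates

def _intron_count(rng: np.random.Generator) -> int:
    """Intron-count distribution echoing the family's reported structure
    (a quarter of genes intron-rich, half with a single intron)."""
    u = rng.random()
    for count, cum in ((0, 0.056), (1, 0.521), (2, 0.620), (3, 0.660), (4, 0.669), (5, 0.677)):
        if u < cum:
            return count
    return int(rng.integers(6, 16))


def generate_gene_coordinates(
    config: SimulationConfig,
    cds_lengths: dict[str, int] | None = None,
):
    """Gene models with planted tandem clusters, plus cluster truth.

    Cluster members sit at the specified start-to-start spacing; all other
    inter-gene gaps exceed the tandem window.  Infeasible placement raises,
    naming the chromosome.
    """
    rng = config.rng(2)
    fam = config.family_ids
    placed_ids = fam[: len(fam) - config.n_unplaced]
    cds_lengths = cds_lengths or {}

    cluster_members: list[list[str]] = []
    cursor = 0
    for chrom, size, spacing in config.tandem_cluster_spec:
        if spacing > config.tandem_window:
            raise ValueError(
                f"cluster spacing {spacing} exceeds tandem window {config.tandem_window}"
            )
        members = placed_ids[cursor : cursor + size]
        if len(members) < size:
            raise ValueError("not enough family genes for the requested clusters")
        cluster_members.append(members)
        cursor += size
    singles = placed_ids[cursor:]

    items: dict[str, list[tuple[list[str], int | None]]] = {
        f"Chr{i + 1:02d}": [] for i in range(config.n_chromosomes)
    }
    for (chrom, _, spacing), members in zip(config.tandem_cluster_spec, cluster_members):
        if chrom not in items:
            raise ValueError(f"cluster chromosome {chrom} not in the genome")
        items[chrom].append((members, spacing))
    for i, gid in enumerate(singles):
        chrom = f"Chr{i % config.n_chromosomes + 1:02d}"
        items[chrom].append(([gid], None))

    genes: list[GeneModel] = []
    for chrom in sorted(items):
        pos = int(rng.integers(100_000, 300_000))
        for members, spacing in items[chrom]:
            for k, gid in enumerate(members):
                if k > 0:
                    pos += spacing
                genes.append(_build_gene(gid, chrom, pos, cds_lengths.get(gid), rng))
            pos = genes[-1].start
            pos += config.tandem_window + int(rng.integers(50_000, 400_000))
            if pos > config.chromosome_length:
                raise ValueError(
                    f"cannot place requested genes on {chrom}: "
                    f"length {config.chromosome_length} bp exceeded"
                )
    truth_clusters = [
        {"chromosome": chrom, "members": members}
        for (chrom, _, _), members in zip(config.tandem_cluster_spec, cluster_members)
    ]
    return {"genes": genes, "clusters": truth_clusters, "unplaced": fam[len(placed_ids):]}


def _build_gene(
    gid: str, chrom: str, start: int, cds_len: int | None, rng: np.random.Generator
) -> GeneModel:
    if cds_len is None:
        cds_len = 3 * int(rng.integers(*FAMILY_LENGTH_RANGE))
    n_introns = _intron_count(rng)
    n_exons = n_introns + 1
    cuts = sorted(rng.choice(np.arange(30, cds_len - 30, 3), size=n_exons - 1, replace=False)) if n_exons > 1 else []
    bounds = [0, *map(int, cuts), cds_len]
    exon_lens = [b - a for a, b in zip(bounds, bounds[1:])]
    strand = "+" if rng.random() < 0.5 else "-"
    utr5, utr3 = 30, 30
    cds_spans, exon_spans = [], []
    pos = start + utr5
    for i, ln in enumerate(exon_lens):
        a, b = pos, pos + ln - 1
        cds_spans.append((a, b))
        ea = a - utr5 if i == 0 else a
        eb = b + utr3 if i == len(exon_lens) - 1 else b
        exon_spans.append((ea, eb))
        pos = b + 1 + int(rng.integers(200, 2001))
    return GeneModel(
        gene_id=gid, chromosome=chrom, start=start,
        end=exon_spans[-1][1], strand=strand, exons=exon_spans, cds=cds_spans,
    )


# ------------------------------------------------------------------ CDS pairs

def _random_cds(rng: np.random.Generator, l_codons: int) -> str:
    pool = np.array(_canonical_codon_pool(l_codons))
    rng.shuffle(pool)
    return "".join(pool)


def _single_nt_variants(codon: str):
    for pos in range(3):
        for b in "TCAG":
            if b != codon[pos]:
                yield pos, codon[:pos] + b + codon[pos + 1 :]


def _plant_edits(cds: str, sd: int, nd: int, rng: np.random.Generator) -> str:
    """Apply exactly sd synonymous and nd nonsynonymous single-nucleotide
    edits, each in a distinct previously unedited codon, never creating a
    stop; bounded rejection (100 retries per edit)."""
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    free = set(range(len(codons)))
    for n_edits, synonymous in ((sd, True), (nd, False)):
        for _ in range(n_edits):
            for attempt in range(100):
                ci = int(rng.choice(sorted(free)))
                aa = GENETIC_CODE[codons[ci]]
                options = [
                    v for _, v in _single_nt_variants(codons[ci])
                    if not is_stop(v) and (GENETIC_CODE[v] == aa) == synonymous
                ]
                if options:
                    codons[ci] = options[int(rng.integers(len(options)))]
                    free.discard(ci)
                    break
            else:
                kind = "synonymous" if synonymous else "nonsynonymous"
                raise RuntimeError(f"could not place a {kind} edit after 100 retries")
    return "".join(codons)


def generate_duplicate_pairs(config: SimulationConfig, pair_genes: list[tuple[str, str]] | None = None):
    """Paired CDS diverged by the planted (Sd*, Nd*) of each spec entry."""
    rng = config.rng(3)
    spec = config.duplicate_pair_spec
    if pair_genes is None:
        pair_genes = [(f"PAIR{k + 1:03d}a", f"PAIR{k + 1:03d}b") for k in range(len(spec))]
    cds: dict[str, str] = {}
    truth = []
    for (sd, nd, l_codons), (ga, gb) in zip(spec, pair_genes):
        if l_codons < 30:
            raise ValueError("pair CDS must be at least 30 codons")
        if sd + nd > l_codons:
            raise ValueError("more edits than codons")
        ancestral = _random_cds(rng, l_codons)
        cds[ga] = ancestral
        cds[gb] = _plant_edits(ancestral, sd, nd, rng)
        truth.append({"gene_a": ga, "gene_b": gb, "sd": sd, "nd": nd, "l_codons": l_codons})
    return {"cds": cds, "truth": truth}


# ------------------------------------------------------------------ expression

def generate_expression(
    config: SimulationConfig,
    gene_ids: list[str] | None = None,
    pairs: list[tuple[str, str]] | None = None,
    shared_pairs: set[int] | None = None,
):
    """Expression matrix with planted dominant tissues.

    A ``specificity_fraction`` of genes get one tissue drawn at >=8x the
    background mean (the margin guarantees the dominant value is the row
    maximum); other rows are near-uniform noise.  Pairs listed in
    ``shared_pairs`` (by index) share their pattern up to a scale factor;
    remaining pairs are forced to contrast.
    """
    import pandas as pd

    if config.n_tissues < 2:
        raise ValueError("need at least two tissues")
    rng = config.rng(4)
    gene_ids = gene_ids if gene_ids is not None else config.family_ids
    tissues = config.tissue_names
    n = len(gene_ids)
    order = rng.permutation(n)
    n_specific = int(round(config.specificity_fraction * n))
    specific_tissue: dict[str, str | None] = {}
    values = np.empty((n, len(tissues)))
    for rank, gi in enumerate(order):
        gid = gene_ids[gi]
        row = rng.uniform(4.0, 6.0, len(tissues))
        if rank < n_specific:
            t = int(rng.integers(len(tissues)))
            row[t] = rng.uniform(40, 60)
            specific_tissue[gid] = tissues[t]
        else:
            specific_tissue[gid] = None
        values[gi] = row
    m = pd.DataFrame(values, index=gene_ids, columns=tissues)

    pair_truth = []
    for k, (ga, gb) in enumerate(pairs or []):
        if ga not in m.index or gb not in m.index:
            continue
        if shared_pairs is not None and k in shared_pairs:
            scale = rng.uniform(0.8, 1.2)
            noise = rng.normal(1.0, 0.02, len(tissues))
            m.loc[gb] = np.maximum(m.loc[ga].to_numpy() * scale * noise, 0.0)
            specific_tissue[gb] = specific_tissue[ga]
            pair_truth.append({"gene_a": ga, "gene_b": gb, "pattern": "shared"})
        else:
            ta, tb = specific_tissue[ga], specific_tissue[gb]
            # contrasting patterns must be separable: give gb a dominant
            # tissue distinct from ga's when the draw left them ambiguous
            if tb is None or ta == tb:
                banned = {ta} if ta is not None else set()
                choices = [t for t in tissues if t not in banned]
                alt = choices[int(rng.integers(len(choices)))]
                row = rng.uniform(4.0, 6.0, len(tissues))
                row[tissues.index(alt)] = rng.uniform(40, 60)
                m.loc[gb] = row
                specific_tissue[gb] = alt
            pair_truth.append({"gene_a": ga, "gene_b": gb, "pattern": "contrast"})
    return {"matrix": m, "specific_tissue": specific_tissue, "pair_truth": pair_truth}


def generate_qpcr(config: SimulationConfig, expression, n_genes: int = 6):
    """Ct table consistent with the expression atlas (reference gene flat at
    Ct 15, target Ct = 28 - log2(abundance), first tissue is calibrator)."""
    import pandas as pd

    m = expression["matrix"]
    genes = list(m.index[:n_genes])
    tissues = list(m.columns[:4])
    rows = []
    for gid in genes:
        for t in tissues:
            rows.append({
                "gene": gid, "sample": t,
                "target_ct": 28.0 - float(np.log2(m.loc[gid, t])),
                "reference_ct": 15.0,
                "is_calibrator": int(t == tissues[0]),
            })
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ populations

_ALT_OF = {"A": "G", "C": "T", "G": "A", "T": "C"}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def generate_populations(
    config: SimulationConfig,
    genes: list[GeneModel] | None = None,
    cds: dict[str, str] | None = None,
):
    """Two-population diploid genotypes at loci inside gene models.

    Genotypes are drawn binomially from the planted (p_wild, p_cult)
    alternate-allele frequencies; each locus lands in an exon (with the
    reference allele read off the gene's CDS) or an intron, and the genic
    context is recorded as truth.
    """
    rng = config.rng(5)
    if genes is None:
        coords = generate_gene_coordinates(config)
        genes = coords["genes"]
    cds = cds or {}
    spec = config.pop_spec
    samples_w = [f"W{i + 1:03d}" for i in range(spec.n_wild)]
    samples_c = [f"C{i + 1:03d}" for i in range(spec.n_cult)]
    popmap = {**{s: "wild" for s in samples_w}, **{s: "cultivated" for s in samples_c}}
    genic = [g for g in genes if g.placed and g.cds]
    loci, truth = [], []
    for i, (p_w, p_c) in enumerate(spec.freqs):
        gene = genic[i % len(genic)]
        want_intron = (i % 3 == 0) and gene.n_introns > 0
        if want_intron:
            a, b = gene.exons[0][1] + 1, gene.exons[1][0] - 1
            pos = int(rng.integers(a, b + 1))
            ref, context = "A", "intron"
        else:
            span_i = int(rng.integers(len(gene.cds)))
            a, b = gene.cds[span_i]
            pos = int(rng.integers(a, b + 1))
            offset = sum(e - s + 1 for s, e in gene.cds[:span_i]) + (pos - a)
            idx = gene.cds_length - 1 - offset if gene.strand == "-" else offset
            seq = cds.get(gene.gene_id)
            base = seq[idx] if seq and idx < len(seq) else "A"
            ref = base.translate(_COMPLEMENT) if gene.strand == "-" else base
            context = "exon"
        alt = _ALT_OF[ref] if rng.random() < 0.5 else sorted(set("ACGT") - {ref})[int(rng.integers(3))]
        g_w = rng.binomial(2, p_w, spec.n_wild)
        g_c = rng.binomial(2, p_c, spec.n_cult)
        gts = [(int(g > 0), int(g > 1)) for g in np.concatenate([g_w, g_c])]
        loci.append({
            "chrom": gene.chromosome, "pos": pos, "id": f"SNP{i + 1:05d}",
            "ref": ref, "alt": alt, "genotypes": gts,
        })
        truth.append({
            "locus_id": f"SNP{i + 1:05d}", "gene_id": gene.gene_id,
            "context": context, "p_wild": float(p_w), "p_cult": float(p_c),
        })
    return {"loci": loci, "samples": samples_w + samples_c, "popmap": popmap, "truth": truth}


# ------------------------------------------------------------------ bundle

def generate_all(config: SimulationConfig, outdir: str | Path) -> dict:
    """Write the full synthetic input bundle and its truth file.

    Files: proteins.fasta, domains.tsv, queries.fasta, kinase_domains.fasta,
    ref_groups.tsv, genes.gff3, cds.fasta, pairs.tsv, expression.tsv,
    qpcr.tsv, genotypes.vcf, popmap.tsv, truth.json.
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    prot = generate_proteome(config)

    # pair membership: tandem pairs inside planted clusters, then segmental
    spec = config.duplicate_pair_spec
    coords_probe = generate_gene_coordinates(config)
    clusters = coords_probe["clusters"]
    tandem_pairs: list[tuple[str, str]] = []
    tandem_cluster_of: dict[int, int] = {}
    for ci, cl in enumerate(clusters):
        mem = cl["members"]
        for k in range(0, len(mem) - 1, 2):
            if len(tandem_pairs) < len(spec):
                tandem_cluster_of[len(tandem_pairs)] = ci
                tandem_pairs.append((mem[k], mem[k + 1]))
    cluster_gene_total = sum(len(c["members"]) for c in clusters)
    pool = [g for g in config.family_ids[cluster_gene_total:]
            if g not in set(coords_probe["unplaced"])]
    seg_needed = len(spec) - len(tandem_pairs)
    if 2 * seg_needed > len(pool):
        raise ValueError("not enough non-cluster genes for the requested pairs")
    segmental_pairs = [(pool[2 * k], pool[2 * k + 1]) for k in range(seg_needed)]
    pair_genes = tandem_pairs + segmental_pairs

    dup = generate_duplicate_pairs(config, pair_genes)

    # coordinates with pair genes given their pair CDS lengths
    cds_lengths = {gid: len(seq) for gid, seq in dup["cds"].items()}
    for gid, meta in prot["truth"].items():
        if meta.get("family") and gid not in cds_lengths:
            cds_lengths[gid] = 3 * len(prot["proteins"][gid])
    coords = generate_gene_coordinates(config, cds_lengths=cds_lengths)
    genes = coords["genes"]

    # per-gene CDS: pair members from the duplication process, rest random
    rng_cds = config.rng(6)
    cds = dict(dup["cds"])
    for g in genes:
        if g.gene_id not in cds:
            cds[g.gene_id] = _random_cds(rng_cds, g.cds_length // 3)

    # expression: coherent clusters share one pattern along a chain of
    # consecutive-member links; a fraction of segmental pairs also share
    shared_clusters = set(range(min(config.n_shared_clusters, len(clusters))))
    shared = {k for k, ci in tandem_cluster_of.items() if ci in shared_clusters}
    n_seg_shared = int(round(config.pair_shared_fraction * len(segmental_pairs)))
    shared |= {len(tandem_pairs) + j for j in range(n_seg_shared)}
    expr_pairs = list(pair_genes)
    for ci in sorted(shared_clusters):
        mem = clusters[ci]["members"]
        for a, b in zip(mem, mem[1:]):
            shared.add(len(expr_pairs))
            expr_pairs.append((a, b))
    expr = generate_expression(config, config.family_ids, expr_pairs, shared)
    qpcr = generate_qpcr(config, expr)

    pops = generate_populations(config, genes, cds)

    # ---- write everything
    io.write_fasta(prot["proteins"], outdir / "proteins.fasta")
    io.write_domains(prot["annotations"], outdir / "domains.tsv")
    io.write_fasta(prot["references"], outdir / "queries.fasta")
    io.write_fasta({**prot["kinase_domains"], **prot["references"]},
                   outdir / "kinase_domains.fasta")
    pd.DataFrame(sorted(prot["ref_groups"].items()), columns=["leaf", "group"]).to_csv(
        outdir / "ref_groups.tsv", sep="\t", index=False)
    io.write_gff3(genes, outdir / "genes.gff3")
    io.write_fasta(cds, outdir / "cds.fasta")
    pd.DataFrame(
        [(a, b, "" if k < len(tandem_pairs) else "collinear")
         for k, (a, b) in enumerate(pair_genes)],
        columns=["gene_a", "gene_b", "evidence"],
    ).to_csv(outdir / "pairs.tsv", sep="\t", index=False)
    io.write_expression(expr["matrix"], outdir / "expression.tsv")
    qpcr.to_csv(outdir / "qpcr.tsv", sep="\t", index=False)
    io.write_vcf(pops["loci"], pops["samples"], outdir / "genotypes.vcf")
    io.write_popmap(pops["popmap"], outdir / "popmap.tsv")

    truth = {
        "genes": prot["truth"],
        "clusters": coords["clusters"],
        "unplaced": coords["unplaced"],
        "pairs": [
            {**t, "mode": "tandem" if k < len(tandem_pairs) else "segmental",
             "expression": "shared" if k in shared else "contrast"}
            for k, t in enumerate(dup["truth"])
        ],
        "shared_clusters": sorted(shared_clusters),
        "specific_tissue": expr["specific_tissue"],
        "loci": pops["truth"],
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return truth
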