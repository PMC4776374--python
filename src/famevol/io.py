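"""Readers and writers for the standard formats the pipeline exchanges.

FASTA goes through Bio.SeqIO, GFF3 through gffutils, VCF through pysam; the
tabular sidecars (domain annotations, expression matrix, population map,
pair lists) are plain TSV handled with pandas.
"""
from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import DomainAnnotation, GeneModel, SnpLocus


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Return an id -> sequence mapping preserving file order."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------- domain TSV

DOMAIN_COLUMNS = ["gene_id", "domain_type", "start", "end", "score"]


def read_domains(path: str | Path) -> list[DomainAnnotation]:
    df = pd.read_csv(path, sep="\t")
    return [
        DomainAnnotation(r.gene_id, r.domain_type, int(r.start), int(r.end), float(r.score))
        for r in df.itertuples(index=False)
    ]


def write_domains(rows: list[DomainAnnotation], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.gene_id, r.domain_type, r.start, r.end, r.score) for r in rows],
        columns=DOMAIN_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- GFF3

def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene/exon/CDS features, 1-based inclusive, GFF3 version 3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            chrom = g.chromosome
            fh.write(
                f"{chrom}\tfamevol\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (a, b) in enumerate(g.exons, 1):
                fh.write(
                    f"{chrom}\tfamevol\texon\t{a}\t{b}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )
            for i, (a, b) in enumerate(g.cds, 1):
                fh.write(
                    f"{chrom}\tfamevol\tCDS\t{a}\t{b}\t.\t{g.strand}\t0\t"
                    f"ID={g.gene_id}.cds{i};Parent={g.gene_id}\n"
                )


def read_gff3(path: str | Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = sorted((f.start, f.end) for f in db.children(g, featuretype="exon"))
        cds = sorted((f.start, f.end) for f in db.children(g, featuretype="CDS"))
        genes.append(
            GeneModel(
                gene_id=g.id, chromosome=g.seqid, start=g.start, end=g.end,
                strand=g.strand if g.strand in "+-" else "+", exons=exons, cds=cds,
            )
        )
    return genes


# ---------------------------------------------------------------- expression

def read_expression(path: str | Path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t", index_col=0)
    if (m.values < 0).any():
        raise ValueError("expression matrix contains negative values")
    return m


def write_expression(m: pd.DataFrame, path: str | Path) -> None:
    m.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------- population map

def read_popmap(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"])
    return dict(zip(df["sample"], df["population"]))


def write_popmap(popmap: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, pop in popmap.items():
            fh.write(f"{sample}\t{pop}\n")


# ---------------------------------------------------------------- VCF

def write_vcf(
    loci: list[dict],
    samples: list[str],
    path: str | Path,
    contigs: list[str] | None = None,
) -> None:
    """Write a minimal VCF 4.2.

    Each locus dict needs: chrom, pos, id, ref, alt, genotypes — a list of
    (a1, a2) allele-index pairs aligned with ``samples``.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in contigs or sorted({l["chrom"] for l in loci}):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for l in sorted(loci, key=lambda x: (x["chrom"], x["pos"])):
            gts = "\t".join(f"{a}/{b}" for a, b in l["genotypes"])
            fh.write(
                f"{l['chrom']}\t{l['pos']}\t{l['id']}\t{l['ref']}\t{l['alt']}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf_loci(
    path: str | Path,
    popmap: dict[str, str],
    wild_label: str = "wild",
    cult_label: str = "cultivated",
) -> list[SnpLocus]:
    """Read biallelic SNP loci with per-population allele counts via pysam."""
    from pysam import VariantFile

    vf = VariantFile(os.fspath(path))
    samples = list(vf.header.samples)
    loci = []
    for rec in vf.fetch() if vf.index is not None else vf:
        alleles = (rec.ref,) + tuple(rec.alts or ())
        counts: dict[str, dict[str, int]] = {wild_label: {}, cult_label: {}}
        for s in samples:
            pop = popmap.get(s)
            if pop not in counts:
                continue
            for ai in rec.samples[s]["GT"]:
                if ai is None:
                    continue
                a = alleles[ai]
                counts[pop][a] = counts[pop].get(a, 0) + 1
        loci.append(
            SnpLocus(
                locus_id=rec.id or f"{rec.chrom}:{rec.pos}",
                chromosome=rec.chrom,
                position=rec.pos,
                ref=rec.ref,
                alt=(rec.alts or ("N",))[0],
                counts_wild=counts[wild_label],
                counts_cult=counts[cult_label],
            )
        )
    return loci
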