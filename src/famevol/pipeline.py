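"""End-to-end driver: identify -> phylo -> duplication -> kaks -> express
-> select, on a validated config, with a manifest of parameter values and
input checksums so identical configs reproduce identical reports.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import expression as expr_mod
from . import family, genome, io, molevol, phylogeny, selection
from .report import percentage
from .types import EvolParams, GeneModel, SelectionParams

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str = "famevol_out"
    # inputs (absent paths skip the stage that needs them)
    proteins: str | None = None
    domains: str | None = None
    queries: str | None = None
    kinase_alignment: str | None = None
    ref_groups: str | None = None
    gff: str | None = None
    pairs: str | None = None
    cds: str | None = None
    expression: str | None = None
    vcf: str | None = None
    popmap: str | None = None
    # stage parameters
    evalue: float = 1e-6
    tandem_window: int = 200_000
    lambda_rate: float = 6.1e-9
    ks_bin_width: float = 0.06
    ks_max: float = 1.02
    omega_cutoff: float = 0.3
    fold: float = 2.0
    floor: float = 1.0
    r_threshold: float = 0.8
    fst_selected: float = 0.45
    fst_neutral: float = 0.15
    estimator: str = "WC84"
    distance_model: str = "p-distance"
    bootstrap_reps: int = 1000
    bootstrap_leaves: int = 60
    seed: int = 0
    manifest: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def validate(self) -> None:
        for name in ("proteins", "domains", "queries", "kinase_alignment", "ref_groups",
                     "gff", "pairs", "cds", "expression", "vcf", "popmap"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config path {name} = {p} does not exist")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _log_stage(name: str, manifest: dict, **info) -> None:
    manifest["stages"][name] = info
    logger.info("stage %s: %s", name, info)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages whose inputs are present; abort on a stage failure.

    Returns the consolidated report (also written to report.json in the
    output directory together with stage TSVs and the manifest).
    """
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    params = {k: v for k, v in asdict(cfg).items() if k != "manifest"}
    manifest: dict = {"parameters": params, "inputs": {}, "stages": {}}
    for name in ("proteins", "domains", "queries", "kinase_alignment", "ref_groups",
                 "gff", "pairs", "cds", "expression", "vcf", "popmap"):
        p = getattr(cfg, name)
        if p is not None:
            manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(p)}
    report: dict = {}

    roster = None
    try:
        # ---------------- identify
        if cfg.proteins and cfg.domains:
            proteins = io.read_fasta(cfg.proteins)
            if cfg.queries:
                queries = io.read_fasta(cfg.queries)
                proteins = family.prescreen_by_similarity(proteins, queries, cfg.evalue)
            annotations = [a for a in io.read_domains(cfg.domains) if a.gene_id in proteins]
            roster = family.filter_by_domains(proteins, annotations)
            pd.DataFrame(
                [(m.gene_id, m.protein_length, m.n_lrr, m.n_kinase, m.n_tm,
                  int(m.has_signal_peptide)) for m in roster],
                columns=["gene_id", "protein_length", "n_LRR", "n_kinase", "n_TM",
                         "has_signal_peptide"],
            ).to_csv(out / "roster.tsv", sep="\t", index=False)
            report["n_family"] = len(roster)
            _log_stage("identify", manifest, n_candidates=len(proteins), n_members=len(roster))
        else:
            _log_stage("identify", manifest, skipped="missing proteins/domains")

        # ---------------- phylo
        assignments: dict[str, str] = {}
        if cfg.kinase_alignment:
            aligned = io.read_fasta(cfg.kinase_alignment)
            tree = phylogeny.neighbor_joining(
                phylogeny.kinase_distance_matrix(aligned, cfg.distance_model))
            tree.write(str(out / "tree.nwk"))
            if cfg.ref_groups:
                refs = dict(pd.read_csv(cfg.ref_groups, sep="\t").itertuples(index=False, name=None))
                assignments, monophyly = phylogeny.assign_groups(tree, refs)
                pd.DataFrame(sorted(assignments.items()), columns=["gene_id", "group"]).to_csv(
                    out / "group_assignments.tsv", sep="\t", index=False)
                report["n_groups_assigned"] = len(set(assignments.values()))
                report["monophyletic_groups"] = sum(monophyly.values())
                ref_names = list(refs)
            else:
                ref_names = []
            sub_n = min(cfg.bootstrap_leaves, len(aligned))
            queries_only = [n for n in aligned if n not in set(ref_names)]
            sub_names = (ref_names + queries_only)[:sub_n]
            sub = {n: aligned[n] for n in sub_names}
            btree = phylogeny.bootstrap_support(sub, cfg.bootstrap_reps, cfg.seed,
                                                cfg.distance_model)
            btree.write(str(out / "subtree_bootstrap.nwk"))
            supports = [n.support for n in btree.non_tips(include_self=False)
                        if getattr(n, "support", None) is not None]
            report["bootstrap_mean_support"] = (
                round(sum(supports) / len(supports), 1) if supports else None)
            _log_stage("phylo", manifest, n_leaves=len(aligned),
                       bootstrap_reps=cfg.bootstrap_reps, subtree=sub_n)
        else:
            _log_stage("phylo", manifest, skipped="missing kinase_alignment")

        # ---------------- duplication
        genes: list[GeneModel] = []
        clusters = []
        classified = []
        pair_list: list[tuple[str, str]] = []
        if cfg.gff:
            genes = io.read_gff3(cfg.gff)
            dist = genome.chromosome_distribution(genes)
            dist["table"].to_csv(out / "chromosome_distribution.tsv", sep="\t", index=False)
            clusters = genome.tandem_clusters(genes, cfg.tandem_window)
            pd.DataFrame(
                [(k, c.chromosome, ",".join(c.members), c.span)
                 for k, c in enumerate(clusters)],
                columns=["cluster", "chromosome", "members", "span"],
            ).to_csv(out / "tandem_clusters.tsv", sep="\t", index=False)
            report["n_tandem_clusters"] = len(clusters)
            report["n_tandem_genes"] = genome.clustered_gene_count(clusters)
            report["pct_tandem_genes"] = percentage(
                report["n_tandem_genes"], dist["placed"]) if dist["placed"] else None
            if dist["table"].shape[0]:
                report["chromosome_pct_range"] = [
                    float(dist["table"]["percent"].min()),
                    float(dist["table"]["percent"].max()),
                ]
            if cfg.pairs:
                pt = pd.read_csv(cfg.pairs, sep="\t")
                pair_list = list(zip(pt["gene_a"], pt["gene_b"]))
                evidence = {
                    (a, b) for a, b, e in zip(pt["gene_a"], pt["gene_b"],
                                              pt.get("evidence", [None] * len(pt)))
                    if isinstance(e, str) and e
                }
                classified = genome.classify_pairs(pair_list, genes, clusters, evidence)
                summ = genome.duplication_summary(classified, genes)
                report["pairs_by_mode"] = summ["pairs_by_mode"]
                report["pct_segmental_genes"] = summ["pct_segmental_genes"]
            _log_stage("duplication", manifest, n_genes=len(genes),
                       n_clusters=len(clusters), n_pairs=len(pair_list))
        else:
            _log_stage("duplication", manifest, skipped="missing gff")

        # ---------------- kaks
        evol = EvolParams(lambda_rate=cfg.lambda_rate, omega_cutoff=cfg.omega_cutoff,
                          ks_bin_width=cfg.ks_bin_width, ks_max=cfg.ks_max)
        kaks_pairs = []
        if cfg.cds and pair_list:
            cds = io.read_fasta(cfg.cds)
            mode_of = {(p.gene_a, p.gene_b): p.mode for p in classified}
            rows = []
            for a, b in pair_list:
                if a not in cds or b not in cds:
                    continue
                ca = molevol.CodonAlignment(cds[a], cds[b])
                pair = molevol.nei_gojobori(ca)
                pair.gene_a, pair.gene_b = a, b
                pair.mode = mode_of.get((a, b))
                if pair.ks is not None:
                    pair.age_my = molevol.date_duplication(pair.ks, evol)
                kaks_pairs.append(pair)
                rows.append({
                    "gene_a": a, "gene_b": b, "mode": pair.mode,
                    "S": pair.s_sites, "N": pair.n_sites, "Sd": pair.sd, "Nd": pair.nd,
                    "pS": pair.ps, "pN": pair.pn, "Ks": pair.ks, "Ka": pair.ka,
                    "omega": pair.omega, "age_MY": pair.age_my,
                    "saturated": int(pair.saturated),
                })
            pd.DataFrame(rows).to_csv(out / "kaks.tsv", sep="\t", index=False)
            edges, counts, peaks = molevol.ks_histogram(kaks_pairs, evol)
            pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:],
                          "count": counts}).to_csv(out / "ks_histogram.tsv", sep="\t",
                                                   index=False)
            omega_counts = molevol.categorize_omega(kaks_pairs, evol)
            ages = [p.age_my for p in kaks_pairs if p.age_my is not None]
            report["ks_peaks"] = peaks
            report["ks_peak_ages_my"] = [
                molevol.date_duplication((a + b) / 2, evol) for a, b in peaks]
            report["omega_below_cutoff"] = omega_counts["below"]
            report["omega_above_cutoff"] = omega_counts["above"]
            report["age_range_my"] = [min(ages), max(ages)] if ages else None
            _log_stage("kaks", manifest, n_pairs=len(kaks_pairs), peaks=peaks)
        else:
            _log_stage("kaks", manifest, skipped="missing cds/pairs")

        # ---------------- express
        if cfg.expression:
            matrix = io.read_expression(cfg.expression)
            prefs = expr_mod.tissue_preference(matrix, cfg.fold, cfg.floor)
            pd.DataFrame(
                [(g, ",".join(ts)) for g, ts in sorted(prefs.items())],
                columns=["gene_id", "preferential_tissues"],
            ).to_csv(out / "tissue_preference.tsv", sep="\t", index=False)
            tissue_counts = {
                t: sum(t in ts for ts in prefs.values()) for t in matrix.columns}
            report["tissue_preferential_counts"] = tissue_counts
            if pair_list:
                div = expr_mod.duplicate_expression_divergence(
                    pair_list, matrix, cfg.r_threshold)
                div.to_csv(out / "pair_expression.tsv", sep="\t", index=False)
                report["similar_pairs"] = int((div["call"] == "similar").sum())
                report["divergent_pairs"] = int((div["call"] == "divergent").sum())
            if clusters:
                ccalls = expr_mod.cluster_expression_calls(
                    [c.members for c in clusters], matrix, cfg.r_threshold)
                report["similar_tandem_clusters"] = sum(
                    v == "similar" for v in ccalls.values())
                cluster_genes = [g for c in clusters for g in c.members
                                 if g in matrix.index]
                if len(cluster_genes) >= 2:
                    norm = expr_mod.genewise_normalize(matrix.loc[cluster_genes])
                    merges, leaves = expr_mod.hierarchical_cluster(norm)
                    (out / "expression_dendrogram.nwk").write_text(
                        expr_mod.dendrogram_newick(merges, leaves) + "\n")
            _log_stage("express", manifest, n_genes=len(matrix))
        else:
            _log_stage("express", manifest, skipped="missing expression")

        # ---------------- select
        if cfg.vcf and cfg.popmap:
            popmap = io.read_popmap(cfg.popmap)
            loci = io.read_vcf_loci(cfg.vcf, popmap)
            cds_seqs = io.read_fasta(cfg.cds) if cfg.cds else {}
            by_chrom: dict[str, list[GeneModel]] = {}
            for g in genes:
                by_chrom.setdefault(g.chromosome, []).append(g)
            effects = {}
            for loc in loci:
                host = next(
                    (g for g in by_chrom.get(loc.chromosome, [])
                     if g.start <= loc.position <= g.end), None)
                if host is None:
                    loc.context = "outside"
                    continue
                loc.gene_id = host.gene_id
                seq = cds_seqs.get(host.gene_id)
                if seq:
                    effects[loc.locus_id] = selection.annotate_effect(loc, host, seq)
                loc.context = (
                    "exon" if any(a <= loc.position <= b for a, b in host.cds)
                    else "intron" if any(a <= loc.position <= b for a, b in host.exons)
                    or host.start <= loc.position <= host.end else "outside")
            sel = SelectionParams(fst_selected=cfg.fst_selected,
                                  fst_neutral=cfg.fst_neutral, estimator=cfg.estimator)
            results, summary = selection.classify_loci(loci, sel, effects)
            pd.DataFrame(
                [(r.locus_id, r.gene_id, r.h_wild, r.h_cult, r.fst, r.cls, r.effect)
                 for r in results],
                columns=["locus_id", "gene_id", "H_wild", "H_cult", "Fst",
                         "class", "effect"],
            ).to_csv(out / "selection.tsv", sep="\t", index=False)
            pd.DataFrame(
                sorted(summary["selected_snps_per_gene"].items()),
                columns=["gene_id", "n_selected_snps"],
            ).to_csv(out / "selected_genes.tsv", sep="\t", index=False)
            divrep = selection.diversity_report(results)
            report["selection"] = {
                "n_loci": summary["n_loci"],
                "by_class": summary["by_class"],
                "pct_by_class": summary["pct_by_class"],
                "selected_genes": summary["selected_genes"],
                "mean_diversity_wild": divrep["mean_wild"],
                "mean_diversity_cult": divrep["mean_cult"],
            }
            sel_results = [r for r in results if r.cls == "selected"]
            report["selection"]["selected_effects"] = {
                e: sum(r.effect == e for r in sel_results)
                for e in ("synonymous", "nonsynonymous", "intronic", "outside")
            }
            _log_stage("select", manifest, n_loci=len(loci))
        else:
            _log_stage("select", manifest, skipped="missing vcf/popmap")
    except Exception as exc:  # partial outputs are retained
        stage = list(manifest["stages"])[-1] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
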