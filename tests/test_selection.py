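"""Gene diversity, Fst estimators, threshold classification and coding
effects, each against closed forms or brute-force oracles."""
import numpy as np
import pytest
from Bio.Seq import Seq

from famevol import io
from famevol.selection import (
    annotate_effect,
    classify_loci,
    diversity_report,
    fst,
    gene_diversity,
)
from famevol.simulate import (
    PopSpec,
    SimulationConfig,
    default_pop_spec,
    generate_populations,
)
from famevol.types import GeneModel, SelectionParams, SnpLocus


class TestGeneDiversity:
    def test_monomorphic_is_zero(self):
        assert gene_diversity({"A": 10}) == 0.0

    def test_biallelic_maximum(self):
        assert gene_diversity({"A": 5, "G": 5}) == pytest.approx(0.5)

    def test_triallelic_direct_arithmetic(self):
        h = gene_diversity({"A": 40, "C": 35, "T": 25})
        assert h == pytest.approx(1 - (0.16 + 0.1225 + 0.0625))

    def test_unbiased_factor(self):
        plain = gene_diversity({"A": 5, "G": 5})
        assert gene_diversity({"A": 5, "G": 5}, unbiased=True) == pytest.approx(
            plain * 10 / 9)

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            gene_diversity({})


def wc84_textbook(p1, p2, n1, n2):
    """Independently coded Weir & Cockerham (1984) theta-hat for one
    biallelic locus (frequencies p per population, n diploids), assuming
    Hardy-Weinberg heterozygosity within populations."""
    r = 2
    nbar = (n1 + n2) / 2
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    num = den = 0.0
    for p_a1, p_a2 in ((p1, p2), (1 - p1, 1 - p2)):
        pbar = (n1 * p_a1 + n2 * p_a2) / (r * nbar)
        s2 = (n1 * (p_a1 - pbar) ** 2 + n2 * (p_a2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * 2 * p_a1 * (1 - p_a1) + n2 * 2 * p_a2 * (1 - p_a2)) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


class TestFst:
    def test_equal_frequencies(self):
        w = {"A": 500, "G": 500}
        assert fst(w, dict(w), "GST") == 0.0
        assert abs(fst(w, dict(w), "WC84")) < 0.005  # small-sample bias only

    def test_fixed_difference_is_one(self):
        assert fst({"A": 2}, {"G": 2}, "GST") == pytest.approx(1.0)
        assert fst({"A": 2}, {"G": 2}, "WC84") == pytest.approx(1.0)
        assert fst({"A": 40}, {"G": 40}, "WC84") == pytest.approx(1.0)

    def test_gst_closed_form_09_vs_01(self):
        counts_w = {"A": 900, "G": 100}
        counts_c = {"A": 100, "G": 900}
        assert fst(counts_w, counts_c, "GST") == pytest.approx((0.5 - 0.18) / 0.5)

    @pytest.mark.parametrize("p1,p2,n1,n2", [
        (0.9, 0.1, 200, 200), (0.7, 0.4, 50, 80), (0.25, 0.3, 30, 30)])
    def test_wc84_matches_independent_formula(self, p1, p2, n1, n2):
        counts_w = {"A": int(2 * n1 * p1), "G": 2 * n1 - int(2 * n1 * p1)}
        counts_c = {"A": int(2 * n2 * p2), "G": 2 * n2 - int(2 * n2 * p2)}
        q1 = counts_w["A"] / (2 * n1)
        q2 = counts_c["A"] / (2 * n2)
        assert fst(counts_w, counts_c, "WC84") == pytest.approx(
            wc84_textbook(q1, q2, n1, n2), abs=1e-12)

    def test_gst_monotone_in_frequency_contrast(self):
        vals = [fst({"A": int(1000 * p), "G": 1000 - int(1000 * p)},
                    {"A": 500, "G": 500}, "GST") for p in (0.5, 0.6, 0.7, 0.8, 0.9)]
        assert vals == sorted(vals)


class TestClassification:
    def _locus(self, counts_w, counts_c, lid="L1"):
        return SnpLocus(lid, "c1", 100, "A", "G", counts_w, counts_c)

    def test_boundaries_are_strict(self):
        params = SelectionParams(estimator="GST")
        # GST of 0.46 / exactly 0.45 constructed by direct frequency choice
        results, _ = classify_loci(
            [self._locus({"A": 980, "G": 20}, {"A": 20, "G": 980})], params)
        assert results[0].cls == "selected"
        mono, _ = classify_loci([self._locus({"A": 10}, {"A": 10})], params)
        assert mono[0].cls == "non-selected" and mono[0].fst == 0.0

    def test_threshold_inequalities_are_strict(self, monkeypatch):
        import famevol.selection as sel

        locus = self._locus({"A": 5, "G": 5}, {"A": 5, "G": 5})
        for value, expected in [(0.46, "selected"), (0.45, "intermediate"),
                                (0.15, "intermediate"), (0.149, "non-selected")]:
            monkeypatch.setattr(sel, "fst", lambda *a, **k: value)
            results, _ = sel.classify_loci([locus])
            assert results[0].cls == expected, value

    def test_printed_nonselected_share(self):
        from famevol.report import percentage

        assert percentage(5182, 7239) == 71.6

    def test_summary_partitions(self):
        rng = np.random.default_rng(2)
        loci = []
        for i in range(50):
            p = rng.uniform(0, 1)
            q = rng.uniform(0, 1)
            loci.append(self._locus(
                {"A": int(100 * p), "G": 100 - int(100 * p)},
                {"A": int(100 * q), "G": 100 - int(100 * q)}, f"L{i}"))
        results, summary = classify_loci(loci, SelectionParams(estimator="GST"))
        assert sum(summary["by_class"].values()) == len(loci) == summary["n_loci"]


def make_gene(strand="+"):
    # two CDS exons 101-130 and 231-260 with an intron between
    return GeneModel(
        gene_id="g", chromosome="c1", start=71, end=290, strand=strand,
        exons=[(71, 130), (231, 290)], cds=[(101, 130), (231, 260)],
    )


class TestEffectAnnotation:
    def test_plus_strand_synonymous_and_nonsynonymous(self):
        cds = "TTT" * 20
        gene = make_gene()
        syn = SnpLocus("s", "c1", 103, "T", "C", {}, {})  # TTT -> TTC
        non = SnpLocus("n", "c1", 101, "T", "G", {}, {})  # TTT -> GTT
        assert annotate_effect(syn, gene, cds) == "synonymous"
        assert annotate_effect(non, gene, cds) == "nonsynonymous"

    def test_intronic_and_outside(self):
        gene = make_gene()
        intron = SnpLocus("i", "c1", 180, "A", "G", {}, {})
        utr = SnpLocus("u", "c1", 80, "A", "G", {}, {})
        assert annotate_effect(intron, gene, "TTT" * 20) == "intronic"
        assert annotate_effect(utr, gene, "TTT" * 20) == "outside"

    def test_reverse_strand_complements(self):
        # '-' strand: CDS is the reverse complement of genomic CDS spans
        genomic = "AAA" * 20  # genomic plus-strand bases across CDS spans
        cds = str(Seq(genomic).reverse_complement())  # TTT...
        gene = make_gene("-")
        # genomic A->G at position 101 hits the last CDS codon's 3rd base:
        # TTT -> TTC, synonymous
        loc = SnpLocus("r", "c1", 101, "A", "G", {}, {})
        assert annotate_effect(loc, gene, cds) == "synonymous"

    def test_all_single_substitutions_match_codon_table(self):
        # 576-case oracle: every codon x every single-nucleotide change
        gene = GeneModel(gene_id="g", chromosome="c1", start=1, end=3,
                         exons=[(1, 3)], cds=[(1, 3)])
        from famevol.molevol import GENETIC_CODE

        n_checked = 0
        for codon in GENETIC_CODE:
            if GENETIC_CODE[codon] == "*":
                continue
            for pos in range(3):
                for alt in "ACGT":
                    if alt == codon[pos]:
                        continue
                    loc = SnpLocus("x", "c1", pos + 1, codon[pos], alt, {}, {})
                    got = annotate_effect(loc, gene, codon)
                    mutated = codon[:pos] + alt + codon[pos + 1 :]
                    expected = (
                        "synonymous"
                        if str(Seq(mutated).translate()) == str(Seq(codon).translate())
                        else "nonsynonymous")
                    assert got == expected
                    n_checked += 1
        assert n_checked == 61 * 9

    def test_indel_rejected(self):
        gene = make_gene()
        with pytest.raises(ValueError):
            annotate_effect(SnpLocus("d", "c1", 101, "TT", "T", {}, {}), gene, "TTT" * 20)


class TestPanelRecovery:
    def test_h_and_gst_match_brute_force_on_generator_panel(self, bundle):
        popmap = io.read_popmap(bundle["dir"] / "popmap.tsv")
        loci = io.read_vcf_loci(bundle["dir"] / "genotypes.vcf", popmap)
        lines = [l.split("\t") for l in
                 (bundle["dir"] / "genotypes.vcf").read_text().splitlines()
                 if not l.startswith("#")]
        samples = (bundle["dir"] / "genotypes.vcf").read_text().splitlines()
        header = next(l for l in samples if l.startswith("#CHROM")).split("\t")
        sample_names = header[9:]
        by_id = {f[2]: f for f in lines}
        for loc in loci[:50]:
            fields = by_id[loc.locus_id]
            gts = dict(zip(sample_names, fields[9:]))
            counts = {"wild": {}, "cultivated": {}}
            for s, gt in gts.items():
                pop = popmap[s]
                for a in gt.split("/"):
                    allele = [fields[3], fields[4]][int(a)]
                    counts[pop][allele] = counts[pop].get(allele, 0) + 1
            assert loc.counts_wild == counts["wild"]
            h_brute = 1 - sum(
                (v / sum(counts["wild"].values())) ** 2 for v in counts["wild"].values())
            assert gene_diversity(loc.counts_wild) == pytest.approx(h_brute)

    def test_planted_population_means_recovered_at_large_n(self):
        cfg = SimulationConfig(
            seed=13, n_family=30, n_decoy=0, tandem_cluster_spec=[],
            duplicate_pair_spec=[], n_unplaced=0,
            pop_spec=PopSpec(freqs=default_pop_spec(1000).freqs,
                             n_wild=500, n_cult=500),
        )
        pops = generate_populations(cfg)
        h_w, h_c = [], []
        for locus in pops["loci"]:
            n_w2 = 2 * cfg.pop_spec.n_wild
            alt_w = sum(sum(gt) for gt in locus["genotypes"][:500]) / n_w2
            alt_c = sum(sum(gt) for gt in locus["genotypes"][500:]) / n_w2
            h_w.append(2 * alt_w * (1 - alt_w))
            h_c.append(2 * alt_c * (1 - alt_c))
        assert abs(np.mean(h_w) - 0.36) < 0.02
        assert abs(np.mean(h_c) - 0.25) < 0.02

    def test_diversity_report_means_and_histograms(self):
        from famevol.types import SelectionResult

        results = [
            SelectionResult("a", None, 0.4, 0.2, 0.1, "non-selected", "outside"),
            SelectionResult("b", None, 0.3, 0.3, 0.1, "non-selected", "outside"),
        ]
        rep = diversity_report(results)
        assert rep["mean_wild"] == 0.35 and rep["mean_cult"] == 0.25
        assert sum(rep["hist_wild"]) == 2
        with pytest.raises(ValueError):
            diversity_report([])
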