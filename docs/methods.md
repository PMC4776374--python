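# Methods

This note documents the models and conventions implemented in `famevol`,
the defaults and why they were chosen, what the synthetic data emulates,
and the choices made where the underlying procedure is genuinely open.

## Family membership

A candidate gene is a family member iff its domain-annotation table carries
at least one LRR interval and at least one kinase interval. The criterion
is definitional, so on annotated input the roster has sensitivity and
specificity 1 by construction; the interesting failure modes are upstream
(annotation quality), which is why annotations are an explicit input rather
than something the package predicts.

Two auxiliary operations support annotation-free workflows:

- **Similarity prescreen.** Smith–Waterman local alignment
  (`Bio.Align.PairwiseAligner`, BLOSUM62, gap open −11 / extend −1) against
  a set of reference family proteins, converted to an expect value
  E = K·m·n·e^(−λS) with the published gapped BLOSUM62 parameters
  λ = 0.267, K = 0.041. The default threshold is 10⁻⁶. This is a
  prescreen only — the domain criterion decides membership — so exact
  reproduction of BLAST's heuristics is not attempted.
- **LRR profile scan.** A 24-column position-weight matrix for the plant
  extracellular LRR consensus `LxxLxxLxLxxNxLxGxIPxxLxx`: conserved columns
  score log(0.6/0.05) for the consensus residue and log-odds of the shared
  remainder otherwise; background columns score 0. Windows at or above the
  threshold (default 60 % of the maximum attainable score) are selected
  greedily by descending score (ties leftmost) without overlap. The profile
  is deliberately simple; it stands on its own as a consensus matcher and
  is not a reproduction of any HMM-based domain database score.

Redundancy: identical gene ids, or identical protein sequences when
requested, collapse to the lexicographically smallest id — a deterministic
stand-in for the manual curation such surveys describe.

## Phylogeny

Distances are computed on an aligned kinase-domain set: p-distance
(mismatches over columns ungapped in both rows; the common protein-NJ
default) or Poisson-corrected −ln(1−p) by flag. A pair with no comparable
columns is an error, as is a Poisson correction at 1−p ≤ 10⁻⁹.

Neighbor joining follows Saitou–Nei: at each step the pair minimising
Q(i,j) = (r−2)d(i,j) − Rᵢ − Rⱼ is joined, with ties broken by the
lexicographically smallest pair of clade representative labels (the
smallest leaf label in each clade), and branch lengths by the standard
half-difference formula. Negative raw branch lengths are retained during
agglomeration and clamped to 0 on output. On additive matrices this
reconstructs the generating tree exactly (verified to 10⁻⁹ against random
5–8 taxon trees and cross-checked against scikit-bio's NJ).

Bootstrap resamples alignment columns with replacement; support for each
internal edge of the full-data tree is the percentage of replicate trees
containing the same bipartition. Group labels transfer from
reference-labelled leaves: each query leaf takes the group of the nearest
reference by patristic distance (ties: lexicographically smallest
reference), and a monophyly report flags groups whose members do not form
a clade. Subgroup boundaries that published surveys read off tree figures
are not reproduced; nearest-reference assignment plus the monophyly
diagnostics are the stated output.

## Duplication analysis

Tandem clusters chain genes on one chromosome whose start-to-start
distance is within a window (default 200 kb), transitively (single
linkage), keeping chains of two or more. Start-to-start is the measured
quantity because the window convention in the plant-family literature is
ambiguous between start/midpoint/gap; the window and hence the convention
is a config knob. Single-linkage chaining lets cluster spans exceed one
window, which is how published clusters of ten genes arise.

Pairs are "tandem" when both genes share a cluster; otherwise "segmental"
when an external collinearity-evidence row covers the pair (mirroring
database-derived segmental calls, which are an input, not something the
package detects), and "segmental-candidate" under the no-evidence
fallback — the fallback deliberately does not assert collinearity.

## Ka/Ks and dating

Nei–Gojobori (1986) with Jukes–Cantor correction:

- Synonymous site count of a codon position = the fraction of its three
  possible single-nucleotide changes that preserve the amino acid; changes
  to stop codons count as nonsynonymous. S + N = 3 × compared codons
  exactly. Codons containing an alignment gap in either row are excluded.
- Codon pairs differing at k positions average the per-step
  synonymous/nonsynonymous counts over all k! orderings of the changes,
  excluding orderings that pass through a stop codon; if every ordering is
  blocked (impossible for ≤ 2 differences between sense codons), all
  orderings are used. The implementation agrees with an independent
  exhaustive enumerator on all 61×61 ordered sense-codon pairs and with
  Biopython's NG86 distances to 10⁻¹².
- pS = Sd/S, Ks = −(3/4)·ln(1 − (4/3)·pS) (Ka analogous); proportions at or
  beyond 3/4 set a saturation flag instead of emitting a distance.
  ω = Ka/Ks is undefined (reported as such) when Ks = 0.

Dating uses the synonymous clock T = Ks/(2λ) with λ = 6.1×10⁻⁹
substitutions/synonymous site/year (the soybean-lineage rate), reported in
million years to one decimal. The Ks histogram uses fixed bins of width
0.06 anchored at 0 up to 1.02 — this bin geometry makes the two
whole-genome-duplication peaks fall on the interval boundaries
0.12/0.18 and 0.54/0.60. Peaks are strict local maxima (boundary bins
compare to their single neighbour). The ω categorisation counts pairs
strictly below vs at-or-above the cutoff (default 0.3), with
undefined-ω pairs reported separately.

## Expression

Rows are z-scored with the population (divide-by-n) standard deviation;
constant rows map to zero vectors and sit at correlation distance 1 from
everything, keeping clustering total and deterministic. Agglomeration is
average linkage (UPGMA update) on 1 − Pearson r with lexicographic
tie-breaks; merge heights agree with scipy's average linkage on tie-free
matrices.

"Tissue-preferential accumulation" has no standard definition; the
implemented rule — value ≥ fold × row median (default 2) and ≥ an absolute
floor (default 1) — allows multi-tissue calls, which per-tissue counts in
published surveys require (they sum to more than the gene total). The
duplicate-divergence call is Pearson r ≥ 0.8 (flag-exposed) per pair;
a tandem cluster is "similar" only if all member pairs are. qPCR relative
expression is 2^(−ΔΔCt) with ΔCt = Ct_target − Ct_reference.

## Selection scan

Gene diversity is H = 1 − Σpᵢ² from per-population allele counts (plain
estimator by default; Nei's n/(n−1) small-sample correction by flag —
population-genetics packages differ on which they report, so both are
available). Fst estimators:

- **GST**: (Ht − Hs)/Ht with Hs the mean within-population diversity and
  Ht the diversity at mean frequencies; exactly 0 for identical frequency
  vectors, 1 for fixed differences, and closed-form testable
  ((0.5−0.18)/0.5 = 0.64 for 0.9 vs 0.1).
- **WC84** (default, what standard population-genetics software such as
  Genepop reports): Weir & Cockerham's
  θ̂ summed over alleles, with Hardy–Weinberg within-population
  heterozygosity assumed when observed heterozygosity is not supplied.
  Negative estimates (possible at low differentiation) are reported as-is.
  With a single diploid per population the 1/(n̄−1) small-sample terms are
  dropped (their asymptotic form is used), keeping the fixed-difference
  limit at 1.

Classification is strict on both sides: Fst > 0.45 → selected,
Fst < 0.15 → non-selected, the closed interval between → intermediate.
Coding effects map the SNP through the gene's CDS spans respecting strand
(alleles reverse-complemented on −), substitute the alternate allele and
compare translations; intron positions are "intronic", genic non-CDS
positions "outside". Only single-nucleotide alleles are supported. SNPs
and gene models must share one coordinate system; out-of-range positions
are rejected rather than silently reinterpreted.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of a genome-wide family survey at
the study's reported scale — 467 family genes (protein lengths 423–1563
aa) plus decoys in three classes (LRR-only, kinase-only, neither); 33
tandem clusters totalling 94 genes (largest 10, smallest 2) placed at
sub-window spacings while all other genes sit more than one window apart;
160 disjoint paralog pairs with exact planted synonymous/nonsynonymous
edit counts positioned so the Ks distribution peaks in the 0.12–0.18 and
0.54–0.60 bins (~12 and ~47 MY at the default clock); a nine-tissue
expression atlas in which 60 % of genes have one dominant tissue drawn at
≥ 8× the background mean, seven coherent tandem clusters and ~15 % of
segmental pairs share patterns; and a 21-wild / 35-cultivated diploid
panel at 2000 loci whose planted allele frequencies give parametric mean
diversities of exactly 0.36 (wild) and 0.25 (cultivated), with 8 % of loci
planted as strong frequency contrasts.

Deliberately not emulated: realistic nucleotide/amino-acid composition,
linkage disequilibrium between loci, indels, alignment uncertainty
(kinase domains are generated at a fixed length, so the "alignment" is
exact), and real domain-database scores. Consequently, passing tests
demonstrates algorithmic correctness and exact parameter recovery under
known conditions — not robustness to alignment error or annotation noise
in real genomes.

Determinism: every generator is a pure function of (config, seed); each
sub-generator draws from its own seeded stream, so outputs are
byte-identical across runs and stable against unrelated config changes.
Codon sequences for paralog pairs are drawn as shuffles of a fixed
balanced codon pool, which pins the synonymous-site total per pair and
keeps planted Ks values inside their target bins. Stop codons are avoided
during edit placement by bounded rejection (100 retries per edit).

## Problem sizes and numerics

The default end-to-end study (617 proteins, 481-leaf NJ tree, 1000
bootstrap replicates on a 60-leaf subtree, 160 codon-aligned pairs, 2000
loci) runs in well under a minute on one CPU; the test suite uses an
80-gene reduction of the same design. Reported ratios are rounded
half-away-from-zero to one decimal everywhere (so 14/17 prints as 82.4 %),
implemented with decimal arithmetic because binary floating-point
round-half-even would print 82.3. Distance-matrix symmetry is enforced to
10⁻¹²; NJ Q-ties are resolved within 10⁻¹² lexicographically.

## Known limitations

- The prescreen E-value uses fixed Karlin–Altschul parameters rather than
  sequence-composition-adjusted ones; it is a filter, not a BLAST clone.
- ω is a counting-method estimate; no maximum-likelihood or
  transition/transversion-weighted variants are provided.
- The WC84 estimator assumes within-population Hardy–Weinberg proportions
  unless observed heterozygosity is supplied (the VCF path does not
  currently propagate per-genotype heterozygosity).
- Cluster-level expression calls require every member pair to pass the
  similarity threshold, which is conservative for large clusters.
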