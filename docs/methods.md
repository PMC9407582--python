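# Methods

`ripscan` implements a desk-scale pipeline for retrotransposon insertion
polymorphisms (RIPs) in pigs: indel structural variants (SVs) ≥ 50 bp are
extracted from alignments of orthologous locus sequences across genome
assemblies, classified against a repeat consensus library, genotyped in
silico per individual, and summarized with standard population-genetic and
genotype–trait association statistics. A synthetic-data generator stands in
for the genome assemblies and sow phenotype records and supplies exact
ground truth for every stage.

## Synthetic study data

The generator emulates the data a multi-breed RIP survey works from.

**Repeat library.** Family consensus sequences are i.i.d. uniform over
{A,C,G,T} at the configured lengths (SINEA 300 bp, ERVI 1500 bp,
ERVIII 1200 bp, LINE1 2000 bp by default). Random consensi are a
deliberate simplification: they carry no CpG structure, A-tails or
subfamily hierarchy, so passing tests show that discovery and annotation
work when families are mutually distinguishable, not that they resolve
closely related SINE subfamilies.

**Locus panel.** Each locus is a random base sequence (default 2 kb,
emulating a gene fragment with flanks) shared by all assemblies.
Assemblies configured as carriers receive a copy of the locus's TE family
inserted at the sequence midpoint, flanked by a duplicated target site
(TSD, default 6–14 bp) — the hallmark of target-primed reverse
transcription. The copy is diverged by i.i.d. substitutions (default 5%,
an upper bound for young pig SINEA insertions); indel-free divergence
keeps the truth coordinates exact. An optional 5′ truncation mimics
partial SINE copies.

**Genotypes.** Individuals are drawn i.i.d. multinomial(p², 2pq, q²) —
Hardy–Weinberg proportions at the configured insertion-allele frequency.
The bundled configuration uses the frequencies observed in the published
survey: a 260-sow Large White panel at p = 0.4308/0.5731/0.2770/0.7849/
0.2912 for CWH43-9, IDO2-9, OPN-1, PRLR-6 and VMP1-12, plus 24-individual
Meishan and Erhualian panels. No pedigree, selection or inbreeding is
modeled, so the panels are exactly at HWE in expectation; real breed
panels (small, related samples) are not, which is why several published
small-n cells deviate strongly.

**Traits.** TNB (total number born), NBA (number born alive) and LW
(litter birthweight, kg) are baseline + Σ(per-allele effect × dose) +
Gaussian noise; litter counts are rounded to integers and clipped at 0,
and NBA is clipped at TNB. Defaults (baselines 9.7/9.3/12.6, noise SD
2.9/2.8/3.9, a +0.6/+0.6/+0.7 effect at CWH43-9 and −0.45 on LW at
IDO2-9) match the scale of the group summaries reported for first-parity
Large White sows. Because NBA noise is drawn independently of TNB, the
NBA ≤ TNB clip pulls the realized NBA mean ~0.8 below its nominal
baseline; effects and directions are unaffected. The additive model has
no dominance, parity or environmental structure, so power estimates on
synthetic panels are optimistic relative to field data.

Every generator draws from its own RNG stream keyed by (fixed offset,
seed), so outputs are byte-identical given the seed and adding loci does
not perturb genotype draws.

## SV discovery

Orthologous locus sequences are aligned pairwise against a designated
reference assembly by optimal global alignment with affine gap costs
(match +2, mismatch −3, gap open −5, gap extend −1; a gap of length L
costs open + (L−1)·extend). Alignment is delegated to
`Bio.Align.PairwiseAligner`; the aligner's first optimal alignment is
taken, which is deterministic for fixed input. The test suite checks the
score against an independent pure-Python Gotoh dynamic program on
instances up to 600 bp. Sequence pairs whose DP matrix would exceed
64 million cells are aligned by anchor seeding: shared unique 31-mers are
chained collinearly and full DP runs only between anchors.

Maximal gap runs are extracted per aligned string; runs of the same type
separated by ≤ 10 aligned columns are merged (merged length = sum of gap
lengths), and merged events ≥ 50 bp — the conventional SV size floor —
are kept. Coordinates are 1-based inclusive on the reference; a pure
insertion is anchored between reference bases with end = begin − 1.

Per-assembly calls at a locus are unified into sites when anchors agree
within 20 bp and lengths to ≥ 0.8 (min/max). Each site carries a
three-state presence map: *filled* (carries the insertion), *empty*
(aligned, no event) and *unknown* (assembly contributed no alignment) —
unaligned flanks must not be mistaken for deletions. Two conventions to
keep in mind when comparing calls with planted truth: the TSD aligns
inside the gap, so called lengths exceed the planted TE length by up to
the TSD length; and at non-zero divergence, chance micro-homology between
the copy edge and the flank can shift the optimal gap placement a few
bases past the TSD.

## Repeat annotation

Each SV sequence is aligned locally (Smith–Waterman; match +10, mismatch
−8, gap open −20, gap extend −4) against both strands of every library
consensus. The best hit is assigned when score > 1000 **and** ≥ 50% of
the SV sequence is covered; ties break by higher coverage, then
lexicographic family name. The cutoff of 1000 is calibrated so that a
full-length, low-divergence SINE of ~280 bp clears it comfortably
(perfect 281 bp match scores 2810) while the empirical null for random
300 bp sequence stays far below; the coverage floor suppresses short
spurious matches inside long ERV-derived SVs. A consequence of the score
scale: copies shorter than ~150 bp cannot reach 1000 even at perfect
identity, so the `passed` flag is meaningful only for SVs in the surveyed
length range (138–442 bp upward), and the best-scoring family is reported
separately for shorter fragments. Whether such a threshold should apply
to the alignment score or to the masked length is configurable; the score
reading is the default.

## In-silico genotyping

A locus is genotyped the way a gel lane is read. Primer sites are all
positions where the primer (or its reverse complement) matches the
template with at most `max_mismatch` substitutions; a product forms when
one primer's plus-strand site lies upstream of the other's minus-strand
site within 3 kb, and its length includes both primer footprints, so the
filled−empty band difference equals insertion + TSD length. Each
haplotype must yield exactly one band within ±10 bp of an expected size;
two filled-size bands call +/+, two empty-size bands −/−, one of each
+/−, and any other pattern (no band, extra bands, off-size band) is
undetermined — mirroring an uninterpretable multi-band lane. On the
bundled panel, where primers sit on undiverged flank, calls reproduce the
generator's truth for every individual.

## Population-genetic statistics

For each locus × breed cell: genotype and allele frequencies; the
Hardy–Weinberg chi-square over the three genotype classes with expected
counts (np², 2npq, nq²), **no continuity correction**, and the p-value
from chi-square with **1 degree of freedom** (three classes minus one,
minus one estimated allele frequency); and the Botstein polymorphic
information content, PIC = 1 − Σpᵢ² − Σᵢ<ⱼ2pᵢ²pⱼ² (biallelic:
1 − p² − q² − 2p²q², maximum 0.375 at p = 0.5). These exact conventions
reproduce the published Large White values (χ² 1.15, 6.93, 3.317; PIC
0.37, 0.370, 0.281, 0.320) from counts reconstructed as
round(frequency × n); the reconstruction verifies the counts re-sum to n.
Monomorphic cells have no defined test and render "N". PIC > 0.5 is
classed high, (0.25, 0.5] moderate, ≤ 0.25 low.

Several published small-sample cells (e.g. IDO2-9 in Duroc, printed
χ² 22.403 where the formula gives 0.421, and the OPN-1 Large White χ² of
2.373 vs a computed 2.339) are not producible by this statistic from
their own printed frequencies; the implementation follows the formula and
recomputes rather than matches those cells.

## Population structure

Genotypes are coded by insertion-allele dose (−/− → 0, +/− → 1,
+/+ → 2); the three-state coding is the default because heterozygotes are
distinguished in the survey's heatmaps, with binarized presence/absence
available as a config flag. Missing entries stay missing in the stored
matrix and are imputed by the column mean only inside an analysis step.
PCA mean-centers columns (no scaling), drops constant columns, and takes
the SVD; each component's largest-magnitude loading is made positive so
signs are reproducible, and explained variance is the squared singular
values over total variance. Clustering is agglomerative on Euclidean
distances with complete linkage by default (the distance is the published
choice; the linkage was not stated, and complete is the common heatmap
default — it is exposed as config). Both are checked against independent
oracles (covariance eigendecomposition; O(n³) brute-force agglomeration).

## Trait association

Per genotype class: n, mean, and sample SD (n−1). The omnibus test is the
tie-corrected Kruskal–Wallis H against chi-square with k−1 df (via
`scipy.stats.kruskal`); pairwise comparisons are Dunn's z tests on pooled
ranks with tie correction, two-sided, raw by default with Bonferroni
available — the raw default matches how published letter displays of this
kind typically behave, and pairwise Mann–Whitney is provided as an
alternative engine since the exact SPSS procedure behind such tables is
ambiguous. Compact letter displays use the insert-and-absorb algorithm at
two independent tiers: lowercase at α = 0.05 and uppercase at α = 0.01;
two groups share a letter iff their pairwise p ≥ α, a property the test
suite verifies on random matrices. Degenerate inputs are handled
explicitly: identical pooled samples give H = 0, p = 1; loci with fewer
than two genotype classes are flagged not testable; singleton groups
report an undefined SD.

## Problem sizes and numerical choices

The bundled study uses 2 kb loci, eight assemblies, five loci, and
260 + 24 + 24 individuals; the full pipeline runs in a few seconds on one
CPU, and the oracle-equivalence panels (100 loci, alignment oracle
≤ 600 bp, 2000-replicate calibration of the Kruskal–Wallis type-I error)
are sized to keep the whole suite in the low minutes while leaving the
statistical checks well-powered. Floating-point conventions: allele
frequencies must sum to 1 within 1e−9 for PIC; PCA rank is cut at
1e−12 of the leading singular value; alignment scores are compared
exactly (integer-valued scoring).

## Known limitations

- Pairwise alignment against one reference replaces true multiple
  alignment; sites private to a non-reference assembly pair would need a
  different reference choice.
- Random repeat consensi and substitution-only divergence understate the
  difficulty of annotating truncated, nested or subfamily-structured
  insertions.
- The genotype simulator has no population structure, relatedness or
  genotyping error, and the trait model is purely additive; recovery
  rates on synthetic panels are best-case.
- Amplicon prediction ignores primer thermodynamics (melting temperature,
  dimers, 3′-end sensitivity); a mismatch count is the only specificity
  model.
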