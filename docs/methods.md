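# Methods

This note records the models, thresholds, and numerical choices behind each
stage, what the synthetic-data generator does and does not emulate, and the
design decisions taken where the procedure was genuinely open.

## Coordinates, strands, and conventions

All in-memory coordinates are 0-based half-open; GFF3 and SAM are converted
at the boundary and restored on export. Pileup TSVs store internal 0-based
positions. Small-RNA tags are matched against both genome strands; a
minus-strand placement records the forward-strand interval with strand `-`,
and its 5′-most base is the interval's right end. Unknown bases (N) never
match any tag base. The fold-change sign convention is
`log2(reference/comparison)` everywhere, so a gene lower in a mutant of a
parent:mutant comparison has a positive log2 fold change; qPCR results
follow the same convention with the test group as reference.

## Genotype calling and deletion scenarios

Per sample and site: depth 0 → `--`; 0 < depth < `min_depth` (default 8) →
NA; minor-allele frequency ≥ `maf_min` (0.25, inclusive) → AB; MAF ≤
`hom_err_max` (0.05) → AA; intermediate → NA. The MAF rule is the published
one; `min_depth` and `hom_err_max` are conventional guards against
shallow-coverage miscalls. A parent AA call becomes `A-`
(hemizygous-compatible) only when no sample shows genuine evidence of a
second allele — an AB call, or an AA call on a different major allele —
so sporadic error reads cannot block the hemizygous pattern.

Scenario 1 requires parent AB and every mutant AA with its allele among the
parent's two; scenario 2 requires parent `A-` at adequate depth and at most
`max_stray_reads` (default 0) mutant reads, enforced across *all* of a
gene's covered sites when grouping by gene — a deleted gene should emit
nothing. Sites with any NA mutant are excluded rather than guessed.
Candidate ranking is by supporting-site count with lexicographic
tie-breaks; `min_support` defaults to 1 and is configurable because the
number of supporting SNPs behind a reported contig is a free choice.

## Small-RNA profiling

Filtering keeps 18–25 nt tags seen at least `min_tag_count` (5) times in
some sample; a strict (> 5) variant exists because both phrasings of the
rule are defensible. Placement allows ≤ 2 substitutions plus at most one
microindel of 1–2 nt, implemented as a vectorized split-alignment scan: for
each genome offset and gap size, prefix/suffix mismatch cumulative sums give
the best split in O(genome × tag) total work; every qualifying (start,
span) is reported with its minimal (mismatch, indel) combination. The scan
is verified against an exhaustive position-by-position oracle.

Classification uses the placement's 5′-most base — deterministic and
order-free for boundary-straddling reads — with precedence gene body
(CDS + introns) > UTR > strand-relative 500-bp flank. A placement inside
two genes' extended regions is counted for both and flagged ambiguous
(`unique_gene` drops such placements instead); read counting is
strand-agnostic, matching the summed-read counting the pipeline emulates.

## MIRNA prediction

Candidate loci are unordered pairs of distinct, perfectly placed tags on
one contig and strand, 5′-start distance ≤ 400 bp inclusive,
non-overlapping. The left arm is reported as the miR arm by convention; the
pair alone cannot identify the mature strand. Acceptance requires
(1) an inter-arm loop ≥ 3 nt, (2) duplex complementarity of the left arm
against the reversed right arm ≥ `duplex_min_paired` (0.6) counting G:U
wobble, scanned over ±2 nt register offsets, and (3) a secondary structure
check: a Nussinov maximum-base-pairing fold (minimum loop 3, G:U allowed)
of the genomic precursor must pair the two arms predominantly with each
other — cross-arm pairs covering ≥ 0.6 of the shorter arm. The Nussinov
fill is a jitted O(n³) dynamic program (a vectorized numpy fill is kept as
the reference path) with a deterministic traceback, verified against
exhaustive enumeration of nested structures on short sequences.

Measured on shuffled-genome controls (random 21-mers extracted from a
shuffled sequence, so every tag places perfectly), the default thresholds
accept about 1 % of candidate pairs (0.8–1.6 % across 10-genome batches)
while accepting 100 % of implanted perfect-duplex loci; the thresholds are
configurable and stricter settings trade control rate against tolerance for
imperfect duplexes. Thermodynamic folding is deliberately not built in; the
maximum-pairing check keeps the package self-contained, and an energy-based
engine can be hooked in where the secondary check is made.

## Differential expression

TMM factors follow the published algorithm: pairwise against a reference
sample (chosen by upper-quartile proximity to the mean), genes zero in
either member excluded, log-ratios double-trimmed (30 % each tail on M,
5 % each tail on A), inverse-asymptotic-variance weighted, and factors
rescaled to geometric mean 1. The implementation reproduces
`edgeR::calcNormFactors(method="TMM")` to ≥ 9 decimals on fixed matrices
(frozen cross-check in the tests).

The exact test conditions the group-A sum on the total under a shared mean
and common dispersion (variance = μ + φμ²): group sums are NB with size
n/φ, and the two-sided p-value sums all outcome probabilities not exceeding
the observed one. Dispersion 0 reduces to the exact binomial split,
verified by enumeration. Counts are first rescaled to a common effective
library size and rounded. The common dispersion is estimated by a pooled
ratio-of-sums method-of-moments estimator, φ̂ = Σ(s²−x̄)/Σx̄², which stays
nearly unbiased at two replicates per group where per-gene moment
estimates are individually useless; unreplicated designs fall back to a
fixed φ = 0.1. Benjamini–Hochberg adjustment is the standard step-up,
cross-checked against statsmodels.

mRNA flags require adjusted p ≤ 0.01 and |log2fc| ≥ 1 (both inclusive);
sRNA flags use fold change alone (> two-fold on normalized counts with
pseudocount 1) because single-replicate libraries support no within-group
variance estimate. Under a global rescaling of all libraries the factors
and fold changes are invariant and fold-only flags are unchanged; exact-test
p-values legitimately are not, since total counts carry information.

## GO enrichment

Gene models annotate through putative orthologs; ortholog multiplicity
m = number of background gene models sharing the ortholog. Each annotated
foreground/background gene contributes m units to each of its ortholog's
terms and to the respective total, and the hypergeometric upper tail is
taken on these multiplied counts (an unweighted mode is provided — the
weighting mirrors the emulated procedure but makes the "units" statistically
non-independent, which a user should know when reading the p-values).
The threshold p ≤ 1e-5 is inclusive; no multiple-testing correction is
applied to enrichment p-values and terms are flat labels without
DAG propagation. Unannotated genes contribute nothing and are logged.

## qPCR ΔΔCt

Technical replicates are averaged per biological replicate before any
statistic. ΔCt = Ct_target − Ct_reference per group and replicate;
per-replicate log2 fold changes are ΔCt_control − ΔCt_test with replicates
paired by sorted id, and the reported value is their mean and SD.
Significance needs fold > 1.5 (strict) and t-test p < 0.05 (strict) on the
ΔCt values; the t-test is unpaired by default with a paired variant
available, since biological replicates of independently grown plants do
not pair naturally but both designs are defensible. Noise-free data
recovers implanted folds exactly (the construction cancels the per-gene
baseline).

## Assembly redundancy

A k-mer (default k = 100) is redundant when another k-mer at a different
coordinate lies within Hamming distance `max_hamming` (default 2). The
pigeonhole partition into max_hamming + 1 segments makes the computation
exact: any qualifying pair shares at least one segment verbatim, so
candidates come from per-segment hash buckets and are verified by direct
comparison. Same-contig partners must start ≥ `min_separation` (default k)
apart, suppressing the trivial self-overlap matches of repetitive windows;
partners on other contigs always qualify. Forward-strand only by default
with a `both_strands` option; k-mers containing N are skipped and counted.
`sample_step` subsamples start positions for large inputs; exact mode is
the default at the scales the package targets.

## Synthetic data: what it emulates, and what it does not

The generator mirrors the emulated study design: a heterozygous polyploid
parent and two mutants sharing deletions (defaults: 200 genes on 2 contigs,
30 % of genes as collapsed homeolog pairs differing at 3 SNPs, 20
heterozygous-loss and 10 hemizygous-loss genes), Poisson depth-30 pileups
with a configurable base-error rate, NB counts with two replicates per
group and variance μ + φμ², small-RNA populations with per-sample 18–25 nt
length mixes, perfectly complementary hairpin arms within 400 bp, 24-nt
siRNA tiles over target gene bodies whose per-genotype intensity encodes
the true fold change, and Ct tables with two biological × two technical
replicates (Ct = baseline − log2 expression + Gaussian noise).

Deliberate simplifications: reads are summarized as allele counts rather
than simulated as error-bearing FASTQ; the second homeolog is collapsed
(its alleles live only in the truth table, as in a collapsed assembly);
hairpin arms are exact reverse complements, so duplex thresholds are
exercised by the shuffled-genome control rather than by imperfect implants;
background small-RNA tags are uniform over the genome, so the genic
alignment share reflects gene density, not chromatin biology; and no
tissue-composition dilution of cell-type-specific signal is modelled — a
per-genotype intensity knob stands in for it. Passing tests therefore
demonstrate algorithmic correctness and calibration, not robustness to
artifacts these simplifications exclude.

Problem sizes in the tests and the acceptance script (for example 2-kb
oracle instances, a 2 × 220-kb genome for 200-gene deletion recovery,
2000-feature calibration runs, 150-tag shuffled controls) are chosen as
desk-scale conditions where the exact oracles remain enumerable; every
stage scales to the full defaults unchanged.

Two generator-level expectations deserve their numbers: with NB dispersion
0.1 and two replicates per group, the realized log2 fold change of a
4-fold gene has standard deviation ≈ 0.36–0.48, so empirical fold changes
concentrate within ±0.5 of 2 only at low dispersion (the construction test
uses φ = 0.02, a plausible value for clonal material; at φ = 0.1 roughly
70–85 % of genes land in that band). Likewise, detection power for 4-fold
genes at the study thresholds is ≈ 0.78–0.87 at φ = 0.1 — the measured
value sits at the edge of 0.8 because the comparison is
information-limited, not because of an implementation deficit (the TMM and
exact-test components match the reference implementation they re-create).

## Known limitations

No BAM/CRAM or compressed-index support (text SAM only, by scope). The
exact test implements the classic common-dispersion conditional test, not
tagwise empirical-Bayes shrinkage or GLMs. MIRNA prediction does not
quantify expression or predict targets. The GO module assumes flat term
labels. The redundancy profiler measures substitution-only (Hamming)
redundancy; indel-mediated redundancy is out of scope.
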