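# Methods

This note documents the models, conventions and numerical choices
behind each stage, what the synthetic generators do and do not emulate,
and the known limitations.

## Read filtering

Rules are evaluated per mate after adapter trimming; failure of either
mate removes the pair, because a surviving orphan is useless for
paired-end de novo assembly. Thresholds are strict inequalities: a mate
with exactly 10% of bases below Q20 (or exactly 10% N) passes. Adapter
trimming removes the longest read suffix exactly matching an adapter
prefix with at least 10 bp of overlap; no mismatches are tolerated.
Exact matching under-trims reads whose adapter bases contain sequencing
errors — accepted deliberately, since it keeps the trimmer a pure,
testable string function. No adapter sequence is assumed by default;
callers supply their own. The post-trim length floor defaults to 36 bp,
a common convention for 150 bp chemistry. The QC report's mean error
rate converts each retained base's Phred score back to an error
probability (10^(−Q/10)) and averages; Q20/Q30 are base fractions, not
read fractions.

## Assembly statistics

Nxx is computed on lengths sorted descending as the length at which the
cumulative sum first reaches the fraction of the total; N90 ≤ N50 by
construction. The 500 bp length filter keeps contigs exactly at the
threshold ("shorter than" is read strictly). N bases count toward total
length and the base-composition denominator, but are excluded from GC
numerators and from per-contig GC fractions in the depth–GC table
(all-N contigs report GC 0 by convention). Depth is an input annotation
from the assembler or read mapper — the package does not recompute
mapping depth; for synthetic data the read simulator reports exact
depths from its own placements.

## Decontamination

Endosymbiont contigs are identified by mean depth strictly above 50×,
the signature of a high-copy intracellular bacterium in a whole-body
library. Flagged contigs are shredded into canonical k-mers (k = 87,
matching the assembly k; canonical = lexicographic minimum of the k-mer
and its reverse complement) and a read pair is purged when either mate
shares *any* canonical k-mer with the index. A single-k-mer trigger at
k = 87 is conservative and fully deterministic: an 87 bp exact match in
a 150 bp read is overwhelming evidence of origin, and the false-trigger
probability for unrelated sequence is negligible (≪ 4^−40 per
comparison). The alternative — identity-threshold alignment — is out of
scope. Reference screening of contigs replaces a database BLAST search
with canonical 31-mer containment against user-supplied reference
FASTA: a contig is flagged when at least half its k-mers occur in the
reference. This is database-free and deterministic; its trade-off is
that it detects only near-exact matches, not remote homology.
Re-assembly after purging is an external hook (a shell command
template); when unset, the depth/reference-filtered contigs pass
through.

## SSR detection

A locus is a maximal run of positions with period m (sequence[i] =
sequence[i+m], both non-N) holding at least the minimum number of
*whole* motif copies: 10 for mononucleotides, 6 for dinucleotides, 5
for tri- through hexanucleotides. Only primitive motifs are reported,
so a tract is never double-reported under a multiple of its period
((AT)₆ is not also (ATAT)₃). Trailing partial copies neither extend
the reported length nor the repeat count, and the reported tract is
anchored at the left end of the run — consequently coordinates on the
reverse complement strand mirror only up to a sub-motif shift (< m bp)
when partial copies exist at both ends; canonical class and repeat
count are strand-invariant. Coordinates in reports are 1-based
inclusive. Compound or interrupted (imperfect) microsatellites are not
detected: perfectness keeps the brute-force oracle in the test suite
exact. Marker-candidate selection discards mononucleotide loci
(indistinguishable from polyadenylation products and homopolymer
sequencing error) and any locus without 200 bp of N-free flank on both
sides.

## Primer design

The designer enumerates every window of length 18–27 in a 300 bp
window on each flank, filters on GC (20–80%), melting temperature
(57–63 °C), homopolymer runs (none ≥ 5), and N content, then scores
every cross-pair satisfying the product-size (80–280 bp, bracketing
typical silver-stained PAGE assays) and Tm-gap (≤ 3 °C) constraints by

    |Tm_f − 60| + |Tm_r − 60| + |product − 180| / 50

with ties broken by smaller product, then leftmost forward start. The
melting temperature is the salt-free linear estimate
81.5 + 0.41·GC% − 675/L, valid for L ≥ 14: monotone in GC and length,
exactly reproducible, and sufficient for ranking. Nearest-neighbor
thermodynamics, hairpin/dimer ΔG screening and multiplex compatibility
are deliberately out of scope; the suggested annealing temperature
(min primer Tm − 5, rounded) is a starting point for gradient
optimisation, not a prediction. Design is a pure function of (locus,
sequence, constraints); reruns are byte-identical.

## Diversity statistics

Allele frequencies count allele copies among non-missing diploid calls
(missing genotypes are excluded per locus, never imputed). Expected
heterozygosity defaults to Nei's unbiased estimator (2N/(2N−1))(1−Σp²)
with a flag for the uncorrected gene diversity; Shannon's index uses
the natural logarithm. Table statistics are pooled across populations
by default (one row per locus for the whole survey), with per-population
mode available. Nei's standard distance averages the J-terms
arithmetically over loci before forming D = −ln(J_xy/√(J_x·J_y));
populations sharing no alleles anywhere give D = +∞, which the tree
builder refuses rather than truncates. Tiny floating excursions of the
identity above 1 for near-identical populations are clamped so D ≥ 0
exactly.

## Neighbor joining

Classic Saitou–Nei agglomeration: join the pair minimising
Q(i,j) = (n−2)d(i,j) − Σ_k d(i,k) − Σ_k d(j,k), with branch lengths
ℓ_i = d(i,j)/2 + (T_i − T_j)/(2(n−2)) and distance updates
d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2. Ties in Q (within 1e−12) are broken
by the lexicographically smallest pair of cluster labels, a cluster
being labelled by its smallest member leaf — this makes the tree a
deterministic function of the matrix. Negative branch lengths are kept
by default (faithful to the algorithm) with an optional clamp for
display. The final two clusters are connected through a root node
carrying the remaining distance; the tree is to be read as unrooted.
On additive matrices NJ is exact, which the tests verify to 1e−9
against independently generated random trees, and the implementation is
cross-checked against scikit-bio's `nj` by tip-to-tip path distances.

## Synthetic data: what it emulates, and what not

The genome generator draws i.i.d. bases at a target GC of 36.5% — the
A/T-rich composition typical of the beetle assembly this pipeline's
workflow is modelled on — and plants perfect SSR tracts at least 250 bp
from contig ends. Each contig is rejection-resampled until background
GC is within 2 points of target and the scanner reports *exactly* the
planted loci, so planted truth tables are exact by construction rather
than approximately true. The read simulator draws fragments uniformly
(length-weighted across contigs, default 300 bp insert, 150 bp mates),
assigns a flat Phred quality and uniform substitution errors (default
Q33 / 0.05% — a typical HiSeq error rate; an error-free profile is
provided for exact-recovery tests). The contamination model generates a
separate genome at 55% GC sequenced at 5× the host depth, mirroring the
elevated-depth/shifted-GC cluster an endosymbiont produces. Defaults:
host depth 20×, contaminant depth therefore 100×, well above the 50×
flagging threshold. Not emulated: position-dependent quality decay,
indels, GC-coverage bias, repeat-induced misassembly, structural
variation — so passing tests demonstrate correctness of the *methods*
on clean signals, not robustness to every artefact of real libraries.

The genotype simulator is Balding–Nichols: ancestral frequencies are
symmetric-Dirichlet, per-population frequencies are Dirichlet around
them with concentration (1−Fst)/Fst, genotypes are two independent
draws (random mating, no null alleles, no linkage, no genotyping
error). Fst = 0 collapses to identical frequencies everywhere. Default
design — 18 populations × 20 diploid individuals × 20 loci, ~8 alleles
per locus, Fst 0.1 — mirrors a typical multi-site survey with moderate
structure; the Fst default is a generic "moderate differentiation"
choice, as marker surveys of this kind rarely fit an explicit Fst.

## Problem sizes in the test and acceptance suites

The scanner-vs-oracle suite runs 120 independent 5 kb A/T-rich
sequences plus 30 planted-repeat mosaics and a derandomised
property-based sweep of short N-containing strings; NJ additivity uses
25 random trees of 4–15 taxa; decontamination recovery uses a ~9 kb
host genome with a 20 kb contaminant at 5× relative depth (~7,000 read
pairs). These sizes make every property exact (set equality, error
< 1e−9, sensitivity exactly 1) while the full suite completes in well
under a minute; growing them changes nothing qualitatively because the
checks are exact rather than statistical.

## Known limitations

No de novo assembler is bundled (re-assembly is an external hook); no
imperfect-SSR detection; no BLAST-style remote-homology screening; no
Hardy–Weinberg testing, Fst estimation or bootstrap support values; the
GenePop writer emits the 3-digit convention and the parser accepts 2-
or 3-digit records but not the haploid variant.
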