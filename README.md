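# ssrforge

Microsatellite (SSR) marker development for non-model genomes, end to
end: raw-read quality filtering, endosymbiont decontamination, assembly
QC, perfect-SSR mining, PCR primer design over SSR flanks, and
population-diversity analysis of the resulting co-dominant markers.

The package targets the common study design in insect population
genetics — e.g. the adzuki bean weevil *Callosobruchus chinensis*, a
major pest of stored legume seeds — where a draft genome is shotgun
sequenced from whole-body DNA, microsatellites are mined from the
contigs, and a panel of validated markers is then scored across many
field populations. Whole-body insect DNA routinely carries sequence
from intracellular bacteria such as *Wolbachia*, so decontamination is a
first-class pipeline stage, not an afterthought.

## What it computes

**Read QC.** A pair is dropped when, after exact suffix–prefix adapter
trimming (≥10 bp overlap), *either* mate has >10% of bases below Q20,
>10% N bases, or fewer than 36 bp. The QC report gives the effective
rate (clean/raw × 100), Q20/Q30 base percentages and the mean per-base
error rate Σ10^(−Q/10)/n.

**Decontamination.** Contigs with depth > 50× are flagged as
endosymbiont, shredded into canonical 87-mers, and every read pair
sharing one k-mer with the index is purged (pair-level). Surviving
contigs are additionally screened against user-supplied contaminant
references by canonical 31-mer containment (flag at ≥ 0.5).

**Assembly QC.** Length filter (≥ 500 bp kept), N50/N90 (length at
which the descending cumulative sum first reaches 50%/90% of the
total), base composition and the per-contig depth-vs-GC table on which
contamination shows up as a separate cluster.

**SSR mining.** All maximal perfect tandem repeats with a primitive
motif of 1–6 bp, at minimum repeat counts 10 (mono), 6 (di) and 5
(tri–hexa). Motifs are grouped into canonical classes (minimum over
cyclic rotations and their reverse complements), mononucleotide loci
are discarded as marker candidates, and loci need 200 bp of clean flank
on both sides to enter primer design.

**Primer design.** Exhaustive enumeration over both flanks under
Primer3-default-style constraints (length 18–27, Tm 57–63 °C with
optimum 60, GC 20–80%, product 80–280 bp, |ΔTm| ≤ 3, no 5-base
homopolymer run), with the salt-free formula
Tm = 81.5 + 0.41·GC% − 675/length and a deterministic best-pair rule.

**Population diversity.** Per locus: allele count *Na*, expected
heterozygosity *He* = (2N/(2N−1))(1 − Σp²), observed heterozygosity
*Ho*, Shannon's index *I* = −Σp·ln p. Between populations: Nei's (1972)
standard distance D = −ln(J_xy/√(J_x·J_y)) with J-terms averaged over
loci, and a Saitou–Nei neighbor-joining dendrogram exported as Newick.

**Synthetic data.** Generators for A/T-rich genomes with planted SSRs
(rejection-resampled so the scanner's truth table is exact), paired
150 bp reads with an optional higher-GC contaminant genome at elevated
depth (with per-pair truth labels), and Balding–Nichols genotype tables
at a chosen Fst — all deterministic given a seed.

## Worked example

```python
import ssrforge as sf

spec = sf.GenomeSpec(n_contigs=5, min_len=2000, max_len=3000,
                     planted_ssrs=[("AC", 8, 0, 500), ("AAG", 6, 1, 700)],
                     seed=42)
contigs, truth = sf.make_genome(spec)
for locus in sf.scan_contigs(contigs):
    print(locus.contig_id, locus.start, locus.end,
          f"({locus.motif})x{locus.repeat_count}", locus.canonical)
```

prints

```
contig_0 501 516 (AC)x8 AC
contig_1 701 718 (AAG)x6 AAG
```

— each planted microsatellite recovered at its exact 1-based
coordinates and grouped under its canonical motif class. The scripts in
`examples/` walk through every stage the same way: simulation+scanning,
read filtering, decontamination, primer design, and an 18-population
diversity analysis ending in a Newick dendrogram. A thin CLI mirrors
the library (`ssrforge qc|decontam|asm-stats|scan|primers|diversity|
distance|tree|run`), with `ssrforge run --config run.json` driving the
whole pipeline and writing a manifest of per-stage counts and output
checksums.

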