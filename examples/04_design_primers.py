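"""Design PCR primer pairs over the flanks of marker-candidate SSRs.

Mononucleotide loci and loci without 200 bp of clean flank are discarded
first; each surviving locus gets the feasible primer pair closest to the
60 degC / 180 bp optima (length 18-27, Tm 57-63, GC 20-80%, product
80-280 bp, Tm gap <= 3, no 5-base homopolymer inside a primer).
"""

import ssrforge as sf

spec = sf.GenomeSpec(
    n_contigs=6,
    min_len=2000,
    max_len=2600,
    gc_target=0.45,
    planted_ssrs=[("AC", 8, i, 900) if i % 2 else ("AAG", 6, i, 900) for i in range(6)],
    seed=5,
)
contigs, _ = sf.make_genome(spec)
loci = sf.scan_contigs(contigs)
candidates = sf.select_marker_candidates(loci, contigs, min_flank=200)
pairs, failures = sf.primer_design.design_for_loci(candidates, contigs)

print(f"{len(loci)} SSRs -> {len(candidates)} candidates -> {len(pairs)} primer pairs")
print(f"{'locus':22s} {'forward':28s} {'reverse':28s} size  Ta")
for p in pairs:
    tag = f"{p.locus.contig_id}:({p.locus.motif})x{p.locus.repeat_count}"
    print(f"{tag:22s} {p.forward:28s} {p.reverse:28s} {p.product_size:4d}  {p.annealing_suggestion}")
for f in failures:
    print(f"no feasible pair for {f.locus.contig_id}: rejections {f.reasons}")
# Ta is the heuristic annealing suggestion: min(primer Tm) - 5, rounded.
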