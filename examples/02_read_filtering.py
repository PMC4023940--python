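"""Filter simulated paired reads and print the sequencing QC report.

Reads with >10% of bases under Q20, >10% N, adapter read-through leaving
<36 bp, or a failing mate are dropped pair-wise; the report gives the
effective rate (clean/raw x 100), Q20/Q30 base percentages and the mean
per-base error rate implied by the Phred scores.
"""

import numpy as np

import ssrforge as sf
from ssrforge.read_qc import Read, ReadPair

rng = np.random.default_rng(1)
contigs, _ = sf.make_genome(sf.GenomeSpec(n_contigs=3, seed=1))
sim = sf.simulate_reads(contigs, depth=10, error_profile=sf.ErrorProfile(mean_q=33), seed=2)

# degrade a fraction of pairs so the filter has something to do
pairs = []
for i, pair in enumerate(sim.pairs):
    if i % 7 == 0:  # inject a low-quality mate: 20% of bases at Q10
        quals = list(pair.mate1.qualities)
        for j in range(0, len(quals), 5):
            quals[j] = 10
        pair = ReadPair(Read(pair.mate1.name, pair.mate1.sequence, quals), pair.mate2)
    pairs.append(pair)

clean = sf.read_qc.filter_pairs(pairs)
report = sf.qc_summary(len(pairs), clean)
print(report.to_json())
print(
    f"\n{report.raw_pairs - report.clean_pairs} of {report.raw_pairs} pairs dropped; "
    f"every kept base has a {report.mean_error_rate:.3f}% expected error rate (Q33 ~ 0.05%)"
)
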