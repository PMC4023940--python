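"""Perfect-microsatellite (SSR) detection.

Finds all maximal perfect tandem repeats with a primitive motif of 1-6 bp,
subject to per-motif-size minimum repeat counts. The defaults follow the
common MISA convention for insect genome surveys: ten repeat units for
mononucleotides, six for dinucleotides and five for tri- through
hexanucleotides. Runs containing N are never repeats, a trailing partial
motif copy does not extend a locus, and a locus is reported exactly once
under its primitive motif ((AT)6 is never also (ATAT)3).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ._util import DNA, revcomp

#: Minimum number of whole motif copies required, keyed by motif size.
MIN_REPEATS_DEFAULT: Mapping[int, int] = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}


@dataclass(frozen=True, order=True)
class SSRLocus:
    """A perfect microsatellite: ``repeat_count`` whole copies of ``motif``.

    Coordinates are 1-based inclusive, as in biological report tables.
    """

    contig_id: str
    start: int
    end: int
    motif: str
    canonical: str
    repeat_count: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __post_init__(self) -> None:
        if self.length != self.repeat_count * len(self.motif):
            raise ValueError(
                f"inconsistent locus: span {self.length} bp != "
                f"{self.repeat_count} x {len(self.motif)} bp motif"
            )


def is_primitive(motif: str) -> bool:
    """True if ``motif`` is not a whole-number repetition of a shorter motif."""
    m = len(motif)
    for d in range(1, m):
        if m % d == 0 and motif == motif[:d] * (m // d):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Normalized motif class label.

    The lexicographically smallest string among all cyclic rotations of the
    motif and all cyclic rotations of its reverse complement, so that e.g.
    GT, TG, CA and AC all map to "AC".
    """
    motif = motif.upper()
    if not 1 <= len(motif) <= 6 or any(c not in DNA for c in motif):
        raise ValueError(f"motif must be 1-6 bp over ACGT, got {motif!r}")
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")
    rc = revcomp(motif)
    rotations = {motif[i:] + motif[:i] for i in range(len(motif))}
    rotations |= {rc[i:] + rc[:i] for i in range(len(rc))}
    return min(rotations)


def scan_sequence(
    sequence: str,
    min_repeats: Mapping[int, int] | None = None,
    contig_id: str = "",
) -> list[SSRLocus]:
    """All maximal perfect SSRs in ``sequence`` meeting the repeat thresholds.

    For each motif size ``m`` the scanner locates maximal runs of positions
    where ``sequence[i] == sequence[i+m]`` (both non-N); a run of ``r``
    matches spans ``r + m`` bases and holds ``(r + m) // m`` whole motif
    copies. Runs whose leading motif is non-primitive belong to a smaller
    motif size and are skipped there. Loci are sorted by start coordinate,
    then motif size.
    """
    if min_repeats is None:
        min_repeats = MIN_REPEATS_DEFAULT
    seq = sequence.upper()
    n = len(seq)
    loci: list[SSRLocus] = []
    for m, min_rep in sorted(min_repeats.items()):
        if m < 1:
            raise ValueError("motif sizes must be >= 1")
        i = 0
        limit = n - m
        while i < limit:
            if seq[i] in DNA and seq[i] == seq[i + m]:
                run_start = i
                while i < limit and seq[i] in DNA and seq[i] == seq[i + m]:
                    i += 1
                copies = (i - run_start + m) // m
                if copies >= min_rep:
                    motif = seq[run_start : run_start + m]
                    if is_primitive(motif):
                        end = run_start + copies * m  # 1-based inclusive
                        loci.append(
                            SSRLocus(
                                contig_id=contig_id,
                                start=run_start + 1,
                                end=end,
                                motif=motif,
                                canonical=canonical_motif(motif),
                                repeat_count=copies,
                            )
                        )
            else:
                i += 1
    loci.sort(key=lambda l: (l.start, len(l.motif)))
    return loci


def scan_contigs(
    contigs: Iterable, min_repeats: Mapping[int, int] | None = None
) -> list[SSRLocus]:
    """Scan a collection of objects with ``.id`` and ``.sequence`` attributes."""
    out: list[SSRLocus] = []
    for c in contigs:
        out.extend(scan_sequence(c.sequence, min_repeats, contig_id=c.id))
    return out


@dataclass
class SsrSummary:
    """Tallies of an SSR catalogue along the partitions survey papers report."""

    total: int = 0
    by_canonical: Counter = field(default_factory=Counter)
    by_motif_size: Counter = field(default_factory=Counter)
    by_length: Counter = field(default_factory=Counter)

    def motif_size_percent(self, size: int) -> float:
        return 100.0 * self.by_motif_size.get(size, 0) / self.total if self.total else 0.0


def summarize(loci: Sequence[SSRLocus]) -> SsrSummary:
    """Count loci by canonical motif class, motif size and tract length (bp)."""
    s = SsrSummary(total=len(loci))
    for locus in loci:
        s.by_canonical[locus.canonical] += 1
        s.by_motif_size[len(locus.motif)] += 1
        s.by_length[locus.length] += 1
    return s


def select_marker_candidates(
    loci: Sequence[SSRLocus],
    contigs: Iterable,
    min_flank: int = 200,
) -> list[SSRLocus]:
    """Filter loci to marker candidates suitable for primer design.

    Mononucleotide loci are discarded (indistinguishable from polyadenylation
    artefacts and homopolymer sequencing error), as are loci with fewer than
    ``min_flank`` bp of N-free sequence on either side.
    """
    seqs = {c.id: c.sequence.upper() for c in contigs}
    kept: list[SSRLocus] = []
    for locus in loci:
        if len(locus.motif) == 1:
            continue
        seq = seqs.get(locus.contig_id)
        if seq is None:
            raise KeyError(f"locus references unknown contig {locus.contig_id!r}")
        left = seq[locus.start - 1 - min_flank : locus.start - 1]
        right = seq[locus.end : locus.end + min_flank]
        if len(left) < min_flank or len(right) < min_flank:
            continue
        if "N" in left or "N" in right:
            continue
        kept.append(locus)
    return kept


def loci_to_tsv(loci: Sequence[SSRLocus], path) -> None:
    """Write loci as a TSV report (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tmotif\tcanonical_motif\trepeats\tlength\n")
        for l in loci:
            fh.write(
                f"{l.contig_id}\t{l.start}\t{l.end}\t{l.motif}\t"
                f"{l.canonical}\t{l.repeat_count}\t{l.length}\n"
            )
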