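"""Endosymbiont decontamination of reads and contigs.

Insect genome assemblies from whole-body DNA frequently carry sequence
from intracellular bacteria such as *Wolbachia*, which appears as a
cluster of contigs at elevated depth and distinct (higher) GC. The
two-stage procedure implemented here:

1. depth stage — contigs above a depth threshold are flagged as
   contaminant, shredded into k-mers (87-mers by default, matching the
   assembly k), and every read pair sharing at least one canonical k-mer
   with that index is purged so the host genome can be re-assembled clean;
2. reference stage — surviving contigs are screened against user-supplied
   contaminant reference sequences by canonical k-mer containment
   (fraction of a contig's k-mers present in the reference), a
   deterministic, database-free stand-in for an alignment search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ._util import canonical_kmer
from .assembly_qc import Contig
from .read_qc import ReadPair

logger = logging.getLogger(__name__)


def flag_by_depth(contigs: Sequence[Contig], depth_threshold: float = 50.0) -> list[str]:
    """Ids of contigs with depth strictly greater than the threshold."""
    return [c.id for c in contigs if c.depth > depth_threshold]


@dataclass
class ContaminantIndex:
    """Canonical k-mer membership index built from flagged contigs."""

    k: int
    kmers: set[str] = field(default_factory=set)
    source_contigs: list[str] = field(default_factory=list)

    def __contains__(self, kmer: str) -> bool:
        return canonical_kmer(kmer) in self.kmers


def _kmers(seq: str, k: int) -> Iterable[str]:
    seq = seq.upper()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            yield canonical_kmer(kmer)


def build_index(contigs: Sequence[Contig], k: int = 87) -> ContaminantIndex:
    """Shred contigs into canonical k-mers (stride 1).

    Contigs shorter than ``k`` contribute no k-mers but are still recorded
    as sources.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not contigs:
        raise ValueError("build_index requires at least one contig")
    index = ContaminantIndex(k=k)
    for c in contigs:
        index.source_contigs.append(c.id)
        index.kmers.update(_kmers(c.sequence, k))
    return index


@dataclass
class PurgeReport:
    reads_removed: int
    reads_kept: int
    contigs_flagged_by_depth: list[str] = field(default_factory=list)
    contigs_flagged_by_reference: list[str] = field(default_factory=list)


def _read_matches(sequence: str, index: ContaminantIndex) -> bool:
    kmers = index.kmers
    seq = sequence.upper()
    k = index.k
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer and canonical_kmer(kmer) in kmers:
            return True
    return False


def purge_reads(
    pairs: Sequence[ReadPair], index: ContaminantIndex
) -> tuple[list[ReadPair], PurgeReport]:
    """Remove pairs where either mate shares a canonical k-mer with the index.

    Removal is pair-level: a single matching mate purges both, since an
    orphaned host mate cannot be used for paired-end re-assembly. Reads
    shorter than k can never match and are always kept.
    """
    kept: list[ReadPair] = []
    removed = 0
    for pair in pairs:
        if _read_matches(pair.mate1.sequence, index) or _read_matches(
            pair.mate2.sequence, index
        ):
            removed += 1
        else:
            kept.append(pair)
    return kept, PurgeReport(reads_removed=removed, reads_kept=len(kept))


def screen_by_reference(
    contigs: Sequence[Contig],
    references: Sequence[Contig],
    k: int = 31,
    containment_threshold: float = 0.5,
) -> tuple[list[Contig], list[str]]:
    """Flag contigs whose k-mer containment in the reference set is high.

    Containment = (contig k-mers present in the reference) / (contig k-mer
    count). Contigs shorter than ``k`` have no k-mers, are never flagged,
    and trigger a warning.
    """
    if not references:
        raise ValueError("screen_by_reference requires a non-empty reference set")
    ref_kmers: set[str] = set()
    for r in references:
        ref_kmers.update(_kmers(r.sequence, k))
    retained: list[Contig] = []
    flagged: list[str] = []
    for c in contigs:
        kmers = list(_kmers(c.sequence, k))
        if not kmers:
            logger.warning(
                "contig %s shorter than k=%d: cannot be screened, retained", c.id, k
            )
            retained.append(c)
            continue
        shared = sum(1 for km in kmers if km in ref_kmers)
        if shared / len(kmers) >= containment_threshold:
            flagged.append(c.id)
        else:
            retained.append(c)
    return retained, flagged


def decontaminate(
    contigs: Sequence[Contig],
    pairs: Sequence[ReadPair],
    references: Sequence[Contig] = (),
    depth_threshold: float = 50.0,
    k: int = 87,
    screen_k: int = 31,
    containment_threshold: float = 0.5,
) -> tuple[list[ReadPair], list[Contig], PurgeReport]:
    """Full two-stage decontamination.

    Returns the purged read pairs, the contig set surviving both the depth
    flagging and the reference screen, and a combined report.
    """
    depth_flagged = set(flag_by_depth(contigs, depth_threshold))
    clean_pairs: list[ReadPair] = list(pairs)
    report = PurgeReport(reads_removed=0, reads_kept=len(clean_pairs))
    if depth_flagged:
        contaminant = [c for c in contigs if c.id in depth_flagged]
        index = build_index(contaminant, k=k)
        clean_pairs, report = purge_reads(clean_pairs, index)
    survivors = [c for c in contigs if c.id not in depth_flagged]
    ref_flagged: list[str] = []
    if references:
        survivors, ref_flagged = screen_by_reference(
            survivors, references, k=screen_k, containment_threshold=containment_threshold
        )
    report.contigs_flagged_by_depth = sorted(depth_flagged)
    report.contigs_flagged_by_reference = ref_flagged
    return clean_pairs, survivors, report
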