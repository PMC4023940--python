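"""Raw paired-end read filtering and sequencing-quality summaries.

A read pair survives filtering only if, after adapter trimming, *both*
mates pass every rule: at most 10% of bases below Q20, at most 10% N
bases, and a minimum post-trim length. This pair-level behaviour matches
what paired-end de novo assembly requires — an orphaned mate is useless
to the assembler.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence


@dataclass
class Read:
    """One mate: sequence over {A,C,G,T,N} with per-base Phred qualities."""

    name: str
    sequence: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.name!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )


@dataclass
class ReadPair:
    mate1: Read
    mate2: Read


@dataclass
class QcReport:
    """Sequencing-run quality summary.

    effective_rate -- clean reads / raw reads x 100
    q20, q30       -- percent of clean bases with Phred >= 20 / >= 30
    gc_percent     -- percent G+C among clean non-N bases
    mean_error_rate -- mean per-base error probability of clean bases, in percent
    """

    raw_pairs: int
    clean_pairs: int
    effective_rate: float
    q20: float
    q30: float
    gc_percent: float
    mean_error_rate: float

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def effective_rate(raw_reads: int, clean_reads: int) -> float:
    """Percent of raw reads surviving filtering (clean/raw x 100)."""
    if raw_reads <= 0:
        raise ValueError("raw_reads must be positive")
    return 100.0 * clean_reads / raw_reads


def trim_adapter(read: Read, adapters: Sequence[str], min_overlap: int = 10) -> Read:
    """Remove adapter read-through from the 3' end of a mate.

    The longest suffix of the read exactly matching a prefix of any adapter,
    with at least ``min_overlap`` bp of overlap, is removed. Exact matching
    keeps the behaviour fully deterministic and testable.
    """
    best = 0
    seq = read.sequence.upper()
    for adapter in adapters:
        a = adapter.upper()
        for ov in range(min(len(seq), len(a)), min_overlap - 1, -1):
            if ov <= best:
                break
            if seq.endswith(a[:ov]):
                best = ov
                break
    if best == 0:
        return read
    keep = len(seq) - best
    return Read(read.name, read.sequence[:keep], read.qualities[:keep])


def _mate_fails(read: Read, q_threshold: int, low_q_frac: float, n_frac: float,
                min_len: int) -> bool:
    n = len(read.sequence)
    if n < min_len:
        return True
    low_q = sum(1 for q in read.qualities if q < q_threshold)
    if low_q / n > low_q_frac:
        return True
    if read.sequence.upper().count("N") / n > n_frac:
        return True
    return False


def filter_read_pair(
    pair: ReadPair,
    adapters: Sequence[str] = (),
    q_threshold: int = 20,
    low_q_frac: float = 0.10,
    n_frac: float = 0.10,
    min_len_after_trim: int = 36,
) -> tuple[bool, ReadPair]:
    """Adapter-trim both mates, then decide keep (True) or drop (False).

    The pair is dropped if *either* mate, after trimming, has more than
    ``low_q_frac`` of its bases below ``q_threshold``, more than ``n_frac``
    N bases, or fewer than ``min_len_after_trim`` bases. The decision is
    symmetric in the two mates.
    """
    if not 0 < low_q_frac <= 1 or not 0 < n_frac <= 1:
        raise ValueError("fraction thresholds must lie in (0, 1]")
    m1 = trim_adapter(pair.mate1, adapters) if adapters else pair.mate1
    m2 = trim_adapter(pair.mate2, adapters) if adapters else pair.mate2
    trimmed = ReadPair(m1, m2)
    for mate in (m1, m2):
        if _mate_fails(mate, q_threshold, low_q_frac, n_frac, min_len_after_trim):
            return False, trimmed
    return True, trimmed


def filter_pairs(pairs: Iterable[ReadPair], **kwargs) -> list[ReadPair]:
    """Apply :func:`filter_read_pair` to a collection, keeping survivors."""
    kept = []
    for pair in pairs:
        keep, trimmed = filter_read_pair(pair, **kwargs)
        if keep:
            kept.append(trimmed)
    return kept


def qc_summary(raw_pairs: int, clean_pairs: Sequence[ReadPair]) -> QcReport:
    """Summarise a filtered read set against its raw input count.

    Base-level statistics (Q20, Q30, GC, mean error rate) are computed over
    the clean bases only; the mean error rate converts each Phred score Q
    back to its error probability 10^(-Q/10).
    """
    if raw_pairs <= 0:
        raise ValueError("at least one raw pair is required")
    n_bases = 0
    q20 = q30 = gc = n_count = 0
    err_sum = 0.0
    for pair in clean_pairs:
        for mate in (pair.mate1, pair.mate2):
            seq = mate.sequence.upper()
            n_bases += len(seq)
            gc += seq.count("G") + seq.count("C")
            n_count += seq.count("N")
            for q in mate.qualities:
                if q >= 20:
                    q20 += 1
                if q >= 30:
                    q30 += 1
                err_sum += 10.0 ** (-q / 10.0)
    denom_gc = n_bases - n_count
    return QcReport(
        raw_pairs=raw_pairs,
        clean_pairs=len(clean_pairs),
        effective_rate=effective_rate(raw_pairs, len(clean_pairs)),
        q20=100.0 * q20 / n_bases if n_bases else 0.0,
        q30=100.0 * q30 / n_bases if n_bases else 0.0,
        gc_percent=100.0 * gc / denom_gc if denom_gc else 0.0,
        mean_error_rate=100.0 * err_sum / n_bases if n_bases else 0.0,
    )


# ---------------------------------------------------------------------------
# FASTQ I/O (Phred+33). Plain text or gzip, inferred from the file name.

def _open(path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path) -> Iterator[Read]:
    """Iterate Phred+33 FASTQ records; raises on malformed records."""
    with _open(path, "r") as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"malformed FASTQ record at index {idx} in {path}")
            if len(seq) != len(qual):
                raise ValueError(
                    f"malformed FASTQ record at index {idx} in {path}: "
                    "sequence/quality length mismatch"
                )
            yield Read(header[1:].strip(), seq, [ord(c) - 33 for c in qual])
            idx += 1


def write_fastq(reads: Iterable[Read], path) -> None:
    with _open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{qual}\n")


def read_fastq_pairs(path1, path2) -> Iterator[ReadPair]:
    it1, it2 = read_fastq(path1), read_fastq(path2)
    for m1, m2 in zip(it1, it2):
        yield ReadPair(m1, m2)
    if next(it1, None) is not None or next(it2, None) is not None:
        raise ValueError("paired FASTQ files have unequal record counts")


def write_fastq_pairs(pairs: Iterable[ReadPair], path1, path2) -> None:
    pairs = list(pairs)
    write_fastq((p.mate1 for p in pairs), path1)
    write_fastq((p.mate2 for p in pairs), path2)
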