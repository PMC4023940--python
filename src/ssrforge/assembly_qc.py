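"""Contig-level assembly statistics and filters.

Covers the usual de novo assembly QC surface: minimum-length filtering,
N50/N90, base composition, and the per-contig depth-vs-GC table used to
spot endosymbiont contamination (bacterial contigs stand out at higher GC
and elevated depth).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO

from ._util import DNA_N, gc_fraction


@dataclass
class Contig:
    """Assembled contig with its mean fold-coverage annotation."""

    id: str
    sequence: str
    depth: float = 0.0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"contig {self.id!r} has empty sequence")
        if self.depth < 0:
            raise ValueError(f"contig {self.id!r} has negative depth")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AssemblyReport:
    total_length: int
    n_contigs: int
    n50: int
    n90: int
    gc_percent: float
    base_counts: dict = field(default_factory=dict)
    base_percents: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def length_filter(contigs: Sequence[Contig], min_len: int = 500) -> list[Contig]:
    """Retain contigs of at least ``min_len`` bp, preserving order.

    Contigs *shorter than* the threshold are removed; a contig exactly at
    the threshold is kept.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return [c for c in contigs if len(c) >= min_len]


def nxx(contigs: Sequence[Contig], fraction: float) -> int:
    """Nxx statistic: e.g. ``nxx(contigs, 0.5)`` is the N50.

    The contig length at which the cumulative length of contigs, sorted in
    descending length order, first reaches ``fraction`` of the total length.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if not contigs:
        raise ValueError("nxx undefined for an empty contig set")
    lengths = sorted((len(c) for c in contigs), reverse=True)
    target = fraction * sum(lengths)
    acc = 0
    for length in lengths:
        acc += length
        if acc >= target:
            return length
    raise AssertionError("unreachable: cumulative sum must reach total")


def base_composition(contigs: Sequence[Contig]) -> AssemblyReport:
    """Full assembly report: totals, N50/N90, base counts and percents.

    N bases count toward total length but are excluded from the GC
    numerator (GC percent is 100*(C+G)/total_length, mirroring how
    assembly reports tabulate base content).
    """
    if not contigs:
        raise ValueError("base_composition requires at least one contig")
    counts = {b: 0 for b in "ACGTN"}
    for c in contigs:
        seq = c.sequence.upper()
        for pos, ch in enumerate(seq):
            if ch not in DNA_N:
                raise ValueError(
                    f"invalid base {ch!r} in contig {c.id!r} at position {pos + 1}"
                )
            counts[ch] += 1
    total = sum(counts.values())
    percents = {b: 100.0 * n / total for b, n in counts.items()}
    return AssemblyReport(
        total_length=total,
        n_contigs=len(contigs),
        n50=nxx(contigs, 0.5),
        n90=nxx(contigs, 0.9),
        gc_percent=100.0 * (counts["G"] + counts["C"]) / total,
        base_counts=counts,
        base_percents=percents,
    )


def base_percent(base_counts: dict, base: str) -> float:
    """Percent of the genome made of ``base`` (or e.g. ``"GC"``), from raw counts."""
    total = sum(base_counts.values())
    if total <= 0:
        raise ValueError("base counts sum to zero")
    return 100.0 * sum(base_counts.get(b, 0) for b in base.upper()) / total


def depth_gc_table(contigs: Sequence[Contig]) -> list[tuple[str, float, float]]:
    """Per-contig (id, gc_fraction, depth) records; GC over non-N bases."""
    return [(c.id, gc_fraction(c.sequence), c.depth) for c in contigs]


# ---------------------------------------------------------------------------
# FASTA + depth-table I/O

def read_fasta(path, depths: dict[str, float] | None = None) -> list[Contig]:
    depths = depths or {}
    return [
        Contig(rec.id, str(rec.seq).upper(), depths.get(rec.id, 0.0))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(contigs: Iterable[Contig], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id}\n")
            for i in range(0, len(c.sequence), width):
                fh.write(c.sequence[i : i + width] + "\n")


def read_depth_tsv(path) -> dict[str, float]:
    """Two-column TSV (contig_id, mean depth); '#' comment lines ignored."""
    depths: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cid, depth = line.split("\t")[:2]
            depths[cid] = float(depth)
    return depths


def write_depth_tsv(contigs: Iterable[Contig], path) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f"{c.id}\t{c.depth:.4f}\n")
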