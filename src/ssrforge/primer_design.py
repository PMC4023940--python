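"""Deterministic primer-pair design over SSR flanks.

A transparent, exhaustively-enumerated subset of the constraint set a
Primer3-style designer applies: primer length 18-27 bp, melting
temperature window with an optimum, GC-content window, product-size
range, a cap on the Tm difference between the mates, and no homopolymer
run of five or more identical bases inside a primer. Melting temperature
uses the classic salt-free Wallace/Marmur-style linear formula

    Tm = 81.5 + 0.41 * GC% - 675 / length

which is monotone in GC and length, adequate for ranking candidates, and
exactly reproducible; nearest-neighbor thermodynamics are deliberately
out of scope. Given the same locus, sequence and constraints the design
is a pure function: re-running it is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from ._util import revcomp
from .ssr_scan import SSRLocus


@dataclass(frozen=True)
class PrimerConstraints:
    """Design constraints; defaults bracket typical SSR genotyping assays."""

    min_len: int = 18
    max_len: int = 27
    tm_min: float = 57.0
    tm_max: float = 63.0
    tm_opt: float = 60.0
    gc_min: float = 20.0
    gc_max: float = 80.0
    product_min: int = 80
    product_max: int = 280
    product_opt: int = 180
    max_tm_diff: float = 3.0
    max_homopolymer: int = 4
    flank_window: int = 300  # how far from the SSR tract to search


@dataclass(frozen=True)
class PrimerPair:
    """A designed pair; coordinates are 1-based on the contig's forward strand.

    ``reverse`` is given 5'->3' on the reverse strand; ``reverse_start`` is
    the forward-strand coordinate of its 3'-most base (the left end of the
    binding site).
    """

    locus: SSRLocus
    forward: str
    reverse: str
    forward_start: int
    reverse_start: int
    product_size: int
    tm_forward: float
    tm_reverse: float
    gc_forward: float
    gc_reverse: float

    @property
    def annealing_suggestion(self) -> int:
        """Heuristic PCR annealing temperature: min primer Tm minus 5, rounded."""
        return round(min(self.tm_forward, self.tm_reverse) - 5)


@dataclass
class DesignFailure:
    """Why no pair could be designed, as per-constraint rejection counts."""

    locus: SSRLocus
    reasons: dict = field(default_factory=dict)


def gc_percent(seq: str) -> float:
    s = seq.upper()
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def melting_temp(primer: str) -> float:
    """Salt-free linear Tm estimate in deg C; requires >= 14 bases over ACGT."""
    if len(primer) < 14:
        raise ValueError("melting_temp requires length >= 14")
    if any(c not in "ACGT" for c in primer.upper()):
        raise ValueError("melting_temp requires bases in {A,C,G,T}")
    return 81.5 + 0.41 * gc_percent(primer) - 675.0 / len(primer)


def _has_long_run(seq: str, max_run: int) -> bool:
    run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        if run > max_run:
            return True
    return False


def _candidates(flank: str, c: PrimerConstraints, reasons: dict) -> list[tuple[int, str, float]]:
    """All windows of ``flank`` passing the single-primer constraints.

    Returns (offset, sequence, tm) triples; offset is 0-based within flank.
    """
    out = []
    n = len(flank)
    for length in range(c.min_len, c.max_len + 1):
        for i in range(n - length + 1):
            window = flank[i : i + length]
            if "N" in window:
                reasons["n_bases"] = reasons.get("n_bases", 0) + 1
                continue
            gc = gc_percent(window)
            if not c.gc_min <= gc <= c.gc_max:
                reasons["gc_window"] = reasons.get("gc_window", 0) + 1
                continue
            if _has_long_run(window, c.max_homopolymer):
                reasons["homopolymer"] = reasons.get("homopolymer", 0) + 1
                continue
            tm = melting_temp(window)
            if not c.tm_min <= tm <= c.tm_max:
                reasons["tm_window"] = reasons.get("tm_window", 0) + 1
                continue
            out.append((i, window, tm))
    return out


def design_primers(
    locus: SSRLocus,
    sequence: str,
    constraints: PrimerConstraints | None = None,
) -> PrimerPair | DesignFailure:
    """Best feasible primer pair flanking ``locus``, or a DesignFailure.

    Forward candidates are enumerated in the left flank and reverse
    candidates (reverse-complemented) in the right flank; neither primer
    overlaps the SSR tract. Among all pairs satisfying the product-size
    and Tm-difference constraints the returned pair minimises

        |tm_f - tm_opt| + |tm_r - tm_opt| + |product - product_opt| / 50

    with ties broken by smaller product, then leftmost forward start.
    """
    c = constraints or PrimerConstraints()
    seq = sequence.upper()
    reasons: dict = {}

    left_lo = max(0, locus.start - 1 - c.flank_window)
    left = seq[left_lo : locus.start - 1]
    right_lo = locus.end  # 0-based offset of first base right of the tract
    right = seq[right_lo : right_lo + c.flank_window]

    fwd = _candidates(left, c, reasons)
    # reverse primer binds the forward-strand window; its sequence is the revcomp
    rev = [(i, revcomp(w), tm) for i, w, tm in _candidates(right, c, reasons)]
    if not fwd or not rev:
        reasons.setdefault("no_candidate_side", 0)
        reasons["no_candidate_side"] += (not fwd) + (not rev)
        return DesignFailure(locus, reasons)

    best = None
    best_key = None
    for fi, fseq, ftm in fwd:
        f_start0 = left_lo + fi
        for ri, rseq, rtm in rev:
            if abs(ftm - rtm) > c.max_tm_diff:
                reasons["tm_diff"] = reasons.get("tm_diff", 0) + 1
                continue
            r_end0 = right_lo + ri + len(rseq) - 1
            product = r_end0 - f_start0 + 1
            if not c.product_min <= product <= c.product_max:
                reasons["product_size"] = reasons.get("product_size", 0) + 1
                continue
            score = (
                abs(ftm - c.tm_opt)
                + abs(rtm - c.tm_opt)
                + abs(product - c.product_opt) / 50.0
            )
            key = (score, product, f_start0)
            if best_key is None or key < best_key:
                best_key = key
                best = PrimerPair(
                    locus=locus,
                    forward=fseq,
                    reverse=rseq,
                    forward_start=f_start0 + 1,
                    reverse_start=right_lo + ri + 1,
                    product_size=product,
                    tm_forward=ftm,
                    tm_reverse=rtm,
                    gc_forward=gc_percent(fseq),
                    gc_reverse=gc_percent(rseq),
                )
    if best is None:
        return DesignFailure(locus, reasons)
    return best


def design_for_loci(
    loci: Sequence[SSRLocus],
    contigs,
    constraints: PrimerConstraints | None = None,
) -> tuple[list[PrimerPair], list[DesignFailure]]:
    """Design one pair per locus; split results into successes and failures."""
    seqs = {c.id: c.sequence.upper() for c in contigs}
    pairs: list[PrimerPair] = []
    failures: list[DesignFailure] = []
    for locus in loci:
        result = design_primers(locus, seqs[locus.contig_id], constraints)
        if isinstance(result, PrimerPair):
            pairs.append(result)
        else:
            failures.append(result)
    return pairs, failures


def primers_to_tsv(pairs: Sequence[PrimerPair], path) -> None:
    """Marker-table TSV: name, primer sequences, product size, suggested Ta."""
    with open(path, "w") as fh:
        fh.write("name\tforward\treverse\tproduct_size\tta\tcontig\tmotif\trepeats\n")
        for i, p in enumerate(pairs, 1):
            l = p.locus
            fh.write(
                f"SSR{i}\t{p.forward}\t{p.reverse}\t{p.product_size}\t"
                f"{p.annealing_suggestion}\t{l.contig_id}\t{l.motif}\t{l.repeat_count}\n"
            )


def polymorphic_rate(tested: int, polymorphic: int) -> float:
    """Percent of screened primer pairs that proved polymorphic."""
    if tested <= 0:
        raise ValueError("tested must be positive")
    if not 0 <= polymorphic <= tested:
        raise ValueError("polymorphic count must lie in [0, tested]")
    return 100.0 * polymorphic / tested
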