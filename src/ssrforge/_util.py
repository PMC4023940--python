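"""Small sequence helpers shared across modules."""

from __future__ import annotations

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA = frozenset("ACGT")
DNA_N = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N} (case preserved)."""
    return seq.translate(_COMP)[::-1]


def gc_fraction(seq: str, *, exclude_n: bool = True) -> float:
    """GC fraction of ``seq``.

    N bases are excluded from both numerator and denominator by default;
    an all-N (or empty) sequence has GC 0 by convention.
    """
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    denom = len(s) - s.count("N") if exclude_n else len(s)
    return gc / denom if denom else 0.0


def canonical_kmer(kmer: str) -> str:
    """Lexicographic min of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def validate_dna(seq: str, allow_n: bool = True) -> int:
    """Return the index of the first invalid character, or -1 if clean."""
    alphabet = DNA_N if allow_n else DNA
    for i, c in enumerate(seq.upper()):
        if c not in alphabet:
            return i
    return -1
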