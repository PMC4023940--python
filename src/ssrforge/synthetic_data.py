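"""Synthetic fixtures for the marker-development pipeline.

Three generators emulate the data the pipeline consumes, each with a
ground-truth sidecar so downstream stages can be tested for exact
recovery:

* :func:`make_genome` — an A/T-rich host genome (default 36.5% GC, the
  composition typical of the adzuki bean weevil assembly) carrying
  planted perfect SSRs at known coordinates. Background sequence is
  rejection-resampled until the SSR scanner finds exactly the planted
  loci, so truth tables are exact by construction.
* :func:`simulate_reads` — paired 150 bp reads with Phred+33 qualities
  at a chosen fold-coverage, optionally mixed with reads from a distinct
  higher-GC "endosymbiont" genome present at elevated depth (the
  *Wolbachia*-style contamination signature), with per-pair host /
  contaminant truth labels.
* :func:`simulate_genotypes` — multi-population diploid genotype tables
  under the Balding-Nichols model: per-population allele frequencies are
  Dirichlet-distributed around shared ancestral frequencies with
  concentration (1 - Fst)/Fst, and genotypes are two independent draws
  (random mating). Fst = 0 collapses every population onto the
  ancestral frequencies.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._util import revcomp
from .assembly_qc import Contig
from .read_qc import Read, ReadPair
from .ssr_scan import SSRLocus, canonical_motif, is_primitive, scan_sequence

#: Sampling-site codes of an 18-population C. chinensis survey design,
#: used as default population labels.
POPULATION_CODES = [
    "BB", "BD", "DX", "DZ", "HF", "HH", "JC", "LC", "LL",
    "LS", "MC", "QD", "QJ", "RD", "TS", "UM", "XY", "YY",
]


# ---------------------------------------------------------------------------
# Genome with planted SSRs

@dataclass
class GenomeSpec:
    """Host-genome recipe: contig sizes, GC target and planted SSRs.

    ``planted_ssrs`` entries are (motif, repeat_count, contig_index,
    offset) with a 0-based offset of the repeat tract start. Tracts must
    not overlap and must sit at least ``edge_margin`` bp from contig ends
    so primer flanks exist.
    """

    n_contigs: int = 4
    min_len: int = 2000
    max_len: int = 5000
    gc_target: float = 0.365
    planted_ssrs: list[tuple[str, int, int, int]] = field(default_factory=list)
    seed: int = 0
    edge_margin: int = 250

    def __post_init__(self) -> None:
        if self.n_contigs < 1 or self.min_len < 1 or self.max_len < self.min_len:
            raise ValueError("invalid contig count or length range")
        if not 0.0 <= self.gc_target <= 1.0:
            raise ValueError("gc_target must lie in [0, 1]")
        spans: dict[int, list[tuple[int, int]]] = {}
        for motif, reps, ci, off in self.planted_ssrs:
            motif = motif.upper()
            if not (1 <= len(motif) <= 6) or any(c not in "ACGT" for c in motif):
                raise ValueError(f"invalid motif {motif!r}")
            if not is_primitive(motif):
                raise ValueError(f"motif {motif!r} is not primitive")
            if not 0 <= ci < self.n_contigs:
                raise ValueError(f"contig index {ci} out of range")
            tract = len(motif) * reps
            if off < self.edge_margin or off + tract > self.min_len - self.edge_margin:
                raise ValueError(
                    f"planted SSR at contig {ci} offset {off} violates the "
                    f"{self.edge_margin} bp edge margin for the shortest contig"
                )
            for s, e in spans.setdefault(ci, []):
                if off < e and s < off + tract:
                    raise ValueError(f"planted SSRs overlap on contig {ci}")
            spans[ci].append((off, off + tract))


def _random_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=probs)


def make_genome(spec: GenomeSpec, max_tries: int = 200) -> tuple[list[Contig], list[SSRLocus]]:
    """Generate host contigs and the exact truth table of planted SSRs.

    Each contig is resampled until (a) its background GC is within 2
    percentage points of the target and (b) the SSR scanner reports
    exactly the planted loci — no chance background repeat and no
    accidental extension of a planted tract.
    """
    rng = np.random.default_rng(spec.seed)
    lengths = [int(rng.integers(spec.min_len, spec.max_len + 1)) for _ in range(spec.n_contigs)]
    by_contig: dict[int, list[tuple[str, int, int]]] = {}
    for motif, reps, ci, off in spec.planted_ssrs:
        by_contig.setdefault(ci, []).append((motif.upper(), reps, off))

    contigs: list[Contig] = []
    truth: list[SSRLocus] = []
    for ci in range(spec.n_contigs):
        length = lengths[ci]
        planted = sorted(by_contig.get(ci, []), key=lambda t: t[2])
        expected = [
            SSRLocus(
                contig_id=f"contig_{ci}",
                start=off + 1,
                end=off + len(motif) * reps,
                motif=motif,
                canonical=canonical_motif(motif),
                repeat_count=reps,
            )
            for motif, reps, off in planted
        ]
        for _ in range(max_tries):
            arr = _random_background(rng, length, spec.gc_target)
            seq = arr.tobytes().decode()
            gc_bg = (seq.count("G") + seq.count("C")) / length
            if abs(gc_bg - spec.gc_target) > 0.02:
                continue
            for motif, reps, off in planted:
                tract = motif * reps
                seq = seq[:off] + tract + seq[off + len(tract):]
            found = scan_sequence(seq, contig_id=f"contig_{ci}")
            if found == expected:
                contigs.append(Contig(id=f"contig_{ci}", sequence=seq))
                truth.extend(expected)
                break
        else:
            raise RuntimeError(
                f"could not realise contig {ci}: planted SSRs too dense or "
                f"spec infeasible after {max_tries} resampling attempts"
            )
    return contigs, truth


# ---------------------------------------------------------------------------
# Paired reads with optional endosymbiont contamination

@dataclass
class ErrorProfile:
    """Flat sequencing-error model: constant Phred quality, uniform
    substitution errors at ``error_rate`` (0 gives error-free reads)."""

    mean_q: int = 33
    error_rate: float = 0.0005

    @classmethod
    def error_free(cls) -> "ErrorProfile":
        return cls(mean_q=40, error_rate=0.0)


@dataclass
class ContaminationSpec:
    """Endosymbiont contamination recipe.

    The contaminant genome is generated from ``seed`` at ``contaminant_gc``
    (distinct from the host's A/T-rich composition) and sequenced at
    ``contaminant_depth_multiplier`` times the host depth — the elevated-
    depth, shifted-GC signature by which such contigs are flagged. When
    ``contaminant_fraction_of_reads`` is set it overrides the pair count
    implied by the depth multiplier.
    """

    contaminant_gc: float = 0.55
    contaminant_depth_multiplier: float = 5.0
    contaminant_fraction_of_reads: float | None = None
    genome_length: int = 20000
    n_contigs: int = 2
    min_gc_margin: float = 0.10

    def validate(self, host_gc: float) -> None:
        if not 0.0 <= self.contaminant_gc <= 1.0:
            raise ValueError("contaminant_gc must lie in [0, 1]")
        if self.contaminant_fraction_of_reads is not None and not (
            0.0 <= self.contaminant_fraction_of_reads <= 1.0
        ):
            raise ValueError("contaminant_fraction_of_reads must lie in [0, 1]")
        if abs(self.contaminant_gc - host_gc) < self.min_gc_margin:
            raise ValueError(
                f"contaminant GC {self.contaminant_gc} within {self.min_gc_margin} "
                f"of host GC {host_gc}: clusters would not separate"
            )


@dataclass
class ReadSimResult:
    pairs: list[ReadPair]
    labels: list[str]  # "host" | "contaminant", aligned with pairs
    contaminant_contigs: list[Contig]
    host_depths: dict[str, float]
    contaminant_depths: dict[str, float]

    def contaminated_assembly(self) -> list[Contig]:
        """Host + contaminant contigs with their exact simulated depths."""
        out = [
            Contig(c.id, c.sequence, self.host_depths.get(c.id, 0.0))
            for c in self._host_contigs
        ]
        out += [
            Contig(c.id, c.sequence, self.contaminant_depths.get(c.id, 0.0))
            for c in self.contaminant_contigs
        ]
        return out

    _host_contigs: list[Contig] = field(default_factory=list)


def _sample_pairs(
    rng: np.random.Generator,
    contigs: Sequence[Contig],
    n_pairs: int,
    read_len: int,
    insert_size: int,
    profile: ErrorProfile,
    prefix: str,
) -> tuple[list[ReadPair], dict[str, float]]:
    lengths = np.array([len(c) for c in contigs], dtype=float)
    for c in contigs:
        if read_len > len(c):
            raise ValueError(f"read_len {read_len} exceeds contig {c.id!r} ({len(c)} bp)")
    weights = lengths / lengths.sum()
    covered = {c.id: 0 for c in contigs}
    pairs: list[ReadPair] = []
    choices = rng.choice(len(contigs), size=n_pairs, p=weights)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    for i, ci in enumerate(choices):
        contig = contigs[int(ci)]
        frag_len = min(insert_size, len(contig))
        start = int(rng.integers(0, len(contig) - frag_len + 1))
        frag = contig.sequence[start : start + frag_len]
        m1 = frag[:read_len]
        m2 = revcomp(frag[-read_len:])
        if profile.error_rate > 0:
            m1 = _inject_errors(rng, m1, profile.error_rate, bases)
            m2 = _inject_errors(rng, m2, profile.error_rate, bases)
        quals = [profile.mean_q] * read_len
        name = f"{prefix}_{i}"
        pairs.append(
            ReadPair(Read(name + "/1", m1, list(quals)), Read(name + "/2", m2, list(quals)))
        )
        covered[contig.id] += 2 * read_len
    depths = {c.id: covered[c.id] / len(c) for c in contigs}
    return pairs, depths


def _inject_errors(rng, seq: str, rate: float, bases) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        alternatives = bases[bases != arr[i]]
        arr[i] = alternatives[int(rng.integers(0, len(alternatives)))]
    return arr.tobytes().decode()


def simulate_reads(
    contigs: Sequence[Contig],
    contamination: ContaminationSpec | None = None,
    read_len: int = 150,
    depth: float = 20.0,
    error_profile: ErrorProfile | None = None,
    insert_size: int = 300,
    seed: int = 0,
) -> ReadSimResult:
    """Simulate paired reads over ``contigs``, optionally contaminated.

    Host pair count is depth * genome_length / (2 * read_len); contaminant
    pairs are drawn from a generated endosymbiont genome at depth *
    contaminant_depth_multiplier. Pairs are shuffled host/contaminant but
    every pair keeps a truth label.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    profile = error_profile or ErrorProfile()
    rng = np.random.default_rng(seed)
    total = sum(len(c) for c in contigs)
    n_host = max(1, round(depth * total / (2 * read_len)))

    host_pairs, host_depths = _sample_pairs(
        rng, contigs, n_host, read_len, insert_size, profile, "host"
    )

    cont_pairs: list[ReadPair] = []
    cont_depths: dict[str, float] = {}
    cont_contigs: list[Contig] = []
    if contamination is not None:
        host_gc = sum(c.sequence.count("G") + c.sequence.count("C") for c in contigs) / total
        contamination.validate(host_gc)
        per_len = contamination.genome_length // contamination.n_contigs
        for j in range(contamination.n_contigs):
            arr = _random_background(rng, per_len, contamination.contaminant_gc)
            cont_contigs.append(Contig(id=f"endo_{j}", sequence=arr.tobytes().decode()))
        if contamination.contaminant_fraction_of_reads is not None:
            f = contamination.contaminant_fraction_of_reads
            n_cont = 0 if f == 0 else round(n_host * f / (1 - f)) if f < 1 else n_host
        else:
            cont_depth = depth * contamination.contaminant_depth_multiplier
            n_cont = round(cont_depth * contamination.genome_length / (2 * read_len))
        if n_cont > 0:
            cont_pairs, cont_depths = _sample_pairs(
                rng, cont_contigs, n_cont, read_len, insert_size, profile, "endo"
            )
        else:
            cont_depths = {c.id: 0.0 for c in cont_contigs}

    pairs = host_pairs + cont_pairs
    labels = ["host"] * len(host_pairs) + ["contaminant"] * len(cont_pairs)
    order = rng.permutation(len(pairs))
    result = ReadSimResult(
        pairs=[pairs[i] for i in order],
        labels=[labels[i] for i in order],
        contaminant_contigs=cont_contigs,
        host_depths=host_depths,
        contaminant_depths=cont_depths,
    )
    result._host_contigs = list(contigs)
    return result


def write_truth_labels(result: ReadSimResult, path) -> None:
    """Sidecar TSV of per-pair truth labels (pair name, host|contaminant)."""
    with open(path, "w") as fh:
        fh.write("pair\tlabel\n")
        for pair, label in zip(result.pairs, result.labels):
            fh.write(f"{pair.mate1.name.rsplit('/', 1)[0]}\t{label}\n")


# ---------------------------------------------------------------------------
# Multi-population genotype tables (Balding-Nichols)

@dataclass
class PopulationModel:
    """Sampling design and differentiation level for genotype simulation.

    Defaults mirror a typical 18-site survey: 18 populations of 20
    diploid individuals scored at 20 loci with about 8 alleles each, and
    moderate structure (Fst = 0.1).
    """

    n_populations: int = 18
    n_individuals_per_pop: int = 20
    n_loci: int = 20
    n_alleles_per_locus: int = 8
    fst: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_populations, self.n_individuals_per_pop, self.n_loci) < 1:
            raise ValueError("counts must be >= 1")
        if self.n_alleles_per_locus < 1:
            raise ValueError("n_alleles_per_locus must be >= 1")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must lie in [0, 1)")

    def population_labels(self) -> list[str]:
        if self.n_populations <= len(POPULATION_CODES):
            return POPULATION_CODES[: self.n_populations]
        return [f"P{i + 1:02d}" for i in range(self.n_populations)]


def simulate_genotypes(model: PopulationModel):
    """Genotype table plus true ancestral and per-population frequencies.

    Returns ``(table, ancestral, per_pop)`` where ``ancestral[locus]`` is
    the shared ancestral allele-frequency vector and
    ``per_pop[locus][pop]`` the Balding-Nichols per-population vector the
    genotypes were drawn from.
    """
    from .popgen import GenotypeTable  # local import to avoid cycle

    rng = np.random.default_rng(model.seed)
    pops = model.population_labels()
    loci = [f"L{i + 1:03d}" for i in range(model.n_loci)]
    k = model.n_alleles_per_locus

    ancestral: dict[str, np.ndarray] = {}
    per_pop: dict[str, dict[str, np.ndarray]] = {}
    calls: dict[str, list[dict]] = {p: [dict() for _ in range(model.n_individuals_per_pop)] for p in pops}

    for locus in loci:
        p_anc = rng.dirichlet(np.ones(k)) if k > 1 else np.array([1.0])
        ancestral[locus] = p_anc
        per_pop[locus] = {}
        for pop in pops:
            if model.fst == 0.0 or k == 1:
                p = p_anc.copy()
            else:
                conc = (1.0 - model.fst) / model.fst
                p = rng.dirichlet(np.maximum(p_anc * conc, 1e-9))
            per_pop[locus][pop] = p
            draws = rng.choice(k, size=(model.n_individuals_per_pop, 2), p=p)
            for i in range(model.n_individuals_per_pop):
                a1, a2 = int(draws[i, 0]) + 1, int(draws[i, 1]) + 1
                calls[pop][i][locus] = (min(a1, a2), max(a1, a2))

    table = GenotypeTable(populations=pops, loci=loci, calls=calls)
    return table, ancestral, per_pop
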