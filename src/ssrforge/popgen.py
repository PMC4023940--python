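"""Population diversity statistics for co-dominant (microsatellite) markers.

Implements the classic marker-assessment toolkit: per-locus allele counts
(Na), expected heterozygosity / gene diversity (He = 1 - sum p_a^2, with
an optional small-sample 2N/(2N-1) correction), observed heterozygosity
(Ho), Shannon's information index (I = -sum p ln p, natural log), Nei's
(1972) standard genetic distance between populations

    D = -ln( Jxy / sqrt(Jx * Jy) )

with the J terms averaged over loci, and a Saitou-Nei neighbor-joining
dendrogram over the resulting distance matrix, exported as Newick.

Genotype data is exchanged in GenePop format, the lingua franca for
multi-population diploid marker tables.
"""

from __future__ import annotations

import io
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

Genotype = tuple[int, int] | None  # unordered allele pair; None = missing


@dataclass
class GenotypeTable:
    """Diploid calls for (population, individual, locus).

    ``calls[pop]`` is a list of individuals; each individual is a dict
    mapping locus name to an unordered allele pair, or ``None`` for a
    missing call. Allele labels are positive integers.
    """

    populations: list[str]
    loci: list[str]
    calls: dict[str, list[dict[str, Genotype]]]

    def __post_init__(self) -> None:
        if not self.populations or not self.loci:
            raise ValueError("need at least one population and one locus")
        for pop in self.populations:
            for ind in self.calls[pop]:
                for locus, g in ind.items():
                    if g is not None and (g[0] < 1 or g[1] < 1):
                        raise ValueError(
                            f"allele labels must be positive ({pop}/{locus}: {g})"
                        )

    def n_individuals(self, pop: str) -> int:
        return len(self.calls[pop])

    def genotypes(self, locus: str, pop: str | None = None) -> list[Genotype]:
        """All calls at ``locus``, in one population or pooled across all."""
        pops = [pop] if pop is not None else self.populations
        return [ind[locus] for p in pops for ind in self.calls[p]]


# ---------------------------------------------------------------------------
# GenePop I/O (3-digit allele coding; 000000 = missing)

def write_genepop(table: GenotypeTable, path_or_buf, title: str = "ssrforge export") -> None:
    close = False
    if isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__"):
        fh = open(path_or_buf, "w")
        close = True
    else:
        fh = path_or_buf
    try:
        fh.write(title + "\n")
        for locus in table.loci:
            fh.write(locus + "\n")
        for pop in table.populations:
            fh.write("Pop\n")
            for i, ind in enumerate(table.calls[pop], 1):
                cells = []
                for locus in table.loci:
                    g = ind[locus]
                    cells.append("000000" if g is None else f"{g[0]:03d}{g[1]:03d}")
                fh.write(f"{pop}_{i} ,  " + " ".join(cells) + "\n")
    finally:
        if close:
            fh.close()


def read_genepop(path_or_buf) -> GenotypeTable:
    """Parse GenePop (2- or 3-digit coding, loci one-per-line or comma-separated)."""
    if isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__"):
        with open(path_or_buf) as fh:
            lines = fh.read().splitlines()
    else:
        lines = path_or_buf.read().splitlines()
    if not lines:
        raise ValueError("empty GenePop input")
    lines = [l.rstrip() for l in lines]
    loci: list[str] = []
    i = 1  # skip title
    while i < len(lines) and lines[i].strip().lower() != "pop":
        loci.extend(x.strip() for x in lines[i].split(",") if x.strip())
        i += 1
    if i == len(lines):
        raise ValueError("GenePop input has no 'Pop' marker")
    pop_blocks: list[tuple[list[str], list[dict[str, Genotype]]]] = []
    current: list[dict[str, Genotype]] | None = None
    names: list[str] | None = None
    for line in lines[i:]:
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.lower() == "pop":
            current = []
            names = []
            pop_blocks.append((names, current))
            continue
        if current is None:
            raise ValueError("genotype row before first 'Pop'")
        if "," not in stripped:
            raise ValueError(f"malformed GenePop row: {stripped!r}")
        ind_name, geno_part = stripped.split(",", 1)
        names.append(ind_name.strip())
        fields = geno_part.split()
        if len(fields) != len(loci):
            raise ValueError(
                f"individual {ind_name.strip()!r}: {len(fields)} genotype fields "
                f"for {len(loci)} loci"
            )
        ind: dict[str, Genotype] = {}
        for locus, cell in zip(loci, fields):
            width = len(cell) // 2
            if width not in (2, 3) or len(cell) != 2 * width:
                raise ValueError(f"bad genotype field {cell!r} at locus {locus}")
            a1, a2 = int(cell[:width]), int(cell[width:])
            ind[locus] = None if a1 == 0 or a2 == 0 else (a1, a2)
        current.append(ind)
    # population labels: the common "NAME_i" prefix of the block's individual
    # names when one exists (the convention write_genepop uses), else "popK"
    populations: list[str] = []
    calls: dict[str, list[dict[str, Genotype]]] = {}
    for k, (blk_names, inds) in enumerate(pop_blocks, 1):
        prefixes = {n.rsplit("_", 1)[0] for n in blk_names if "_" in n}
        label = prefixes.pop() if len(prefixes) == 1 else f"pop{k}"
        if label in calls:
            label = f"{label}.{k}"
        populations.append(label)
        calls[label] = inds
    return GenotypeTable(populations=populations, loci=loci, calls=calls)


# ---------------------------------------------------------------------------
# Allele frequencies and per-locus statistics

def allele_frequencies(
    table: GenotypeTable, pooled: bool = False
) -> dict[str, dict]:
    """Per-locus allele frequency vectors.

    pooled=False -> {locus: {population: {allele: freq}}};
    pooled=True  -> {locus: {allele: freq}} over all populations.
    Frequencies count allele copies among non-missing calls (2 per diploid
    individual). A locus with no calls in a unit is omitted from that unit.
    """
    out: dict[str, dict] = {}
    for locus in table.loci:
        if pooled:
            freqs = _freqs(table.genotypes(locus))
            if freqs:
                out[locus] = freqs
        else:
            per_pop = {}
            for pop in table.populations:
                freqs = _freqs(table.genotypes(locus, pop))
                if freqs:
                    per_pop[pop] = freqs
            out[locus] = per_pop
    return out


def _freqs(genotypes: Iterable[Genotype]) -> dict[int, float]:
    counts: Counter = Counter()
    for g in genotypes:
        if g is not None:
            counts[g[0]] += 1
            counts[g[1]] += 1
    total = sum(counts.values())
    return {a: c / total for a, c in sorted(counts.items())} if total else {}


@dataclass
class LocusStats:
    locus: str
    na: int
    he: float
    ho: float
    shannon_i: float
    n: int  # non-missing individuals


def locus_stats(
    table: GenotypeTable,
    locus: str,
    pop: str | None = None,
    unbiased: bool = True,
) -> LocusStats:
    """Na, He, Ho and Shannon's I at one locus (pooled when ``pop`` is None).

    He is the gene diversity 1 - sum p^2, multiplied by 2N/(2N-1) when
    ``unbiased`` (Nei's small-sample correction, the POPGENE-style default).
    """
    genotypes = [g for g in table.genotypes(locus, pop) if g is not None]
    if not genotypes:
        raise ValueError(f"locus {locus!r} has no non-missing calls")
    freqs = _freqs(genotypes)
    n = len(genotypes)
    h = 1.0 - sum(p * p for p in freqs.values())
    he = h * (2 * n) / (2 * n - 1) if unbiased and n > 0 else h
    ho = sum(1 for g in genotypes if g[0] != g[1]) / n
    shannon = -sum(p * math.log(p) for p in freqs.values() if p > 0)
    return LocusStats(locus=locus, na=len(freqs), he=he, ho=ho, shannon_i=shannon, n=n)


def diversity_table(table: GenotypeTable, unbiased: bool = True) -> list[LocusStats]:
    """Pooled per-locus statistics for every locus, in table order."""
    return [locus_stats(table, locus, unbiased=unbiased) for locus in table.loci]


def summarize_diversity(stats: Sequence) -> dict[str, float]:
    """Across-locus summary of a diversity table.

    Accepts LocusStats objects or any records with na/he/ho/shannon_i
    attributes or keys, and returns the means plus ranges that marker
    surveys conventionally report.
    """
    def get(rec, name):
        return getattr(rec, name) if hasattr(rec, name) else rec[name]

    if not stats:
        raise ValueError("no locus statistics to summarize")
    na = [get(r, "na") for r in stats]
    he = [get(r, "he") for r in stats]
    ho = [get(r, "ho") for r in stats]
    si = [get(r, "shannon_i") for r in stats]
    k = len(stats)
    return {
        "n_loci": k,
        "mean_na": sum(na) / k,
        "min_na": min(na),
        "max_na": max(na),
        "mean_he": sum(he) / k,
        "min_he": min(he),
        "max_he": max(he),
        "mean_ho": sum(ho) / k,
        "min_ho": min(ho),
        "max_ho": max(ho),
        "mean_shannon_i": sum(si) / k,
        "min_shannon_i": min(si),
        "max_shannon_i": max(si),
    }


# ---------------------------------------------------------------------------
# Nei's standard genetic distance (1972) and neighbor joining

def nei_distance(
    freqs_x: Mapping[str, Mapping[int, float]],
    freqs_y: Mapping[str, Mapping[int, float]],
) -> float:
    """Nei's standard distance D = -ln(Jxy / sqrt(Jx Jy)) over shared loci.

    The J terms are arithmetic means over loci of sum(x_a * y_a),
    sum(x_a^2) and sum(y_a^2). Populations sharing no alleles at any
    locus have Jxy = 0 and D = +inf.
    """
    shared = [l for l in freqs_x if l in freqs_y]
    if not shared:
        raise ValueError("no shared loci between populations")
    jxy = jx = jy = 0.0
    for locus in shared:
        x, y = freqs_x[locus], freqs_y[locus]
        jxy += sum(px * y.get(a, 0.0) for a, px in x.items())
        jx += sum(p * p for p in x.values())
        jy += sum(p * p for p in y.values())
    k = len(shared)
    jxy, jx, jy = jxy / k, jx / k, jy / k
    if jxy == 0.0:
        return math.inf
    identity = jxy / math.sqrt(jx * jy)
    # guard tiny float excursions above 1 for identical populations
    return -math.log(min(identity, 1.0))


def nei_distance_matrix(table: GenotypeTable) -> DistanceMatrix:
    """Pairwise Nei distances between populations as a labelled matrix."""
    per_pop = allele_frequencies(table, pooled=False)
    pops = table.populations
    freqs = {
        pop: {locus: per_pop[locus][pop] for locus in table.loci if pop in per_pop[locus]}
        for pop in pops
    }
    n = len(pops)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = nei_distance(freqs[pops[i]], freqs[pops[j]])
    return DistanceMatrix(d, ids=pops)


def neighbor_joining(dm: DistanceMatrix, clamp_negative: bool = False) -> TreeNode:
    """Saitou-Nei neighbor joining with a deterministic tie-break.

    At each step the pair (i, j) minimising
    Q(i, j) = (n - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k)
    is joined; ties are broken by the lexicographically smallest pair of
    cluster labels (a cluster is labelled by its smallest leaf name).
    Negative branch lengths are kept unless ``clamp_negative``. With fewer
    than three taxa a trivial star tree is returned.
    """
    labels = list(dm.ids)
    if any(not np.isfinite(x) for x in np.asarray(dm.data).ravel()):
        raise ValueError("distance matrix contains non-finite entries")
    if len(labels) < 3:
        children = []
        for i, lab in enumerate(labels):
            node = TreeNode(name=lab)
            node.length = float(dm[labels[0], lab]) if i else 0.0
            children.append(node)
        return TreeNode(children=children)

    def _len(x: float) -> float:
        return max(0.0, x) if clamp_negative else x

    nodes: dict[str, TreeNode] = {lab: TreeNode(name=lab) for lab in labels}
    d: dict[str, dict[str, float]] = {
        a: {b: float(dm[a, b]) for b in labels if b != a} for a in labels
    }
    active = sorted(labels)  # cluster keys = smallest leaf name in the cluster

    while len(active) > 2:
        n = len(active)
        totals = {a: sum(d[a].values()) for a in active}
        best_pair = None
        best_q = math.inf
        for ai in range(n):
            for bi in range(ai + 1, n):
                a, b = active[ai], active[bi]
                q = (n - 2) * d[a][b] - totals[a] - totals[b]
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12 and (a, b) < best_pair
                ):
                    best_q = q
                    best_pair = (a, b)
        a, b = best_pair
        dab = d[a][b]
        la = 0.5 * dab + (totals[a] - totals[b]) / (2 * (n - 2))
        lb = dab - la
        na, nb = nodes.pop(a), nodes.pop(b)
        na.length = _len(la)
        nb.length = _len(lb)
        parent = TreeNode(children=[na, nb])
        key = min(a, b)
        new_d = {
            c: 0.5 * (d[a][c] + d[b][c] - dab) for c in active if c not in (a, b)
        }
        for c in list(d):
            d[c].pop(a, None)
            d[c].pop(b, None)
        del d[a], d[b]
        for c, val in new_d.items():
            d[c][key] = val
        d[key] = new_d
        nodes[key] = parent
        active = sorted(set(active) - {a, b} | {key})

    a, b = active
    na, nb = nodes[a], nodes[b]
    na.length = 0.0
    nb.length = _len(d[a][b])
    return TreeNode(children=[na, nb])


def to_newick(tree: TreeNode) -> str:
    """Serialize a tree to a single-line Newick string."""
    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


def from_newick(newick: str) -> TreeNode:
    return TreeNode.read(io.StringIO(newick))


def write_phylip(dm: DistanceMatrix, path) -> None:
    """Square PHYLIP distance-matrix format."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.ids)}\n")
        for lab in dm.ids:
            row = " ".join(f"{float(dm[lab, other]):.6f}" for other in dm.ids)
            fh.write(f"{lab:<10s} {row}\n")
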