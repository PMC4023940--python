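"""Independent reference implementations used only to check the package.

Everything here is deliberately naive — exhaustive enumeration and
direct-definition arithmetic — and shares no code with the implementation
it validates.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


def _primitive(motif: str) -> bool:
    for d in range(1, len(motif)):
        if len(motif) % d == 0 and motif == motif[:d] * (len(motif) // d):
            return False
    return True


def brute_force_ssrs(seq: str, min_repeats: dict[int, int]) -> set[tuple]:
    """Every maximal perfect tandem repeat, by exhaustive start/size/extension.

    Returns tuples (start_1based, end_1based, motif, copies).
    """
    seq = seq.upper()
    n = len(seq)
    found = set()
    for m, min_rep in min_repeats.items():
        for i in range(n - m + 1):
            motif = seq[i : i + m]
            if "N" in motif or not _primitive(motif):
                continue
            copies = 1
            while seq[i + copies * m : i + (copies + 1) * m] == motif:
                copies += 1
            if copies < min_rep:
                continue
            # leftmost phase only: if the period-m structure continues one
            # base to the left, this start is a shifted view of the same run
            if i >= 1 and seq[i - 1] != "N" and seq[i - 1] == seq[i + m - 1]:
                continue
            found.add((i + 1, i + copies * m, motif, copies))
    return found


def brute_force_nxx(lengths: list[int], fraction: float) -> int:
    """Nxx by scanning every prefix of the descending-sorted lengths."""
    lengths = sorted(lengths, reverse=True)
    total = sum(lengths)
    for k in range(1, len(lengths) + 1):
        if sum(lengths[:k]) >= fraction * total:
            return lengths[k - 1]
    raise AssertionError


def check_primer_pair(pair, sequence: str, c) -> list[str]:
    """Audit one designed pair against every constraint; returns violations."""
    problems = []
    seq = sequence.upper()
    locus = pair.locus
    for name, primer in (("forward", pair.forward), ("reverse", pair.reverse)):
        if not c.min_len <= len(primer) <= c.max_len:
            problems.append(f"{name}: length {len(primer)}")
        gc = 100.0 * sum(primer.count(b) for b in "GC") / len(primer)
        if not c.gc_min <= gc <= c.gc_max:
            problems.append(f"{name}: gc {gc}")
        tm = 81.5 + 0.41 * gc - 675.0 / len(primer)
        if not c.tm_min <= tm <= c.tm_max:
            problems.append(f"{name}: tm {tm}")
        run, longest = 1, 1
        for a, b in zip(primer, primer[1:]):
            run = run + 1 if a == b else 1
            longest = max(longest, run)
        if longest > c.max_homopolymer:
            problems.append(f"{name}: homopolymer run {longest}")
    if abs(pair.tm_forward - pair.tm_reverse) > c.max_tm_diff:
        problems.append("tm diff")
    if not c.product_min <= pair.product_size <= c.product_max:
        problems.append(f"product {pair.product_size}")
    # placement: forward on + strand left of tract, reverse binds right of tract
    f0 = pair.forward_start - 1
    if seq[f0 : f0 + len(pair.forward)] != pair.forward:
        problems.append("forward does not match contig")
    if f0 + len(pair.forward) > locus.start - 1:
        problems.append("forward overlaps SSR tract")
    r0 = pair.reverse_start - 1
    binding = seq[r0 : r0 + len(pair.reverse)]
    if binding.translate(_COMP)[::-1] != pair.reverse:
        problems.append("reverse does not match contig")
    if r0 < locus.end:
        problems.append("reverse overlaps SSR tract")
    if pair.product_size != r0 + len(pair.reverse) - f0:
        problems.append("product size inconsistent with coordinates")
    return problems


def random_additive_matrix(rng: np.random.Generator, n_taxa: int):
    """Random binary tree -> its exact tip-to-tip path-length matrix.

    Built by random sequential attachment with positive branch lengths;
    distances computed by tracing paths through the parent map, entirely
    independent of any tree library.
    """
    # nodes: 0..n_taxa-1 leaves; internal nodes appended
    parent: dict[int, tuple[int, float]] = {}
    nodes = [0, 1]
    nxt = n_taxa  # internal ids
    edges: dict[tuple[int, int], float] = {}

    def add_edge(a, b, w):
        edges[(a, b)] = w
        edges[(b, a)] = w

    add_edge(0, 1, float(rng.uniform(0.1, 2.0)))
    for leaf in range(2, n_taxa):
        # pick a random existing edge, split it with a new internal node
        a, b = list(edges.keys())[int(rng.integers(0, len(edges)))]
        w = edges[(a, b)]
        split = float(rng.uniform(0.1, 0.9)) * w
        mid = nxt
        nxt += 1
        del edges[(a, b)], edges[(b, a)]
        add_edge(a, mid, split)
        add_edge(mid, b, w - split)
        add_edge(mid, leaf, float(rng.uniform(0.1, 2.0)))
    # all-pairs shortest path over the tree (BFS accumulating weights)
    import collections

    adj: dict[int, list[tuple[int, float]]] = collections.defaultdict(list)
    for (a, b), w in edges.items():
        adj[a].append((b, w))
    d = np.zeros((n_taxa, n_taxa))
    for src in range(n_taxa):
        dist = {src: 0.0}
        queue = collections.deque([src])
        while queue:
            u = queue.popleft()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    queue.append(v)
        for dst in range(n_taxa):
            d[src, dst] = dist[dst]
    d = (d + d.T) / 2.0  # float path sums differ in the last ulp per direction
    np.fill_diagonal(d, 0.0)
    return d


def shannon_index(freqs) -> float:
    return float(-sum(p * np.log(p) for p in freqs if p > 0))
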