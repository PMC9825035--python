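"""Independent brute-force oracles used by the test suite.

These deliberately avoid the algorithms used by the package: repeats are
found by definitional maximal-run extraction over every diagonal of the full
self-comparison matrix, linkage closure goes through networkx connected
components, effects come from a whole-protein translation diff, and MST
weights come from networkx.
"""

from __future__ import annotations

import numpy as np

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = np.array([3, 2, 1, 0])  # A<->T, C<->G


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE[c] for c in seq], dtype=np.int8)


def _runs(match: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) half-open."""
    if match.size == 0:
        return []
    padded = np.concatenate(([False], match, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def brute_force_repeats(seq: str, min_len: int) -> set[tuple]:
    """All maximal exact repeat pairs (identity 1.0) on both strands.

    Examines every (i, j) cell of the self-comparison matrix, organized by
    diagonal (same strand, offset j - i) and anti-diagonal (inverted,
    constant i + j with i < j). Returns canonical tuples
    (interval_a, interval_b, strand) with interval_a <= interval_b.
    """
    arr = _encode(seq)
    n = len(arr)
    out: set[tuple] = set()
    for d in range(1, n):
        match = arr[: n - d] == arr[d:]
        for s, e in _runs(match):
            if e - s >= min_len:
                out.add(((s, e), (s + d, e + d), "same"))
    comp = _COMP[arr]
    for c in range(2 * n - 1):
        lo = max(0, c - n + 1)
        hi = (c - 1) // 2
        if hi < lo:
            continue
        # i ascending in [lo, hi]; partner j = c - i descending
        left = arr[lo : hi + 1]
        right = comp[c - hi : c - lo + 1][::-1]
        match = left == right
        for s, e in _runs(match):
            if e - s >= min_len:
                i1, i2 = lo + s, lo + e - 1
                a = (i1, i2 + 1)
                b = (c - i2, c - i1 + 1)
                if a == b:
                    continue
                out.add((min(a, b), max(a, b), "inverted"))
    return out


def brute_force_union_length(intervals: list[tuple[int, int]], n: int) -> int:
    """Union length of intervals by per-base boolean marking."""
    marked = np.zeros(n, dtype=bool)
    for s, e in intervals:
        marked[s:e] = True
    return int(marked.sum())


def brute_force_overlap(variant_start: int, variant_end: int,
                        intervals: list[tuple[int, int]]) -> bool:
    return any(variant_start < e and s < variant_end for s, e in intervals)


def brute_force_linkage(calls: np.ndarray, missing: int = -1) -> list[list[int]]:
    """Perfect-linkage site groups by pairwise partition comparison
    (set-of-frozensets) followed by networkx transitive closure."""
    import networkx as nx

    n_acc, n_sites = calls.shape

    def partition(j: int, rows: list[int]) -> set[frozenset]:
        groups: dict[int, set[int]] = {}
        for i in rows:
            groups.setdefault(int(calls[i, j]), set()).add(i)
        return {frozenset(g) for g in groups.values()}

    g = nx.Graph()
    usable = [j for j in range(n_sites)
              if int((calls[:, j] != missing).sum()) >= 2]
    g.add_nodes_from(usable)
    for a_idx, j1 in enumerate(usable):
        for j2 in usable[a_idx + 1 :]:
            rows = [i for i in range(n_acc)
                    if calls[i, j1] != missing and calls[i, j2] != missing]
            if not rows:
                continue
            if partition(j1, rows) == partition(j2, rows):
                g.add_edge(j1, j2)
    return sorted((sorted(c) for c in nx.connected_components(g)),
                  key=lambda grp: grp[0])


def brute_force_mst_weight(dist: np.ndarray) -> float:
    """Minimum spanning tree weight via networkx."""
    import networkx as nx

    g = nx.Graph()
    n = dist.shape[0]
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            g.add_edge(i, j, weight=float(dist[i, j]))
    if n <= 1:
        return 0.0
    tree = nx.minimum_spanning_tree(g)
    return float(sum(d["weight"] for _, _, d in tree.edges(data=True)))


_AA_TABLE = {}
_B = "TCAG"
_AAS = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, _a in enumerate(_AAS):
    _AA_TABLE[_B[_i // 16] + _B[(_i // 4) % 4] + _B[_i % 4]] = _a


def _translate(cds: str) -> str:
    return "".join(_AA_TABLE[cds[i : i + 3]] for i in range(0, len(cds) - 2, 3))


def brute_force_snp_effect(genome_seq: str, gene, pos: int, alt: str) -> str:
    """Effect of an equal-length substitution by editing the whole genome,
    re-extracting the CDS and diffing the full translated proteins."""
    ref_len = len(alt)  # equal-length substitution
    edited = genome_seq[: pos - 1] + alt + genome_seq[pos - 1 + ref_len :]
    prot_ref = _translate(gene.coding_sequence(genome_seq))
    prot_alt = _translate(gene.coding_sequence(edited))
    if prot_alt == prot_ref:
        return "synonymous"
    for i, (a, b) in enumerate(zip(prot_ref, prot_alt)):
        if a == b:
            continue
        if b == "*" or a == "*":
            return "nonsense"
        if i == 0 and a == "M":
            return "nonsense"
    return "missense"
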