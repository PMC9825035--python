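"""Tag-site selection by perfect linkage, haplotype assignment, naming,
minimum-spanning networks and haplotype-group clustering.

Polymorphic sites are partitioned into perfect-linkage classes: two sites
belong to the same class iff, over all accessions where both are observed,
they induce the same partition of accessions (allele labels irrelevant).
One tag site per class then losslessly encodes the full genotype vector,
and distinct tag-allele vectors define the haplotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from organellotype.variants import MISSING, VariantSite
from organellotype.variantstats import classify_site

logger = logging.getLogger(__name__)


@dataclass
class GenotypeMatrix:
    """Accessions x sites allele-index matrix (-1 = missing call)."""

    accessions: list[str]
    sites: list[VariantSite]
    calls: np.ndarray  # (n_accessions, n_sites) int

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int16)
        if self.calls.shape != (len(self.accessions), len(self.sites)):
            raise ValueError("calls shape inconsistent with accessions x sites")

    @classmethod
    def from_sites(cls, accessions: list[str], sites: list[VariantSite]) -> "GenotypeMatrix":
        calls = np.stack([s.genotypes for s in sites], axis=1) if sites else \
            np.zeros((len(accessions), 0), dtype=np.int16)
        return cls(accessions=accessions, sites=sites, calls=calls)

    def drop_heteroplasmic(self, max_fraction: float = 0.5) -> "GenotypeMatrix":
        """Remove sites with mixed (heteroplasmic) calls in more than
        ``max_fraction`` of accessions.

        At such sites the majority-allele collapse is driven by depth noise
        rather than haplotype, so they carry no haplotype signal; they are
        analyzed by the RAF module instead.
        """
        n = len(self.accessions)
        keep = [
            j for j, s in enumerate(self.sites)
            if n == 0 or s.n_heteroplasmic / n <= max_fraction
        ]
        return GenotypeMatrix(
            accessions=self.accessions,
            sites=[self.sites[j] for j in keep],
            calls=self.calls[:, keep],
        )

    def drop_monomorphic(self) -> "GenotypeMatrix":
        """Remove columns with fewer than two observed distinct alleles."""
        keep = []
        for j in range(self.calls.shape[1]):
            col = self.calls[:, j]
            if len(np.unique(col[col != MISSING])) >= 2:
                keep.append(j)
        return GenotypeMatrix(
            accessions=self.accessions,
            sites=[self.sites[j] for j in keep],
            calls=self.calls[:, keep],
        )


@dataclass
class TagSet:
    """A partition of site indices into perfect-linkage groups plus one tag each."""

    groups: list[list[int]]
    tag_of_group: list[int]
    excluded: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for g, t in zip(self.groups, self.tag_of_group):
            if t not in g:
                raise ValueError(f"tag {t} not in its group")
            if seen & set(g):
                raise ValueError("groups are not disjoint")
            seen |= set(g)

    @property
    def tags(self) -> list[int]:
        return sorted(self.tag_of_group)


def _same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """True iff two call columns induce identical accession partitions
    over co-observed accessions (bijective allele relabeling allowed)."""
    both = (a != MISSING) & (b != MISSING)
    if not both.any():
        return False
    av, bv = a[both], b[both]
    fwd: dict[int, int] = {}
    rev: dict[int, int] = {}
    for x, y in zip(av.tolist(), bv.tolist()):
        if fwd.setdefault(x, y) != y or rev.setdefault(y, x) != x:
            return False
    return True


def linkage_partition(m: GenotypeMatrix) -> TagSet:
    """Group sites by perfect linkage (transitively closed) and pick tags.

    The tag of a group is its leftmost biallelic SNP, falling back to the
    leftmost site when the group has none. Sites observed in fewer than two
    accessions are excluded with a warning.
    """
    n_sites = m.calls.shape[1]
    if n_sites == 0:
        raise ValueError("genotype matrix has no sites")
    usable = []
    excluded = []
    for j in range(n_sites):
        if (m.calls[:, j] != MISSING).sum() < 2:
            excluded.append(j)
            logger.warning(
                "site %s observed in <2 accessions; excluded from linkage",
                m.sites[j].label,
            )
        else:
            usable.append(j)
    parent = {j: j for j in usable}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for ii, j1 in enumerate(usable):
        for j2 in usable[ii + 1 :]:
            if find(j1) == find(j2):
                continue
            if _same_partition(m.calls[:, j1], m.calls[:, j2]):
                parent[find(j2)] = find(j1)

    by_root: dict[int, list[int]] = {}
    for j in usable:
        by_root.setdefault(find(j), []).append(j)
    groups = sorted((sorted(g) for g in by_root.values()), key=lambda g: g[0])
    tags = []
    for g in groups:
        snps = [
            j for j in g
            if classify_site(m.sites[j]).kind == "SNP"
            and classify_site(m.sites[j]).allelism == "biallelic"
        ]
        tags.append(snps[0] if snps else g[0])
    return TagSet(groups=groups, tag_of_group=tags, excluded=excluded)


@dataclass
class HaplotypeTable:
    """Named tag-allele vectors with per-accession assignments."""

    tag_sites: list[int]  # site indices into the source matrix
    sites: list[VariantSite]  # the tag VariantSites, matrix order
    names: list[str]  # haplotype names, rank order
    vectors: list[tuple[int, ...]]  # allele vector per name
    assignment: dict[str, str]  # accession -> haplotype name
    unassigned: list[str]

    def counts(self, accessions: list[str] | None = None) -> dict[str, int]:
        pool = set(accessions) if accessions is not None else None
        out = {name: 0 for name in self.names}
        for acc, name in self.assignment.items():
            if pool is None or acc in pool:
                out[name] += 1
        return out

    @property
    def vector_of(self) -> dict[str, tuple[int, ...]]:
        return dict(zip(self.names, self.vectors))


def assign_haplotypes(m: GenotypeMatrix, tags: TagSet) -> HaplotypeTable:
    """Map each fully-observed accession to its tag-allele vector.

    Accessions with any missing tag call are reported unassigned, never
    imputed. Haplotype names at this stage are provisional ("H1", ...) in
    order of first appearance.
    """
    tag_idx = tags.tags
    sub = m.calls[:, tag_idx]
    vectors: list[tuple[int, ...]] = []
    index_of: dict[tuple[int, ...], int] = {}
    assignment: dict[str, str] = {}
    unassigned: list[str] = []
    for i, acc in enumerate(m.accessions):
        row = sub[i]
        if (row == MISSING).any():
            unassigned.append(acc)
            continue
        vec = tuple(int(x) for x in row)
        if vec not in index_of:
            index_of[vec] = len(vectors)
            vectors.append(vec)
        assignment[acc] = f"H{index_of[vec] + 1}"
    return HaplotypeTable(
        tag_sites=tag_idx,
        sites=[m.sites[j] for j in tag_idx],
        names=[f"H{i + 1}" for i in range(len(vectors))],
        vectors=vectors,
        assignment=assignment,
        unassigned=unassigned,
    )


def name_haplotypes(
    t: HaplotypeTable, prefix: str, naming_population: list[str] | None = None
) -> HaplotypeTable:
    """Rename haplotypes prefix+rank by descending count in the naming
    population; ties broken by full-panel count, then allele vector."""
    pop_counts = t.counts(naming_population)
    all_counts = t.counts()
    order = sorted(
        range(len(t.names)),
        key=lambda i: (
            -pop_counts[t.names[i]],
            -all_counts[t.names[i]],
            t.vectors[i],
        ),
    )
    new_name = {t.names[old]: f"{prefix}{rank + 1}" for rank, old in enumerate(order)}
    return HaplotypeTable(
        tag_sites=t.tag_sites,
        sites=t.sites,
        names=[f"{prefix}{r + 1}" for r in range(len(order))],
        vectors=[t.vectors[old] for old in order],
        assignment={acc: new_name[h] for acc, h in t.assignment.items()},
        unassigned=list(t.unassigned),
    )


def hamming(a: tuple[int, ...], b: tuple[int, ...]) -> int:
    """Number of tag sites at which two allele vectors differ."""
    if len(a) != len(b):
        raise ValueError("vectors of unequal length")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class HaplotypeNetwork:
    """Minimum-spanning haplotype network.

    ``edges`` form a minimum spanning tree over pairwise Hamming distances;
    ``alternative_edges`` are the non-tree edges that could replace a
    maximal edge on their tree path at equal cost (ties of the MST).
    """

    nodes: list[str]
    node_counts: dict[str, int]
    edges: list[tuple[str, str, int]]
    alternative_edges: list[tuple[str, str, int]]

    def total_weight(self) -> int:
        return sum(w for _, _, w in self.edges)


def build_network(t: HaplotypeTable) -> HaplotypeNetwork:
    """Minimum spanning tree (Kruskal, deterministic tie-breaking by
    (length, rank, rank)) plus equal-length alternative edges."""
    n = len(t.names)
    counts = t.counts()
    if n == 0:
        raise ValueError("no haplotypes")
    dist = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = hamming(t.vectors[i], t.vectors[j])
    edges = sorted(
        ((int(dist[i, j]), i, j) for i in range(n) for j in range(i + 1, n)),
    )
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree: list[tuple[int, int, int]] = []
    rest: list[tuple[int, int, int]] = []
    for w, i, j in edges:
        ri, rj = find(i), find(j)
        if ri == rj:
            rest.append((w, i, j))
        else:
            parent[ri] = rj
            tree.append((w, i, j))

    adj: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n)}
    for w, i, j in tree:
        adj[i].append((j, w))
        adj[j].append((i, w))

    def max_on_path(u: int, v: int) -> int:
        # DFS on the tree; n is small (tens of haplotypes)
        stack = [(u, -1, 0)]
        while stack:
            node, par, mx = stack.pop()
            if node == v:
                return mx
            for nb, w in adj[node]:
                if nb != par:
                    stack.append((nb, node, max(mx, w)))
        raise RuntimeError("tree path not found")

    alternative = [(w, i, j) for w, i, j in rest if w == max_on_path(i, j)]
    return HaplotypeNetwork(
        nodes=list(t.names),
        node_counts=counts,
        edges=[(t.names[i], t.names[j], w) for w, i, j in tree],
        alternative_edges=[(t.names[i], t.names[j], w) for w, i, j in alternative],
    )


@dataclass
class GroupAssignment:
    group_of_haplotype: dict[str, str]

    def haplotypes_in(self, group: str) -> list[str]:
        return [h for h, g in self.group_of_haplotype.items() if g == group]


def cluster_groups(t: HaplotypeTable, k: int, prefix: str = "G") -> GroupAssignment:
    """Average-linkage agglomerative clustering of haplotypes into k groups.

    Groups are labeled prefix+rank by descending total accession count
    (ties by the best haplotype rank they contain).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(t.names)
    if k > n:
        raise ValueError(f"k={k} exceeds number of haplotypes ({n})")
    if n == 1:
        return GroupAssignment({t.names[0]: f"{prefix}1"})
    dist = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = hamming(t.vectors[i], t.vectors[j])
    labels = sch.fcluster(sch.linkage(squareform(dist), method="average"),
                          t=k, criterion="maxclust")
    counts = t.counts()
    by_label: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        by_label.setdefault(int(lab), []).append(i)
    ranked = sorted(
        by_label.values(),
        key=lambda idxs: (-sum(counts[t.names[i]] for i in idxs), min(idxs)),
    )
    out: dict[str, str] = {}
    for rank, idxs in enumerate(ranked):
        for i in idxs:
            out[t.names[i]] = f"{prefix}{rank + 1}"
    return GroupAssignment(group_of_haplotype=out)


def write_haplotype_tsv(t: HaplotypeTable, path: str | Path) -> None:
    """Haplotype x tag-site allele table with REF/ALT-rendered alleles."""
    with open(path, "w") as fh:
        header = ["haplotype", "count"] + [f"p.{s.pos}" for s in t.sites]
        fh.write("\t".join(header) + "\n")
        counts = t.counts()
        for name, vec in zip(t.names, t.vectors):
            alleles = [t.sites[j].alleles[a] for j, a in enumerate(vec)]
            fh.write("\t".join([name, str(counts[name])] + alleles) + "\n")


def write_assignment_tsv(t: HaplotypeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("accession\thaplotype\n")
        for acc, name in sorted(t.assignment.items()):
            fh.write(f"{acc}\t{name}\n")
        for acc in sorted(t.unassigned):
            fh.write(f"{acc}\tNA\n")


def write_network_tsv(net: HaplotypeNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("from\tto\tsteps\tkind\n")
        for u, v, w in net.edges:
            fh.write(f"{u}\t{v}\t{w}\tprimary\n")
        for u, v, w in net.alternative_edges:
            fh.write(f"{u}\t{v}\t{w}\talternative\n")


def to_networkx(net: HaplotypeNetwork):
    """Convert to a networkx Graph (primary edges; alternatives attributed)."""
    import networkx as nx

    g = nx.Graph()
    for node in net.nodes:
        g.add_node(node, count=net.node_counts.get(node, 0))
    for u, v, w in net.edges:
        g.add_edge(u, v, weight=w, kind="primary")
    for u, v, w in net.alternative_edges:
        g.add_edge(u, v, weight=w, kind="alternative")
    return g
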