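import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_force_linkage, brute_force_mst_weight
from organellotype import synthdata as sd
from organellotype.haplotyper import (
    GenotypeMatrix,
    HaplotypeTable,
    assign_haplotypes,
    build_network,
    cluster_groups,
    hamming,
    linkage_partition,
    name_haplotypes,
)
from organellotype.variants import MISSING, VariantSite, read_vcf


def _matrix(calls, alts_per_site=None):
    calls = np.asarray(calls, dtype=np.int16)
    n_acc, n_sites = calls.shape
    sites = []
    for j in range(n_sites):
        n_alts = (alts_per_site[j] if alts_per_site else
                  max(1, int(calls[:, j].max())))
        alts = tuple("GTC"[:n_alts])
        sites.append(VariantSite(contig="c", pos=(j + 1) * 10, ref="A", alts=alts))
    return GenotypeMatrix(
        accessions=[f"a{i}" for i in range(n_acc)], sites=sites, calls=calls
    )


class TestLinkagePartition:
    def test_relabeling_invariance(self):
        # {A,A,B,B} and {C,C,T,T} induce the same accession partition
        m = _matrix([[0, 1], [0, 1], [1, 0], [1, 0]])
        tags = linkage_partition(m)
        assert tags.groups == [[0, 1]]

    def test_crossing_partitions(self):
        m = _matrix([[0, 0], [0, 1], [1, 0], [1, 1]])
        tags = linkage_partition(m)
        assert tags.groups == [[0], [1]]

    def test_transitive_closure_with_missing(self):
        # sites 0-1 agree on rows 0-2; sites 1-2 agree on rows 1-3;
        # 0 and 2 land in one group through 1 even if never co-compared
        calls = np.array([
            [0, 0, MISSING],
            [0, 0, 0],
            [1, 1, 1],
            [MISSING, 1, 1],
        ])
        tags = linkage_partition(_matrix(np.where(calls == MISSING, MISSING, calls)))
        assert tags.groups == [[0, 1, 2]]

    def test_sparse_site_excluded(self):
        calls = np.array([[0, MISSING], [1, MISSING], [0, 0], [1, MISSING]])
        m = _matrix(calls)
        tags = linkage_partition(m)
        assert tags.excluded == [1]

    def test_tag_prefers_leftmost_biallelic_snp(self):
        calls = np.array([[0, 0], [1, 1], [2, 1], [0, 0]])
        sites = [
            VariantSite(contig="c", pos=10, ref="A", alts=("G", "T")),  # multiallelic
            VariantSite(contig="c", pos=20, ref="A", alts=("G",)),
        ]
        m = GenotypeMatrix(accessions=list("wxyz"), sites=sites,
                           calls=calls.astype(np.int16))
        tags = linkage_partition(m)
        # not perfectly linked (partition {0,3}{1,2}... site0: {0,3},{1},{2};
        # site1: {0,3},{1,2}) -> two groups; each tags itself
        assert tags.groups == [[0], [1]]
        assert tags.tag_of_group == [0, 1]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_acc, n_sites = 30, 12
        calls = rng.integers(0, 3, size=(n_acc, n_sites)).astype(np.int16)
        miss = rng.random((n_acc, n_sites)) < 0.1
        calls[miss] = MISSING
        # ensure columns stay polymorphic enough for the contract
        m = _matrix(calls, alts_per_site=[3] * n_sites)
        tags = linkage_partition(m)
        expected = brute_force_linkage(calls)
        got = sorted(tags.groups + [[j] for j in tags.excluded])
        assert got == sorted(expected + [[j] for j in tags.excluded])


class TestAssignment:
    def test_all_identical(self):
        m = _matrix([[0, 1]] * 5)
        tags = linkage_partition(m)
        t = assign_haplotypes(m, tags)
        assert len(t.names) == 1
        assert len(t.assignment) == 5

    def test_missing_tag_call_unassigned(self):
        calls = np.array([[0, 0], [1, 1], [MISSING, 0]])
        m = _matrix(calls)
        t = assign_haplotypes(m, linkage_partition(m))
        assert len(t.unassigned) == 1
        assert len(t.assignment) + len(t.unassigned) == 3

    def test_planted_panel_recovery(self, panel):
        truth, vcf = panel
        accs, vsites = read_vcf(vcf)
        m = (GenotypeMatrix.from_sites(accs, vsites)
             .drop_heteroplasmic().drop_monomorphic())
        t = assign_haplotypes(m, linkage_partition(m))
        planted = {a: h for a, h in zip(truth.accessions, truth.haplotype_of)}
        assert not t.unassigned
        rec = {}
        for acc, name in t.assignment.items():
            rec.setdefault(name, set()).add(acc)
        pl = {}
        for acc in t.assignment:
            pl.setdefault(planted[acc], set()).add(acc)
        assert {frozenset(v) for v in rec.values()} == {frozenset(v) for v in pl.values()}

    def test_tag_partition_equals_full_partition(self, panel):
        # distinguishability preservation on complete data
        truth, vcf = panel
        accs, vsites = read_vcf(vcf)
        m = (GenotypeMatrix.from_sites(accs, vsites)
             .drop_heteroplasmic().drop_monomorphic())
        tags = linkage_partition(m)
        tag_cols = m.calls[:, tags.tags]
        full_cols = m.calls
        def part(cols):
            groups = {}
            for i in range(cols.shape[0]):
                groups.setdefault(tuple(cols[i]), set()).add(i)
            return {frozenset(v) for v in groups.values()}
        assert part(tag_cols) == part(full_cols)


class TestNaming:
    def _table(self, counts):
        # build a table with given per-haplotype counts
        names = [f"H{i+1}" for i in range(len(counts))]
        vectors = [tuple([i] + [0] * 3) for i in range(len(counts))]
        assignment = {}
        k = 0
        for name, c in zip(names, counts):
            for _ in range(c):
                assignment[f"acc{k}"] = name
                k += 1
        sites = [VariantSite(contig="c", pos=(j + 1) * 10, ref="A",
                             alts=("G", "T", "C"))
                 for j in range(4)]
        return HaplotypeTable(tag_sites=[0, 1, 2, 3], sites=sites, names=names,
                              vectors=vectors, assignment=assignment, unassigned=[])

    def test_rank_by_count(self):
        t = self._table([300, 500, 1])
        named = name_haplotypes(t, "CT")
        assert named.vector_of["CT1"] == (1, 0, 0, 0)  # the 500-count one
        counts = named.counts()
        assert [counts[f"CT{i+1}"] for i in range(3)] == [500, 300, 1]

    def test_tie_broken_by_full_panel(self):
        t = self._table([10, 10, 12])
        # naming population sees both H1 and H2 at 5; full panel prefers H2=10+2
        pop = [a for a, h in t.assignment.items() if h == "H1"][:5] + \
              [a for a, h in t.assignment.items() if h == "H2"][:5]
        t.assignment["extra1"] = "H2"
        t.assignment["extra2"] = "H2"
        named = name_haplotypes(t, "CT", naming_population=pop)
        # H3 absent from naming population -> last; H2 beats H1 on full panel
        assert named.vector_of["CT1"] == (1, 0, 0, 0)

    def test_shuffle_invariance(self):
        rng = np.random.default_rng(1)
        t = self._table([50, 30, 30, 7, 1])
        baseline = name_haplotypes(t, "MT")
        for _ in range(20):
            items = list(t.assignment.items())
            rng.shuffle(items)
            t2 = HaplotypeTable(
                tag_sites=t.tag_sites, sites=t.sites, names=t.names,
                vectors=t.vectors, assignment=dict(items), unassigned=[],
            )
            named = name_haplotypes(t2, "MT")
            assert named.vector_of == baseline.vector_of
            assert named.assignment == baseline.assignment


class TestHamming:
    def test_identical(self):
        assert hamming((0, 1, 2), (0, 1, 2)) == 0

    def test_three_of_27(self):
        a = tuple([0] * 27)
        b = tuple([1 if i in (3, 9, 20) else 0 for i in range(27)])
        assert hamming(a, b) == 3

    def test_symmetric_random(self, rng):
        for _ in range(50):
            a = tuple(rng.integers(0, 4, 20).tolist())
            b = tuple(rng.integers(0, 4, 20).tolist())
            assert hamming(a, b) == hamming(b, a)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            hamming((0, 1), (0, 1, 2))

    @given(st.lists(st.integers(0, 3), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_identity_property(self, vec):
        assert hamming(tuple(vec), tuple(vec)) == 0


def _table_from_vectors(vectors, counts=None):
    n = len(vectors)
    names = [f"H{i+1}" for i in range(n)]
    counts = counts or [1] * n
    assignment = {}
    k = 0
    for name, c in zip(names, counts):
        for _ in range(c):
            assignment[f"a{k}"] = name
            k += 1
    n_sites = len(vectors[0])
    sites = [VariantSite(contig="c", pos=(j + 1) * 10, ref="A", alts=("G", "T", "C"))
             for j in range(n_sites)]
    return HaplotypeTable(tag_sites=list(range(n_sites)), sites=sites, names=names,
                          vectors=[tuple(v) for v in vectors],
                          assignment=assignment, unassigned=[])


class TestNetwork:
    def test_equilateral_triangle(self):
        # three haplotypes at mutual distance 1
        t = _table_from_vectors([(0, 0, 0), (1, 0, 0), (2, 0, 0)])
        net = build_network(t)
        assert net.total_weight() == 2
        assert len(net.edges) == 2
        assert len(net.alternative_edges) == 1
        assert net.alternative_edges[0][2] == 1

    def test_single_haplotype(self):
        t = _table_from_vectors([(0, 0)])
        net = build_network(t)
        assert net.nodes == ["H1"]
        assert net.edges == [] and net.alternative_edges == []

    @pytest.mark.parametrize("seed", range(10))
    def test_mst_weight_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 16))
        vectors = {tuple(rng.integers(0, 3, 12).tolist()) for _ in range(n)}
        vectors = sorted(vectors)
        t = _table_from_vectors(vectors)
        net = build_network(t)
        m = len(vectors)
        dist = np.zeros((m, m))
        for i in range(m):
            for j in range(m):
                dist[i, j] = hamming(vectors[i], vectors[j])
        assert net.total_weight() == brute_force_mst_weight(dist)
        assert len(net.edges) == m - 1  # spans all haplotypes

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        vectors = sorted({tuple(rng.integers(0, 2, 8).tolist()) for _ in range(10)})
        t = _table_from_vectors(vectors)
        n1, n2 = build_network(t), build_network(t)
        assert n1.edges == n2.edges
        assert n1.alternative_edges == n2.alternative_edges


class TestClusterGroups:
    def test_two_separated_clusters(self):
        # within-cluster distance <= 1, between >= 10
        base_a = [0] * 12
        base_b = [2] * 12
        vectors = [tuple(base_a)]
        for i in range(3):
            v = list(base_a); v[i] = 1; vectors.append(tuple(v))
        vectors.append(tuple(base_b))
        for i in range(3):
            v = list(base_b); v[i] = 1; vectors.append(tuple(v))
        t = _table_from_vectors(vectors, counts=[10, 1, 1, 1, 5, 1, 1, 1])
        grp = cluster_groups(t, 2, prefix="CTG")
        labels = [grp.group_of_haplotype[f"H{i+1}"] for i in range(8)]
        assert labels[:4] == ["CTG1"] * 4  # bigger cluster is group 1
        assert labels[4:] == ["CTG2"] * 4

    def test_k_equals_n(self):
        t = _table_from_vectors([(0, 0), (0, 1), (1, 1)])
        grp = cluster_groups(t, 3)
        assert len(set(grp.group_of_haplotype.values())) == 3

    def test_k_one(self):
        t = _table_from_vectors([(0, 0), (0, 1), (1, 1)])
        grp = cluster_groups(t, 1)
        assert set(grp.group_of_haplotype.values()) == {"G1"}

    def test_k_invalid(self):
        t = _table_from_vectors([(0, 0)])
        with pytest.raises(ValueError):
            cluster_groups(t, 0)
        with pytest.raises(ValueError):
            cluster_groups(t, 2)


class TestCountsConservation:
    def test_assigned_plus_unassigned(self, panel):
        truth, vcf = panel
        accs, vsites = read_vcf(vcf)
        m = (GenotypeMatrix.from_sites(accs, vsites)
             .drop_heteroplasmic().drop_monomorphic())
        t = assign_haplotypes(m, linkage_partition(m))
        assert len(t.assignment) + len(t.unassigned) == len(accs)
        assert sum(t.counts().values()) == len(t.assignment)
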