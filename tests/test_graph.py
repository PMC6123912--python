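"""Junction search, grouping, group decomposition, graph building, compaction."""

from trareco.assembly import Contig
from trareco.consensus import profile_from_seq
from trareco.graph import (ContigGroup, Junction, NodeData, PREFIX,
                           SplicingGraph, build_graph, compact, find_junctions,
                           filter_junctions_by_group_size, group_contigs, to_gfa)
from trareco.simulate import _random_seq

from oracles import union_find_components


def contig_pool(*seqs: str) -> list[Contig]:
    return [Contig(i, profile_from_seq(s)) for i, s in enumerate(seqs)]


class TestFindJunctions:
    def test_shared_first_exon_boundaries(self, rng):
        e1, e2, e3 = (_random_seq(rng, 300), _random_seq(rng, 250),
                      _random_seq(rng, 250))
        pool = contig_pool(e1 + e2, e1 + e3)
        js = find_junctions(pool, 24, 0.0)
        # prefix of each contig (= e1 + a chimeric stretch) aligns in the other;
        # the inner end must sit at the exon1 joint (position 300)
        assert js, "expected junctions between isoforms sharing exon 1"
        assert any(j.boundary_on_dst() == 300 or
                   j.boundary_on_src(pool[j.src].length) == 300 for j in js)
        for j in js:
            assert j.overlap >= 24
            assert j.mismatches == 0

    def test_unrelated_contigs_share_nothing(self, rng):
        pool = contig_pool(_random_seq(rng, 800), _random_seq(rng, 800))
        assert find_junctions(pool, 24, 0.06) == []

    def test_overlap_below_threshold_rejected(self, rng):
        core = _random_seq(rng, 23)   # one below J_th = 24
        a = _random_seq(rng, 200) + core
        b = _random_seq(rng, 100) + core + _random_seq(rng, 100)
        js = [j for j in find_junctions(contig_pool(a, b), 24, 0.0)
              if j.src == 0]
        assert js == []


class TestGroupContigs:
    def test_no_junctions_all_singletons(self, rng):
        pool = contig_pool(*[_random_seq(rng, 100) for _ in range(5)])
        groups = group_contigs(pool, [])
        assert len(groups) == 5
        assert all(len(g.contig_ids) == 1 for g in groups)

    def test_chain_is_transitive(self, rng):
        pool = contig_pool(*[_random_seq(rng, 100) for _ in range(3)])
        js = [Junction(0, 0, 1, PREFIX, 30, 0, 0),
              Junction(1, 1, 2, PREFIX, 30, 0, 0)]
        groups = group_contigs(pool, js)
        assert len(groups) == 1 and groups[0].contig_ids == [0, 1, 2]

    def test_components_match_union_find_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 12))
            pool = contig_pool(*["ACGT" * 10] * 0 or
                               [_random_seq(rng, 60) for _ in range(n)])
            k = int(rng.integers(0, n * 2))
            links = [(int(rng.integers(0, n)), int(rng.integers(0, n)))
                     for _ in range(k)]
            links = [(a, b) for a, b in links if a != b]
            js = [Junction(i, a, b, PREFIX, 30, 0, 0)
                  for i, (a, b) in enumerate(links)]
            got = frozenset(frozenset(g.contig_ids)
                            for g in group_contigs(pool, js))
            assert got == union_find_components(list(range(n)), links)


class TestFilterJunctionsByGroupSize:
    @staticmethod
    def star_group(n: int, rng) -> ContigGroup:
        ids = list(range(n))
        js = [Junction(i, i, n - 1, PREFIX, 30 + int(rng.integers(0, 50)), 0, 0)
              for i in range(n - 1)]
        return ContigGroup(ids, js)

    def test_oversized_star_decomposed(self, rng):
        g = self.star_group(50, rng)
        out = filter_junctions_by_group_size(g, 40)
        assert all(len(sub.contig_ids) <= 40 for sub in out)
        removed = len(g.junctions) - sum(len(sub.junctions) for sub in out)
        assert removed >= 10

    def test_small_group_untouched(self, rng):
        g = self.star_group(10, rng)
        out = filter_junctions_by_group_size(g, 40)
        assert len(out) == 1 and out[0].junctions == g.junctions

    def test_weakest_junctions_removed_first(self, rng):
        g = self.star_group(50, rng)
        out = filter_junctions_by_group_size(g, 40)
        kept = {j.jid for sub in out for j in sub.junctions}
        # priority-queue oracle: repeatedly drop the smallest overlap
        js = sorted(g.junctions, key=lambda j: (j.overlap, -j.mismatches, j.jid))
        expect_removed = {j.jid for j in js[:len(g.junctions) - len(kept)]}
        assert kept == {j.jid for j in g.junctions} - expect_removed


class TestBuildGraph:
    def test_single_contig_single_node(self, rng):
        pool = contig_pool(_random_seq(rng, 400))
        g = build_graph(ContigGroup([0], []), {0: pool[0]})
        assert g.n_nodes == 1 and g.n_edges == 0

    def test_shared_middle_exon_topology(self, rng):
        # contig shapes the greedy grower actually produces for two isoforms
        # sharing a middle exon: one full isoform, plus the second isoform's
        # flanks each reaching partway into the shared exon
        e1, sh, e2, e3, e4 = (_random_seq(rng, 300), _random_seq(rng, 300),
                              _random_seq(rng, 300), _random_seq(rng, 300),
                              _random_seq(rng, 300))
        pool = contig_pool(e1 + sh + e2, e3 + sh[:90], sh[210:] + e4)
        contigs = {c.id: c for c in pool}
        js = find_junctions(pool, 24, 0.0)
        g = compact(build_graph(group_contigs(pool, js)[0], contigs))
        assert g.n_nodes == 5 and g.n_edges == 4
        degs = sorted((g.g.in_degree(n), g.g.out_degree(n)) for n in g.g.nodes)
        assert degs == [(0, 1), (0, 1), (1, 0), (1, 0), (2, 2)]

    def test_segmentation_reconstructs_contigs(self, rng):
        e1, sh, e2, e3 = (_random_seq(rng, 300), _random_seq(rng, 300),
                          _random_seq(rng, 280), _random_seq(rng, 320))
        pool = contig_pool(e1 + sh + e2, e3 + sh)
        contigs = {c.id: c for c in pool}
        js = find_junctions(pool, 24, 0.0)
        g = build_graph(group_contigs(pool, js)[0], contigs)
        for c in pool:
            joined = "".join(
                c.profile.rep_str()[a:b] for a, b, _ in g.seg_map[c.id])
            assert joined == c.rep_str()

    def test_coverage_conserved_by_segmentation_and_compaction(self, rng):
        e1, sh, e2, e3, e4 = [_random_seq(rng, 250) for _ in range(5)]
        pool = contig_pool(e1 + sh + e2, e3 + sh[:80], sh[170:] + e4)
        contigs = {c.id: c for c in pool}
        total = sum(int(c.profile.coverage().sum()) for c in pool)
        js = find_junctions(pool, 24, 0.0)
        g = build_graph(group_contigs(pool, js)[0], contigs)
        assert g.coverage_total() == total
        assert compact(g).coverage_total() == total


def chain_graph(reps: list[str], edges: list[tuple[int, int]]) -> SplicingGraph:
    g = SplicingGraph()
    for i, rep in enumerate(reps):
        g.add_node(i, NodeData(profile_from_seq(rep), label=str(i)))
    g.g.add_edges_from(edges)
    return g


class TestCompact:
    def test_chain_collapses_to_one_node(self):
        g = chain_graph(["AAAA", "CCCC", "GGGG"], [(0, 1), (1, 2)])
        out = compact(g)
        assert out.n_nodes == 1 and out.n_edges == 0
        assert next(iter(out.data.values())).rep_str() == "AAAACCCCGGGG"

    def test_diamond_already_minimal(self):
        g = chain_graph(["AA", "CC", "GG", "TT"],
                        [(0, 1), (0, 2), (1, 3), (2, 3)])
        out = compact(g)
        assert sorted(out.g.edges) == sorted(g.g.edges)

    def test_idempotent_and_minimal_on_random_graphs(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 10))
            reps = [_random_seq(rng, int(rng.integers(4, 12))) for _ in range(n)]
            edges = {(int(rng.integers(0, n)), int(rng.integers(0, n)))
                     for _ in range(int(rng.integers(0, 2 * n)))}
            g = chain_graph(reps, sorted(edges))
            once = compact(g)
            assert once.is_minimal()
            twice = compact(once)
            assert sorted(twice.g.edges) == sorted(once.g.edges)
            assert twice.n_nodes == once.n_nodes
            # coverage mass conserved
            assert once.coverage_total() == g.coverage_total()


def test_gfa_dump_well_formed(rng):
    g = chain_graph(["AAAA", "CCCC"], [(0, 1)])
    text = to_gfa(g)
    lines = text.strip().split("\n")
    assert lines[0].startswith("H\t")
    s_lines = [l for l in lines if l.startswith("S\t")]
    l_lines = [l for l in lines if l.startswith("L\t")]
    assert len(s_lines) == 2 and len(l_lines) == 1
    assert all(len(l.split("\t")) == 4 for l in s_lines)
    assert all(l.split("\t")[5] == "0M" for l in l_lines)
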