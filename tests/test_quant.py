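"""Path enumeration, loopy-graph rule, pair filtering, non-negative lasso."""

import numpy as np
import pytest

from trareco.graph import NodeData, SplicingGraph
from trareco.quant import (PathCandidate, enumerate_paths, inclusion_matrix,
                           kkt_residual, lasso_objective, nn_lasso,
                           pair_filter, select_candidates, to_rpkm)
from trareco.consensus import profile_from_seq

from oracles import enumerate_paths_oracle, nn_lasso_qp_oracle


def make_graph(n: int, edges: list[tuple[int, int]],
               rep_len: int = 6) -> SplicingGraph:
    g = SplicingGraph()
    for i in range(n):
        g.add_node(i, NodeData(profile_from_seq(("ACGT" * rep_len)[:rep_len]),
                               label=str(i)))
    g.g.add_edges_from(edges)
    return g


class TestEnumeratePaths:
    def test_two_bubbles_give_four_paths(self):
        edges = [(0, 1), (0, 2), (1, 3), (2, 3), (3, 4), (3, 5), (4, 6), (5, 6)]
        g = make_graph(7, edges)
        paths = enumerate_paths(g)
        assert len(paths) == 4

    def test_cycle_allows_double_but_not_triple_inclusion(self):
        # s -> u -> v -> u -> t is legal (u twice); three visits of u are not
        edges = [(0, 1), (1, 2), (2, 1), (1, 3)]
        g = make_graph(4, edges)
        node_seqs = [p.nodes for p in enumerate_paths(g)]
        assert (0, 1, 2, 1, 3) in node_seqs
        assert (0, 1, 3) in node_seqs
        assert all(p.count(1) <= 2 for p in node_seqs)

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 7))
            edges = sorted({(int(rng.integers(0, n)), int(rng.integers(0, n)))
                            for _ in range(int(rng.integers(0, 2 * n)))})
            g = make_graph(n, edges)
            got = sorted(p.nodes for p in enumerate_paths(g))
            expect = sorted(enumerate_paths_oracle(edges, list(range(n))))
            assert got == expect, (n, edges)

    def test_empty_graph(self):
        assert enumerate_paths(SplicingGraph()) == []

    def test_max_paths_cap(self):
        # 2^10 bubble paths, capped at 100
        edges = []
        for i in range(10):
            a = 3 * i
            edges += [(a, a + 1), (a, a + 2), (a + 1, a + 3), (a + 2, a + 3)]
        g = make_graph(31, edges)
        assert len(enumerate_paths(g, max_paths=100)) == 100


class TestPairFilter:
    def test_single_end_identity(self):
        paths = [PathCandidate((0, 1), "ACGT")]
        assert pair_filter(paths, []) == paths

    def test_no_reach_information_identity(self):
        paths = [PathCandidate((0, 1), "ACGT")]
        assert pair_filter(paths, [(0, 1)]) == paths

    def test_unsupported_combination_eliminated(self):
        # two isoforms e1-e2-e3-e4 and e1-e2-e3'-e4; mate pairs link e2 with
        # e3 and e4, and e3' with its own flanks, but never e2..e3'..e4 jointly
        node_len = {0: 300, 1: 300, 2: 300, 3: 300, 4: 300}   # 3 is e3'
        true_a = PathCandidate((0, 1, 2, 4), "A" * 1200)
        true_b = PathCandidate((0, 1, 3, 4), "A" * 1200)
        fake = PathCandidate((0, 1, 4), "A" * 900)            # skips both
        pairs = [(0, 1), (1, 2), (2, 4), (1, 3), (3, 4), (0, 2), (0, 3), (1, 4)]
        kept = pair_filter([true_a, true_b, fake], pairs, node_len, reach=350.0)
        assert true_a in kept and true_b in kept
        assert fake not in kept   # no mate pair ever spanned e1..e4 directly

    def test_cross_isoform_chimera_eliminated(self):
        # diamond: a-S-b real, c-S-d real; a-S-d is an artifact: no mate pair
        # ever spans from a to d
        node_len = {0: 400, 1: 300, 2: 400, 3: 400, 4: 400}
        paths = [PathCandidate((0, 1, 2), "A" * 1100),
                 PathCandidate((0, 1, 4), "A" * 1100),
                 PathCandidate((3, 1, 2), "A" * 1100),
                 PathCandidate((3, 1, 4), "A" * 1100)]
        pairs = [(0, 1), (1, 2), (0, 2), (3, 1), (1, 4), (3, 4)]
        kept = pair_filter(paths, pairs, node_len, reach=320.0)
        assert [p.nodes for p in kept] == [(0, 1, 2), (3, 1, 4)]


class TestInclusionMatrix:
    def test_linear_path(self):
        g = make_graph(3, [(0, 1), (1, 2)])
        paths = enumerate_paths(g)
        A = inclusion_matrix(g, paths)
        assert A.shape == (3, 1) and A[:, 0].tolist() == [1, 1, 1]

    def test_loop_counts_twice(self):
        g = make_graph(4, [(0, 1), (1, 2), (2, 1), (1, 3)])
        paths = enumerate_paths(g)
        A = inclusion_matrix(g, paths)
        loop_col = [j for j, p in enumerate(paths) if len(p.nodes) == 5][0]
        assert A[1, loop_col] == 2

    def test_column_sums_equal_path_node_counts(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 7))
            edges = sorted({(int(rng.integers(0, n)), int(rng.integers(0, n)))
                            for _ in range(n)})
            g = make_graph(n, edges)
            paths = enumerate_paths(g)
            A = inclusion_matrix(g, paths)
            for j, p in enumerate(paths):
                assert A[:, j].sum() == len(p.nodes)


class TestNnLasso:
    def test_exact_recovery_at_zero_penalty(self, rng):
        A = np.eye(4) + 0.1 * rng.random((4, 4))
        x_true = np.abs(rng.random(4)) + 0.5
        x = nn_lasso(A @ x_true, A, 0.0)
        assert np.allclose(x, x_true, atol=1e-6)

    def test_large_penalty_kills_solution(self, rng):
        A = np.abs(rng.random((6, 3)))
        y = np.abs(rng.random(6))
        lam = 2.0 * np.abs(A.T @ y).max()
        assert (nn_lasso(y, A, lam) == 0).all()

    def test_objective_matches_qp_oracle(self, rng):
        for _ in range(50):
            m, n = int(rng.integers(3, 10)), int(rng.integers(1, 6))
            A = rng.random((m, n)) * rng.integers(1, 3, (m, n))
            y = rng.random(m) * 10
            lam = float(rng.choice([0.0, 0.1, 1.0, 5.0]))
            x = nn_lasso(y, A, lam)
            x_qp = nn_lasso_qp_oracle(y, A, lam)
            f, f_qp = lasso_objective(y, A, lam, x), lasso_objective(y, A, lam, x_qp)
            assert f <= f_qp + 1e-6
            assert abs(f - f_qp) <= 1e-6 * max(1.0, abs(f_qp))

    def test_kkt_conditions_hold(self, rng):
        for _ in range(20):
            A = rng.random((8, 4))
            y = rng.random(8) * 5
            x = nn_lasso(y, A, 0.5)
            assert kkt_residual(y, A, 0.5, x) <= 1e-6
            assert lasso_objective(y, A, 0.5, x) <= lasso_objective(
                y, A, 0.5, np.zeros(4))

    def test_l1_norm_non_increasing_in_lambda(self, rng):
        A = np.abs(rng.random((10, 6)))
        y = np.abs(rng.random(10)) * 10
        norms = [np.abs(nn_lasso(y, A, lam)).sum()
                 for lam in [0.0, 0.01, 0.1, 1.0, 10.0, 100.0]]
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_non_finite_inputs_rejected(self):
        with pytest.raises(ValueError):
            nn_lasso(np.array([np.nan]), np.ones((1, 1)), 0.0)


class TestSelection:
    def test_short_paths_dropped(self):
        paths = [PathCandidate((0,), "A" * 180), PathCandidate((1,), "A" * 250)]
        out = select_candidates(paths, np.array([5.0, 5.0]), l_th=200, cd_th=0)
        assert [r.length for r in out] == [250]

    def test_cd_zero_keeps_all_positive(self):
        paths = [PathCandidate((0,), "A" * 300), PathCandidate((1,), "A" * 300)]
        out = select_candidates(paths, np.array([0.4, 0.0]), l_th=200, cd_th=0)
        assert len(out) == 1 and out[0].depth == pytest.approx(0.4)

    def test_candidate_count_monotone_in_cd_th(self, rng):
        paths = [PathCandidate((i,), "A" * 300) for i in range(20)]
        x = rng.random(20) * 20
        counts = [len(select_candidates(paths, x, 200, cd))
                  for cd in (0, 1, 2, 4, 8, 12, 16)]
        assert counts == sorted(counts, reverse=True)


class TestRpkm:
    def test_direct_value(self):
        assert to_rpkm(1.0, 100, 10**6) == pytest.approx(10.0)

    def test_zero_depth(self):
        assert to_rpkm(0.0, 100, 10**6) == 0.0

    def test_round_trip_against_read_count_form(self, rng):
        for _ in range(20):
            d = float(rng.random() * 50)
            l_k = int(rng.integers(300, 3000))
            L = 100.0
            N = int(rng.integers(10**5, 10**7))
            n_k = d * l_k / L
            assert to_rpkm(d, L, N) == pytest.approx(1e9 * n_k / (l_k * N))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            to_rpkm(1.0, 0, 10**6)
        with pytest.raises(ValueError):
            to_rpkm(1.0, 100, 0)
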