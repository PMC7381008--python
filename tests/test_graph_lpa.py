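import warnings

import numpy as np
import pytest

from conftest import random_graph
from lexiprop import (
    SeedSet,
    build_graph,
    init_labels,
    propagate_step,
    propagate_to_convergence,
    solve_exact,
    threshold_lexicon,
    transition_matrix,
)
from lexiprop.embeddings import CandidateSet
from lexiprop.graph_lpa import LabelState


def chain_graph():
    """dep seed s -- u -- nondep seed t with sims 0.8 / 0.4."""
    cand = CandidateSet(words={"s", "t", "u"},
                        edges=[("s", "u", 0.8), ("t", "u", 0.4)], T_c=0.3)
    seeds = SeedSet(depressive={"s"}, nondepressive={"t"})
    return build_graph(cand, seeds)


class TestBuildGraph:
    def test_node_and_edge_counts(self):
        g = chain_graph()
        assert g.n == 3 and g.weights.nnz == 4  # 2 undirected edges stored twice

    def test_node_order_seeds_first(self):
        g = chain_graph()
        assert g.nodes == ["s", "t", "u"]
        assert g.flags == ["seed_dep", "seed_nondep", "unknown"]

    def test_missing_polarity_rejected(self):
        cand = CandidateSet(words={"s", "u"}, edges=[("s", "u", 0.9)], T_c=0.5)
        with pytest.raises(ValueError):
            build_graph(cand, SeedSet(depressive={"s"}, nondepressive={"zz"}))

    def test_edgeless_candidates_rejected(self):
        cand = CandidateSet(words={"s", "t"}, edges=[], T_c=0.5)
        with pytest.raises(ValueError):
            build_graph(cand, SeedSet(depressive={"s"}, nondepressive={"t"}))

    def test_isolated_node_flagged(self):
        cand = CandidateSet(words={"s", "t", "u", "lone"},
                            edges=[("s", "u", 0.8), ("t", "u", 0.4)], T_c=0.3)
        with pytest.warns(UserWarning, match="isolated"):
            g = build_graph(cand, SeedSet(depressive={"s"}, nondepressive={"t"}))
        assert g.isolated == ["lone"]


class TestTransitionMatrix:
    def test_hand_normalization(self):
        g = chain_graph()
        T = transition_matrix(g).toarray()
        u = g.nodes.index("u")
        assert T[g.nodes.index("s"), u] == pytest.approx(0.8 / 1.2)
        assert T[g.nodes.index("t"), u] == pytest.approx(0.4 / 1.2)

    def test_single_neighbor_column_is_exactly_one(self):
        g = chain_graph()
        T = transition_matrix(g).toarray()
        s = g.nodes.index("s")
        assert T[g.nodes.index("u"), s] == 1.0

    def test_columns_sum_to_one(self, bench_space, bench_seeds):
        from lexiprop import extend_candidates
        cand = extend_candidates(bench_seeds, bench_space, 0.5)
        g = build_graph(cand, bench_seeds)
        T = transition_matrix(g)
        sums = np.asarray(T.sum(axis=0)).ravel()
        deg = np.asarray(g.weights.getnnz(axis=0))
        assert np.allclose(sums[deg > 0], 1.0, atol=1e-12)
        assert np.all(sums[deg == 0] == 0.0)

    def test_isolated_node_zero_column(self):
        cand = CandidateSet(words={"s", "t", "u", "lone"},
                            edges=[("s", "u", 0.8), ("t", "u", 0.4)], T_c=0.3)
        with pytest.warns(UserWarning):
            g = build_graph(cand, SeedSet(depressive={"s"}, nondepressive={"t"}))
        T = transition_matrix(g).toarray()
        i = g.nodes.index("lone")
        assert not T[:, i].any() and not T[i, :].any()

    def test_row_normalization_variant(self):
        g = chain_graph()
        T = transition_matrix(g, normalization="row").toarray()
        sums = T.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)


class TestPropagation:
    def test_init_labels_ten_node_illustration(self):
        words = ["i1", "i2", "i3"] + [f"j{k}" for k in range(7)]
        edges = [("i1", "j0", 0.7), ("i2", "j1", 0.7), ("i3", "j2", 0.7)]
        edges += [(a, b, 0.6) for a, b in zip(words[3:], words[4:])]
        cand = CandidateSet(words=set(words), edges=edges, T_c=0.5)
        g = build_graph(cand, SeedSet(depressive={"i1", "i2"}, nondepressive={"i3"}))
        state = init_labels(g)
        assert list(state.V) == [-1, -1, 1, 0, 0, 0, 0, 0, 0, 0]
        assert state.iteration == 0

    def test_one_step_hand_value(self):
        g = chain_graph()
        T = transition_matrix(g)
        state = propagate_step(T, init_labels(g), g)
        assert state.V[g.nodes.index("u")] == pytest.approx(2 / 3 * -1 + 1 / 3 * 1)
        assert state.iteration == 1

    def test_seed_labels_clamped_each_step(self):
        g = chain_graph()
        T = transition_matrix(g)
        state = init_labels(g)
        for _ in range(5):
            state = propagate_step(T, state, g)
            assert state.V[g.nodes.index("s")] == -1.0
            assert state.V[g.nodes.index("t")] == 1.0

    def test_star_graph_converges_after_one_effective_step(self):
        words = ["s", "t", "u1", "u2"]
        edges = [("s", "u1", 0.9), ("t", "u1", 0.9), ("s", "u2", 0.5), ("t", "u2", 0.9)]
        cand = CandidateSet(words=set(words), edges=edges, T_c=0.4)
        g = build_graph(cand, SeedSet(depressive={"s"}, nondepressive={"t"}))
        state = propagate_to_convergence(g, tol=1e-10)
        assert state.converged and state.iteration == 2

    def test_symmetric_chain_fixed_point_is_zero(self):
        cand = CandidateSet(words={"s", "t", "u"},
                            edges=[("s", "u", 0.6), ("t", "u", 0.6)], T_c=0.5)
        g = build_graph(cand, SeedSet(depressive={"s"}, nondepressive={"t"}))
        state = propagate_to_convergence(g, tol=1e-12)
        assert state.V[g.nodes.index("u")] == pytest.approx(0.0, abs=1e-10)

    def test_chain_exact_value(self):
        g = chain_graph()
        state = propagate_to_convergence(g, tol=1e-12)
        assert state.V[g.nodes.index("u")] == pytest.approx(-1 / 3, abs=1e-9)

    def test_max_iter_reached_warns_and_flags(self):
        # 4-chain s - u1 - u2 - t converges only asymptotically
        cand = CandidateSet(words={"s", "t", "u1", "u2"},
                            edges=[("s", "u1", 0.8), ("u1", "u2", 0.6), ("t", "u2", 0.7)],
                            T_c=0.5)
        g = build_graph(cand, SeedSet(depressive={"s"}, nondepressive={"t"}))
        with pytest.warns(UserWarning, match="converge"):
            state = propagate_to_convergence(g, tol=1e-12, max_iter=3)
        assert not state.converged


class TestSolveExact:
    def test_single_unknown_linear_solve(self):
        g = chain_graph()
        state = solve_exact(g)
        assert state.V[g.nodes.index("u")] == pytest.approx(-1 / 3)

    def test_seedfree_component_zeroed_and_reported(self):
        words = {"s", "t", "u", "a", "b"}
        edges = [("s", "u", 0.8), ("t", "u", 0.4), ("a", "b", 0.9)]
        cand = CandidateSet(words=words, edges=edges, T_c=0.3)
        g = build_graph(cand, SeedSet(depressive={"s"}, nondepressive={"t"}))
        with pytest.warns(UserWarning, match="seed-free"):
            state = solve_exact(g)
        assert state.V[g.nodes.index("a")] == 0.0
        assert state.V[g.nodes.index("b")] == 0.0

    def test_agrees_with_iteration_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            g, _ = random_graph(rng)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                it = propagate_to_convergence(g, tol=1e-8, max_iter=20000)
                ex = solve_exact(g)
            assert np.max(np.abs(it.V - ex.V)) <= 1e-6

    def test_sign_symmetry_under_polarity_swap(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            g, seeds = random_graph(rng, n_max=30)
            swapped = SeedSet(depressive=seeds.nondepressive, nondepressive=seeds.depressive)
            from lexiprop.embeddings import CandidateSet as CS
            edges = []
            W = g.weights.tocoo()
            for i, j, v in zip(W.row, W.col, W.data):
                if i < j:
                    a, b = sorted((g.nodes[i], g.nodes[j]))
                    edges.append((a, b, float(v)))
            cand = CS(words=set(g.nodes), edges=edges, T_c=0.5)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                g2 = build_graph(cand, swapped)
                v1 = dict(zip(g.nodes, solve_exact(g).V))
                v2 = dict(zip(g2.nodes, solve_exact(g2).V))
            for w in v1:
                assert v2[w] == pytest.approx(-v1[w], abs=1e-10)

    def test_labels_bounded_every_iteration(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            g, _ = random_graph(rng, n_max=30)
            T = transition_matrix(g)
            state = init_labels(g)
            for _ in range(50):
                state = propagate_step(T, state, g)
                assert np.all(state.V >= -1.0 - 1e-12)
                assert np.all(state.V <= 1.0 + 1e-12)


class TestThresholdLexicon:
    def make_state(self, g, values):
        V = np.array([values[w] for w in g.nodes], dtype=float)
        return LabelState(V=V, iteration=1, converged=True)

    def test_strict_cut(self):
        g = chain_graph()
        lex = threshold_lexicon(self.make_state(g, {"s": -1, "t": 1, "u": -0.6}), g)
        assert "u" in lex.depressive
        lex = threshold_lexicon(self.make_state(g, {"s": -1, "t": 1, "u": -0.5}), g)
        assert "u" not in lex.depressive and "u" not in lex.nondepressive

    def test_zero_label_excluded(self):
        g = chain_graph()
        lex = threshold_lexicon(self.make_state(g, {"s": -1, "t": 1, "u": 0.0}), g)
        assert len(lex) == 2  # just the seeds

    def test_seeds_always_included_at_unit_score(self):
        g = chain_graph()
        lex = threshold_lexicon(self.make_state(g, {"s": -1, "t": 1, "u": 0.9}), g)
        assert lex.depressive["s"] == -1.0 and lex.nondepressive["t"] == 1.0
        assert lex.nondepressive["u"] == pytest.approx(0.9)

    def test_lexicon_size_nonincreasing_in_cut(self, bench_space, bench_seeds):
        from lexiprop import extend_candidates
        cand = extend_candidates(bench_seeds, bench_space, 0.5)
        g = build_graph(cand, bench_seeds)
        state = propagate_to_convergence(g)
        sizes = [len(threshold_lexicon(state, g, cut=c)) for c in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert sizes == sorted(sizes, reverse=True)

    def test_tsv_roundtrip(self, tmp_path):
        g = chain_graph()
        lex = threshold_lexicon(self.make_state(g, {"s": -1, "t": 1, "u": -0.7}), g)
        path = tmp_path / "lex.tsv"
        lex.to_tsv(path)
        from lexiprop.graph_lpa import Lexicon
        lex2 = Lexicon.from_tsv(path)
        assert set(lex2.depressive) == set(lex.depressive)
        assert lex2.depressive["u"] == pytest.approx(-0.7, abs=1e-6)
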