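"""Signed-graph construction, cycle enumeration and the odd-cycle rule."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oscicycle import (
    CAPABLE,
    NOT_CAPABLE,
    CycleRecord,
    SignedDigraph,
    classify_cycle,
    enumerate_simple_cycles,
    enumerate_subnetworks,
    loop_coverage,
    motif_graph,
    network_oscillation_potential,
    subnetwork_count,
)
from oscicycle.exceptions import ArgumentError, SizeError
from oscicycle.fixtures import CBG_LOOPS, generate_random_signed_graph


class TestSignedDigraph:
    def test_edge_sign_derived_from_source(self):
        g = SignedDigraph([("a", "E"), ("b", "I")], [("a", "b"), ("b", "a")])
        assert not g.edge_is_inhibitory("a", "b")
        assert g.edge_is_inhibitory("b", "a")

    def test_mixed_sign_node_rejected(self):
        with pytest.raises(ArgumentError):
            SignedDigraph([("a", "E"), ("a", "I")], [])

    def test_duplicate_edge_rejected(self):
        with pytest.raises(ArgumentError):
            SignedDigraph([("a", "E"), ("b", "E")], [("a", "b"), ("a", "b")])

    def test_unknown_endpoint_rejected(self):
        with pytest.raises(ArgumentError):
            SignedDigraph([("a", "E")], [("a", "zzz")])

    def test_self_loop_allowed(self):
        g = SignedDigraph([("a", "I")], [("a", "a")])
        cycles = enumerate_simple_cycles(g)
        assert len(cycles) == 1 and cycles[0].length == 1

    def test_json_roundtrip(self, cbg, tmp_path):
        path = tmp_path / "g.json"
        path.write_text(__import__("json").dumps(cbg.to_dict()))
        g2 = SignedDigraph.from_json(path)
        assert sorted(g2.nodes) == sorted(cbg.nodes)
        assert sorted(g2.edges) == sorted(cbg.edges)

    def test_csv_roundtrip(self, tmp_path):
        (tmp_path / "nodes.csv").write_text("node,sign\na,E\nb,I\n")
        (tmp_path / "edges.csv").write_text("source,target\na,b\nb,a\n")
        g = SignedDigraph.from_csv(tmp_path / "edges.csv", tmp_path / "nodes.csv")
        assert g.sign("b") == "I" and ("a", "b") in g.edges

    def test_dot_export_mentions_all_nodes(self, iii_graph):
        dot = iii_graph.to_dot()
        for n in iii_graph.nodes:
            assert n in dot


class TestCycleEnumeration:
    def test_ei_pair_single_cycle(self):
        g = motif_graph("EI")
        cycles = enumerate_simple_cycles(g)
        assert len(cycles) == 1 and cycles[0].length == 2

    def test_iii_ring_single_cycle(self, iii_graph):
        cycles = enumerate_simple_cycles(iii_graph)
        assert len(cycles) == 1 and cycles[0].length == 3
        assert cycles[0].n_inhibitory == 3

    def test_cbg_contains_the_six_loops(self, cbg):
        canon = {CycleRecord.canonicalize(seq) for seq in CBG_LOOPS.values()}
        found = {c.nodes for c in enumerate_simple_cycles(cbg)}
        assert canon <= found

    def test_size_guard(self):
        g = SignedDigraph([(f"n{i}", "E") for i in range(21)], [])
        with pytest.raises(SizeError):
            enumerate_simple_cycles(g)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_path_search(self, seed):
        """Johnson-algorithm enumeration agrees with brute-force DFS over
        all simple paths on small random graphs."""
        g = generate_random_signed_graph(6, edge_prob=0.35, self_loops=True, seed=seed)
        edge_set = set(g.edges)
        names = g.nodes
        brute = set()
        for length in range(1, len(names) + 1):
            for perm in itertools.permutations(names, length):
                ok = all(
                    (perm[i], perm[(i + 1) % length]) in edge_set
                    for i in range(length)
                )
                if ok:
                    brute.add(CycleRecord.canonicalize(perm))
        ours = {c.nodes for c in enumerate_simple_cycles(g)}
        assert ours == brute


class TestOddCycleRule:
    @pytest.mark.parametrize(
        "motif, verdict",
        [("EI", CAPABLE), ("EEI", CAPABLE), ("EII", NOT_CAPABLE),
         ("III", CAPABLE), ("EEE", NOT_CAPABLE), ("II", NOT_CAPABLE)],
    )
    def test_ring_motifs(self, motif, verdict):
        (cycle,) = enumerate_simple_cycles(motif_graph(motif))
        assert classify_cycle(cycle) == verdict

    @given(st.lists(st.sampled_from("EI"), min_size=1, max_size=10),
           st.integers(0, 9))
    @settings(deadline=None, max_examples=100)
    def test_parity_invariant_under_rotation(self, signs, shift):
        names = [f"{s}{i}" for i, s in enumerate(signs)]
        g = SignedDigraph(
            list(zip(names, signs)),
            [(names[i], names[(i + 1) % len(names)]) for i in range(len(names))],
        )
        rec = CycleRecord.from_graph(g, names)
        rotated = names[shift % len(names):] + names[: shift % len(names)]
        rec2 = CycleRecord.from_graph(g, rotated)
        assert rec.parity == rec2.parity
        assert rec.nodes == rec2.nodes  # canonical form identical

    def test_acyclic_network_cannot_oscillate(self):
        g = SignedDigraph(
            [("a", "E"), ("b", "I"), ("c", "E")], [("a", "b"), ("a", "c"), ("b", "c")]
        )
        rep = network_oscillation_potential(g)
        assert not rep.can_oscillate and rep.cycles == []

    def test_eii_only_network_cannot_oscillate(self):
        rep = network_oscillation_potential(motif_graph("EII"))
        assert not rep.can_oscillate

    def test_eei_network_can_oscillate(self):
        rep = network_oscillation_potential(motif_graph("EEI"))
        assert rep.can_oscillate

    def test_negative_self_loop_reported_separately(self):
        g = SignedDigraph([("a", "I")], [("a", "a")])
        rep = network_oscillation_potential(g)
        assert rep.can_oscillate
        assert len(rep.negative_self_loops) == 1


class TestSubnetworks:
    def test_trivial_counts(self, cbg):
        g3 = SignedDigraph([("a", "E"), ("b", "E"), ("c", "E")], [])
        assert len(list(enumerate_subnetworks(g3, 2, 3))) == 4
        assert len(list(enumerate_subnetworks(g3, 3, 3))) == 1
        assert len(list(enumerate_subnetworks(cbg, 2, 7))) == 246

    def test_bad_bounds(self, cbg):
        with pytest.raises(ArgumentError):
            list(enumerate_subnetworks(cbg, 0, 3))
        with pytest.raises(ArgumentError):
            list(enumerate_subnetworks(cbg, 5, 3))

    @given(st.integers(1, 10), st.data())
    @settings(deadline=None, max_examples=60)
    def test_count_matches_binomial_sum(self, n, data):
        kmin = data.draw(st.integers(1, n))
        kmax = data.draw(st.integers(kmin, n))
        g = SignedDigraph([(f"n{i}", "E") for i in range(n)], [])
        subs = list(enumerate_subnetworks(g, kmin, kmax))
        assert len(subs) == len(set(subs)) == subnetwork_count(n, kmin, kmax)
        assert subnetwork_count(n, kmin, kmax) == sum(
            math.comb(n, k) for k in range(kmin, kmax + 1)
        )


def _coverage_inclusion_exclusion(n_nodes, loop_sets, kmin, kmax):
    """Independent oracle: inclusion-exclusion over unions of loop node sets."""
    total = 0
    for r in range(1, len(loop_sets) + 1):
        for combo in itertools.combinations(loop_sets, r):
            union = frozenset().union(*combo)
            u = len(union)
            count = sum(
                math.comb(n_nodes - u, k - u)
                for k in range(max(kmin, u), kmax + 1)
            )
            total += (-1) ** (r + 1) * count
    return total


class TestLoopCoverage:
    def test_single_loop_small_graph(self):
        g = SignedDigraph([("1", "E"), ("2", "I"), ("3", "E")], [("1", "2"), ("2", "1")])
        rep = loop_coverage(g, [{"1", "2"}], 2, 3)
        assert rep.total == 4 and rep.covered == 2

    def test_unknown_loop_node(self, cbg):
        with pytest.raises(ArgumentError):
            loop_coverage(cbg, [{"Proto", "Unknown"}], 2, 7)

    def test_cbg_against_inclusion_exclusion(self, cbg):
        loop_sets = [frozenset(s) for s in CBG_LOOPS.values()]
        rep = loop_coverage(cbg, loop_sets, 2, 7)
        assert rep.covered == _coverage_inclusion_exclusion(8, loop_sets, 2, 7)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_graphs_against_inclusion_exclusion(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        g = generate_random_signed_graph(n, edge_prob=0.4, seed=rng)
        cycles = enumerate_simple_cycles(g)
        loop_sets = list({frozenset(c.nodes) for c in cycles})[:4]
        if not loop_sets:
            loop_sets = [frozenset(list(g.nodes)[:2])]
        kmin, kmax = 2, n - 1 if n > 2 else n
        rep = loop_coverage(g, loop_sets, kmin, kmax)
        assert rep.covered == _coverage_inclusion_exclusion(n, loop_sets, kmin, kmax)
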