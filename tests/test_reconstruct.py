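"""Reconstruction: evidence graphs, feasibility, enumeration, long-insert filter."""

from collections import Counter

import numpy as np
import pytest

from conftest import brute_force_solutions, small_reference
from unscramble.genome import HalfSite, SignedCircularGenome, junction_pair
from unscramble.reconstruct import (
    InfeasibleEvidenceError,
    build_junction_graph,
    count_genomes,
    enumerate_genomes,
    filter_and_select,
    is_feasible,
    long_insert_consistency,
)
from unscramble.simulate import ReadModel, SimulationConfig, simulate_long_pairs, simulate_scramble


def hs(t):
    return HalfSite.parse(t)


def jp(a, b):
    return junction_pair(hs(a), hs(b))


def evidence_of(seq):
    g = SignedCircularGenome(seq)
    return list(g.adjacency_multiset().items()), dict(g.copy_numbers())


class TestBuildGraph:
    def test_parental_circle_shape(self):
        edges, copies = evidence_of(range(1, 6))
        graph = build_junction_graph(edges, copies)
        assert len(graph.vertices) == 10
        assert sum(graph.junction_edges.values()) == 5
        assert sum(graph.copy_numbers.values()) == 5

    def test_deletion_strain_shape(self):
        edges, copies = evidence_of([1, 2, 4])
        graph = build_junction_graph(edges, copies)
        assert len(graph.vertices) == 6
        assert sum(graph.junction_edges.values()) == 3

    def test_self_pair_with_parallel_segment_edges(self):
        edges, copies = evidence_of([1, 2, 2, 3])
        graph = build_junction_graph(edges, copies)
        assert graph.copy_numbers[2] == 2
        assert graph.junction_edges[jp("2R", "2L")] == 1

    def test_parental_multiplicity_inferred_from_copy_numbers(self):
        # (1,2,3,2,3,4): the parental pair {2R,3L} occurs twice
        g = SignedCircularGenome([1, 2, 3, 2, 3, 4])
        parental = small_reference(4).parental_pairs
        pairs = set(g.adjacency_multiset())
        graph = build_junction_graph(pairs, g.copy_numbers(), parental_pairs=parental)
        assert graph.junction_edges[jp("2R", "3L")] == 2

    def test_junction_to_zero_copy_segment_rejected(self):
        with pytest.raises(InfeasibleEvidenceError, match="zero-copy"):
            build_junction_graph([jp("1R", "2L")], {1: 1, 2: 0})


class TestMultiplicityInference:
    def test_reused_parental_adjacency_balanced(self):
        from unscramble.junctions import JunctionObservation
        from unscramble.reconstruct import infer_junction_multiplicities

        # (1,2,3,4,2,3,5): the parental pair {2R,3L} is used twice, while
        # {3R,4L} (also between two duplicated segments) is used once
        g = SignedCircularGenome([1, 2, 3, 4, 2, 3, 5])
        ref = small_reference(5)
        obs = [
            JunctionObservation(pair, 10, "x")
            for pair in g.adjacency_multiset()
        ]
        mults = infer_junction_multiplicities(obs, ref.parental_pairs, g.copy_numbers())
        assert mults[jp("2R", "3L")] == 2
        assert mults[jp("3R", "4L")] == 1
        graph = build_junction_graph(
            [o.pair for o in obs], g.copy_numbers(), multiplicities=mults
        )
        ok, _ = is_feasible(graph)
        assert ok
        assert g.canonical() in set(enumerate_genomes(graph).candidates)


class TestFeasibility:
    def test_parental_circle_feasible(self):
        edges, copies = evidence_of(range(1, 4))
        ok, problems = is_feasible(build_junction_graph(edges, copies))
        assert ok and not problems

    def test_missing_junction_reports_degree_deficit(self):
        edges = [jp("1R", "2L"), jp("2R", "3L")]  # {3R,1L} missing
        ok, problems = is_feasible(build_junction_graph(edges, {1: 1, 2: 1, 3: 1}))
        assert not ok
        assert any("3R" in p for p in problems) and any("1L" in p for p in problems)

    def test_two_disjoint_circles_infeasible(self):
        edges = [jp("1R", "2L"), jp("2R", "1L"), jp("3R", "4L"), jp("4R", "3L")]
        ok, problems = is_feasible(build_junction_graph(edges, {i: 1 for i in range(1, 5)}))
        assert not ok and any("components" in p for p in problems)
        # brute force: no single circular sequence realizes both sub-circles
        ev = Counter({jp("1R", "2L"): 1, jp("2R", "1L"): 1, jp("3R", "4L"): 1, jp("4R", "3L"): 1})
        assert brute_force_solutions(ev, {i: 1 for i in range(1, 5)}) == set()


class TestEnumeration:
    def test_deletion_strain_unique_solution(self):
        edges, copies = evidence_of([1, 2, 4])
        rs = enumerate_genomes(build_junction_graph(edges, copies))
        assert [c.sequence for c in rs.candidates] == [(1, 2, 4)]

    def test_parental_evidence_returns_parent(self):
        edges, copies = evidence_of(range(1, 44))
        rs = enumerate_genomes(build_junction_graph(edges, copies))
        assert rs.total_count == 1
        assert rs.selected.sequence == tuple(range(1, 44))

    def test_two_solution_duplication_ambiguity(self):
        pairs = [
            jp("1R", "2L"), jp("2R", "3L"), jp("3R", "4L"), jp("4R", "5L"),
            jp("5R", "2L"), jp("2R", "6L"), jp("6R", "4L"), jp("4R", "1L"),
        ]
        graph = build_junction_graph(pairs, {1: 1, 2: 2, 3: 1, 4: 2, 5: 1, 6: 1})
        rs = enumerate_genomes(graph)
        assert {c.sequence for c in rs.candidates} == {
            (1, 2, 3, 4, 5, 2, 6, 4),
            (1, 2, 6, 4, 5, 2, 3, 4),
        }
        assert count_genomes(graph) == 2

    def test_candidates_share_length_copy_vector_and_adjacencies(self, synixr):
        for s in range(20):
            g, _ = simulate_scramble(synixr, SimulationConfig(n_events=4), seed=500 + s)
            if max(g.copy_numbers().values()) > 3:
                continue
            edges, copies = evidence_of(g.sequence)
            rs = enumerate_genomes(build_junction_graph(edges, copies), limit=3000)
            ev = g.adjacency_multiset()
            for c in rs.candidates:
                assert len(c) == len(g)
                assert c.copy_numbers() == g.copy_numbers()
                assert c.adjacency_multiset() == ev

    def test_infeasible_graph_raises(self):
        graph = build_junction_graph([jp("1R", "2L")], {1: 1, 2: 1})
        with pytest.raises(InfeasibleEvidenceError):
            enumerate_genomes(graph)

    def test_count_matches_enumeration_on_random_strains(self, synixr):
        for s in range(25):
            g, _ = simulate_scramble(synixr, SimulationConfig(n_events=5), seed=900 + s)
            if max(g.copy_numbers().values()) > 3:
                continue
            edges, copies = evidence_of(g.sequence)
            graph = build_junction_graph(edges, copies)
            rs = enumerate_genomes(graph, limit=100_000)
            assert count_genomes(graph) == rs.total_count

    def test_rotations_fixed_convention_counts_orbits(self):
        edges, copies = evidence_of([1, 2, 3])
        graph = build_junction_graph(edges, copies)
        assert count_genomes(graph, "canonical") == 1
        # 3 rotations of (1,2,3) plus 3 of the reflection (-3,-2,-1)
        assert count_genomes(graph, "rotations-fixed") == 6


class TestBruteForceOracle:
    def test_enumeration_equals_brute_force_small(self):
        # spot-check beyond the exhaustive acceptance sweep
        for seq in [(1, 2, 3, 4), (1, -3, -2, 4), (1, 2, 2, 3), (1, 2, -2, 3),
                    (1, 2, 3, 2, 3), (1, -2, 2, 3), (1, 2, 1, -2)]:
            g = SignedCircularGenome(seq)
            ev = g.adjacency_multiset()
            copies = dict(g.copy_numbers())
            got = set(enumerate_genomes(build_junction_graph(list(ev.items()), copies)).candidates)
            assert got == brute_force_solutions(ev, copies)


class TestLongInsertFilter:
    @pytest.fixture
    def toy(self):
        ref = small_reference(6)
        A = SignedCircularGenome([1, 2, 3, 4, 5, 2, 6, 4])
        B = SignedCircularGenome([1, 2, 6, 4, 5, 2, 3, 4])
        return ref, A, B

    def test_all_parental_pairs_are_regular(self, toy):
        ref, A, _ = toy
        g = ref.parental_genome()
        rm = ReadModel(long_insert_mean=2500, long_insert_sd=100)
        lp = simulate_long_pairs(g, ref, rm, n_pairs=80, seed=1)
        chk = long_insert_consistency(g, lp, ref, min_insert=1500, max_insert=3500)
        assert chk.rate == 1.0 and not chk.irregular_clusters

    def test_pairs_from_A_discriminate_against_B(self, toy):
        ref, A, B = toy
        rm = ReadModel(long_insert_mean=2500, long_insert_sd=100)
        lp = simulate_long_pairs(A, ref, rm, n_pairs=200, seed=2)
        chkA = long_insert_consistency(A, lp, ref, min_insert=1500, max_insert=3500)
        chkB = long_insert_consistency(B, lp, ref, min_insert=1500, max_insert=3500)
        assert chkA.rate == 1.0
        assert chkB.SE > 0 and chkB.rate < chkA.rate

    def test_filter_keeps_generating_candidate(self, toy):
        ref, A, B = toy
        rm = ReadModel(long_insert_mean=2500, long_insert_sd=100)
        lp = simulate_long_pairs(A, ref, rm, n_pairs=200, seed=3)
        res = filter_and_select(
            [A, B], lp, ref, min_insert=1500, max_insert=3500
        )
        assert res.candidates == [A.canonical()]
        assert res.selected == A.canonical()

    def test_no_long_pairs_keeps_all_selects_lowest(self, toy):
        ref, A, B = toy
        res = filter_and_select([B, A], None, ref)
        assert len(res.candidates) == 2
        assert res.selected == min(A.canonical(), B.canonical(), key=lambda g: g.sequence)

    def test_single_candidate_returned_unchanged(self, toy):
        ref, A, _ = toy
        res = filter_and_select([A], None, ref)
        assert res.candidates == [A.canonical()] and res.selected == A.canonical()

    def test_true_genome_never_removed_noiseless(self, synixr):
        kept = 0
        trials = 0
        for s in range(60):
            g, _ = simulate_scramble(synixr, SimulationConfig(n_events=3), seed=2000 + s)
            if max(g.copy_numbers().values()) > 3:
                continue
            trials += 1
            edges, copies = evidence_of(g.sequence)
            rs = enumerate_genomes(build_junction_graph(edges, copies), limit=5000)
            lp = simulate_long_pairs(
                g, synixr, ReadModel(long_insert_sd=500), n_pairs=300, seed=s
            )
            res = filter_and_select(rs.candidates, lp, synixr)
            if g.canonical() in set(res.candidates):
                kept += 1
        assert kept == trials
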