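"""Breakpoint graph, FISH partition, cycle decomposition, abundances."""

import numpy as np
import pandas as pd
import pytest

from dmrecon import (
    build_graph,
    decompose_cycles,
    estimate_abundances,
    make_truth,
    partition_populations_by_fish,
    simulate_fish,
    structure_summary,
)
from dmrecon.assembly import DecompositionError, GraphError
from dmrecon.config import SimConfig
from dmrecon.structures import (
    ADJACENCY,
    DMStructure,
    Junction,
    JunctionSide,
    Segment,
    shared_junction_ids,
)

from helpers import (
    cycles_equal_up_to_symmetry,
    oracle_decompose,
    random_graph_instance,
)


def truth_graph(seed=1, infer=True):
    cfg = SimConfig(seed=seed)
    truth = make_truth(cfg)
    segs = []
    for name, s in truth.segments.items():
        s.tier = truth.multiplicity(name)
        segs.append(s)
    junctions = truth.junctions
    if infer:
        for j in junctions:
            j.multiplicity = 1  # exercise the balance-based inference
    return cfg, truth, build_graph(segs, junctions)


class TestBuildGraph:
    def test_default_fixture_edge_counts(self):
        _, _, graph = truth_graph()
        assert len(graph.segments) == 11
        assert len(graph.junction_edges) == 8
        shared = [e for e in graph.junction_edges if e.multiplicity == 2]
        assert len(shared) == 1
        assert shared[0].id == "IV"

    def test_no_junctions_no_cycles(self):
        segs = [Segment("a", "c", 0, 100, tier=1)]
        # a lone amplified segment has dangling ends
        with pytest.raises(GraphError):
            build_graph(segs, [])
        # with no amplified segments at all there is nothing to decompose
        graph = build_graph([], [])
        assert decompose_cycles(graph) == []

    def test_overloaded_node_rejected(self):
        segs = [
            Segment("a", "c", 0, 100, tier=1),
            Segment("b", "c", 200, 300, tier=1),
            Segment("d", "c", 400, 500, tier=1),
        ]
        js = [
            Junction("j1", JunctionSide("c", 100, "-", "a"), JunctionSide("c", 200, "+", "b")),
            Junction("j2", JunctionSide("c", 100, "-", "a"), JunctionSide("c", 400, "+", "d")),
            Junction("j3", JunctionSide("c", 100, "-", "a"), JunctionSide("c", 300, "-", "b")),
        ]
        with pytest.raises(GraphError, match="balance"):
            build_graph(segs, js)

    def test_junction_on_baseline_segment_rejected(self):
        segs = [Segment("a", "c", 0, 100, tier=0), Segment("b", "c", 200, 300, tier=1)]
        js = [Junction("j1", JunctionSide("c", 100, "-", "a"),
                       JunctionSide("c", 200, "+", "b"))]
        with pytest.raises(GraphError):
            build_graph(segs, js)


class TestFishPartition:
    def test_default_truth_two_populations(self, truth, sim_config):
        table = simulate_fish(truth, sim_config)
        part = partition_populations_by_fish(table, probe_map=sim_config.fish_probes)
        assert len(part.patterns) == 2
        h4b_positive = [p for p, pat in part.patterns.items() if pat["BAC-H4b"]]
        assert len(h4b_positive) == 1

    def test_single_pattern_single_population(self):
        table = pd.DataFrame(
            {"cell_id": ["c0", "c0", "c1"], "dm_id": ["d0", "d1", "d2"],
             "p1": [1, 1, 1], "p2": [1, 1, 1]}
        )
        part = partition_populations_by_fish(table)
        assert len(part.patterns) == 1

    def test_recovered_means_within_one_percent(self, truth):
        cfg = SimConfig(seed=17)
        cfg.n_cells = 10000
        table = simulate_fish(truth, cfg)
        part = partition_populations_by_fish(table, probe_map=cfg.fish_probes)
        means = sorted(part.mean_counts.values())
        assert means[0] == pytest.approx(101.0, rel=0.01)
        assert means[1] == pytest.approx(107.0, rel=0.01)

    def test_all_zero_dms_reported_unassigned(self):
        table = pd.DataFrame(
            {"cell_id": ["c0", "c0"], "dm_id": ["d0", "d1"],
             "p1": [1, 0], "p2": [0, 0]}
        )
        part = partition_populations_by_fish(table)
        assert part.n_unassigned == 1

    def test_subset_merge_folds_dropout_pattern(self):
        table = pd.DataFrame(
            {"cell_id": ["c0"] * 6, "dm_id": [f"d{i}" for i in range(6)],
             "p1": [1, 1, 1, 1, 1, 1], "p2": [1, 1, 1, 1, 0, 1]}
        )
        merged = partition_populations_by_fish(table, subset_merge=True)
        plain = partition_populations_by_fish(table, subset_merge=False)
        assert len(merged.patterns) == 1
        assert len(plain.patterns) == 2


class TestDecomposeCycles:
    def test_default_fixture_two_cycles_three_and_six_junctions(self, truth):
        cfg, t, graph = truth_graph()
        fish = simulate_fish(t, cfg)
        part = partition_populations_by_fish(fish, probe_map=cfg.fish_probes)
        copies = {name: t.expected_copies(name) for name in t.segments}
        structures = decompose_cycles(graph, part.constraints, copies=copies)
        assert sorted(st.n_junctions for st in structures) == [3, 6]
        assert cycles_equal_up_to_symmetry(structures, t.structures)
        assert len(shared_junction_ids(structures)) == 1

    def test_single_two_segment_circle(self):
        segs = [Segment("a", "c", 0, 100, tier=1), Segment("b", "c", 200, 300, tier=1)]
        js = [
            Junction("j1", JunctionSide("c", 100, "-", "a"), JunctionSide("c", 200, "+", "b")),
            Junction("j2", JunctionSide("c", 300, "-", "b"), JunctionSide("c", 0, "+", "a")),
        ]
        structures = decompose_cycles(build_graph(segs, js))
        assert len(structures) == 1
        assert structures[0].n_junctions == 2

    def test_unsatisfiable_constraints_error_lists_violation(self):
        segs = [Segment("a", "c", 0, 100, tier=1), Segment("b", "c", 200, 300, tier=1)]
        js = [
            Junction("j1", JunctionSide("c", 100, "-", "a"), JunctionSide("c", 200, "+", "b")),
            Junction("j2", JunctionSide("c", 300, "-", "b"), JunctionSide("c", 0, "+", "a")),
        ]
        from dmrecon.assembly import FishConstraints

        constraints = FishConstraints(must_separate={frozenset(("a", "b"))})
        with pytest.raises(DecompositionError, match="share a cycle"):
            decompose_cycles(build_graph(segs, js), constraints)

    def test_twenty_random_instances_match_oracle_and_truth(self):
        for rep in range(20):
            rng = np.random.default_rng(1000 + rep)
            segments, junctions, constraints, truth = random_graph_instance(rng)
            graph = build_graph(segments, junctions, infer_multiplicity=False)
            got = decompose_cycles(graph, constraints)
            oracle = oracle_decompose(graph, constraints)
            assert cycles_equal_up_to_symmetry(got, oracle)
            assert cycles_equal_up_to_symmetry(got, truth)


class TestEstimateAbundances:
    def test_noiseless_exact_recovery(self, truth):
        copies = {name: truth.expected_copies(name) for name in truth.segments}
        model = estimate_abundances(truth.structures, copies)
        assert model.abundances["pop1"] == pytest.approx(101.0, abs=1e-9)
        assert model.abundances["pop2"] == pytest.approx(107.0, abs=1e-9)
        assert model.residual == pytest.approx(0.0, abs=1e-9)

    def test_shared_to_specific_ratio_exactly_two(self, truth):
        copies = {name: truth.expected_copies(name) for name in truth.segments}
        model = estimate_abundances(truth.structures, copies)
        assert model.copy_ratio == 2.0

    def test_zero_abundance_structure_estimated_zero(self, truth):
        copies = {}
        for name in truth.segments:
            mult1 = sum(1 for s, _ in truth.structures[0].segments if s == name)
            copies[name] = 101.0 * mult1
        model = estimate_abundances(truth.structures, copies)
        assert model.abundances["pop1"] == pytest.approx(101.0, abs=1e-9)
        assert model.abundances["pop2"] == pytest.approx(0.0, abs=1e-9)

    def test_indistinguishable_structures_rejected(self):
        st = DMStructure("x", (("a", "+"), ("b", "+")), ("j1", "j2"))
        st2 = DMStructure("y", (("a", "+"), ("b", "-")), ("j3", "j4"))
        with pytest.raises(GraphError, match="indistinguishable"):
            estimate_abundances([st, st2], {"a": 10.0, "b": 10.0})


class TestStructureSummary:
    def test_junction_count_equals_block_count(self, truth):
        for st in truth.structures:
            rec = structure_summary(st)
            assert rec["n_junctions"] == rec["n_blocks"]

    def test_exactly_one_shared_junction_flagged(self, truth):
        shared = shared_junction_ids(truth.structures)
        recs = [structure_summary(st, shared_ids=shared) for st in truth.structures]
        assert all(r["shared_junctions"] == ["IV"] for r in recs)

    def test_population_one_length_is_segment_sum(self, truth):
        pop1 = next(s for s in truth.structures if s.id == "pop1")
        lengths = {n: s.length for n, s in truth.segments.items()}
        rec = structure_summary(pop1, segment_lengths=lengths)
        assert rec["total_length"] == sum(
            lengths[n] for n, _ in pop1.segments
        ) == 5000


class TestCanonicalization:
    def test_rotation_and_reflection_invariance(self, truth):
        rng = np.random.default_rng(3)
        for st in truth.structures:
            n = st.n_segments
            r = int(rng.integers(n))
            rotated = DMStructure(
                "r",
                st.segments[r:] + st.segments[:r],
                st.connectors[r:] + st.connectors[:r],
            )
            assert rotated.same_molecule(st)
            flip = {"+": "-", "-": "+"}
            rseg = tuple((s, flip[o]) for s, o in reversed(st.segments))
            rcon = tuple(st.connectors[(n - 2 - j) % n] for j in range(n))
            reflected = DMStructure("f", rseg, rcon)
            assert reflected.same_molecule(st)
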