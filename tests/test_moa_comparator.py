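"""Interaction frequencies, consensus graphs, overlap and differential activity."""

import math

import numpy as np
import pytest

from conftest import make_interactome
from moanet.moa_comparator import (
    consensus_moa_graph,
    differential_activity,
    export_moa_dot,
    interaction_frequencies,
    optimize_frequency_threshold,
    overlap_analysis,
    perturbed_protein_set,
)
from moanet.propagation_model import (
    ActivityState,
    MoAModel,
    ModelParameters,
    ModelSolution,
    compile_network,
    propagate,
    unit_parameters,
)


def manual_moa(inter, weight_rows, activity_rows, stimulus):
    """Assemble an ensemble from explicit per-solution weights/activities."""
    net = compile_network(inter)
    sols = []
    for weights, acts in zip(weight_rows, activity_rows):
        w = np.array([weights.get(k, 0.0) for k in net.edge_keys])
        params = ModelParameters(w, net.edge_keys)
        state = ActivityState(dict(acts), True, 1, dict(stimulus))
        sols.append(ModelSolution(params, (), 1.0, 0, state=state))
    return MoAModel(dict(stimulus), sols, net, 0)


class TestInteractionFrequencies:
    def test_counting_definition(self):
        inter = make_interactome([("T", "E")])
        acts_on = {"T": 1.0, "E": 0.5}
        rows_w = [{("E", "T"): 0.8}] * 37 + [{("E", "T"): 0.0}] * 63
        rows_a = [acts_on] * 100
        moa = manual_moa(inter, rows_w, rows_a, {"T": 1})
        freq = interaction_frequencies(moa)
        assert freq[("E", "T")] == pytest.approx(0.37)

    def test_never_and_always_active(self):
        inter = make_interactome([("A", "B"), ("B", "C")])
        acts = {"A": 1.0, "B": 0.5, "C": 0.0}
        rows_w = [{("A", "B"): 0.9, ("B", "C"): 0.01}] * 4
        moa = manual_moa(inter, rows_w, [acts] * 4, {"A": 1})
        freq = interaction_frequencies(moa)
        assert freq[("A", "B")] == 1.0
        assert freq[("B", "C")] == 0.0  # weight below epsilon

    def test_requires_upstream_signal(self):
        # strong weight but no activity at either endpoint -> inactive
        inter = make_interactome([("A", "B")])
        moa = manual_moa(
            inter, [{("A", "B"): 0.9}], [{"A": 0.0, "B": 0.0}], {"X": 1}
        )
        assert interaction_frequencies(moa)[("A", "B")] == 0.0


class TestThresholdOptimization:
    def test_full_graph_within_budget_takes_min_frequency(self):
        freq = {("A", "B"): 0.2, ("B", "C"): 0.7}
        assert optimize_frequency_threshold(freq, max_nodes=10) == 0.2

    def test_exhaustive_scan_on_constructed_map(self):
        """Ten edges arranged so only thresholds >= 0.4 keep <= 3 nodes."""
        freq = {}
        # high-frequency core triangle
        freq[("A", "B")] = 0.9
        freq[("B", "C")] = 0.5
        freq[("A", "C")] = 0.4
        # low-frequency periphery fanning out to new nodes
        for i, f in enumerate([0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.38]):
            freq[("A", f"P{i}")] = f
        # independent exhaustive scan
        best = None
        for t in sorted(set(freq.values())):
            nodes = {n for (u, v), f in freq.items() if f >= t for n in (u, v)}
            if len(nodes) <= 3:
                best = t
                break
        assert best == 0.4
        assert optimize_frequency_threshold(freq, max_nodes=3) == 0.4

    def test_all_frequencies_equal(self):
        freq = {("A", "B"): 0.6, ("B", "C"): 0.6}
        assert optimize_frequency_threshold(freq, max_nodes=5) == 0.6

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            optimize_frequency_threshold({})

    def test_retention_is_antimonotone_in_threshold(self):
        rng = np.random.default_rng(3)
        freq = {(f"N{i}", f"N{i+1}"): float(rng.uniform()) for i in range(30)}
        prev_edges = None
        for t in sorted(set(freq.values())):
            g = consensus_moa_graph(freq, t)
            edges = set(g.edges)
            if prev_edges is not None:
                assert edges <= prev_edges
            prev_edges = edges


class TestConsensusGraph:
    def test_threshold_zero_keeps_everything(self):
        freq = {("A", "B"): 0.0, ("B", "C"): 0.5}
        g = consensus_moa_graph(freq, 0.0)
        assert set(g.edges) == set(freq)

    def test_exclusive_edge_flagging(self):
        fa = {("A", "B"): 0.9, ("B", "C"): 0.1}
        fb = {("A", "B"): 0.8, ("B", "C"): 0.7}
        g = consensus_moa_graph([fa, fb], 0.5, map_names=("one", "two"))
        assert g.exclusive_edges("two") == {("B", "C")}
        assert g.exclusive_edges("one") == set()
        assert g.presence[("A", "B")] == (True, True)

    def test_identical_maps_have_no_exclusives(self):
        f = {("A", "B"): 0.9, ("B", "C"): 0.6}
        g = consensus_moa_graph([f, dict(f)], 0.5, map_names=("x", "y"))
        assert g.exclusive_edges("x") == set() and g.exclusive_edges("y") == set()

    def test_node_activity_labels(self):
        g = consensus_moa_graph(
            {("A", "B"): 0.9}, 0.5, activities={"A": 0.8, "B": -0.3}
        )
        assert g.node_activity["A"] == 0.8 and g.node_activity["B"] == -0.3

    def test_graphml_round_trip(self, tmp_path):
        from moanet.moa_comparator import export_moa_graphml, load_moa_graphml

        fa = {("A", "B"): 0.9, ("B", "C"): 0.1}
        fb = {("A", "B"): 0.8, ("B", "C"): 0.7}
        g = consensus_moa_graph(
            [fa, fb], 0.5, activities={"A": 0.4, "B": -0.2, "C": 0.0},
            map_names=("one", "two"),
        )
        path = tmp_path / "moa.graphml"
        export_moa_graphml(g, path)
        back = load_moa_graphml(path)
        assert back.map_names == g.map_names
        assert back.threshold == g.threshold
        assert back.edges == g.edges
        assert back.presence == g.presence
        assert back.node_activity == pytest.approx(g.node_activity)


class TestPerturbedSet:
    def test_all_zero_activities_empty(self):
        inter = make_interactome([("A", "B")])
        moa = manual_moa(inter, [{}], [{"A": 0.0, "B": 0.0}], {})
        assert perturbed_protein_set(moa) == set()

    def test_clamped_stimulus_nodes_excluded(self):
        inter = make_interactome([("A", "B")])
        moa = manual_moa(inter, [{}], [{"A": 1.0, "B": 0.0}], {"A": 1})
        assert perturbed_protein_set(moa, 0.0) == set()

    def test_propagated_chain_included(self):
        inter = make_interactome([("T", "M"), ("M", "E")])
        net = compile_network(inter)
        params = unit_parameters(net)
        state = propagate(net, params, {"T": 1})
        sol = ModelSolution(params, (), 1.0, 0, state=state)
        moa = MoAModel({"T": 1}, [sol], net, 0)
        assert state["E"] > 0.05
        assert perturbed_protein_set(moa, 0.05) == {"M", "E"}

    def test_explicit_exclusion_widens(self):
        inter = make_interactome([("T", "M")])
        moa = manual_moa(inter, [{}], [{"T": 1.0, "M": 0.9}], {"T": 1})
        assert perturbed_protein_set(moa) == {"M"}
        assert perturbed_protein_set(moa, exclude={"T", "M"}) == set()


class TestOverlap:
    def test_nested_sets(self):
        rep = overlap_analysis({"p1", "p2", "p3"}, {f"p{i}" for i in range(1, 7)})
        assert (rep.n_a, rep.n_b, rep.n_intersection) == (3, 6, 3)
        assert rep.a_subset_of_b and not rep.b_subset_of_a

    def test_disjoint_sets(self):
        rep = overlap_analysis({"a"}, {"b"})
        assert rep.n_intersection == 0
        assert not rep.a_subset_of_b and not rep.b_subset_of_a

    def test_equal_sets_both_flags(self):
        rep = overlap_analysis({"a", "b"}, {"a", "b"})
        assert rep.a_subset_of_b and rep.b_subset_of_a

    def test_swap_symmetry(self):
        a, b = {"x", "y"}, {"y", "z", "w"}
        r1, r2 = overlap_analysis(a, b), overlap_analysis(b, a)
        assert (r1.n_a, r1.n_b) == (r2.n_b, r2.n_a)
        assert r1.a_subset_of_b == r2.b_subset_of_a


class TestDifferentialActivity:
    @pytest.mark.parametrize(
        "delta,significant",
        [(0.6, True), (0.5, False), (-0.51, True), (-0.5, False), (0.0, False)],
    )
    def test_strict_absolute_threshold(self, delta, significant):
        rep = differential_activity({"p": delta}, {"p": 0.0})
        assert rep.rows[0].significant is significant

    def test_self_comparison_has_no_significant_changes(self):
        acts = {"a": 0.9, "b": -0.7, "c": 0.1}
        rep = differential_activity(acts, dict(acts))
        assert rep.significant == ()

    def test_missing_proteins_default_to_zero(self):
        rep = differential_activity({"a": 0.8}, {"b": 0.6})
        by_name = {r.protein: r for r in rep.rows}
        assert by_name["a"].delta == pytest.approx(0.8)
        assert by_name["b"].delta == pytest.approx(-0.6)

    def test_sorted_by_absolute_delta(self):
        rep = differential_activity({"a": 0.1, "b": 0.9, "c": -0.5}, {})
        assert [r.protein for r in rep.rows] == ["b", "c", "a"]


class TestDotExport:
    def test_empty_graph_is_valid_digraph(self, tmp_path):
        g = consensus_moa_graph({("A", "B"): 0.1}, 0.5)
        assert g.edges == {}
        path = tmp_path / "empty.dot"
        export_moa_dot(g, path)
        text = path.read_text()
        assert text.startswith("digraph") and text.rstrip().endswith("}")

    def test_exclusive_edge_gets_distinct_color(self, tmp_path):
        fa = {("A", "B"): 0.9}
        fb = {("A", "B"): 0.9, ("B", "C"): 0.8}
        g = consensus_moa_graph([fa, fb], 0.5, map_names=("one", "two"))
        path = tmp_path / "moa.dot"
        export_moa_dot(g, path)
        lines = path.read_text().splitlines()
        shared = next(l for l in lines if '"A" -> "B"' in l)
        exclusive = next(l for l in lines if '"B" -> "C"' in l)
        assert "color=black" in shared
        assert "color=black" not in exclusive

    def test_dot_structure_parses(self, tmp_path):
        g = consensus_moa_graph(
            {("A", "B"): 0.9, ("B", "C"): 0.7}, 0.5, activities={"A": 0.5, "B": -0.5}
        )
        path = tmp_path / "moa.dot"
        export_moa_dot(g, path)
        text = path.read_text()
        assert text.count("{") == text.count("}")
        assert text.count("->") == 2
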