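"""Signed propagation dynamics, constraint training and ensembles."""

import math

import numpy as np
import pytest

from conftest import drug, make_interactome, motive, restriction
from moanet.knowledge_base import TruthTable
from moanet.network_builder import Interactome
from moanet.propagation_model import (
    ActivityState,
    MoAModel,
    ModelParameters,
    ModelSolution,
    TrainConfig,
    compile_network,
    derive_seed,
    ensemble_accuracy,
    load_ensemble,
    predicted_activity,
    propagate,
    restriction_satisfied,
    sample_solutions,
    save_ensemble,
    train,
    unit_parameters,
)
from moanet.synthetic_data import generate_interactome
from oracle import naive_propagate


def tiny_truth_table():
    """One trivially satisfiable positive (direct target->effector edge) and
    one structurally unsatisfiable-as-positive negative (isolated stimulus)."""
    inter = make_interactome([("T", "E")])
    inter.add_node("T2")
    pos = restriction(drug("d1", ("T", 1)), motive("m", ("E", 1)), label=True)
    neg = restriction(drug("d2", ("T2", 1)), motive("m", ("E", 1)), label=False)
    return inter, TruthTable((pos, neg))


class TestPropagate:
    def test_edgeless_network_keeps_stimulus_only(self):
        inter = Interactome()
        for n in ("T", "X", "Y"):
            inter.add_node(n)
        state = propagate(inter, unit_parameters(inter), {"T": 1})
        assert state["T"] == 1.0
        assert state["X"] == 0.0 and state["Y"] == 0.0

    @pytest.mark.parametrize("sign,expected", [(1, math.tanh(1)), (-1, -math.tanh(1))])
    def test_single_edge_closed_form(self, sign, expected):
        inter = make_interactome([("T", "E", sign)])
        params = unit_parameters(inter, damping=1.0)
        state = propagate(inter, params, {"T": 1})
        assert state["E"] == pytest.approx(expected, abs=1e-9)
        assert state.converged

    def test_clamped_nodes_hold_exactly_and_bounds(self, rng):
        inter = generate_interactome(20, 3, 0.3, seed=4)
        nodes = sorted(inter.nodes)
        stim = {nodes[0]: 1, nodes[5]: -1}
        state = propagate(inter, unit_parameters(inter), stim)
        assert state[nodes[0]] == 1.0 and state[nodes[5]] == -1.0
        assert all(-1 <= a <= 1 for a in state.activities.values())

    def test_sign_symmetry_of_stimulus(self):
        inter = generate_interactome(15, 3, 0.4, seed=8)
        nodes = sorted(inter.nodes)
        params = unit_parameters(inter, magnitude=0.7)
        up = propagate(inter, params, {nodes[0]: 1})
        down = propagate(inter, params, {nodes[0]: -1})
        for n in inter.nodes:
            assert up[n] == pytest.approx(-down[n], abs=1e-9)

    def test_matches_naive_oracle_on_small_networks(self, rng):
        for _ in range(25):
            inter = generate_interactome(
                int(rng.integers(2, 7)), 2, 0.4, seed=int(rng.integers(2**31))
            )
            net = compile_network(inter)
            w = rng.uniform(0, 1, net.n_edges)
            params = ModelParameters(w, net.edge_keys, damping=0.5)
            nodes = sorted(inter.nodes)
            stim = {nodes[0]: int(rng.choice([-1, 1]))}
            ours = propagate(net, params, stim, tol=1e-12, max_iter=200)
            theirs = naive_propagate(
                inter, dict(zip(net.edge_keys, w)), stim, 0.5, 1e-12, 200
            )
            for n in nodes:
                assert ours[n] == pytest.approx(theirs[n], abs=1e-9)

    def test_unmapped_stimulus_reported(self, path_graph):
        state = propagate(path_graph, unit_parameters(path_graph), {"A": 1, "ZZ": 1})
        assert state.unmapped == ("ZZ",)

    def test_nonfinite_weight_rejected(self, path_graph):
        net = compile_network(path_graph)
        with pytest.raises(ValueError):
            ModelParameters(np.array([1.0, np.nan, 0.5]), net.edge_keys)

    def test_reachability_monotone_under_nonnegative_weights(self):
        inter = generate_interactome(40, 3, 0.0, seed=2)
        nodes = sorted(inter.nodes)
        params = unit_parameters(inter, magnitude=0.4)
        small = propagate(inter, params, {nodes[0]: 1})
        large = propagate(inter, params, {nodes[0]: 1, nodes[10]: 1})
        support_small = {n for n, a in small.activities.items() if abs(a) > 1e-9}
        support_large = {n for n, a in large.activities.items() if abs(a) > 1e-9}
        assert support_small <= support_large


class TestRestrictionSatisfaction:
    M = motive("m", ("E", 1))
    POS = restriction(drug("d", ("T", 1)), M, label=True)
    NEG = restriction(drug("d", ("T", 1)), M, label=False)

    @pytest.mark.parametrize(
        "activity,label,expected",
        [
            (0.5, True, True),     # responding in the expected direction
            (-0.5, True, False),   # wrong direction
            (0.05, True, False),   # below the activation floor
            (0.5, False, False),   # positive criterion holds -> negative violated
            (0.05, False, True),
        ],
    )
    def test_single_effector_cases(self, activity, label, expected):
        r = self.POS if label else self.NEG
        assert restriction_satisfied({"E": activity}, r, 0.1) is expected

    def test_strict_majority_with_tie_unsatisfied(self):
        m2 = motive("m2", ("E1", 1), ("E2", 1))
        r = restriction(drug("d", ("T", 1)), m2, label=True)
        assert restriction_satisfied({"E1": 0.5, "E2": -0.5}, r, 0.1) is False
        assert restriction_satisfied({"E1": 0.5, "E2": 0.5}, r, 0.1) is True

    def test_treats_expects_opposite_direction(self):
        r = restriction(drug("d", ("T", 1)), self.M, relation="treats", label=True)
        assert restriction_satisfied({"E": -0.5}, r, 0.1) is True
        assert restriction_satisfied({"E": 0.5}, r, 0.1) is False

    def test_no_mapped_effectors_is_indeterminate(self):
        assert restriction_satisfied({"X": 0.5}, self.POS, 0.1) is None


class TestTraining:
    def test_trivially_satisfiable_instance_reaches_perfect_accuracy(self):
        """SA finds the single-edge mechanism; an exhaustive weight grid
        confirms that perfect accuracy is attainable (and at which weights)."""
        inter, tt = tiny_truth_table()
        net = compile_network(inter)

        # independent oracle: scan the one trainable weight on a grid
        grid_best = 0.0
        for w in np.linspace(0, 1, 21):
            params = ModelParameters(np.array([w]), net.edge_keys)
            state = propagate(net, params, {"T": 1})
            ok_pos = restriction_satisfied(state, tt.restrictions[0], 0.1)
            state_neg = propagate(net, params, {"T2": 1})
            ok_neg = restriction_satisfied(state_neg, tt.restrictions[1], 0.1)
            grid_best = max(grid_best, (ok_pos + ok_neg) / 2)
        assert grid_best == 1.0

        sol = train(net, tt, TrainConfig(sa_steps=80), seed=0)
        assert sol.accuracy == 1.0
        assert not sol.below_floor

    def test_contradictory_restrictions_cap_accuracy(self):
        inter = make_interactome([("T", "E")])
        inter.add_node("T2")
        up = restriction(drug("d", ("T", 1)), motive("m+", ("E", 1)), label=True)
        down = restriction(drug("d", ("T", 1)), motive("m-", ("E", -1)), label=True)
        neg = restriction(drug("d2", ("T2", 1)), motive("m+", ("E", 1)), label=False)
        tt = TruthTable((up, down, neg))
        sol = train(inter, tt, TrainConfig(sa_steps=80), seed=1)
        assert sum(bool(s) for s in sol.satisfaction[:2]) <= 1

    def test_same_seed_identical_solution(self):
        inter, tt = tiny_truth_table()
        a = train(inter, tt, TrainConfig(sa_steps=40), seed=7)
        b = train(inter, tt, TrainConfig(sa_steps=40), seed=7)
        assert np.array_equal(a.parameters.weights, b.parameters.weights)
        assert a.accuracy == b.accuracy

    def test_best_accuracy_trace_is_nondecreasing(self, default_scenario, default_net):
        sol = train(default_net, default_scenario.truth_table,
                    TrainConfig(sa_steps=60), seed=3)
        trace = sol.best_accuracy_trace
        assert all(a <= b for a, b in zip(trace, trace[1:]))

    def test_below_floor_solutions_flagged(self):
        inter = make_interactome([("T", "E")])
        inter.add_node("T2")
        up = restriction(drug("d", ("T", 1)), motive("m+", ("E", 1)), label=True)
        down = restriction(drug("d", ("T", 1)), motive("m-", ("E", -1)), label=True)
        neg = restriction(drug("d2", ("T2", 1)), motive("m+", ("E", 1)), label=False)
        tt = TruthTable((up, down, neg))
        moa = sample_solutions(inter, tt, {"T": 1}, n=2, accuracy_floor=0.9,
                               seed=0, config=TrainConfig(sa_steps=30), max_retries=0)
        assert all(s.below_floor for s in moa.solutions)
        assert moa.accepted == []


class TestEnsembles:
    def test_singleton_ensemble_matches_direct_training(self):
        inter, tt = tiny_truth_table()
        cfg = TrainConfig(sa_steps=40)
        moa = sample_solutions(inter, tt, {"T": 1}, n=1, seed=5, config=cfg)
        direct = train(inter, tt, cfg, seed=derive_seed(5, 0))
        assert np.array_equal(
            moa.solutions[0].parameters.weights, direct.parameters.weights
        )

    def test_distinct_master_seeds_differ(self, default_scenario, default_net):
        cfg = TrainConfig(sa_steps=40)
        stim = default_scenario.drugs[0].stimulus()
        m1 = sample_solutions(default_net, default_scenario.truth_table, stim,
                              n=2, seed=1, config=cfg)
        m2 = sample_solutions(default_net, default_scenario.truth_table, stim,
                              n=2, seed=2, config=cfg)
        assert any(
            not np.array_equal(a.parameters.weights, b.parameters.weights)
            for a, b in zip(m1.solutions, m2.solutions)
        )

    def test_ensemble_reproducible_from_master_seed(self):
        inter, tt = tiny_truth_table()
        cfg = TrainConfig(sa_steps=30)
        m1 = sample_solutions(inter, tt, {"T": 1}, n=3, seed=9, config=cfg)
        m2 = sample_solutions(inter, tt, {"T": 1}, n=3, seed=9, config=cfg)
        for a, b in zip(m1.solutions, m2.solutions):
            assert np.array_equal(a.parameters.weights, b.parameters.weights)

    def test_predicted_activity_mean_and_bounds(self):
        inter = make_interactome([("T", "E")])
        net = compile_network(inter)
        params = unit_parameters(net)

        def sol(val):
            state = ActivityState({"T": 1.0, "E": val}, True, 1, {"T": 1})
            return ModelSolution(params, (), 1.0, 0, state=state)

        moa = MoAModel({"T": 1}, [sol(1.0), sol(-1.0)], net, 0)
        acts = predicted_activity(moa)
        assert acts["E"] == 0.0
        moa_same = MoAModel({"T": 1}, [sol(0.25), sol(0.25)], net, 0)
        assert predicted_activity(moa_same)["E"] == 0.25
        assert all(abs(v) <= 1 for v in acts.values())

    def test_empty_ensemble_rejected(self):
        inter = make_interactome([("T", "E")])
        with pytest.raises(ValueError):
            MoAModel({"T": 1}, [], compile_network(inter), 0)

    def test_serialization_round_trip(self, tmp_path):
        inter, tt = tiny_truth_table()
        moa = sample_solutions(inter, tt, {"T": 1}, n=3, seed=4,
                               config=TrainConfig(sa_steps=30))
        save_ensemble(moa, tmp_path / "ens")
        back = load_ensemble(tmp_path / "ens", inter)
        assert back.stimulus == moa.stimulus
        assert back.n_solutions == moa.n_solutions
        for a, b in zip(moa.solutions, back.solutions):
            assert np.allclose(a.parameters.weights, b.parameters.weights)
            assert a.accuracy == b.accuracy
            assert a.state.activities == pytest.approx(b.state.activities)
        assert ensemble_accuracy(back) == pytest.approx(ensemble_accuracy(moa))
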