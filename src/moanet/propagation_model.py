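"""Signed signal propagation, constraint training and MoA solution ensembles.

The model treats the response network as a system of interacting protein
activities.  Drug targets are clamped to their action sign (+1/-1) and signal
spreads over signed, weighted edges by a damped saturating update

    a_i  <-  (1 - lambda) * a_i  +  lambda * tanh( sum_j  w_ji * sign_ji * a_j )

iterated to a fixed point.  Activities live in [-1, 1] by construction; clamped
(stimulated) nodes hold their stimulus value exactly.  The trainable quantities
are the edge-weight magnitudes in [0, 1]; edge signs are fixed by the
interactome, keeping every solution interpretable as a signed mechanism.

Training searches weight magnitudes by simulated annealing so that the model
complies with a truth table of known drug–condition relationships: a drug that
*induces* a condition must drive a majority of the condition's effectors toward
their pathological direction (above an activation floor), a drug that *treats*
it the opposite way, and an explicit non-association must fail the positive
criterion.  A mechanism-of-action (MoA) model for one stimulus is an ensemble
of independently trained solutions (default 100), each a different mechanistic
hypothesis consistent with the constraints.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .knowledge_base import Restriction, TruthTable
from .network_builder import EdgeKey, Interactome, ResponseNetwork

_MASK64 = (1 << 64) - 1


def derive_seed(master_seed: int, index: int) -> int:
    """Counter-based splitmix64 stream: independent 31-bit seeds per solution."""
    z = (master_seed + 0x9E3779B97F4A7C15 * (index + 1)) & _MASK64
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    z ^= z >> 31
    return int(z % (1 << 31))


# ---------------------------------------------------------------------------
# Compiled network and parameters
# ---------------------------------------------------------------------------

class CompiledNetwork:
    """Index-aligned arrays for fast propagation over an interactome.

    Undirected edges transmit in both directions; directed edges only
    source -> target.  Edge order is the interactome's canonical sorted order,
    and weight vectors are keyed 1:1 to it.
    """

    def __init__(self, interactome: Interactome):
        self.interactome = interactome
        self.nodes: list[str] = sorted(interactome.nodes)
        self.node_index: dict[str, int] = {a: i for i, a in enumerate(self.nodes)}
        edges = interactome.sorted_edges()
        self.edge_keys: tuple[EdgeKey, ...] = tuple(e.key for e in edges)
        self.edge_index: dict[EdgeKey, int] = {k: i for i, k in enumerate(self.edge_keys)}
        self.src = np.array([self.node_index[e.source] for e in edges], dtype=np.intp)
        self.dst = np.array([self.node_index[e.target] for e in edges], dtype=np.intp)
        self.signs = np.array([e.sign for e in edges], dtype=np.float64)
        self.directed = np.array([e.directed for e in edges], dtype=bool)
        self._graph: nx.Graph | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edge_keys)

    @property
    def graph(self) -> nx.Graph:
        if self._graph is None:
            self._graph = self.interactome.to_networkx()
        return self._graph

    def weight_matrix(self, weights: np.ndarray) -> np.ndarray:
        """Dense signed influence matrix W with W[i, j] = weight of j -> i."""
        n = self.n_nodes
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != (self.n_edges,):
            raise ValueError("weights not keyed 1:1 to network edges")
        if not np.all(np.isfinite(w)):
            raise ValueError("non-finite edge weight")
        W = np.zeros((n, n))
        np.add.at(W, (self.dst, self.src), w * self.signs)
        und = ~self.directed
        np.add.at(W, (self.src[und], self.dst[und]), w[und] * self.signs[und])
        return W

    def clamp_arrays(self, stimulus: Mapping[str, int]) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Map a stimulus onto node indices; unmapped proteins are reported."""
        idx, vals, unmapped = [], [], []
        for acc, v in sorted(stimulus.items()):
            if acc in self.node_index:
                idx.append(self.node_index[acc])
                vals.append(float(v))
            else:
                unmapped.append(acc)
        return np.array(idx, dtype=np.intp), np.array(vals), unmapped


def compile_network(network: Interactome | ResponseNetwork | CompiledNetwork) -> CompiledNetwork:
    if isinstance(network, CompiledNetwork):
        return network
    if isinstance(network, ResponseNetwork):
        return CompiledNetwork(network.subgraph)
    return CompiledNetwork(network)


@dataclass
class ModelParameters:
    """Trainable edge-weight magnitudes plus propagation hyperparameters.

    Effective signed weights are ``magnitude * edge sign`` and therefore lie in
    [-1, 1].  ``damping`` is the update mixing rate lambda in (0, 1];
    ``activation_floor`` is the minimum |activity| for an effector to count as
    responding.
    """

    weights: np.ndarray
    edge_keys: tuple[EdgeKey, ...]
    damping: float = 0.5
    activation_floor: float = 0.1

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if len(self.weights) != len(self.edge_keys):
            raise ValueError("weights not keyed 1:1 to edges")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite weight")
        if np.any(np.abs(self.weights) > 1 + 1e-12):
            raise ValueError("weight magnitude exceeds 1")
        if not (0 < self.damping <= 1):
            raise ValueError("damping must be in (0, 1]")
        if self.activation_floor <= 0:
            raise ValueError("activation floor must be > 0")


def unit_parameters(
    network: Interactome | ResponseNetwork | CompiledNetwork,
    magnitude: float = 1.0,
    damping: float = 0.5,
    activation_floor: float = 0.1,
) -> ModelParameters:
    """All-equal edge magnitudes; the untrained baseline parameterization."""
    net = compile_network(network)
    return ModelParameters(
        np.full(net.n_edges, magnitude), net.edge_keys, damping, activation_floor
    )


@dataclass
class ActivityState:
    """Converged node activities for one stimulus, all within [-1, 1]."""

    activities: dict[str, float]
    converged: bool
    n_iter: int
    clamped: dict[str, int]
    unmapped: tuple[str, ...] = ()

    def __getitem__(self, acc: str) -> float:
        return self.activities[acc]


# ---------------------------------------------------------------------------
# Propagation
# ---------------------------------------------------------------------------

def _iterate(
    W: np.ndarray,
    clamp_idx: np.ndarray,
    clamp_vals: np.ndarray,
    damping: float,
    tol: float,
    max_iter: int,
    x0: np.ndarray | None = None,
) -> tuple[np.ndarray, bool, int]:
    """Damped fixed-point iteration; columns of x0 are independent stimuli."""
    n = W.shape[0]
    if clamp_vals.ndim == 1:
        clamp_vals = clamp_vals[:, None]
    x = np.zeros((n, clamp_vals.shape[1])) if x0 is None else x0.copy()
    if clamp_idx.size:
        x[clamp_idx] = clamp_vals
    lam = damping
    for it in range(1, max_iter + 1):
        x_new = (1 - lam) * x + lam * np.tanh(W @ x)
        if clamp_idx.size:
            x_new[clamp_idx] = clamp_vals
        delta = float(np.max(np.abs(x_new - x))) if x.size else 0.0
        x = x_new
        if delta < tol:
            return x, True, it
    return x, False, max_iter


def propagate(
    network: Interactome | ResponseNetwork | CompiledNetwork,
    params: ModelParameters,
    stimulus: Mapping[str, int],
    tol: float = 1e-6,
    max_iter: int = 100,
) -> ActivityState:
    """Propagate a stimulus to a converged activity state.

    Stimulated nodes are clamped to their stimulus value for the whole
    iteration.  Non-convergence within ``max_iter`` is flagged on the returned
    state, not raised.
    """
    net = compile_network(network)
    W = net.weight_matrix(params.weights)
    clamp_idx, clamp_vals, unmapped = net.clamp_arrays(stimulus)
    x, converged, n_iter = _iterate(
        W, clamp_idx, clamp_vals[:, None], params.damping, tol, max_iter
    )
    acts = {acc: float(x[i, 0]) for i, acc in enumerate(net.nodes)}
    clamped = {acc: int(v) for acc, v in stimulus.items() if acc in net.node_index}
    return ActivityState(acts, converged, n_iter, clamped, tuple(unmapped))


# ---------------------------------------------------------------------------
# Restriction satisfaction
# ---------------------------------------------------------------------------

def restriction_satisfied(
    state: ActivityState | Mapping[str, float],
    restriction: Restriction,
    activation_floor: float = 0.1,
) -> bool | None:
    """Whether one truth-table restriction holds in an activity state.

    The positive criterion requires a strict majority of the mapped response
    effectors to respond in the expected direction with |activity| at or above
    the floor; ties are unsatisfied.  For ``label=False`` the restriction is
    satisfied exactly when the positive criterion fails.  Returns ``None``
    (indeterminate) when no effector maps into the state.
    """
    acts = state.activities if isinstance(state, ActivityState) else state
    mapped = [e for e in restriction.response if e.protein.accession in acts]
    if not mapped:
        return None
    agree = 0
    for eff in mapped:
        a = acts[eff.protein.accession]
        expected = restriction.expected_direction(eff)
        if abs(a) >= activation_floor and math.copysign(1.0, a) == expected:
            agree += 1
    positive_holds = agree > len(mapped) / 2
    return positive_holds if restriction.label else not positive_holds


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Simulated-annealing and propagation settings for constraint training.

    The annealer alternates unbiased Gaussian perturbations of a random subset
    of weights with mechanism-guided moves that strengthen (for violated
    positive restrictions) or weaken (for violated negatives) shortest
    stimulus-to-effector paths.  A final minimality pass zeroes every weight
    whose removal does not reduce training accuracy, so that solutions are
    sparse mechanistic hypotheses rather than dense weight fields.
    """

    sa_steps: int = 200
    t0: float = 1.0
    cooling: float = 0.95
    sigma: float = 0.2
    perturb_frac: float = 0.05
    guided_prob: float = 0.5
    sparsify_prob: float = 0.25
    parsimony: float = 0.01
    prune: bool = True
    damping: float = 0.5
    # training-time propagation budget: activities only need to be resolved
    # well below the 0.05/0.1 decision floors, not to machine precision
    tol: float = 1e-4
    max_iter: int = 60
    activation_floor: float = 0.1
    accuracy_floor: float = 0.9
    path_cutoff: int = 6


@dataclass
class ModelSolution:
    """One trained parameter set with its per-restriction satisfaction."""

    parameters: ModelParameters
    satisfaction: tuple[bool | None, ...]
    accuracy: float
    seed: int
    below_floor: bool = False
    converged: bool = True
    best_accuracy_trace: tuple[float, ...] = ()
    state: ActivityState | None = None  # converged state for the ensemble stimulus


@dataclass
class MoAModel:
    """Ensemble of trained solutions for one stimulus over one network."""

    stimulus: dict[str, int]
    solutions: list[ModelSolution]
    network: CompiledNetwork
    master_seed: int
    name: str = ""

    def __post_init__(self) -> None:
        if not self.solutions:
            raise ValueError("MoA model needs at least one solution")

    @property
    def n_solutions(self) -> int:
        return len(self.solutions)

    @property
    def accepted(self) -> list[ModelSolution]:
        return [s for s in self.solutions if not s.below_floor]


class _Trainer:
    """Shared, per-(network, truth table) state reused across ensemble members."""

    def __init__(self, net: CompiledNetwork, truth_table: TruthTable, config: TrainConfig):
        self.net = net
        self.tt = truth_table
        self.cfg = config

        # one propagation column per unique stimulus
        stim_maps: dict[str, dict[str, int]] = {}
        self.col_of: list[int] = []
        for r in truth_table.restrictions:
            name = r.stimulus.name
            if name not in stim_maps:
                stim_maps[name] = r.stimulus.stimulus()
            self.col_of.append(list(stim_maps).index(name))
        self.stim_names = list(stim_maps)
        n, k = net.n_nodes, len(stim_maps)
        self.clamp_mask = np.zeros((n, k), dtype=bool)
        self.clamp_vals = np.zeros((n, k))
        for j, name in enumerate(self.stim_names):
            idx, vals, _ = net.clamp_arrays(stim_maps[name])
            self.clamp_mask[idx, j] = True
            self.clamp_vals[idx, j] = vals

        # per-restriction effector rows / expected signs (mapped only)
        self.eff_rows: list[np.ndarray] = []
        self.eff_expected: list[np.ndarray] = []
        for r in truth_table.restrictions:
            rows, exp = [], []
            for eff in sorted(r.response):
                if eff.protein.accession in net.node_index:
                    rows.append(net.node_index[eff.protein.accession])
                    exp.append(r.expected_direction(eff))
            self.eff_rows.append(np.array(rows, dtype=np.intp))
            self.eff_expected.append(np.array(exp, dtype=np.float64))

        self._path_cache: dict[tuple[str, str], list[tuple[tuple[int, ...], int]]] = {}

    # -- propagation over all stimuli at once --------------------------------

    def states(
        self, weights: np.ndarray, x0: np.ndarray | None = None
    ) -> tuple[np.ndarray, bool]:
        """Fixed point for all stimuli at once; ``x0`` warm-starts the iteration
        (small weight perturbations converge in a few steps from the previous
        accepted state)."""
        W = self.net.weight_matrix(weights)
        x = np.where(self.clamp_mask, self.clamp_vals, 0.0) if x0 is None else x0.copy()
        x = np.where(self.clamp_mask, self.clamp_vals, x)
        lam = self.cfg.damping
        for _ in range(self.cfg.max_iter):
            x_new = (1 - lam) * x + lam * np.tanh(W @ x)
            x_new = np.where(self.clamp_mask, self.clamp_vals, x_new)
            delta = float(np.max(np.abs(x_new - x))) if x.size else 0.0
            x = x_new
            if delta < self.cfg.tol:
                return x, True
        return x, False

    def satisfaction(self, x: np.ndarray) -> tuple[list[bool | None], float]:
        sats: list[bool | None] = []
        n_ok = n_det = 0
        floor = self.cfg.activation_floor
        for i, r in enumerate(self.tt.restrictions):
            rows = self.eff_rows[i]
            if rows.size == 0:
                sats.append(None)
                continue
            a = x[rows, self.col_of[i]]
            agree = int(np.sum((np.abs(a) >= floor) & (np.sign(a) == self.eff_expected[i])))
            positive = agree > rows.size / 2
            ok = positive if r.label else not positive
            sats.append(ok)
            n_det += 1
            n_ok += ok
        return sats, (n_ok / n_det if n_det else 0.0)

    def evaluate(
        self, weights: np.ndarray, x0: np.ndarray | None = None
    ) -> tuple[float, list[bool | None], bool, np.ndarray]:
        x, converged = self.states(weights, x0)
        sats, acc = self.satisfaction(x)
        return acc, sats, converged, x

    # -- guided proposals ----------------------------------------------------

    def _shortest_paths(self, source: str, target: str) -> list[tuple[tuple[int, ...], int]]:
        """Up to 8 tied shortest paths as (edge indices, sign parity) pairs."""
        key = (source, target)
        if key not in self._path_cache:
            entries: list[tuple[tuple[int, ...], int]] = []
            try:
                for i, nodes in enumerate(
                    nx.all_shortest_paths(self.net.graph, source, target)
                ):
                    if i >= 8 or len(nodes) - 1 > self.cfg.path_cutoff:
                        break
                    idxs, parity = [], 1
                    for u, v in zip(nodes, nodes[1:]):
                        e = self.net.interactome.get_edge(u, v)
                        idxs.append(self.net.edge_index[e.key])
                        parity *= e.sign
                    entries.append((tuple(idxs), parity))
            except (nx.NetworkXNoPath, nx.NodeNotFound):
                pass
            self._path_cache[key] = entries
        return self._path_cache[key]

    def propose_guided(
        self, w: np.ndarray, sats: Sequence[bool | None], rng: np.random.Generator
    ) -> np.ndarray | None:
        violated = [i for i, s in enumerate(sats) if s is False]
        if not violated:
            return None
        i = int(rng.choice(violated))
        r = self.tt.restrictions[i]
        targets = [
            (t.protein.accession, t.action)
            for t in sorted(r.stimulus.targets)
            if t.protein.accession in self.net.node_index
        ]
        if not targets:
            return None
        w_new = w.copy()
        effectors = sorted(r.response)
        if r.label:
            # strengthen a shortest stimulus->effector path per effector until
            # a strict majority could respond; prefer paths whose sign parity
            # already produces the expected direction
            mapped = [e for e in effectors if e.protein.accession in self.net.node_index]
            need = len(mapped) // 2 + 1
            order = rng.permutation(len(mapped))
            boosted = 0
            for j in order:
                eff = mapped[j]
                expected = r.expected_direction(eff)
                matching, fallback = [], []
                for t_acc, t_action in targets:
                    for path, parity in self._shortest_paths(t_acc, eff.protein.accession):
                        (matching if parity * t_action == expected else fallback).append(path)
                candidates = matching or fallback
                if not candidates:
                    continue
                path = candidates[int(rng.integers(len(candidates)))]
                idx = list(path)
                w_new[idx] = np.clip(
                    np.maximum(w_new[idx], rng.uniform(0.6, 1.0, len(idx))), 0, 1
                )
                boosted += 1
                if boosted >= need:
                    break
            if boosted == 0:
                return None
        else:
            # weaken the inputs of effectors currently responding pathologically
            hit = False
            for eff in effectors:
                acc = eff.protein.accession
                if acc not in self.net.node_index:
                    continue
                row = self.net.node_index[acc]
                incident = np.where((self.net.src == row) | (self.net.dst == row))[0]
                if incident.size:
                    w_new[incident] *= rng.uniform(0.0, 0.4)
                    hit = True
            if not hit:
                return None
        return w_new

    def propose_gaussian(self, w: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        m = self.net.n_edges
        k = max(1, int(round(self.cfg.perturb_frac * m)))
        idx = rng.choice(m, size=min(k, m), replace=False)
        w_new = w.copy()
        w_new[idx] = np.clip(w_new[idx] + rng.normal(0, self.cfg.sigma, idx.size), 0, 1)
        return w_new

    def propose_sparsify(self, w: np.ndarray, rng: np.random.Generator) -> np.ndarray | None:
        """Zero a random tenth of the active edges (mechanism-minimality move)."""
        active = np.where(w > 1e-9)[0]
        if active.size == 0:
            return None
        k = max(1, active.size // 10)
        idx = rng.choice(active, size=k, replace=False)
        w_new = w.copy()
        w_new[idx] = 0.0
        return w_new

    # -- annealing -----------------------------------------------------------

    def anneal(self, seed: int) -> ModelSolution:
        cfg = self.cfg
        rng = np.random.default_rng(seed)
        w = np.zeros(self.net.n_edges)
        acc, sats, _, _ = self.evaluate(w)
        obj = acc - cfg.parsimony * float(np.mean(w)) if w.size else acc
        best_w, best_obj = w.copy(), obj
        best_acc_seen = acc
        trace = [best_acc_seen]

        temperature = cfg.t0
        for _ in range(cfg.sa_steps):
            if best_acc_seen >= 1.0 and temperature < 0.01:
                break
            u = rng.random()
            w_new = None
            if u < cfg.guided_prob:
                w_new = self.propose_guided(w, sats, rng)
            elif u < cfg.guided_prob + cfg.sparsify_prob:
                w_new = self.propose_sparsify(w, rng)
            if w_new is None:
                w_new = self.propose_gaussian(w, rng)
            acc_new, sats_new, _, _ = self.evaluate(w_new)
            obj_new = acc_new - cfg.parsimony * float(np.mean(w_new))
            d = obj_new - obj
            if d >= 0 or rng.random() < math.exp(d / max(temperature, 1e-12)):
                w, acc, sats, obj = w_new, acc_new, sats_new, obj_new
                if obj > best_obj:
                    best_w, best_obj = w.copy(), obj
            best_acc_seen = max(best_acc_seen, acc)
            trace.append(best_acc_seen)
            temperature *= cfg.cooling

        w = best_w
        acc, sats, converged, _ = self.evaluate(w)
        if cfg.prune:
            w, acc, sats = self.prune_pass(w, acc, rng)
            _, _, converged, _ = self.evaluate(w)

        params = ModelParameters(
            w, self.net.edge_keys, cfg.damping, cfg.activation_floor
        )
        return ModelSolution(
            parameters=params,
            satisfaction=tuple(sats),
            accuracy=acc,
            seed=seed,
            below_floor=acc < cfg.accuracy_floor,
            converged=converged,
            best_accuracy_trace=tuple(trace),
        )

    def prune_pass(
        self, w: np.ndarray, acc: float, rng: np.random.Generator
    ) -> tuple[np.ndarray, float, list[bool | None]]:
        """Zero every weight whose removal leaves training accuracy intact.

        A bulk sweep first drops all weights too small to transmit signal
        (below the comparator's default activity epsilon); surviving edges are
        then tested one by one in random order.
        """
        w = w.copy()
        for floor in (0.05, 0.15, 0.3, 0.5):
            bulk = w.copy()
            bulk[bulk < floor] = 0.0
            if not np.any(bulk != w):
                continue
            acc_bulk, _, _, _ = self.evaluate(bulk)
            if acc_bulk >= acc:
                w, acc = bulk, acc_bulk
            else:
                break
        active = np.where(w > 1e-9)[0]
        for i in rng.permutation(active):
            saved = w[i]
            w[i] = 0.0
            acc_new, _, _, _ = self.evaluate(w)
            if acc_new < acc:
                w[i] = saved
            else:
                acc = acc_new
        acc, sats, _, _ = self.evaluate(w)
        return w, acc, sats


def train(
    network: Interactome | ResponseNetwork | CompiledNetwork,
    truth_table: TruthTable,
    config: TrainConfig | None = None,
    seed: int = 0,
) -> ModelSolution:
    """Train one model solution against the truth table (reproducible in seed)."""
    net = compile_network(network)
    trainer = _Trainer(net, truth_table, config or TrainConfig())
    return trainer.anneal(seed)


def sample_solutions(
    network: Interactome | ResponseNetwork | CompiledNetwork,
    truth_table: TruthTable,
    stimulus: Mapping[str, int],
    n: int = 100,
    accuracy_floor: float | None = None,
    seed: int = 0,
    config: TrainConfig | None = None,
    max_retries: int = 1,
    name: str = "",
) -> MoAModel:
    """Sample an ensemble of n independently trained solutions for a stimulus.

    Each solution is trained from a seed derived from the master seed by a
    counter-based splitmix stream, so the ensemble is reproducible and
    independent of sampling order.  Solutions below the accuracy floor are
    re-trained from fresh derived seeds up to ``max_retries`` times, then kept
    flagged ``below_floor``.  Each retained solution also carries its converged
    activity state under the ensemble stimulus.
    """
    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    cfg = config or TrainConfig()
    if accuracy_floor is not None:
        cfg = replace(cfg, accuracy_floor=accuracy_floor)
    net = compile_network(network)
    trainer = _Trainer(net, truth_table, cfg)

    solutions: list[ModelSolution] = []
    for i in range(n):
        best: ModelSolution | None = None
        for attempt in range(max_retries + 1):
            sol = trainer.anneal(derive_seed(seed, i * (max_retries + 1) + attempt))
            if best is None or sol.accuracy > best.accuracy:
                best = sol
            if not best.below_floor:
                break
        assert best is not None
        best.state = propagate(net, best.parameters, stimulus, cfg.tol, cfg.max_iter)
        solutions.append(best)
    return MoAModel(dict(stimulus), solutions, net, seed, name=name)


def predicted_activity(moa: MoAModel) -> dict[str, float]:
    """Per-protein arithmetic mean of converged activities across solutions."""
    accs = moa.network.nodes
    total = np.zeros(len(accs))
    for sol in moa.solutions:
        if sol.state is None:
            raise ValueError("solution lacks a converged state")
        total += np.array([sol.state.activities[a] for a in accs])
    mean = total / moa.n_solutions
    return {a: float(v) for a, v in zip(accs, mean)}


def ensemble_accuracy(moa: MoAModel, accepted_only: bool = True) -> float:
    """Mean training accuracy across (accepted) ensemble solutions."""
    pool = moa.accepted if accepted_only else moa.solutions
    if not pool:
        return float("nan")
    return float(np.mean([s.accuracy for s in pool]))


# ---------------------------------------------------------------------------
# Ensemble serialization (tabular weights + JSON manifest)
# ---------------------------------------------------------------------------

def save_ensemble(moa: MoAModel, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    weight_rows = []
    state_rows = []
    for si, sol in enumerate(moa.solutions):
        nz = np.where(sol.parameters.weights > 0)[0]
        for ei in nz:
            s, t = moa.network.edge_keys[ei]
            weight_rows.append(
                {"solution": si, "source": s, "target": t,
                 "weight": float(sol.parameters.weights[ei])}
            )
        if sol.state is not None:
            for acc, a in sol.state.activities.items():
                state_rows.append({"solution": si, "protein": acc, "activity": a})
    pd.DataFrame.from_records(
        weight_rows, columns=["solution", "source", "target", "weight"]
    ).to_csv(directory / "weights.tsv", sep="\t", index=False)
    pd.DataFrame.from_records(
        state_rows, columns=["solution", "protein", "activity"]
    ).to_csv(directory / "states.tsv", sep="\t", index=False)
    manifest = {
        "name": moa.name,
        "master_seed": moa.master_seed,
        "stimulus": moa.stimulus,
        "n_solutions": moa.n_solutions,
        "solutions": [
            {
                "seed": s.seed,
                "accuracy": s.accuracy,
                "below_floor": s.below_floor,
                "converged": s.converged,
                "damping": s.parameters.damping,
                "activation_floor": s.parameters.activation_floor,
            }
            for s in moa.solutions
        ],
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_ensemble(
    directory: str | Path,
    network: Interactome | ResponseNetwork | CompiledNetwork,
) -> MoAModel:
    directory = Path(directory)
    net = compile_network(network)
    manifest = json.loads((directory / "manifest.json").read_text())
    weights = pd.read_csv(directory / "weights.tsv", sep="\t")
    states = pd.read_csv(directory / "states.tsv", sep="\t")
    solutions = []
    for si, meta in enumerate(manifest["solutions"]):
        w = np.zeros(net.n_edges)
        sub = weights[weights["solution"] == si]
        for row in sub.itertuples():
            w[net.edge_index[(row.source, row.target)]] = row.weight
        ssub = states[states["solution"] == si]
        acts = {str(r.protein): float(r.activity) for r in ssub.itertuples()}
        state = ActivityState(
            acts, meta["converged"], -1,
            {k: int(v) for k, v in manifest["stimulus"].items() if k in net.node_index},
        )
        params = ModelParameters(
            w, net.edge_keys, meta["damping"], meta["activation_floor"]
        )
        solutions.append(
            ModelSolution(
                parameters=params,
                satisfaction=(),
                accuracy=meta["accuracy"],
                seed=meta["seed"],
                below_floor=meta["below_floor"],
                converged=meta["converged"],
                state=state,
            )
        )
    return MoAModel(
        {k: int(v) for k, v in manifest["stimulus"].items()},
        solutions, net, manifest["master_seed"], name=manifest.get("name", ""),
    )
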