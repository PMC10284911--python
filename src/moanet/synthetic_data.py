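"""Seeded generators for fully synthetic study scenarios with known ground truth.

The curated inputs the modeling workflow expects — a signed interactome, drug
and motive characterizations, a labeled truth table, adverse-event count
tables — come from manual literature review and proprietary databases and are
not redistributable.  This module generates structurally analogous synthetic
versions with *planted* ground truth, so that every pipeline stage (curation,
network construction, constraint training, relationship scoring, MoA
comparison) is testable offline:

* interactomes are preferential-attachment graphs (heavy-tailed degrees, like
  protein interaction networks), each edge independently signed;
* drugs and conditions are random disjoint target/effector sets;
* mechanisms are planted as short signed paths from drug targets to condition
  effectors whose sign parity matches the effector's pathological direction;
* truth tables label planted pairs positive and unplanted pairs negative,
  with optional independent label noise.

Every generator is a pure function of (parameters, seed): regeneration is
bit-identical.  ``hemophilia_toy_scenario`` wires the three printed hemophilia
drug characterizations (emicizumab, rFVIIa, aPCC — all activating, with
aPCC's target set strictly containing rFVIIa's) into a small generated
interactome, preserving the subset structure that drives the full-overlap
comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .knowledge_base import (
    AEProfile,
    DrugCharacterization,
    DrugTarget,
    Effector,
    MotiveCharacterization,
    ProteinRef,
    Restriction,
    TruthTable,
)
from .network_builder import EdgeKey, Interactome, export_interactome_tsv

# Printed characterization of the three hemophilia agents: drug ->
# (accession, short name, action sign); all actions are activating.
TABLE1_DRUGS: dict[str, tuple[tuple[str, str, int], ...]] = {
    "emicizumab": (("P00742", "FX", 1),),
    "rFVIIa": (("P08709", "FVII", 1),),
    "aPCC": (
        ("P00734", "FII", 1),
        ("P08709", "FVII", 1),
        ("P00740", "FIX", 1),
        ("P00742", "FX", 1),
        ("P01042", "KNG1", 1),
        ("P06870", "KLK1", 1),
    ),
}

MOTIVE_NAMES = (
    "Increased platelet activation",
    "Increased complement activation",
    "Hyperhomocysteinemia",
    "Increased coagulation",
)


@dataclass
class SyntheticScenario:
    """A complete generated study scenario with its planted ground truth."""

    interactome: Interactome
    drugs: list[DrugCharacterization]
    conditions: list[MotiveCharacterization]
    truth_table: TruthTable | None
    planted: dict[tuple[str, str], tuple[EdgeKey, ...]]  # (drug, condition) -> edges
    seed: int
    params: dict = field(default_factory=dict)

    def drug(self, name: str) -> DrugCharacterization:
        for d in self.drugs:
            if d.name == name:
                return d
        raise KeyError(name)

    def condition(self, name: str) -> MotiveCharacterization:
        for c in self.conditions:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def outcome(self) -> MotiveCharacterization:
        """Union of all motives' effectors: the adverse outcome as a whole."""
        effs: dict[ProteinRef, Effector] = {}
        for c in self.conditions:
            for e in c.effectors:
                effs.setdefault(e.protein, e)
        return MotiveCharacterization("outcome", frozenset(effs.values()))

    @property
    def planted_edges(self) -> set[EdgeKey]:
        return {k for edges in self.planted.values() for k in edges}

    def planted_edges_for_drug(self, drug_name: str) -> set[EdgeKey]:
        return {
            k
            for (d, _), edges in self.planted.items()
            if d == drug_name
            for k in edges
        }


# ---------------------------------------------------------------------------
# Interactome generation
# ---------------------------------------------------------------------------

def _accession(i: int) -> str:
    return f"P{i:05d}"


def generate_interactome(
    n_nodes: int,
    mean_degree: float = 4.0,
    p_negative_sign: float = 0.2,
    seed: int = 0,
) -> Interactome:
    """Connected preferential-attachment interactome with random edge signs.

    Preferential attachment reproduces the heavy-tailed degree distribution of
    protein interaction networks; each edge is independently inhibitory
    (sign -1) with probability ``p_negative_sign``.  Edges are undirected.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    m = max(1, int(round(mean_degree / 2)))
    if m >= n_nodes:
        raise ValueError("mean_degree too large for n_nodes")
    rng = np.random.default_rng(seed)
    g = nx.barabasi_albert_graph(n_nodes, m, seed=int(rng.integers(2**31)))
    inter = Interactome()
    for i in range(n_nodes):
        inter.add_node(ProteinRef(_accession(i)))
    for u, v in sorted(g.edges()):
        sign = -1 if rng.random() < p_negative_sign else 1
        inter.add_edge(_accession(u), _accession(v), sign=sign)
    return inter


# ---------------------------------------------------------------------------
# Characterizations
# ---------------------------------------------------------------------------

def generate_characterizations(
    interactome: Interactome,
    n_drugs: int,
    n_conditions: int,
    targets_per_drug: int = 2,
    effectors_per_condition: int = 3,
    p_inhibitory_target: float = 0.0,
    p_negative_direction: float = 0.5,
    seed: int = 0,
) -> tuple[list[DrugCharacterization], list[MotiveCharacterization]]:
    """Random disjoint drug target sets and condition effector sets."""
    rng = np.random.default_rng(seed)
    need = n_drugs * targets_per_drug + n_conditions * effectors_per_condition
    accs = sorted(interactome.nodes)
    if need > len(accs):
        raise ValueError("not enough interactome nodes for the requested sets")
    chosen = [accs[i] for i in rng.choice(len(accs), size=need, replace=False)]
    drugs = []
    pos = 0
    for d in range(n_drugs):
        targets = frozenset(
            DrugTarget(
                ProteinRef(chosen[pos + t]),
                -1 if rng.random() < p_inhibitory_target else 1,
            )
            for t in range(targets_per_drug)
        )
        pos += targets_per_drug
        drugs.append(DrugCharacterization(f"drug{d + 1:02d}", targets))
    conditions = []
    for c in range(n_conditions):
        effectors = frozenset(
            Effector(
                ProteinRef(chosen[pos + e]),
                -1 if rng.random() < p_negative_direction else 1,
            )
            for e in range(effectors_per_condition)
        )
        pos += effectors_per_condition
        conditions.append(MotiveCharacterization(f"condition{c + 1:02d}", effectors))
    return drugs, conditions


# ---------------------------------------------------------------------------
# Mechanism planting
# ---------------------------------------------------------------------------

def plant_mechanism(
    interactome: Interactome,
    drug: DrugCharacterization,
    condition: MotiveCharacterization,
    path_len: int = 2,
    seed: int = 0,
) -> list[tuple[EdgeKey, ...]]:
    """Plant signed target->effector paths making the pair mechanistically real.

    For each drug target, a path of length <= ``path_len`` is planted (reusing
    an existing shortest path when its sign parity already matches, otherwise
    adding edges) to every effector of the condition, so the pair is genuinely
    satisfiable under the strict-majority response criterion.  The sign
    product along each path times the target's action sign equals the
    effector's pathological direction.  Returns the planted paths as edge-key
    tuples; replanting with the same seed is identical.
    """
    if path_len < 1:
        raise ValueError("path_len must be >= 1")
    rng = np.random.default_rng(seed)
    graph = interactome.to_networkx()
    effectors = sorted(condition.effectors)

    paths: list[tuple[EdgeKey, ...]] = []
    for target in sorted(drug.targets):
        for eff in effectors:
            path = _plant_path(
                interactome, graph, target, eff, path_len, rng
            )
            paths.append(path)
    return paths


def _path_parity(interactome: Interactome, nodes: Sequence[str]) -> int:
    parity = 1
    for u, v in zip(nodes, nodes[1:]):
        parity *= interactome.get_edge(u, v).sign
    return parity


def _plant_path(
    interactome: Interactome,
    graph: nx.Graph,
    target: DrugTarget,
    effector: Effector,
    path_len: int,
    rng: np.random.Generator,
) -> tuple[EdgeKey, ...]:
    t = target.protein.accession
    e = effector.protein.accession
    needed = effector.direction * target.action
    if t == e:
        raise ValueError("target and effector coincide; cannot plant a path")

    # reuse an existing short path when its parity already matches
    try:
        nodes = nx.shortest_path(graph, t, e)
        if len(nodes) - 1 <= path_len and _path_parity(interactome, nodes) == needed:
            return tuple(
                interactome.get_edge(u, v).key for u, v in zip(nodes, nodes[1:])
            )
    except (nx.NetworkXNoPath, nx.NodeNotFound):
        pass

    # direct edge
    existing = interactome.get_edge(t, e)
    if existing is None:
        edge = interactome.add_edge(t, e, sign=needed)
        graph.add_edge(t, e, sign=needed)
        return (edge.key,)
    if existing.sign == needed:
        return (existing.key,)

    # two-hop detour through an intermediate whose edges are free or compatible
    if path_len >= 2:
        accs = sorted(interactome.nodes)
        for _ in range(200):
            x = accs[int(rng.integers(len(accs)))]
            if x in (t, e):
                continue
            e1 = interactome.get_edge(t, x)
            e2 = interactome.get_edge(x, e)
            s1 = e1.sign if e1 is not None else None
            s2 = e2.sign if e2 is not None else None
            if s1 is not None and s2 is not None and s1 * s2 != needed:
                continue
            if s1 is None:
                s1 = needed * (s2 if s2 is not None else 1)
                e1 = interactome.add_edge(t, x, sign=s1)
                graph.add_edge(t, x, sign=s1)
            if s2 is None:
                s2 = needed * s1
                e2 = interactome.add_edge(x, e, sign=s2)
                graph.add_edge(x, e, sign=s2)
            if s1 * s2 == needed:
                return (e1.key, e2.key)
    raise RuntimeError(
        f"could not plant a parity-{needed} path {t} -> {e} within length {path_len}"
    )


# ---------------------------------------------------------------------------
# Truth tables and AE profiles
# ---------------------------------------------------------------------------

def generate_truth_table(
    scenario: SyntheticScenario,
    n_negatives: int | None = None,
    label_noise: float = 0.0,
    seed: int = 0,
) -> TruthTable:
    """Label planted pairs positive and sampled unplanted pairs negative.

    Each label is then independently flipped with probability ``label_noise``
    (must be < 0.5; 0.5 would destroy all information).  Negatives are drawn
    without replacement from the unplanted (drug, condition) pairs.
    """
    if not (0 <= label_noise < 0.5):
        raise ValueError("label_noise must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    planted_pairs = sorted(scenario.planted)
    all_pairs = [
        (d.name, c.name) for d in scenario.drugs for c in scenario.conditions
    ]
    unplanted = [p for p in all_pairs if p not in scenario.planted]
    if n_negatives is None:
        n_negatives = min(len(planted_pairs), len(unplanted))
    if n_negatives > len(unplanted):
        raise ValueError(
            f"requested {n_negatives} negatives but only {len(unplanted)} unplanted pairs"
        )
    neg_idx = sorted(rng.choice(len(unplanted), size=n_negatives, replace=False))
    negative_pairs = [unplanted[i] for i in neg_idx]

    restrictions = []
    for pairs, label in ((planted_pairs, True), (negative_pairs, False)):
        for drug_name, cond_name in pairs:
            flip = rng.random() < label_noise
            cond = scenario.condition(cond_name)
            restrictions.append(
                Restriction(
                    stimulus=scenario.drug(drug_name),
                    condition=cond_name,
                    response=cond.effectors,
                    relation="induces",
                    label=(not label) if flip else label,
                )
            )
    labels = {r.label for r in restrictions}
    if labels != {True, False}:  # noise flipped away an entire class
        raise ValueError("label noise destroyed a label class; re-seed or lower noise")
    return TruthTable(tuple(restrictions))


def generate_ae_profiles(
    trial_sizes: Mapping[str, int],
    event_freqs: Mapping[str, float],
    seed: int = 0,
) -> list[AEProfile]:
    """Binomial adverse-event counts per trial at specified true frequencies."""
    for name, f in event_freqs.items():
        if not (0 <= f <= 1):
            raise ValueError(f"frequency for {name!r} outside [0, 1]")
    rng = np.random.default_rng(seed)
    profiles = []
    for trial, n in sorted(trial_sizes.items()):
        events = tuple(
            (event, int(rng.binomial(n, f))) for event, f in sorted(event_freqs.items())
        )
        profiles.append(AEProfile(trial, n, events))
    return profiles


# ---------------------------------------------------------------------------
# Assembled scenarios
# ---------------------------------------------------------------------------

def signal_scenario(
    seed: int = 0,
    n_nodes: int = 300,
    mean_degree: float = 4.0,
    p_negative_sign: float = 0.2,
    n_drugs: int = 8,
    n_conditions: int = 4,
    targets_per_drug: int = 2,
    effectors_per_condition: int = 3,
    conditions_per_drug: int = 2,
    path_len: int = 2,
    n_negatives: int | None = None,
    label_noise: float = 0.05,
    drugs_with_mechanism: int | None = None,
) -> SyntheticScenario:
    """The default planted-mechanism scenario used throughout the test suite.

    300 nodes at mean degree 4 with 8 drugs and 4 conditions is large enough
    for non-trivial multi-hop mechanisms yet small enough that ensemble
    training stays sub-minute.  Each drug is planted into two conditions;
    the truth table holds the planted positives plus an equal number of
    unplanted negatives, with 5% label noise by default.
    """
    rng = np.random.default_rng(seed)
    interactome = generate_interactome(
        n_nodes, mean_degree, p_negative_sign, seed=int(rng.integers(2**31))
    )
    drugs, conditions = generate_characterizations(
        interactome,
        n_drugs,
        n_conditions,
        targets_per_drug,
        effectors_per_condition,
        seed=int(rng.integers(2**31)),
    )
    planted: dict[tuple[str, str], tuple[EdgeKey, ...]] = {}
    n_mech = len(drugs) if drugs_with_mechanism is None else drugs_with_mechanism
    for drug in drugs[:n_mech]:
        cond_idx = rng.choice(n_conditions, size=conditions_per_drug, replace=False)
        for ci in sorted(cond_idx):
            cond = conditions[int(ci)]
            paths = plant_mechanism(
                interactome, drug, cond, path_len, seed=int(rng.integers(2**31))
            )
            planted[(drug.name, cond.name)] = tuple(
                sorted({k for p in paths for k in p})
            )
    scenario = SyntheticScenario(
        interactome=interactome,
        drugs=drugs,
        conditions=conditions,
        truth_table=None,
        planted=planted,
        seed=seed,
        params=dict(
            n_nodes=n_nodes,
            mean_degree=mean_degree,
            p_negative_sign=p_negative_sign,
            n_drugs=n_drugs,
            n_conditions=n_conditions,
            targets_per_drug=targets_per_drug,
            effectors_per_condition=effectors_per_condition,
            conditions_per_drug=conditions_per_drug,
            path_len=path_len,
            label_noise=label_noise,
        ),
    )
    scenario.truth_table = generate_truth_table(
        scenario, n_negatives, label_noise, seed=int(rng.integers(2**31))
    )
    return scenario


def recovery_scenario(seed: int = 0) -> SyntheticScenario:
    """Default-scale instance with one identifiable planted mechanism.

    A single drug receives a planted mechanism into a single condition,
    planted at path length 1 (direct signed target->effector edges), with
    noise-free labels.  Direct edges are uniquely shortest, so the planted
    mechanism is identifiable and edge-level recovery (precision/recall of
    planted edges among high-frequency ensemble edges) is well defined.
    """
    return signal_scenario(
        seed=seed,
        n_drugs=2,
        n_conditions=2,
        conditions_per_drug=1,
        path_len=1,
        label_noise=0.0,
        n_negatives=3,
        drugs_with_mechanism=1,
    )


def hemophilia_toy_scenario(seed: int = 0, n_nodes: int = 60) -> SyntheticScenario:
    """The printed hemophilia drug characterizations on a small interactome.

    Emits emicizumab (FX up), rFVIIa (FVII up) and aPCC (FII, FVII, FIX, FX,
    KNG1, KLK1, all up) verbatim, so that rFVIIa's targets are a strict subset
    of aPCC's and the combination stimuli nest:
    targets(emicizumab + rFVIIa) is a proper subset of targets(emicizumab + aPCC).
    Four condition motives with activating effectors are wired into an
    all-positive-sign generated interactome (nonnegative influence makes the
    nested-stimulus full-overlap property exact), and each drug is planted
    into the coagulation motive.
    """
    rng = np.random.default_rng(seed)
    interactome = generate_interactome(
        n_nodes, mean_degree=4.0, p_negative_sign=0.0, seed=int(rng.integers(2**31))
    )

    # graft the six printed coagulation proteins in place of generated nodes
    table1_accs: dict[str, str] = {}
    for drug_rows in TABLE1_DRUGS.values():
        for acc, short, _ in drug_rows:
            table1_accs[acc] = short
    generated = sorted(interactome.nodes)
    replace_idx = rng.choice(len(generated), size=len(table1_accs), replace=False)
    mapping = {
        generated[int(i)]: acc
        for i, acc in zip(sorted(replace_idx), sorted(table1_accs))
    }
    grafted = Interactome()
    for old_acc in generated:
        new_acc = mapping.get(old_acc, old_acc)
        grafted.add_node(ProteinRef(new_acc, table1_accs.get(new_acc)))
    for e in interactome.sorted_edges():
        grafted.add_edge(
            mapping.get(e.source, e.source),
            mapping.get(e.target, e.target),
            sign=e.sign,
            directed=e.directed,
        )

    drugs = [
        DrugCharacterization(
            name,
            frozenset(
                DrugTarget(ProteinRef(acc, short), action)
                for acc, short, action in rows
            ),
        )
        for name, rows in TABLE1_DRUGS.items()
    ]

    free = sorted(set(grafted.nodes) - set(table1_accs))
    eff_accs = [
        free[i]
        for i in rng.choice(len(free), size=3 * len(MOTIVE_NAMES), replace=False)
    ]
    conditions = []
    for mi, name in enumerate(MOTIVE_NAMES):
        effectors = frozenset(
            Effector(ProteinRef(a), 1) for a in eff_accs[3 * mi : 3 * mi + 3]
        )
        conditions.append(MotiveCharacterization(name, effectors))

    coag = conditions[MOTIVE_NAMES.index("Increased coagulation")]
    planted: dict[tuple[str, str], tuple[EdgeKey, ...]] = {}
    for drug in drugs:
        paths = plant_mechanism(
            grafted, drug, coag, path_len=2, seed=int(rng.integers(2**31))
        )
        planted[(drug.name, coag.name)] = tuple(sorted({k for p in paths for k in p}))

    scenario = SyntheticScenario(
        interactome=grafted,
        drugs=drugs,
        conditions=conditions,
        truth_table=None,
        planted=planted,
        seed=seed,
        params=dict(n_nodes=n_nodes, toy=True),
    )
    scenario.truth_table = generate_truth_table(
        scenario, n_negatives=3, label_noise=0.0, seed=int(rng.integers(2**31))
    )
    return scenario


# ---------------------------------------------------------------------------
# Scenario serialization
# ---------------------------------------------------------------------------

def write_scenario(scenario: SyntheticScenario, directory: str | Path) -> None:
    """Serialize a scenario bundle: TSV tables plus a JSON manifest."""
    from .knowledge_base import (
        write_drug_characterizations,
        write_motive_characterizations,
    )

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    export_interactome_tsv(scenario.interactome, directory / "interactome.tsv")
    write_drug_characterizations(scenario.drugs, directory / "drugs.tsv")
    write_motive_characterizations(scenario.conditions, directory / "motives.tsv")
    manifest = {
        "seed": scenario.seed,
        "params": scenario.params,
        "planted": {
            f"{d}|{c}": [list(k) for k in edges]
            for (d, c), edges in sorted(scenario.planted.items())
        },
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
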