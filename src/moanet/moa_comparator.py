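"""Comparison analyses over trained MoA ensembles.

Turns solution ensembles into interpretable consensus graphs and runs the
three comparison analyses used to contrast two drug combinations:

* interaction-frequency maps — how often each network edge is active across
  the ensemble's solutions, with a readability-constrained threshold chooser;
* perturbed-protein-set overlap — which proteins each stimulus indirectly
  drives, and whether one combination's reach nests inside the other's;
* differential predicted activity — per-protein activity difference between
  two ensembles, significant when |delta| exceeds 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .network_builder import EdgeKey
from .propagation_model import MoAModel, predicted_activity

logger = logging.getLogger("moanet")

DEFAULT_WEIGHT_EPS = 0.05
DEFAULT_ACTIVITY_EPS = 0.05
DEFAULT_PERTURBATION_FLOOR = 0.05
DEFAULT_DIFF_THRESHOLD = 0.5
DEFAULT_MAX_NODES = 30

EXCLUSIVE_COLORS = ("black", "forestgreen", "firebrick")


# ---------------------------------------------------------------------------
# Interaction frequencies
# ---------------------------------------------------------------------------

def interaction_frequencies(
    moa: MoAModel,
    weight_eps: float = DEFAULT_WEIGHT_EPS,
    activity_eps: float = DEFAULT_ACTIVITY_EPS,
) -> dict[EdgeKey, float]:
    """Fraction of ensemble solutions in which each edge is active.

    An edge is active in a solution when its weight magnitude exceeds
    ``weight_eps`` *and* signal actually reaches it: the upstream endpoint's
    converged |activity| exceeds ``activity_eps`` (for undirected edges, the
    more active endpoint counts as upstream).
    """
    net = moa.network
    counts = np.zeros(net.n_edges)
    for sol in moa.solutions:
        if sol.state is None:
            raise ValueError("solution lacks a converged state")
        a = np.array([abs(sol.state.activities[acc]) for acc in net.nodes])
        upstream = np.where(
            net.directed, a[net.src], np.maximum(a[net.src], a[net.dst])
        )
        active = (sol.parameters.weights > weight_eps) & (upstream > activity_eps)
        counts += active
    freqs = counts / moa.n_solutions
    return {k: float(f) for k, f in zip(net.edge_keys, freqs)}


def optimize_frequency_threshold(
    freq: Mapping[EdgeKey, float], max_nodes: int = DEFAULT_MAX_NODES
) -> float:
    """Smallest frequency threshold whose retained subgraph is readable.

    Candidate thresholds are the sorted distinct frequencies present; retention
    keeps edges with frequency >= threshold.  The chosen threshold is the
    smallest one whose retained node count is at most ``max_nodes`` (maximal
    retained frequency mass subject to the node budget; ties break toward the
    smaller threshold).  If no candidate meets the budget the largest candidate
    is returned.
    """
    if not freq:
        raise ValueError("empty frequency map")
    candidates = sorted(set(freq.values()))
    for t in candidates:
        nodes = {n for (u, v), f in freq.items() if f >= t for n in (u, v)}
        if len(nodes) <= max_nodes:
            return float(t)
    return float(candidates[-1])


# ---------------------------------------------------------------------------
# Consensus MoA graph
# ---------------------------------------------------------------------------

@dataclass
class MoAGraph:
    """Thresholded consensus graph with per-ensemble presence flags.

    ``edges`` maps edge key -> per-map frequencies; ``presence`` maps edge key
    -> per-map booleans (frequency >= threshold in that map); ``node_activity``
    carries the mean predicted activity used for sign labels.
    """

    map_names: tuple[str, ...]
    threshold: float
    edges: dict[EdgeKey, tuple[float, ...]] = field(default_factory=dict)
    presence: dict[EdgeKey, tuple[bool, ...]] = field(default_factory=dict)
    node_activity: dict[str, float] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return {n for k in self.edges for n in k}

    def exclusive_edges(self, map_name: str) -> set[EdgeKey]:
        """Edges above threshold in exactly this map."""
        j = self.map_names.index(map_name)
        return {
            k
            for k, pres in self.presence.items()
            if pres[j] and not any(p for i, p in enumerate(pres) if i != j)
        }


def consensus_moa_graph(
    freqs: Mapping[EdgeKey, float] | Sequence[Mapping[EdgeKey, float]],
    threshold: float,
    activities: Mapping[str, float] | Sequence[Mapping[str, float]] | None = None,
    map_names: Sequence[str] | None = None,
) -> MoAGraph:
    """Retain edges meeting the threshold in at least one frequency map.

    With two maps, each retained edge is flagged per map, supporting
    "detected only under combination B" style annotations.  Node labels carry
    the mean activity (averaged across the supplied activity maps).
    """
    freq_maps = [freqs] if isinstance(freqs, Mapping) else list(freqs)
    if not freq_maps:
        raise ValueError("no frequency maps supplied")
    names = tuple(map_names or (f"map{i + 1}" for i in range(len(freq_maps))))
    if len(names) != len(freq_maps):
        raise ValueError("map_names length mismatch")

    all_keys = sorted({k for m in freq_maps for k in m})
    graph = MoAGraph(names, threshold)
    for k in all_keys:
        per_map = tuple(float(m.get(k, 0.0)) for m in freq_maps)
        pres = tuple(f >= threshold for f in per_map)
        if any(pres):
            graph.edges[k] = per_map
            graph.presence[k] = pres

    if activities is not None:
        act_maps = [activities] if isinstance(activities, Mapping) else list(activities)
        for n in graph.nodes:
            vals = [m[n] for m in act_maps if n in m]
            if vals:
                graph.node_activity[n] = float(np.mean(vals))
    return graph


# ---------------------------------------------------------------------------
# Perturbed sets, overlap, differential activity
# ---------------------------------------------------------------------------

def perturbed_protein_set(
    moa: MoAModel,
    perturbation_floor: float = DEFAULT_PERTURBATION_FLOOR,
    exclude: set[str] | None = None,
) -> set[str]:
    """Proteins whose mean predicted |activity| exceeds the floor.

    Clamped stimulus nodes are excluded by default — the analysis concerns
    *indirectly* driven changes; pass ``exclude`` to widen the exclusion (e.g.
    the union of two combinations' stimuli when comparing their reach).
    """
    acts = predicted_activity(moa)
    excluded = set(moa.stimulus) if exclude is None else set(exclude)
    return {
        acc
        for acc, a in acts.items()
        if abs(a) > perturbation_floor and acc not in excluded
    }


@dataclass(frozen=True)
class OverlapReport:
    n_a: int
    n_b: int
    n_intersection: int
    a_subset_of_b: bool
    b_subset_of_a: bool
    members_a: tuple[str, ...]
    members_b: tuple[str, ...]
    members_common: tuple[str, ...]


def overlap_analysis(set_a: set[str], set_b: set[str]) -> OverlapReport:
    """Exact set arithmetic between two perturbed protein sets."""
    inter = set_a & set_b
    return OverlapReport(
        n_a=len(set_a),
        n_b=len(set_b),
        n_intersection=len(inter),
        a_subset_of_b=inter == set_a,
        b_subset_of_a=inter == set_b,
        members_a=tuple(sorted(set_a)),
        members_b=tuple(sorted(set_b)),
        members_common=tuple(sorted(inter)),
    )


@dataclass(frozen=True)
class DifferentialRow:
    protein: str
    activity_a: float
    activity_b: float
    delta: float
    significant: bool


@dataclass(frozen=True)
class DifferentialActivityReport:
    rows: tuple[DifferentialRow, ...]
    threshold: float

    @property
    def significant(self) -> tuple[DifferentialRow, ...]:
        return tuple(r for r in self.rows if r.significant)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "protein": r.protein,
                    "activity_a": r.activity_a,
                    "activity_b": r.activity_b,
                    "delta": r.delta,
                    "significant": r.significant,
                }
                for r in self.rows
            ],
            columns=["protein", "activity_a", "activity_b", "delta", "significant"],
        )


def differential_activity(
    activities_a: Mapping[str, float],
    activities_b: Mapping[str, float],
    diff_threshold: float = DEFAULT_DIFF_THRESHOLD,
) -> DifferentialActivityReport:
    """Per-protein activity difference A - B, sorted by |delta| descending.

    A change is significant when |delta| is strictly greater than the
    threshold (default 0.5).  Proteins present in only one map are treated as
    activity 0 in the other ("not detected"), with a log note.
    """
    only_a = set(activities_a) - set(activities_b)
    only_b = set(activities_b) - set(activities_a)
    if only_a or only_b:
        logger.info(
            "differential_activity: %d proteins missing from B, %d from A; treated as 0",
            len(only_a), len(only_b),
        )
    rows = []
    for p in sorted(set(activities_a) | set(activities_b)):
        a = float(activities_a.get(p, 0.0))
        b = float(activities_b.get(p, 0.0))
        delta = a - b
        rows.append(DifferentialRow(p, a, b, delta, abs(delta) > diff_threshold))
    rows.sort(key=lambda r: (-abs(r.delta), r.protein))
    return DifferentialActivityReport(tuple(rows), diff_threshold)


# ---------------------------------------------------------------------------
# DOT export
# ---------------------------------------------------------------------------

def export_moa_dot(graph: MoAGraph, path: str | Path) -> None:
    """Write the consensus MoA graph as a Graphviz DOT digraph.

    Edge color encodes per-map exclusivity (shared edges black, edges detected
    only in the i-th map in the i-th exclusivity color); node fill encodes the
    mean activity sign.
    """
    lines = ["digraph moa {", '  graph [overlap=false];']
    for n in sorted(graph.nodes):
        a = graph.node_activity.get(n)
        if a is None:
            fill, label = "white", n
        else:
            fill = "lightsalmon" if a > 0 else ("lightblue" if a < 0 else "white")
            label = f"{n}\\n{a:+.2f}"
        lines.append(f'  "{n}" [label="{label}", style=filled, fillcolor={fill}];')
    for k in sorted(graph.edges):
        pres = graph.presence[k]
        freqs = graph.edges[k]
        present_idx = [i for i, p in enumerate(pres) if p]
        if len(present_idx) == 1 and len(pres) > 1:
            color = EXCLUSIVE_COLORS[(present_idx[0] + 1) % len(EXCLUSIVE_COLORS)]
        else:
            color = EXCLUSIVE_COLORS[0]
        label = "/".join(f"{f:.2f}" for f in freqs)
        lines.append(
            f'  "{k[0]}" -> "{k[1]}" [color={color}, label="{label}", dir=none];'
        )
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


def export_moa_graphml(graph: MoAGraph, path: str | Path) -> None:
    """GraphML serialization carrying per-map frequencies and presence flags."""
    import networkx as nx

    g = nx.Graph(threshold=graph.threshold, map_names="|".join(graph.map_names))
    for n in sorted(graph.nodes):
        g.add_node(n, activity=float(graph.node_activity.get(n, 0.0)))
    for k in sorted(graph.edges):
        attrs = {}
        for j, name in enumerate(graph.map_names):
            attrs[f"freq_{name}"] = graph.edges[k][j]
            attrs[f"present_{name}"] = bool(graph.presence[k][j])
        g.add_edge(*k, **attrs)
    nx.write_graphml(g, path)


def load_moa_graphml(path: str | Path) -> MoAGraph:
    import networkx as nx

    g = nx.read_graphml(path)
    map_names = tuple(g.graph["map_names"].split("|"))
    graph = MoAGraph(map_names, float(g.graph["threshold"]))
    for u, v, data in g.edges(data=True):
        key = (u, v) if u <= v else (v, u)
        graph.edges[key] = tuple(float(data[f"freq_{n}"]) for n in map_names)
        graph.presence[key] = tuple(bool(data[f"present_{n}"]) for n in map_names)
    for n, data in g.nodes(data=True):
        graph.node_activity[n] = float(data.get("activity", 0.0))
    return graph


def write_overlap_report(report: OverlapReport, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "metric": [
                "n_a", "n_b", "n_intersection", "a_subset_of_b", "b_subset_of_a",
            ],
            "value": [
                report.n_a, report.n_b, report.n_intersection,
                report.a_subset_of_b, report.b_subset_of_a,
            ],
        }
    )
    df.to_csv(path, sep="\t", index=False)
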