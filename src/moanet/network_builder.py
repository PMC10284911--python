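"""Response-network construction from a signed protein–protein interactome.

The response network around a condition is the subgraph spanned by a set of
seed proteins (disease effectors, optionally drug targets) together with their
direct interactors — distance-1 neighbors in the interactome.  Candidate
mechanisms are then pathways through this network linking drug targets to
disease effectors.

Interactomes are signed (+1 activating / -1 inhibiting edges), optionally
directed, and keyed by UniProtKB-style accessions.  Supported formats: TSV edge
lists (source|target|sign|directed), SIF with "int+"/"int-" relations, and
GraphML with typed attributes (Cytoscape-compatible).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import networkx as nx
import pandas as pd

from .knowledge_base import ProteinRef

EdgeKey = tuple[str, str]


@dataclass(frozen=True)
class Edge:
    """One signed interaction; undirected edges are stored once, canonically."""

    source: str
    target: str
    sign: int
    directed: bool = False

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise ValueError(f"edge sign must be +1 or -1, got {self.sign}")
        if self.source == self.target:
            raise ValueError(f"self-loop on {self.source}")

    @property
    def key(self) -> EdgeKey:
        return (self.source, self.target)


def canonical_endpoints(u: str, v: str, directed: bool) -> tuple[str, str]:
    """Directed edges keep orientation; undirected use lexicographic order."""
    if directed or u <= v:
        return (u, v)
    return (v, u)


@dataclass
class Interactome:
    """A signed protein interaction graph.

    ``nodes`` maps accession -> ProteinRef; ``edges`` maps canonical endpoint
    pairs -> Edge.  Isolated nodes are allowed.
    """

    nodes: dict[str, ProteinRef] = field(default_factory=dict)
    edges: dict[EdgeKey, Edge] = field(default_factory=dict)

    def add_node(self, ref: ProteinRef | str) -> None:
        if isinstance(ref, str):
            ref = ProteinRef(ref)
        self.nodes.setdefault(ref.accession, ref)

    def add_edge(self, u: str, v: str, sign: int = 1, directed: bool = False) -> Edge:
        s, t = canonical_endpoints(u, v, directed)
        edge = Edge(s, t, sign, directed)
        self.add_node(s)
        self.add_node(t)
        self.edges[edge.key] = edge
        return edge

    def has_edge(self, u: str, v: str) -> bool:
        return (u, v) in self.edges or (v, u) in self.edges

    def get_edge(self, u: str, v: str) -> Edge | None:
        return self.edges.get((u, v)) or self.edges.get((v, u))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, acc: str) -> set[str]:
        """Adjacent accessions, ignoring edge direction."""
        out: set[str] = set()
        for (s, t) in self.edges:
            if s == acc:
                out.add(t)
            elif t == acc:
                out.add(s)
        return out

    def to_networkx(self) -> nx.Graph:
        """Undirected view with sign/directed edge attributes (for distances)."""
        g = nx.Graph()
        for acc, ref in self.nodes.items():
            g.add_node(acc, short_name=ref.short_name or "")
        for e in self.edges.values():
            g.add_edge(e.source, e.target, sign=e.sign, directed=e.directed)
        return g

    def sorted_edges(self) -> list[Edge]:
        return [self.edges[k] for k in sorted(self.edges)]


@dataclass
class ResponseNetwork:
    """Seed proteins plus direct interactors, as an induced subgraph."""

    seeds: set[str]
    subgraph: Interactome
    provenance: dict[str, str]  # accession -> "seed" | "interactor"
    missing_seeds: list[str]    # requested seeds absent from the interactome

    @property
    def n_nodes(self) -> int:
        return self.subgraph.n_nodes

    @property
    def n_edges(self) -> int:
        return self.subgraph.n_edges


@dataclass(frozen=True)
class NetworkStats:
    n_proteins: int
    n_interactions: int
    n_seeds: int
    degree_min: int
    degree_mean: float
    degree_max: int


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def build_response_network(
    interactome: Interactome,
    seeds: Iterable[ProteinRef | str],
    include_interactor_edges: bool = True,
    shells: int = 1,
) -> ResponseNetwork:
    """Extract the subgraph of seeds and their direct interactors.

    The node set is the union of closed neighborhoods of the mapped seeds; the
    edge set is the induced subgraph by default.  With
    ``include_interactor_edges=False`` only edges incident to a seed are kept.
    ``shells`` widens the expansion to k-hop neighbors (1 = direct interactors
    only, the default and the standard response-network definition).
    Seeds absent from the interactome are reported in ``missing_seeds`` rather
    than raising, unless *no* seed maps, which is an error.
    """
    if shells < 1:
        raise ValueError("shells must be >= 1")
    accs = [s.accession if isinstance(s, ProteinRef) else s for s in seeds]
    if not accs:
        raise ValueError("seed set is empty")
    mapped = [a for a in accs if a in interactome.nodes]
    missing = sorted(set(accs) - set(mapped))
    if not mapped:
        raise ValueError("no seed protein maps into the interactome")

    seed_set = set(mapped)
    node_set = set(seed_set)
    frontier = set(seed_set)
    for _ in range(shells):
        nxt: set[str] = set()
        for e in interactome.edges.values():
            if e.source in frontier:
                nxt.add(e.target)
            if e.target in frontier:
                nxt.add(e.source)
        nxt -= node_set
        node_set |= nxt
        frontier = nxt

    sub = Interactome()
    for acc in node_set:
        sub.add_node(interactome.nodes[acc])
    for e in interactome.edges.values():
        if e.source in node_set and e.target in node_set:
            if include_interactor_edges or e.source in seed_set or e.target in seed_set:
                sub.add_edge(e.source, e.target, e.sign, e.directed)

    provenance = {a: ("seed" if a in seed_set else "interactor") for a in node_set}
    return ResponseNetwork(seed_set, sub, provenance, missing)


def network_stats(net: ResponseNetwork) -> NetworkStats:
    degrees: dict[str, int] = {a: 0 for a in net.subgraph.nodes}
    for e in net.subgraph.edges.values():
        degrees[e.source] += 1
        degrees[e.target] += 1
    vals = list(degrees.values())
    return NetworkStats(
        n_proteins=net.n_nodes,
        n_interactions=net.n_edges,
        n_seeds=len(net.seeds),
        degree_min=min(vals) if vals else 0,
        degree_mean=(sum(vals) / len(vals)) if vals else 0.0,
        degree_max=max(vals) if vals else 0,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

Format = Literal["SIF", "GraphML", "TSV"]

_SIF_RELATIONS = {"int+": 1, "int-": -1}


def load_interactome(path: str | Path, format: Format | None = None) -> Interactome:
    """Load an interactome from SIF, GraphML or a TSV edge list.

    The format is inferred from the suffix when not given.  Unsigned inputs
    (plain SIF relations) default to sign +1.  Malformed lines raise a parse
    error carrying the line number.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "SIF":
        return _load_sif(path)
    if fmt == "TSV":
        return _load_tsv(path)
    if fmt == "GraphML":
        return _load_graphml(path)
    raise ValueError(f"unknown interactome format {fmt!r}")


def export_network(
    net: ResponseNetwork | Interactome, path: str | Path, format: Format | None = None
) -> None:
    """Write a network to SIF or GraphML (Cytoscape-compatible).

    SIF encodes the sign in the relation ("int+"/"int-"); GraphML carries sign
    and directedness on edges and, for response networks, seed/interactor
    provenance on nodes.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    inter = net.subgraph if isinstance(net, ResponseNetwork) else net
    provenance = net.provenance if isinstance(net, ResponseNetwork) else {}
    if fmt == "SIF":
        lines = [
            f"{e.source}\t{'int+' if e.sign > 0 else 'int-'}\t{e.target}"
            for e in inter.sorted_edges()
        ]
        isolated = sorted(set(inter.nodes) - {n for e in inter.edges.values() for n in e.key})
        path.write_text("\n".join(lines + isolated) + ("\n" if lines or isolated else ""))
    elif fmt == "GraphML":
        g = nx.Graph()
        for acc, ref in inter.nodes.items():
            attrs = {"short_name": ref.short_name or ""}
            if provenance:
                attrs["provenance"] = provenance.get(acc, "interactor")
            g.add_node(acc, **attrs)
        for e in inter.sorted_edges():
            g.add_edge(e.source, e.target, sign=e.sign, directed=e.directed)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unsupported export format {fmt!r}")


def export_interactome_tsv(inter: Interactome, path: str | Path) -> None:
    records = [
        {"source": e.source, "target": e.target, "sign": e.sign, "directed": e.directed}
        for e in inter.sorted_edges()
    ]
    pd.DataFrame.from_records(
        records, columns=["source", "target", "sign", "directed"]
    ).to_csv(path, sep="\t", index=False)


def _infer_format(path: Path) -> Format:
    suffix = path.suffix.lower()
    if suffix == ".sif":
        return "SIF"
    if suffix == ".graphml":
        return "GraphML"
    if suffix in (".tsv", ".txt"):
        return "TSV"
    raise ValueError(f"cannot infer network format from {path.name!r}")


def _load_sif(path: Path) -> Interactome:
    inter = Interactome()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) == 1:
            inter.add_node(parts[0])
        elif len(parts) >= 3:
            source, relation = parts[0], parts[1]
            sign = _SIF_RELATIONS.get(relation, 1)
            for target in parts[2:]:
                try:
                    inter.add_edge(source, target, sign=sign)
                except ValueError as exc:
                    raise ValueError(f"{path.name}:{lineno}: {exc}") from exc
        else:
            raise ValueError(f"{path.name}:{lineno}: malformed SIF line {line!r}")
    return inter


def _load_tsv(path: Path) -> Interactome:
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = {"source", "target"}
    if not expected.issubset(df.columns):
        raise ValueError(f"{path.name}: TSV edge list needs columns source, target")
    inter = Interactome()
    for i, row in enumerate(df.itertuples(), start=2):
        sign = int(getattr(row, "sign", 1) or 1)
        directed = str(getattr(row, "directed", "False")).lower() in ("true", "1")
        try:
            inter.add_edge(row.source, row.target, sign=sign, directed=directed)
        except ValueError as exc:
            raise ValueError(f"{path.name}:{i}: {exc}") from exc
    return inter


def _load_graphml(path: Path) -> Interactome:
    g = nx.read_graphml(path)
    inter = Interactome()
    for node, data in g.nodes(data=True):
        inter.add_node(ProteinRef(str(node), data.get("short_name") or None))
    for u, v, data in g.edges(data=True):
        sign = int(data.get("sign", 1))
        directed = bool(data.get("directed", False))
        inter.add_edge(str(u), str(v), sign=sign, directed=directed)
    return inter
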