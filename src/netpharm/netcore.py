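"""Undirected simple-graph data model and edge-list I/O.

Every stage of the screening pipeline — protein–protein interaction (PPI)
networks, compound–target bipartite networks, and the screened subnetworks —
lives on the same substrate: an undirected simple graph whose node IDs are
gene symbols or compound names.  Graphs are stored in a :class:`networkx.Graph`
behind a thin value-semantics wrapper so that set-algebra operations
(intersection, induced subgraphs) compare by node/edge *content*.

Supported file dialects:

* ``tsv-2col`` — two whitespace/tab-separated columns per edge, ``#`` comments
  allowed, a line with a single field denotes an isolated node.
* ``sif`` — Cytoscape simple-interaction format: ``node<TAB>relation<TAB>node
  [node ...]``; a bare one-field line denotes an isolated node.

Self-loop lines are dropped (and tallied), duplicate and reversed-duplicate
lines collapse to one edge: PPI semantics assume simple undirected graphs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

logger = logging.getLogger("netpharm")

EDGE_FORMATS = ("tsv-2col", "sif")

#: Relation token written on SIF edge lines ("pp" = protein–protein).
DEFAULT_SIF_RELATION = "pp"


class ParseError(ValueError):
    """A malformed line in an edge-list / table file (carries line number)."""


def normalize_symbol(symbol: str, uppercase: bool = True) -> str:
    """Whitespace-strip (and by default uppercase) a gene-symbol/node ID.

    Symbols arrive from many source databases with inconsistent casing;
    uppercasing at ingest makes set intersections behave.  Raises
    ``ValueError`` on empty/whitespace-only IDs.
    """
    s = symbol.strip()
    if not s:
        raise ValueError("empty node identifier")
    return s.upper() if uppercase else s


@dataclass
class Network:
    """Undirected simple graph with value (node/edge-set) equality.

    Invariants: no self-loops, no duplicate edges, every edge endpoint is a
    node, node IDs are non-empty stripped strings.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    name: str = ""

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        nodes: Iterable[str] = (),
        name: str = "",
        uppercase: bool = True,
    ) -> "Network":
        """Build a network from an edge iterable plus optional isolated nodes.

        Self-loops are rejected here (unlike file ingest, where they are
        dropped with a warning) because programmatic self-loops are a bug.
        """
        g = nx.Graph()
        for n in nodes:
            g.add_node(normalize_symbol(n, uppercase))
        for u, v in edges:
            nu, nv = normalize_symbol(u, uppercase), normalize_symbol(v, uppercase)
            if nu == nv:
                raise ValueError(f"self-loop edge on node {nu!r}")
            g.add_edge(nu, nv)
        return cls(graph=g, name=name)

    # -- views --------------------------------------------------------------
    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def edges(self) -> frozenset[frozenset[str]]:
        """Edges as a set of 2-element frozensets ((u,v) == (v,u))."""
        return frozenset(frozenset((u, v)) for u, v in self.graph.edges)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    def neighbors(self, node: str) -> set[str]:
        return set(self.graph.neighbors(node))

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        label = f" {self.name!r}" if self.name else ""
        return f"<Network{label}: {self.n_nodes} nodes, {self.n_edges} edges>"


@dataclass
class ReadReport:
    """Ingest bookkeeping returned alongside a parsed :class:`Network`."""

    n_lines: int = 0
    n_self_loops_dropped: int = 0
    n_duplicate_edges: int = 0


def read_edge_list(
    path: str | Path,
    format: str = "tsv-2col",
    uppercase: bool = True,
    with_report: bool = False,
) -> Network | tuple[Network, ReadReport]:
    """Read an undirected edge list in ``tsv-2col`` or ``sif`` dialect.

    Duplicate lines and reversed duplicates collapse to one edge; self-loop
    lines are dropped and counted (warning logged).  Raises
    :class:`ParseError` naming the offending line for malformed input.
    """
    if format not in EDGE_FORMATS:
        raise ValueError(f"unknown edge-list format {format!r}; expected one of {EDGE_FORMATS}")
    path = Path(path)
    g = nx.Graph()
    report = ReadReport()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            report.n_lines += 1
            if len(fields) == 1:
                # bare node line: isolated node (both dialects)
                g.add_node(normalize_symbol(fields[0], uppercase))
                continue
            if format == "tsv-2col":
                if len(fields) < 2:
                    raise ParseError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
                pairs = [(fields[0], fields[1])]
            else:  # sif: source relation target [target...]
                if len(fields) < 3:
                    raise ParseError(
                        f"{path}:{lineno}: SIF line needs >=3 fields (source relation target), "
                        f"got {len(fields)}"
                    )
                src = fields[0]
                pairs = [(src, t) for t in fields[2:]]
            for u, v in pairs:
                nu, nv = normalize_symbol(u, uppercase), normalize_symbol(v, uppercase)
                if nu == nv:
                    report.n_self_loops_dropped += 1
                    continue
                if g.has_edge(nu, nv):
                    report.n_duplicate_edges += 1
                g.add_edge(nu, nv)
    if report.n_self_loops_dropped:
        logger.warning(
            "%s: dropped %d self-loop line(s)", path, report.n_self_loops_dropped
        )
    net = Network(graph=g, name=path.stem)
    return (net, report) if with_report else net


def write_network(
    net: Network,
    path: str | Path,
    format: str = "tsv-2col",
    sif_relation: str = DEFAULT_SIF_RELATION,
) -> None:
    """Write ``net`` so that :func:`read_edge_list` round-trips it exactly.

    Isolated nodes are emitted as bare one-field lines in both dialects so
    that node sets (not just edge sets) survive the round trip.  Output is
    sorted, hence byte-deterministic for a given network.
    """
    if format not in EDGE_FORMATS:
        raise ValueError(f"unknown edge-list format {format!r}; expected one of {EDGE_FORMATS}")
    path = Path(path)
    edges = sorted(tuple(sorted(e)) for e in net.edges)
    touched = {n for e in edges for n in e}
    isolated = sorted(net.nodes - touched)
    with path.open("w") as fh:
        for u, v in edges:
            if format == "tsv-2col":
                fh.write(f"{u}\t{v}\n")
            else:
                fh.write(f"{u}\t{sif_relation}\t{v}\n")
        for n in isolated:
            fh.write(f"{n}\n")


def induced_subgraph(net: Network, keep: Iterable[str]) -> Network:
    """Subgraph on ``net.nodes ∩ keep`` with all surviving-endpoint edges.

    IDs in ``keep`` absent from the network are ignored.
    """
    keep = set(keep) & set(net.graph.nodes)
    return Network(graph=nx.Graph(net.graph.subgraph(keep)), name=net.name)


def intersect_networks(
    net_a: Network, net_b: Network, keep_isolated: bool = False
) -> Network:
    """Edge-wise intersection of two networks.

    The edge set is ``E_A ∩ E_B``.  With ``keep_isolated`` the node set is
    ``V_A ∩ V_B`` (common nodes survive even without a common edge); by
    default only endpoints of surviving edges are kept.
    """
    common_edges = net_a.edges & net_b.edges
    g = nx.Graph()
    for e in common_edges:
        u, v = tuple(e)
        g.add_edge(u, v)
    if keep_isolated:
        g.add_nodes_from(net_a.nodes & net_b.nodes)
    return Network(graph=g, name=f"{net_a.name}&{net_b.name}".strip("&"))


def connected_components(net: Network) -> list[frozenset[str]]:
    """Partition of the node set into connected components (largest first)."""
    comps = [frozenset(c) for c in nx.connected_components(net.graph)]
    return sorted(comps, key=lambda c: (-len(c), sorted(c)[0] if c else ""))


def write_node_list(nodes: Sequence[str] | frozenset[str], path: str | Path) -> None:
    """One symbol per line, sorted (core-target export)."""
    Path(path).write_text("".join(f"{n}\n" for n in sorted(nodes)))
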