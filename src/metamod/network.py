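"""Bipartite enzyme-metabolite network: representation, I/O and preprocessing.

The global metabolic network is an undirected bipartite graph in which one
node class holds enzyme-commission (EC) reaction identifiers (e.g.
``2.5.1.49``) and the other holds compound identifiers (e.g. KEGG
``C00073``).  An edge connects a reaction to one of its substrate or product
metabolites.  All downstream module discovery operates on this graph.
"""

from __future__ import annotations

import csv
from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator

import networkx as nx

__all__ = [
    "NodeType",
    "MetabolicNetwork",
    "BipartitenessError",
    "EdgeListParseError",
    "FilterResult",
    "read_edge_list",
    "write_edge_list",
    "write_graphml",
    "filter_currency_metabolites",
    "connected_components",
    "bfs_reachable",
]


class NodeType(str, Enum):
    """The two node classes of the bipartite network."""

    EC = "EC"
    METABOLITE = "METABOLITE"


class BipartitenessError(ValueError):
    """An id is used both as an EC and as a metabolite, or an edge joins two
    nodes of the same class."""


class EdgeListParseError(ValueError):
    """A malformed row in a tab-separated edge-list file."""


@dataclass(frozen=True)
class MetabolicNetwork:
    """Undirected bipartite graph of EC and metabolite nodes.

    Wraps a :class:`networkx.Graph` whose nodes carry a ``node_type``
    attribute.  Treat instances as immutable; preprocessing operations
    return copies.
    """

    graph: nx.Graph = field(repr=False)

    # -- construction -------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        extra_nodes: Iterable[tuple[str, NodeType]] = (),
    ) -> "MetabolicNetwork":
        """Build a network from ``(ec_id, metabolite_id)`` pairs.

        Duplicate pairs collapse to a single edge.  ``extra_nodes`` may add
        isolated nodes of either class.
        """
        g = nx.Graph()
        types: dict[str, NodeType] = {}

        def _add(node: str, t: NodeType) -> None:
            node = node.strip()
            if not node:
                raise EdgeListParseError("empty node id")
            seen = types.get(node)
            if seen is not None and seen is not t:
                raise BipartitenessError(
                    f"node {node!r} appears both as {seen.value} and {t.value}"
                )
            types[node] = t
            g.add_node(node, node_type=t)

        for ec, met in edges:
            ec, met = ec.strip(), met.strip()
            if ec == met:
                raise BipartitenessError(f"self-loop on id {ec!r}")
            _add(ec, NodeType.EC)
            _add(met, NodeType.METABOLITE)
            g.add_edge(ec, met)
        for node, t in extra_nodes:
            _add(node, t)
        return cls(g)

    # -- accessors ----------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_type(self, node: str) -> NodeType:
        return self.graph.nodes[node]["node_type"]

    def nodes_of_type(self, t: NodeType) -> set[str]:
        return {v for v, d in self.graph.nodes(data="node_type") if d is t}

    @property
    def ec_nodes(self) -> set[str]:
        return self.nodes_of_type(NodeType.EC)

    @property
    def metabolite_nodes(self) -> set[str]:
        return self.nodes_of_type(NodeType.METABOLITE)

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    def validate(self) -> None:
        """Check the bipartite invariant on every edge (cheap; O(E))."""
        for u, v in self.graph.edges:
            tu, tv = self.node_type(u), self.node_type(v)
            if tu is tv:
                raise BipartitenessError(f"edge ({u!r}, {v!r}) joins two {tu.value} nodes")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_EDGE_HEADER = ("ec_id", "metabolite_id")


def read_edge_list(path: str) -> MetabolicNetwork:
    """Read a tab-separated edge list with header ``ec_id\tmetabolite_id``.

    Duplicate rows collapse to a single edge.  Raises
    :class:`EdgeListParseError` naming the offending line for malformed rows
    and :class:`BipartitenessError` if an id occurs in both columns.
    """
    pairs: list[tuple[str, str]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise EdgeListParseError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        if tuple(header[:2]) != _EDGE_HEADER:
            raise EdgeListParseError(
                f"{path}: expected header {_EDGE_HEADER}, got {tuple(header)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue  # blank line
            if len(row) < 2 or not row[0].strip() or not row[1].strip():
                raise EdgeListParseError(f"{path}: line {lineno}: expected 2 columns")
            pairs.append((row[0], row[1]))
    if not pairs:
        raise EdgeListParseError(f"{path}: no edges")
    return MetabolicNetwork.from_edges(pairs)


def write_edge_list(net: MetabolicNetwork, path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_EDGE_HEADER)
        rows = []
        for u, v in net.graph.edges:
            if net.node_type(u) is NodeType.EC:
                rows.append((u, v))
            else:
                rows.append((v, u))
        for row in sorted(rows):
            w.writerow(row)


def write_graphml(net: MetabolicNetwork, path: str) -> None:
    """GraphML export with a ``node_type`` string attribute per node."""
    g = nx.Graph()
    for v, t in net.graph.nodes(data="node_type"):
        g.add_node(v, node_type=t.value)
    g.add_edges_from(net.graph.edges)
    nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FilterResult:
    """Outcome of currency-metabolite removal."""

    network: MetabolicNetwork
    removed_metabolites: frozenset[str]
    isolated_ecs: frozenset[str]  # ECs left with degree 0 (retained)


def filter_currency_metabolites(
    net: MetabolicNetwork,
    max_degree: int | None = None,
    explicit_list: Iterable[str] | None = None,
) -> FilterResult:
    """Remove currency metabolites (ubiquitous hubs such as water or ATP).

    Exactly one of ``max_degree`` (remove metabolites of degree strictly
    greater) or ``explicit_list`` (remove the named metabolites) must be
    given.  EC nodes are never removed; ECs isolated by the removal are
    retained and reported.
    """
    if (max_degree is None) == (explicit_list is None):
        raise ValueError("provide exactly one of max_degree / explicit_list")
    if explicit_list is not None:
        to_remove = {m.strip() for m in explicit_list}
        for m in to_remove:
            if m in net.graph and net.node_type(m) is NodeType.EC:
                raise ValueError(f"explicit currency list names EC node {m!r}")
        to_remove &= net.metabolite_nodes
    else:
        if max_degree < 1:
            raise ValueError("max_degree must be positive")
        to_remove = {
            m for m in net.metabolite_nodes if net.graph.degree[m] > max_degree
        }
    g = net.graph.copy()
    g.remove_nodes_from(to_remove)
    isolated = frozenset(
        v for v, d in g.degree if d == 0 and g.nodes[v]["node_type"] is NodeType.EC
    )
    return FilterResult(MetabolicNetwork(g), frozenset(to_remove), isolated)


def connected_components(net: MetabolicNetwork) -> list[set[str]]:
    """Connected components, largest first; ties broken by the
    lexicographically smallest member id."""
    comps = [set(c) for c in nx.connected_components(net.graph)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def bfs_reachable(
    net: MetabolicNetwork,
    allowed: Iterable[str],
    source: str,
    max_len: int,
) -> set[str]:
    """Nodes of ``allowed`` reachable from ``source`` by a path of strictly
    fewer than ``max_len`` edges within the subgraph induced by ``allowed``.

    The source itself is at distance 0 and always included.
    """
    allowed = set(allowed)
    if source not in allowed:
        raise ValueError(f"source {source!r} not in allowed set")
    if max_len < 1:
        raise ValueError("max_len must be positive")
    g = net.graph
    reached = {source}
    frontier = deque([source])
    for _depth in range(max_len - 1):
        if not frontier:
            break
        next_frontier: deque[str] = deque()
        while frontier:
            u = frontier.popleft()
            for w in g[u]:
                if w in allowed and w not in reached:
                    reached.add(w)
                    next_frontier.append(w)
        frontier = next_frontier
    return reached


def iter_induced_edges(net: MetabolicNetwork, nodes: Iterable[str]) -> Iterator[tuple[str, str]]:
    """Edges of the subgraph induced by ``nodes`` (each as a sorted pair)."""
    nodes = set(nodes)
    for u, v in net.graph.subgraph(nodes).edges:
        yield tuple(sorted((u, v)))  # type: ignore[misc]
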