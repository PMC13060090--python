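"""Anchor clustering and Steiner-tree completion into connected modules.

Anchors that are frequently joined by short disease-associated paths are
grouped by average-linkage hierarchical clustering on the distance 1 - M.
Each cluster is then completed into a connected subgraph of the global
network with a shortest-path Steiner heuristic: every anchor starts as its
own subtree, and at each step one path of globally minimal length between
two subtrees is chosen at random and merged, until a single tree remains.
The module is the subgraph induced by all collected nodes (not necessarily
a tree).  The greedy closest-pair merge is the classic 2-approximation of
the minimum Steiner tree on the metric closure.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .network import MetabolicNetwork, NodeType, iter_induced_edges
from .sampling import CoMembershipMatrix, SamplingConfig, co_membership, identify_anchors
from .scores import AnnotatedNetwork, BumFit

__all__ = [
    "AnchorCluster",
    "Module",
    "cluster_anchors",
    "steiner_complete",
    "build_modules",
    "discover_modules",
    "DiscoveryResult",
]


@dataclass(frozen=True)
class AnchorCluster:
    """A set of anchors hypothesised to belong to one module."""

    anchors: frozenset[str]

    def __post_init__(self) -> None:
        if not self.anchors:
            raise ValueError("empty anchor cluster")

    @property
    def is_singleton(self) -> bool:
        return len(self.anchors) == 1


@dataclass(frozen=True)
class Module:
    """A connected subgraph of the global network built around a cluster.

    ``nodes`` are the nodes collected by the Steiner heuristic (anchors plus
    connector nodes); ``edges`` is the full induced edge set.  ``p_hat`` is
    the mean p-value over the module's anchors, and ``valid`` marks modules
    with at least the configured number of anchors.
    """

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    anchors_ec: frozenset[str]
    anchors_met: frozenset[str]
    p_hat: float
    valid: bool = False
    module_id: int | None = None

    @property
    def anchors(self) -> frozenset[str]:
        return self.anchors_ec | self.anchors_met

    @property
    def n_ec(self) -> int:
        return len(self.anchors_ec)

    @property
    def n_met(self) -> int:
        return len(self.anchors_met)


def cluster_anchors(
    M: CoMembershipMatrix,
    cut: float = 0.8,
    cut_mode: str = "distance",
) -> list[AnchorCluster]:
    """Average-linkage clustering of anchors on the distance 1 - M.

    With ``cut_mode="similarity"`` (default) the dendrogram is cut so that
    merges happen only while average co-membership stays >= ``cut``
    (distance <= 1 - cut).  ``cut_mode="distance"`` instead cuts the 1 - M
    dendrogram at height ``cut`` directly.  Clusters are returned sorted by
    their lexicographically smallest member; singletons are legitimate
    output (flagged via :attr:`AnchorCluster.is_singleton`).
    """
    if not (0.0 < cut < 1.0):
        raise ValueError("cut must be in (0, 1)")
    ids = list(M.node_ids)
    if len(ids) == 0:
        return []
    if len(ids) == 1:
        return [AnchorCluster(frozenset(ids))]
    dist = 1.0 - np.asarray(M.values, dtype=float)
    if not np.allclose(dist, dist.T):
        raise ValueError("co-membership matrix is not symmetric")
    np.fill_diagonal(dist, 0.0)
    np.clip(dist, 0.0, 1.0, out=dist)
    z = linkage(squareform(dist, checks=False), method="average")
    height = (1.0 - cut) if cut_mode == "similarity" else cut
    if cut_mode not in ("similarity", "distance"):
        raise ValueError(f"unknown cut_mode {cut_mode!r}")
    labels = fcluster(z, t=height, criterion="distance")
    groups: dict[int, set[str]] = {}
    for node, lab in zip(ids, labels):
        groups.setdefault(int(lab), set()).add(node)
    clusters = [AnchorCluster(frozenset(g)) for g in groups.values()]
    clusters.sort(key=lambda c: min(c.anchors))
    return clusters


# ---------------------------------------------------------------------------
# Steiner completion
# ---------------------------------------------------------------------------


def _multi_source_bfs(adj: Mapping[str, Iterable[str]], sources: set[str]):
    """Distances and predecessor lists from a node set (unit edge weights)."""
    dist = {s: 0 for s in sources}
    preds: dict[str, list[str]] = {s: [] for s in sources}
    q = deque(sources)
    while q:
        u = q.popleft()
        du = dist[u]
        for w in adj[u]:
            if w not in dist:
                dist[w] = du + 1
                preds[w] = [u]
                q.append(w)
            elif dist[w] == du + 1:
                preds[w].append(u)
    return dist, preds


def _enumerate_paths(
    target: str,
    preds: Mapping[str, list[str]],
    sources: set[str],
    cap: int,
) -> list[tuple[str, ...]]:
    """All shortest paths from the source set to ``target`` (capped)."""
    out: list[tuple[str, ...]] = []
    stack: list[tuple[str, tuple[str, ...]]] = [(target, (target,))]
    while stack and len(out) < cap:
        node, path = stack.pop()
        if node in sources:
            out.append(path[::-1])
            continue
        for p in sorted(preds[node]):
            stack.append((p, path + (p,)))
    return out


def steiner_complete(
    net: MetabolicNetwork,
    anchors: AnchorCluster | Iterable[str],
    rng: np.random.Generator,
    max_paths: int = 1000,
) -> Module:
    """Connect a cluster's anchors into one subtree of the network.

    Each anchor starts as its own subtree; repeatedly, all inter-subtree
    shortest paths of globally minimal length are enumerated (capped at
    ``max_paths`` per step) and one is selected uniformly at random, merging
    the subtrees it touches.  Anchor metadata (types, p-values, validity)
    is filled in by :func:`build_modules`.
    """
    anchor_set = set(anchors.anchors if isinstance(anchors, AnchorCluster) else anchors)
    if not anchor_set:
        raise ValueError("no anchors to connect")
    g = net.graph
    missing = anchor_set - set(g.nodes)
    if missing:
        raise ValueError(f"anchors not in network: {sorted(missing)[:5]}")

    trees: list[set[str]] = [{a} for a in sorted(anchor_set)]
    while len(trees) > 1:
        # distances from every tree, then the globally minimal tree-pair gap
        bfs = [_multi_source_bfs(g, t) for t in trees]
        best_len = None
        for i in range(len(trees)):
            dist_i = bfs[i][0]
            for j in range(i + 1, len(trees)):
                d = min(
                    (dist_i[v] for v in trees[j] if v in dist_i), default=None
                )
                if d is not None and (best_len is None or d < best_len):
                    best_len = d
        if best_len is None:
            raise ValueError("anchors span multiple connected components")
        candidates: list[tuple[str, ...]] = []
        for i in range(len(trees)):
            dist_i, preds_i = bfs[i]
            later = set().union(*trees[i + 1 :]) if i + 1 < len(trees) else set()
            for v in sorted(later):
                if dist_i.get(v) == best_len:
                    room = max_paths - len(candidates)
                    if room <= 0:
                        break
                    candidates.extend(
                        _enumerate_paths(v, preds_i, trees[i], room)
                    )
        path = candidates[int(rng.integers(len(candidates)))]
        new_nodes = set(path)
        merged = new_nodes.copy()
        rest: list[set[str]] = []
        for t in trees:
            if t & merged:
                merged |= t
            else:
                rest.append(t)
        trees = rest + [merged]

    nodes = frozenset(trees[0])
    edges = frozenset(iter_induced_edges(net, nodes))
    a_ec = frozenset(v for v in anchor_set if net.node_type(v) is NodeType.EC)
    a_met = anchor_set - a_ec
    return Module(nodes, edges, a_ec, frozenset(a_met), p_hat=float("nan"))


def build_modules(
    net: MetabolicNetwork,
    clusters: Iterable[AnchorCluster],
    an: AnnotatedNetwork,
    min_anchors: int = 2,
    rng: np.random.Generator | None = None,
) -> list[Module]:
    """Complete every cluster into a module and annotate it.

    ``p_hat`` is the arithmetic mean of the anchors' observed p-values; a
    module is valid when its total anchor count reaches ``min_anchors``.
    Modules are returned sorted by ascending ``p_hat`` (ties by node set)
    and numbered from 1.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    out = []
    for cluster in clusters:
        mod = steiner_complete(net, cluster, rng)
        p_hat = float(np.mean([an.p[a] for a in cluster.anchors]))
        valid = (mod.n_ec + mod.n_met) >= min_anchors
        out.append(replace(mod, p_hat=p_hat, valid=valid))
    out.sort(key=lambda m: (m.p_hat, tuple(sorted(m.nodes))))
    return [replace(m, module_id=i) for i, m in enumerate(out, start=1)]


@dataclass
class DiscoveryResult:
    """Everything produced by one end-to-end identification pass."""

    anchors: set[str]
    matrix: CoMembershipMatrix
    clusters: list[AnchorCluster]
    modules: list[Module]

    @property
    def valid_modules(self) -> list[Module]:
        return [m for m in self.modules if m.valid]


def discover_modules(
    an: AnnotatedNetwork,
    fits: Mapping[NodeType, BumFit],
    cfg: SamplingConfig,
    cut: float = 0.8,
    cut_mode: str = "distance",
    min_anchors: int = 2,
) -> DiscoveryResult:
    """Full identification pass: anchors -> M -> clusters -> modules.

    Deterministic for a fixed ``cfg.seed`` (the Steiner stage draws from a
    substream of the same master seed).
    """
    anchors = identify_anchors(an, fits)
    if not anchors:
        empty = CoMembershipMatrix([], np.zeros((0, 0)), cfg.n_iter)
        return DiscoveryResult(anchors, empty, [], [])
    M = co_membership(an, fits, cfg, targets=anchors)
    clusters = cluster_anchors(M, cut=cut, cut_mode=cut_mode)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 104729]))
    modules = build_modules(an.network, clusters, an, min_anchors=min_anchors, rng=rng)
    return DiscoveryResult(anchors, M, clusters, modules)
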