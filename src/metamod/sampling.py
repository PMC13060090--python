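"""Iterated Monte-Carlo labelling and the co-membership matrix M.

Each iteration (i) imputes a p-value for every unobserved node by sampling
from its omic's fitted mixture, (ii) labels every node disease-associated
(DA) with a probability that decreases in its p-value, and (iii) checks,
within the subgraph induced by the DA nodes only, which node pairs are
joined by a path of fewer than ``k`` edges.  Across iterations the fraction
of times each pair is both DA-labelled and so connected estimates the
probability that the two nodes belong to the same disease-associated
region.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .network import NodeType
from .scores import AnnotatedNetwork, BumFit, da_probability, sample_pvalues

__all__ = [
    "SamplingConfig",
    "CoMembershipMatrix",
    "identify_anchors",
    "sample_da_set",
    "co_membership",
]


@dataclass(frozen=True)
class SamplingConfig:
    """Knobs of the iterated sampling stage.

    ``k`` bounds path length: a pair counts as connected when a DA path of
    strictly fewer than k edges joins it.  ``mode`` selects how a p-value
    maps to a DA probability (see :func:`metamod.scores.da_probability`).
    """

    n_iter: int = 1000
    k: int = 5
    mode: str = "one_minus_p"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class CoMembershipMatrix:
    """Symmetric matrix of pairwise short-DA-path connection frequencies.

    Entry (u, v) is the fraction of iterations in which u and v were both
    DA and joined by a path of < k edges through DA nodes.  The diagonal
    holds each node's empirical DA frequency (a node is trivially connected
    to itself whenever it is DA).
    """

    node_ids: list[str]
    values: np.ndarray
    n_iter: int
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {v: i for i, v in enumerate(self.node_ids)}

    def __len__(self) -> int:
        return len(self.node_ids)

    def get(self, u: str, v: str) -> float:
        return float(self.values[self._index[u], self._index[v]])

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("node_id\t" + "\t".join(self.node_ids) + "\n")
            buf = io.StringIO()
            np.savetxt(buf, self.values, fmt="%.6g", delimiter="\t")
            for node, line in zip(self.node_ids, buf.getvalue().splitlines()):
                fh.write(f"{node}\t{line}\n")


def identify_anchors(
    an: AnnotatedNetwork, fits: Mapping[NodeType, BumFit]
) -> set[str]:
    """Observed nodes with p-value strictly below their omic's tau.

    A sentinel tau of 0 yields no anchors of that type; unobserved nodes are
    never anchors regardless of imputation.
    """
    out = set()
    for node, p in an.p.items():
        if p < fits[an.node_type(node)].tau:
            out.add(node)
    return out


class _SamplingEngine:
    """Pre-indexed arrays for fast repeated label-and-search iterations."""

    def __init__(
        self,
        an: AnnotatedNetwork,
        fits: Mapping[NodeType, BumFit] | None,
        mode: str,
    ):
        g = an.network.graph
        self.ids: list[str] = sorted(g.nodes)
        index = {v: i for i, v in enumerate(self.ids)}
        self.n = len(self.ids)
        self.adj: list[list[int]] = [
            [index[w] for w in g[v]] for v in self.ids
        ]
        self.mode = mode
        self.fits = fits

        # DA probabilities of observed nodes never change across iterations.
        self.base_prob = np.zeros(self.n)
        self.unobs_by_type: dict[NodeType, np.ndarray] = {}
        for t in NodeType:
            unobs = []
            for v in an.network.nodes_of_type(t):
                i = index[v]
                if v in an.p:
                    self.base_prob[i] = da_probability(
                        an.p[v], None if fits is None else fits[t], mode
                    )
                else:
                    unobs.append(i)
            self.unobs_by_type[t] = np.array(sorted(unobs), dtype=np.intp)
            if len(unobs) and fits is None:
                raise ValueError("unobserved nodes present: per-type fits are required")
        self.index = index

    def labels(self, rng: np.random.Generator) -> np.ndarray:
        """One iteration's DA indicator vector.

        Randomness is consumed in a fixed order (EC imputations, metabolite
        imputations, then the Bernoulli labels) so results are invariant to
        the path-length bound k.
        """
        prob = self.base_prob
        imputed = False
        for t in NodeType:
            idx = self.unobs_by_type[t]
            if idx.size:
                if not imputed:
                    prob = prob.copy()
                    imputed = True
                pv = sample_pvalues(self.fits[t], idx.size, rng)
                prob[idx] = da_probability(pv, self.fits[t], self.mode)
        return rng.random(self.n) < prob


def sample_da_set(
    an: AnnotatedNetwork,
    fits: Mapping[NodeType, BumFit] | None,
    cfg: SamplingConfig,
    rng: np.random.Generator,
) -> set[str]:
    """Draw one DA node set: impute unobserved p-values, then label each node
    DA independently with probability decreasing in its p-value."""
    eng = _SamplingEngine(an, fits, cfg.mode)
    da = eng.labels(rng)
    return {eng.ids[i] for i in np.flatnonzero(da)}


def co_membership(
    an: AnnotatedNetwork,
    fits: Mapping[NodeType, BumFit] | None,
    cfg: SamplingConfig,
    targets: Iterable[str] | str = "anchors",
) -> CoMembershipMatrix:
    """Estimate the co-membership matrix M by iterated sampling.

    ``targets`` selects the rows/columns reported: ``"anchors"`` (the
    default; requires fits), ``"all"``, or an explicit iterable of node ids.
    Connectivity itself is always evaluated on the full DA-induced subgraph,
    so restricting the output does not change any retained entry.

    Deterministic for a fixed ``cfg.seed``: one master seed spawns one
    substream per iteration.
    """
    if an.network.n_nodes == 0:
        raise ValueError("empty network")
    if isinstance(targets, str):
        if targets == "anchors":
            if fits is None:
                raise ValueError("targets='anchors' requires fits")
            target_ids = sorted(identify_anchors(an, fits))
        elif targets == "all":
            target_ids = sorted(an.network.nodes)
        else:
            raise ValueError(f"unknown targets spec {targets!r}")
    else:
        target_ids = sorted(set(targets))
        missing = set(target_ids) - an.network.nodes
        if missing:
            raise ValueError(f"target ids not in network: {sorted(missing)[:5]}")

    eng = _SamplingEngine(an, fits, cfg.mode)
    m = len(target_ids)
    values = np.zeros((m, m))
    if m == 0:
        return CoMembershipMatrix(target_ids, values, cfg.n_iter)

    t_idx = [eng.index[v] for v in target_ids]
    tpos = np.full(eng.n, -1, dtype=np.intp)
    for pos, i in enumerate(t_idx):
        tpos[i] = pos
    tpos_list = tpos.tolist()

    adj = eng.adj
    depth_budget = cfg.k - 1  # strict bound: paths of < k edges
    pair_counts = np.zeros((m, m), dtype=np.int64)
    diag_counts = np.zeros(m, dtype=np.int64)
    stamp = [0] * eng.n
    cur = 0

    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_iter)
    for child in children:
        rng = np.random.default_rng(child)
        da = eng.labels(rng).tolist()
        for pos, src in enumerate(t_idx):
            if not da[src]:
                continue
            diag_counts[pos] += 1
            # BFS through DA nodes only, up to depth_budget edges
            cur += 1
            stamp[src] = cur
            frontier = [src]
            reached: list[int] = []
            for _d in range(depth_budget):
                nxt: list[int] = []
                for x in frontier:
                    for w in adj[x]:
                        if da[w] and stamp[w] != cur:
                            stamp[w] = cur
                            nxt.append(w)
                if not nxt:
                    break
                reached.extend(nxt)
                frontier = nxt
            for w in reached:
                tp = tpos_list[w]
                if tp > pos:
                    pair_counts[pos, tp] += 1

    values = (pair_counts + pair_counts.T).astype(float)
    np.fill_diagonal(values, diag_counts)
    values /= cfg.n_iter
    return CoMembershipMatrix(target_ids, values, cfg.n_iter)
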