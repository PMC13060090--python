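"""Topology-aware permutation test for module significance.

Dense regions of the metabolic network can yield low-p-value modules by
topology alone.  Significance is therefore assessed against a null that
preserves both the network and the multiset of p-values: observed p-values
are shuffled among the observed node positions (within each node class
separately) and the whole identification procedure is rerun.  A shuffle
counts as a success for a real module with N_EC anchor ECs, N_met anchor
metabolites and mean anchor p-value p_hat when it produces at least as many
valid modules as the real run and some valid shuffled module matches or
beats all three statistics.  Because shuffling permutes values within a
node class, the per-omic mixture fit and its threshold tau are invariant
and are reused, not refitted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .modules import Module, discover_modules
from .network import NodeType
from .sampling import SamplingConfig
from .scores import AnnotatedNetwork, BumFit

__all__ = [
    "PermutationResult",
    "shuffle_scores",
    "permutation_pvalue",
    "permutation_test",
    "fdr_correct",
]


@dataclass(frozen=True)
class PermutationResult:
    """Permutation outcome for one real module."""

    module_id: int | None
    n_perm: int
    n_success: int
    p_perm: float
    q: float = float("nan")


def shuffle_scores(an: AnnotatedNetwork, rng: np.random.Generator) -> AnnotatedNetwork:
    """Permute observed p-values among observed positions, per node class.

    EC values move only among observed EC nodes and metabolite values among
    observed metabolite nodes; the observed set and each class's p-value
    multiset are preserved exactly.
    """
    new_p: dict[str, float] = {}
    for t in NodeType:
        nodes = sorted(v for v in an.p if an.node_type(v) is t)
        values = [an.p[v] for v in nodes]
        perm = rng.permutation(len(nodes))
        for node, j in zip(nodes, perm):
            new_p[node] = values[j]
    return an.with_pvalues(new_p)


def permutation_pvalue(n_success: int, n_perm: int) -> float:
    """Pseudocount estimate (r + 1) / (B + 1); never exactly zero."""
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    if not 0 <= n_success <= n_perm:
        raise ValueError("success count out of range")
    return (n_success + 1) / (n_perm + 1)


def permutation_test(
    an: AnnotatedNetwork,
    fits: Mapping[NodeType, BumFit],
    cfg: SamplingConfig,
    real_modules: Sequence[Module],
    B: int = 100,
    cut: float = 0.8,
    cut_mode: str = "distance",
    min_anchors: int = 2,
    perm_n_iter: int | None = None,
    gate: str = "global",
) -> list[PermutationResult]:
    """Permutation p-values and BH q-values for the real modules.

    Only valid real modules are tested; invalid ones receive p_perm = 1.
    ``perm_n_iter`` optionally scales down the Monte-Carlo depth of the
    per-shuffle reruns (approximate mode).  ``gate`` controls the
    at-least-as-many-valid-modules correction: ``"global"`` (default)
    requires every success's shuffle to reach the real run's valid-module
    count; ``"rank"`` requires only as many valid modules as the tested
    module's rank.  Results are invariant to shuffle order (one substream
    per shuffle from the master seed).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not real_modules:
        raise ValueError("no real modules to test")
    if gate not in ("global", "rank"):
        raise ValueError(f"unknown gate {gate!r}")

    shuffle_cfg_n = cfg.n_iter if perm_n_iter is None else perm_n_iter
    valid_real = [m for m in real_modules if m.valid]
    n_valid_real = len(valid_real)
    # rank of each valid module by ascending p_hat (1 = strongest)
    order = sorted(range(n_valid_real), key=lambda i: valid_real[i].p_hat)
    rank = {id(valid_real[i]): r + 1 for r, i in enumerate(order)}

    successes = {id(m): 0 for m in valid_real}
    master = np.random.SeedSequence([cfg.seed, 15485863])
    children = master.spawn(B)
    for child in children:
        rng = np.random.default_rng(child)
        shuffled = shuffle_scores(an, rng)
        sub_seed = int(rng.integers(2**31 - 1))
        sub_cfg = replace(cfg, seed=sub_seed, n_iter=shuffle_cfg_n)
        res = discover_modules(
            shuffled, fits, sub_cfg, cut=cut, cut_mode=cut_mode, min_anchors=min_anchors
        )
        shuffle_valid = res.valid_modules
        n_valid_shuffle = len(shuffle_valid)
        stats = [(m.n_ec, m.n_met, m.p_hat) for m in shuffle_valid]
        for m in valid_real:
            need = n_valid_real if gate == "global" else rank[id(m)]
            if n_valid_shuffle < need:
                continue
            if any(
                ne >= m.n_ec and nm >= m.n_met and ph <= m.p_hat
                for ne, nm, ph in stats
            ):
                successes[id(m)] += 1

    results = []
    for m in real_modules:
        if m.valid:
            p = permutation_pvalue(successes[id(m)], B)
            results.append(PermutationResult(m.module_id, B, successes[id(m)], p))
        else:
            results.append(PermutationResult(m.module_id, B, B, 1.0))
    # BH over the tested (valid) modules only; untested singletons keep q = 1
    tested = [i for i, m in enumerate(real_modules) if m.valid]
    qs = [1.0] * len(results)
    for i, q in zip(tested, fdr_correct([results[i].p_perm for i in tested])):
        qs[i] = q
    return [replace(r, q=q) for r, q in zip(results, qs)]


def fdr_correct(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])
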