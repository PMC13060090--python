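"""Pathway over-representation baselines and module-pathway comparison.

These are the conventional analyses the module discovery is compared
against: Fisher's exact (hypergeometric upper-tail) over-representation of
significant features in predefined pathways, and per-module overlap tests
asking whether a discovered module concentrates in, or crosses, canonical
pathway boundaries.  A module "mostly contained" in a pathway has more than
80% of its nodes inside it.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from scipy.stats import hypergeom

from .modules import Module
from .significance import fdr_correct

__all__ = [
    "PathwayDB",
    "read_pathway_table",
    "ora",
    "module_pathway_overlap",
]

CONTAINMENT_CUTOFF = 0.8
OVERLAP_FDR = 0.05


@dataclass(frozen=True)
class PathwayDB:
    """Pathway membership sets over a feature universe."""

    pathways: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for pid, members in self.pathways.items():
            if not members <= self.universe:
                raise ValueError(f"pathway {pid!r} has members outside the universe")

    @classmethod
    def from_memberships(cls, pathways: dict[str, Iterable[str]]) -> "PathwayDB":
        sets = {pid: frozenset(m) for pid, m in pathways.items()}
        universe = frozenset().union(*sets.values()) if sets else frozenset()
        return cls(sets, universe)


def read_pathway_table(path: str) -> PathwayDB:
    """Read a TSV with header ``pathway_id\tnode_id``, one membership per row."""
    memberships: dict[str, set[str]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = [h.strip() for h in next(reader)]
        if header[:2] != ["pathway_id", "node_id"]:
            raise ValueError(f"{path}: expected header pathway_id/node_id")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2 or not row[0].strip() or not row[1].strip():
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            memberships.setdefault(row[0].strip(), set()).add(row[1].strip())
    return PathwayDB.from_memberships(memberships)


def hypergeom_upper_tail(n_overlap: int, n_in: int, n_sel: int, n_bg: int) -> float:
    """P(X >= n_overlap) for X ~ Hypergeom(n_bg, n_in, n_sel).

    The one-sided Fisher's exact p-value of the 2x2 table
    (in-set x selected) under over-representation.
    """
    if not (0 <= n_in <= n_bg and 0 <= n_sel <= n_bg):
        raise ValueError("inconsistent margins")
    if not 0 <= n_overlap <= min(n_in, n_sel):
        raise ValueError("overlap exceeds a margin")
    return float(hypergeom.sf(n_overlap - 1, n_bg, n_in, n_sel))


def ora(
    significant: Iterable[str],
    background: Iterable[str],
    db: PathwayDB,
) -> pd.DataFrame:
    """Per-pathway over-representation of significant features.

    The test is restricted to ``background``: pathway sets are intersected
    with it before the hypergeometric upper-tail test.  Returns one row per
    pathway with counts, p, and BH q.
    """
    significant = set(significant)
    background = set(background)
    if not background:
        raise ValueError("empty background")
    if not significant <= background:
        raise ValueError("significant features must be a subset of the background")
    rows = []
    n_bg = len(background)
    n_sig = len(significant)
    for pid in sorted(db.pathways):
        members = db.pathways[pid] & background
        n_in = len(members)
        n_sig_in = len(members & significant)
        p = hypergeom_upper_tail(n_sig_in, n_in, n_sig, n_bg)
        rows.append((pid, n_sig_in, n_in, n_sig, n_bg, p))
    df = pd.DataFrame(rows, columns=["pathway_id", "n_sig_in", "n_in", "n_sig", "n_bg", "p"])
    df["q"] = fdr_correct(df["p"].tolist()) if len(df) else []
    return df


def module_pathway_overlap(
    module: Module,
    db: PathwayDB,
    universe: Iterable[str],
    two_sided: bool = False,
) -> pd.DataFrame:
    """Fisher's exact overlap of one module with each pathway.

    Evaluated over ``universe`` (typically all network nodes annotated to at
    least one pathway); module nodes outside the universe are dropped with a
    count.  ``containment`` is the fraction of (retained) module nodes
    inside the pathway; ``mostly_contained`` flags containment > 0.8.
    ``significant`` marks overlaps at q < 0.05.  The default test is
    one-sided (over-representation); ``two_sided`` switches to the
    two-sided Fisher p.
    """
    if not module.nodes:
        raise ValueError("empty module")
    universe = set(universe)
    mod = set(module.nodes) & universe
    n_dropped = len(module.nodes) - len(mod)
    if not mod:
        raise ValueError("no module nodes in the universe")
    n_bg = len(universe)
    rows = []
    for pid in sorted(db.pathways):
        members = db.pathways[pid] & universe
        n_in = len(members)
        overlap = len(members & mod)
        if two_sided:
            from scipy.stats import fisher_exact

            table = [
                [overlap, len(mod) - overlap],
                [n_in - overlap, n_bg - len(mod) - n_in + overlap],
            ]
            p = float(fisher_exact(table, alternative="two-sided")[1])
        else:
            p = hypergeom_upper_tail(overlap, n_in, len(mod), n_bg)
        containment = overlap / len(mod)
        rows.append((pid, overlap, n_in, p, containment))
    df = pd.DataFrame(rows, columns=["pathway_id", "n_overlap", "n_in", "p", "containment"])
    df["q"] = fdr_correct(df["p"].tolist()) if len(df) else []
    df["mostly_contained"] = df["containment"] > CONTAINMENT_CUTOFF
    df["significant"] = df["q"] < OVERLAP_FDR
    df.attrs["n_dropped"] = n_dropped
    return df
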