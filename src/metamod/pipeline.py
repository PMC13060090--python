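"""End-to-end pipeline: read inputs, discover modules, test significance,
write tabular outputs and a reproducibility manifest."""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import module_pathway_overlap, ora, read_pathway_table
from .modules import DiscoveryResult, discover_modules
from .network import NodeType, filter_currency_metabolites, read_edge_list
from .sampling import SamplingConfig
from .scores import BumFit, fit_bum, project_scores, read_score_table
from .significance import PermutationResult, permutation_test

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)

MODULE_FDR = 0.1  # modules with q below this are reported significant


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and input context."""


@dataclass
class RunConfig:
    """Serializable configuration of one full run."""

    network: str = ""
    ec_scores: str = ""
    met_scores: str = ""
    outdir: str = "metamod_out"
    pathways: str | None = None
    fdr_level: float = 0.1
    k: int = 5
    n_iter: int = 1000
    cut: float = 0.8
    cut_mode: str = "distance"
    min_anchors: int = 2
    B: int = 100
    perm_n_iter: int | None = None
    mode: str = "one_minus_p"
    currency_max_degree: int | None = None
    currency_list: list[str] = field(default_factory=list)
    write_matrix: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def sampling(self) -> SamplingConfig:
        return SamplingConfig(n_iter=self.n_iter, k=self.k, mode=self.mode, seed=self.seed)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(f"stage {name!r}: {exc}") from exc

        return wrapper

    return deco


def _write_fit_report(path: Path, fits: dict[NodeType, BumFit], an) -> None:
    lines = []
    for t, fit in fits.items():
        lines += [
            f"[{t.value}]",
            f"  n_pvalues   = {fit.n}",
            f"  a_hat       = {fit.a:.6g}",
            f"  lambda_hat  = {fit.lam:.6g}",
            f"  tau (FDR={fit.fdr_level:g}) = {fit.tau:.6g}",
            f"  loglik      = {fit.loglik:.6g}",
            f"  boundary    = {fit.boundary}",
            f"  coverage    = {an.coverage.get(t, 0.0):.4f}",
            "",
        ]
    path.write_text("\n".join(lines))


def _module_tables(
    res: DiscoveryResult, perm: list[PermutationResult] | None, an
) -> tuple[pd.DataFrame, pd.DataFrame]:
    node_rows, summary_rows = [], []
    perm_by_id = {r.module_id: r for r in perm} if perm else {}
    for mod in res.modules:
        for node in sorted(mod.nodes):
            node_rows.append(
                (
                    mod.module_id,
                    node,
                    an.node_type(node).value,
                    node in mod.anchors,
                    an.p.get(node, float("nan")),
                )
            )
        r = perm_by_id.get(mod.module_id)
        summary_rows.append(
            (
                mod.module_id,
                mod.n_ec,
                mod.n_met,
                len(mod.nodes),
                f"{mod.p_hat:.6g}",
                mod.valid,
                f"{r.p_perm:.6g}" if r else "",
                f"{r.q:.6g}" if r else "",
                bool(r and r.q < MODULE_FDR and mod.valid),
            )
        )
    nodes_df = pd.DataFrame(
        node_rows, columns=["module_id", "node_id", "node_type", "is_anchor", "p_value"]
    )
    summary_df = pd.DataFrame(
        summary_rows,
        columns=["module_id", "n_ec", "n_met", "n_nodes", "p_hat", "valid", "p_perm", "q", "significant"],
    )
    return nodes_df, summary_df


@_stage("pipeline")
def run_pipeline(cfg: RunConfig) -> pd.DataFrame:
    """Run every stage and write results under ``cfg.outdir``.

    Outputs: ``manifest.json`` (config + versions), ``fit_report.txt``,
    ``anchors.tsv``, ``modules_nodes.tsv``, ``modules_summary.tsv``,
    optionally ``comembership.tsv`` and per-module enrichment tables.
    Returns the summary table.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    try:
        net = read_edge_list(cfg.network)
    except OSError as exc:
        raise PipelineError(f"stage 'read network': cannot read {cfg.network!r}: {exc}") from exc
    if cfg.currency_max_degree is not None and cfg.currency_list:
        raise PipelineError("stage 'currency filter': give max_degree or a list, not both")
    if cfg.currency_max_degree is not None:
        net = filter_currency_metabolites(net, max_degree=cfg.currency_max_degree).network
    elif cfg.currency_list:
        net = filter_currency_metabolites(net, explicit_list=cfg.currency_list).network

    try:
        ec_scores = read_score_table(cfg.ec_scores)
        met_scores = read_score_table(cfg.met_scores)
    except OSError as exc:
        raise PipelineError(f"stage 'read scores': {exc}") from exc

    an = project_scores(net, ec_scores, met_scores)
    logger.info(
        "coverage: EC %.3f, metabolite %.3f (%d dropped)",
        an.coverage[NodeType.EC],
        an.coverage[NodeType.METABOLITE],
        an.n_dropped,
    )

    fits: dict[NodeType, BumFit] = {}
    for t, table in ((NodeType.EC, ec_scores), (NodeType.METABOLITE, met_scores)):
        pv = [an.p[v] for v in an.p if an.node_type(v) is t]
        if len(pv) < 20:
            raise PipelineError(
                f"stage 'fit bum': only {len(pv)} observed {t.value} p-values (need >= 20)"
            )
        fits[t] = fit_bum(pv, fdr_level=cfg.fdr_level)
    _write_fit_report(outdir / "fit_report.txt", fits, an)

    scfg = cfg.sampling()
    res = discover_modules(
        an, fits, scfg, cut=cfg.cut, cut_mode=cfg.cut_mode, min_anchors=cfg.min_anchors
    )
    with open(outdir / "anchors.tsv", "w") as fh:
        fh.write("node_id\tnode_type\tp_value\n")
        for v in sorted(res.anchors):
            fh.write(f"{v}\t{an.node_type(v).value}\t{an.p[v]:.6g}\n")
    if cfg.write_matrix and len(res.matrix):
        res.matrix.to_tsv(str(outdir / "comembership.tsv"))

    perm = None
    if res.modules:
        logger.info("testing %d modules with %d permutations", len(res.modules), cfg.B)
        perm = permutation_test(
            an,
            fits,
            scfg,
            res.modules,
            B=cfg.B,
            cut=cfg.cut,
            cut_mode=cfg.cut_mode,
            min_anchors=cfg.min_anchors,
            perm_n_iter=cfg.perm_n_iter,
        )
    nodes_df, summary_df = _module_tables(res, perm, an)
    nodes_df.to_csv(outdir / "modules_nodes.tsv", sep="\t", index=False)
    summary_df.to_csv(outdir / "modules_summary.tsv", sep="\t", index=False)

    if cfg.pathways:
        db = read_pathway_table(cfg.pathways)
        universe = net.nodes & db.universe
        sig = {
            v
            for v in an.p
            if an.p[v] < fits[an.node_type(v)].tau
        }
        ora_df = ora(sig & an.observed, an.observed, db)
        ora_df.to_csv(outdir / "ora.tsv", sep="\t", index=False)
        overlap_rows = []
        for mod in res.modules:
            if not (set(mod.nodes) & universe):
                continue
            df = module_pathway_overlap(mod, db, universe)
            df.insert(0, "module_id", mod.module_id)
            overlap_rows.append(df)
        if overlap_rows:
            pd.concat(overlap_rows).to_csv(
                outdir / "module_pathway_overlap.tsv", sep="\t", index=False
            )

    manifest = {
        "config": cfg.to_dict(),
        "versions": {
            "metamod": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "n_anchors": len(res.anchors),
        "n_modules": len(res.modules),
        "n_significant": int(summary_df["significant"].sum()) if len(summary_df) else 0,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return summary_df
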