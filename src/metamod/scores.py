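"""Per-omic p-value ingestion, projection onto the network, and the
beta-uniform mixture (BUM) model.

P-values from independent differential-abundance analyses of each omic
(metagenomic ECs, metabolomic compounds) are modelled as a mixture of a
Uniform(0,1) noise component, with weight ``lam``, and a Beta(a, 1) signal
component with shape ``a`` in (0,1):

    f(x | a, lam) = lam + (1 - lam) * a * x**(a - 1)

The fitted mixture yields (i) an FDR-controlled p-value threshold ``tau``
that defines the "anchor" nodes around which modules are built, and (ii) a
sampling distribution used to impute p-values for unobserved network nodes.
The fit is done per omic: nothing couples the EC and metabolite mixtures.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .network import MetabolicNetwork, NodeType

__all__ = [
    "ScoreTable",
    "AnnotatedNetwork",
    "BumFit",
    "read_score_table",
    "project_scores",
    "fit_bum",
    "fdr_threshold",
    "sample_pvalues",
    "da_probability",
]

logger = logging.getLogger(__name__)

P_FLOOR = 1e-10  # exact zeros are clamped here: the Beta(a,1) density diverges at 0
_BOUND = 1e-6  # parameter box (a, lam) in [_BOUND, 1 - _BOUND]


# ---------------------------------------------------------------------------
# Score tables and projection
# ---------------------------------------------------------------------------


@dataclass
class ScoreTable:
    """One p-value per feature id, with its node class.

    ``n_clamped`` counts input p-values at or below zero that were raised to
    the floor.
    """

    entries: dict[str, tuple[NodeType, float]]
    n_clamped: int = 0

    def __post_init__(self) -> None:
        for node, (_t, p) in self.entries.items():
            if not (0.0 < p <= 1.0):
                raise ValueError(f"p-value for {node!r} outside (0, 1]: {p}")

    @classmethod
    def from_pairs(
        cls,
        pairs: dict[str, float] | list[tuple[str, float]],
        node_type: NodeType,
        p_floor: float = P_FLOOR,
    ) -> "ScoreTable":
        items = pairs.items() if isinstance(pairs, dict) else pairs
        entries: dict[str, tuple[NodeType, float]] = {}
        clamped = 0
        for node, p in items:
            if p <= 0.0:
                p = p_floor
                clamped += 1
            entries[node.strip()] = (node_type, float(p))
        return cls(entries, n_clamped=clamped)

    def __len__(self) -> int:
        return len(self.entries)

    def pvalues(self) -> np.ndarray:
        return np.array([p for _t, p in self.entries.values()], dtype=float)


def read_score_table(path: str, p_floor: float = P_FLOOR) -> ScoreTable:
    """Read a TSV with header ``node_id  node_type  p_value``.

    Node types must be ``EC`` or ``METABOLITE``.  Exact zeros are clamped to
    ``p_floor`` and logged; duplicated ids are an error.
    """
    entries: dict[str, tuple[NodeType, float]] = {}
    clamped = 0
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = [h.strip() for h in next(reader)]
        if header[:3] != ["node_id", "node_type", "p_value"]:
            raise ValueError(f"{path}: expected header node_id/node_type/p_value")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns")
            node = row[0].strip()
            try:
                t = NodeType(row[1].strip())
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: unknown node_type {row[1]!r}"
                ) from None
            p = float(row[2])
            if p <= 0.0:
                p = p_floor
                clamped += 1
            if not p <= 1.0:
                raise ValueError(f"{path}: line {lineno}: p-value {p} > 1")
            if node in entries:
                raise ValueError(f"{path}: line {lineno}: duplicate id {node!r}")
            entries[node] = (t, p)
    if clamped:
        logger.warning("%s: clamped %d nonpositive p-values to %g", path, clamped, p_floor)
    return ScoreTable(entries, n_clamped=clamped)


@dataclass
class AnnotatedNetwork:
    """The network with p-values attached to its observed nodes.

    ``p`` maps observed node ids to their p-value; every other network node
    is "unobserved" and will receive imputed p-values during sampling.
    Score-table ids absent from the network are dropped (``n_dropped``),
    never silently merged.
    """

    network: MetabolicNetwork
    p: dict[str, float]
    coverage: dict[NodeType, float] = field(default_factory=dict)
    n_dropped: int = 0

    @property
    def observed(self) -> set[str]:
        return set(self.p)

    def node_type(self, node: str) -> NodeType:
        return self.network.node_type(node)

    def with_pvalues(self, p: dict[str, float]) -> "AnnotatedNetwork":
        return replace(self, p=dict(p))


def project_scores(
    net: MetabolicNetwork,
    ec_scores: ScoreTable,
    met_scores: ScoreTable,
) -> AnnotatedNetwork:
    """Attach each score-table p-value to its network node.

    Ids present in both tables with conflicting types raise; ids absent from
    the network are dropped and counted.  Per-class coverage (observed /
    total) is reported on the result.
    """
    for node, (t, _p) in ec_scores.entries.items():
        if node in met_scores.entries and met_scores.entries[node][0] is not t:
            raise ValueError(f"id {node!r} appears in both tables with conflicting types")

    p: dict[str, float] = {}
    dropped = 0
    for table, expect in ((ec_scores, NodeType.EC), (met_scores, NodeType.METABOLITE)):
        for node, (t, pv) in table.entries.items():
            if t is not expect:
                raise ValueError(
                    f"{expect.value} score table contains {t.value} entry {node!r}"
                )
            if node not in net.graph:
                dropped += 1
                continue
            if net.node_type(node) is not t:
                raise ValueError(
                    f"id {node!r} typed {t.value} in scores but "
                    f"{net.node_type(node).value} in the network"
                )
            p[node] = pv

    coverage: dict[NodeType, float] = {}
    for t in NodeType:
        total = len(net.nodes_of_type(t))
        obs = sum(1 for v in p if net.node_type(v) is t)
        coverage[t] = obs / total if total else 0.0
    if dropped:
        logger.info("project_scores: dropped %d score ids absent from the network", dropped)
    return AnnotatedNetwork(net, p, coverage=coverage, n_dropped=dropped)


# ---------------------------------------------------------------------------
# Beta-uniform mixture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BumFit:
    """Maximum-likelihood beta-uniform mixture fit for one omic.

    ``tau`` is the p-value threshold at which the Pounds-Morris estimate of
    the false discovery rate among {p < tau} equals ``fdr_level``; ``tau == 0``
    is a sentinel meaning no threshold attains the requested FDR (no anchors
    for this omic).  ``boundary`` flags estimates clipped at the parameter
    box, where the mixture is effectively degenerate.
    """

    a: float
    lam: float
    tau: float
    loglik: float
    n: int
    fdr_level: float = 0.1
    boundary: bool = False

    @property
    def pi_upper(self) -> float:
        """Upper bound on the noise proportion: f evaluated at x = 1."""
        return self.lam + (1.0 - self.lam) * self.a

    def density(self, x: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        return self.lam + (1.0 - self.lam) * self.a * np.power(x, self.a - 1.0)

    def cdf(self, x: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        return self.lam * x + (1.0 - self.lam) * np.power(x, self.a)


def _negloglik(params: np.ndarray, logp: np.ndarray) -> float:
    a, lam = params
    dens = lam + (1.0 - lam) * a * np.exp((a - 1.0) * logp)
    return -float(np.sum(np.log(dens)))


_STARTS = [(0.5, 0.5), (0.1, 0.9), (0.9, 0.1), (0.3, 0.3), (0.05, 0.5)]


def fit_bum(
    pvalues,
    min_n: int = 20,
    fdr_level: float = 0.1,
    p_floor: float = P_FLOOR,
) -> BumFit:
    """Fit the mixture by maximum likelihood over (a, lam) in (0,1)^2.

    Uses bounded quasi-Newton (L-BFGS-B) from several fixed starts; the
    likelihood surface can be bimodal near the boundaries, so a single start
    is not trusted.  Estimates landing on the box are clipped and flagged.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size < min_n:
        raise ValueError(f"need at least {min_n} p-values, got {p.size}")
    if np.any(p <= 0.0):
        p = np.where(p <= 0.0, p_floor, p)
        logger.warning("fit_bum: clamped nonpositive p-values to %g", p_floor)
    if np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")

    if np.ptp(p) == 0.0:
        warnings.warn("all p-values identical: degenerate fit, forcing lam toward 1")
        a, lam = 0.5, 1.0 - _BOUND
        ll = -_negloglik(np.array([a, lam]), np.log(p))
        tau = fdr_threshold_params(a, lam, fdr_level, p_floor=p_floor)
        return BumFit(a, lam, tau, ll, int(p.size), fdr_level, boundary=True)

    logp = np.log(p)
    bounds = [(_BOUND, 1.0 - _BOUND)] * 2
    best = None
    for start in _STARTS:
        res = optimize.minimize(
            _negloglik, np.array(start), args=(logp,), method="L-BFGS-B", bounds=bounds
        )
        if best is None or res.fun < best.fun:
            best = res
    a, lam = (float(np.clip(v, _BOUND, 1.0 - _BOUND)) for v in best.x)
    boundary = a <= _BOUND or a >= 1.0 - _BOUND or lam <= _BOUND or lam >= 1.0 - _BOUND
    if boundary:
        logger.warning("fit_bum: estimate on parameter boundary (a=%.3g, lam=%.3g)", a, lam)
    tau = fdr_threshold_params(a, lam, fdr_level, p_floor=p_floor)
    return BumFit(a, lam, tau, -float(best.fun), int(p.size), fdr_level, boundary=boundary)


def _fdr_curve(t: float, a: float, lam: float) -> float:
    """Pounds-Morris FDR estimate among p-values below t."""
    pi_ub = lam + (1.0 - lam) * a
    cdf = lam * t + (1.0 - lam) * t**a
    return pi_ub * t / cdf


def fdr_threshold_params(
    a: float,
    lam: float,
    fdr: float,
    p_floor: float = P_FLOOR,
    verify_tol: float = 1e-9,
) -> float:
    """Closed-form p-value threshold tau with estimated FDR equal to ``fdr``.

    Solves pi_ub * t / F(t) = fdr for t, where pi_ub = lam + (1-lam)*a
    bounds the noise proportion and F is the mixture CDF:

        tau = ((pi_ub - fdr * lam) / (fdr * (1 - lam))) ** (1 / (a - 1))

    The closed form is cross-checked against a numeric root of the FDR
    identity to ``verify_tol``.  Returns the sentinel 0.0 (with a warning)
    when no threshold in (p_floor, 1) attains the requested FDR -- either
    the signal is too weak (tau collapses below the p-value floor) or the
    estimated noise proportion is already below ``fdr``.
    """
    if not (0.0 < fdr < 1.0):
        raise ValueError("fdr must be in (0, 1)")
    pi_ub = lam + (1.0 - lam) * a
    base = (pi_ub - fdr * lam) / (fdr * (1.0 - lam))
    if base <= 1.0:
        # FDR(t) < fdr for every t in (0,1): the identity has no interior root.
        warnings.warn(
            f"no p-value threshold attains FDR={fdr} (pi_ub={pi_ub:.3g}); "
            "returning sentinel 0"
        )
        return 0.0
    tau = base ** (1.0 / (a - 1.0))
    if not np.isfinite(tau) or tau <= p_floor:
        warnings.warn(
            f"FDR={fdr} threshold {tau:.3g} below the p-value floor; returning sentinel 0"
        )
        return 0.0
    # independent numeric root of the same identity
    f = lambda t: _fdr_curve(t, a, lam) - fdr  # noqa: E731
    lo, hi = p_floor / 10.0, 1.0 - 1e-15
    if f(lo) < 0.0 < f(hi):
        root = optimize.brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16)
        if abs(root - tau) > verify_tol:
            raise AssertionError(
                f"closed-form tau {tau!r} disagrees with numeric root {root!r}"
            )
    return float(tau)


def fdr_threshold(fit: BumFit, fdr: float) -> float:
    """Threshold tau at which the estimated FDR among {p < tau} equals ``fdr``."""
    return fdr_threshold_params(fit.a, fit.lam, fdr)


def sample_pvalues(fit: BumFit, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n i.i.d. p-values from the fitted mixture.

    With probability ``lam`` a draw is Uniform(0,1); otherwise it is
    U**(1/a), the inverse-CDF transform of Beta(a, 1).
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    if n == 0:
        return np.empty(0)
    out = rng.random(n)
    signal = rng.random(n) >= fit.lam
    k = int(signal.sum())
    if k:
        out[signal] = rng.random(k) ** (1.0 / fit.a)
    np.clip(out, P_FLOOR, 1.0, out=out)
    return out


def da_probability(
    p: np.ndarray | float,
    fit: BumFit | None = None,
    mode: str = "one_minus_p",
) -> np.ndarray | float:
    """Probability that a node with p-value ``p`` is disease-associated.

    ``bum_posterior`` is the posterior probability of the signal component
    under the fitted mixture,

        (1 - lam) * a * p**(a-1) / (lam + (1 - lam) * a * p**(a-1)),

    and ``one_minus_p`` is the literal 1 - p.  Both are non-increasing in p.
    """
    arr = np.asarray(p, dtype=float)
    if mode == "one_minus_p":
        out = 1.0 - arr
    elif mode == "bum_posterior":
        if fit is None:
            raise ValueError("bum_posterior mode requires a fit")
        signal = (1.0 - fit.lam) * fit.a * np.power(arr, fit.a - 1.0)
        out = signal / (fit.lam + signal)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = np.clip(out, 0.0, 1.0)
    return float(out) if np.isscalar(p) or np.ndim(p) == 0 else out
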