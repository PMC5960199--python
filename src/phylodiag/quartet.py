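"""Exact likelihoods and branch-length optimization for unrooted 4-taxon
trees via Felsenstein pruning.

A quartet has five branches: one per leaf plus the internal branch joining
the two cherries.  For a resolved topology grouping leaves (i,j) against
(k,l) the site likelihood is

    L(site) = sum_x pi_x * L_i(x) L_j(x) * sum_y P_int(x,y) L_k(y) L_l(y)

averaged over discrete-gamma rate categories with equal weights.  Branch
lengths are shared across partitions; per-partition models contribute
additively to the log-likelihood.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .core import Alignment
from .models import SubstitutionModel

#: Leaf pairings for the three resolved topologies, in the fixed input
#: order of the four taxa: T1 = (1,2 | 3,4), T2 = (1,3 | 2,4),
#: T3 = (1,4 | 2,3).
TOPOLOGY_SPLITS = {
    "T1": ((0, 1), (2, 3)),
    "T2": ((0, 2), (1, 3)),
    "T3": ((0, 3), (1, 2)),
}
TOPOLOGIES = ("T1", "T2", "T3")

BL_MIN = 1e-8
BL_MAX = 10.0
_LOG_FLOOR = 1e-300


@dataclass
class QuartetData:
    """Site patterns of four sequences, compressed per partition.

    Each partition entry holds integer state codes (4, n_patterns), the
    pattern multiplicities, and the partition's substitution model.
    Columns where any of the four taxa is missing are excluded.
    """

    taxa: tuple
    partitions: list  # of (codes 4 x npat, weights npat, SubstitutionModel)
    n_sites_used: int

    @classmethod
    def from_alignment(cls, aln: Alignment, taxa, scheme_partitions, models) -> "QuartetData":
        """``scheme_partitions``: iterable of (name, column array);
        ``models``: mapping partition name -> SubstitutionModel."""
        sub = aln.take_taxa(list(taxa))
        codes = sub.encode()
        parts = []
        used = 0
        for name, cols in scheme_partitions:
            c = codes[:, np.asarray(cols, dtype=int)]
            keep = (c >= 0).all(axis=0)
            c = c[:, keep]
            if c.shape[1] == 0:
                continue
            pats, weights = np.unique(c, axis=1, return_counts=True)
            parts.append((pats, weights.astype(float), models[name]))
            used += int(keep.sum())
        return cls(taxa=tuple(taxa), partitions=parts, n_sites_used=used)

    @property
    def is_determined(self) -> bool:
        return self.n_sites_used > 0


@dataclass
class QuartetResult:
    taxa: tuple
    lnL: dict  # topology label -> optimized log-likelihood
    weights: tuple  # (p1, p2, p3)
    n_sites_used: int
    branch_lengths: dict = field(default_factory=dict)
    converged: bool = True


def _tip_partials(P: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """(npat, k) conditional likelihoods of a leaf under parent states."""
    out = P.T[np.maximum(codes, 0)]
    out[codes < 0] = 1.0
    return out


def quartet_loglik(qdata: QuartetData, topology: str, branch_lengths) -> float:
    """Log-likelihood of one resolved topology at the given branch lengths
    ``(b1, b2, b3, b4, b_internal)`` (leaf order = qdata.taxa order)."""
    (i, j), (k, l) = TOPOLOGY_SPLITS[topology]
    b = np.asarray(branch_lengths, dtype=float)
    if b.size != 5:
        raise ValueError("a quartet has exactly five branch lengths")
    if (b < 0).any():
        raise ValueError("branch lengths must be non-negative")
    total = 0.0
    for pats, weights, model in qdata.partitions:
        site_like = np.zeros(pats.shape[1])
        C = model.n_categories
        for rate in model.category_rates:
            Li = _tip_partials(model.transition_matrix(b[i], rate), pats[i])
            Lj = _tip_partials(model.transition_matrix(b[j], rate), pats[j])
            Lk = _tip_partials(model.transition_matrix(b[k], rate), pats[k])
            Ll = _tip_partials(model.transition_matrix(b[l], rate), pats[l])
            P5 = model.transition_matrix(b[4], rate)
            inner = (Lk * Ll) @ P5.T  # (npat, k): sum_y P(x,y) Lk Ll
            site_like += (Li * Lj * inner) @ model.frequencies / C
        total += float(weights @ np.log(np.maximum(site_like, _LOG_FLOOR)))
    return total


class _TopologyEvaluator:
    """Incremental likelihood evaluation for one topology.

    Caches per-partition, per-category tip partials and the internal-branch
    transition matrix so that changing a single branch length only
    recomputes the affected component — the workhorse of the coordinate
    search.
    """

    def __init__(self, qdata: QuartetData, topology: str, b: np.ndarray):
        self.qdata = qdata
        (self.i, self.j), (self.k, self.l) = TOPOLOGY_SPLITS[topology]
        self.b = np.asarray(b, dtype=float).copy()
        self._rebuild()

    def _rebuild(self):
        self.cache = []
        for pats, weights, model in self.qdata.partitions:
            per_cat = []
            for rate in model.category_rates:
                L = [_tip_partials(model.transition_matrix(self.b[m], rate), pats[m])
                     for m in range(4)]
                P5 = model.transition_matrix(self.b[4], rate)
                per_cat.append({"L": L, "P5": P5})
            self.cache.append(per_cat)

    def loglik(self, edge: int | None = None, x: float | None = None) -> float:
        """Log-likelihood at the cached lengths, optionally with ``edge``
        set to ``x`` (cache untouched)."""
        i, j, k, l = self.i, self.j, self.k, self.l
        total = 0.0
        for (pats, weights, model), per_cat in zip(self.qdata.partitions, self.cache):
            site_like = np.zeros(pats.shape[1])
            for rate, cc in zip(model.category_rates, per_cat):
                L = cc["L"]
                P5 = cc["P5"]
                Li, Lj, Lk, Ll = L[i], L[j], L[k], L[l]
                if edge is not None:
                    if edge == 4:
                        P5 = model.transition_matrix(x, rate)
                    else:
                        newL = _tip_partials(model.transition_matrix(x, rate), pats[edge])
                        if edge == i:
                            Li = newL
                        elif edge == j:
                            Lj = newL
                        elif edge == k:
                            Lk = newL
                        else:
                            Ll = newL
                inner = (Lk * Ll) @ P5.T
                site_like += (Li * Lj * inner) @ model.frequencies / model.n_categories
            total += float(weights @ np.log(np.maximum(site_like, _LOG_FLOOR)))
        return total

    def set_edge(self, edge: int, x: float):
        self.b[edge] = x
        for (pats, _, model), per_cat in zip(self.qdata.partitions, self.cache):
            for rate, cc in zip(model.category_rates, per_cat):
                if edge == 4:
                    cc["P5"] = model.transition_matrix(x, rate)
                else:
                    cc["L"][edge] = _tip_partials(model.transition_matrix(x, rate),
                                                  pats[edge])


def optimize_quartet(qdata: QuartetData, topology: str,
                     init: float = 0.1, tol: float = 1e-6,
                     max_rounds: int = 100):
    """Coordinate-wise branch-length optimization (bounded Brent per
    branch, round-robin) until the log-likelihood improves by less than
    ``tol`` or ``max_rounds`` rounds elapse.

    Returns ``(lnL, branch_lengths, converged)``; deterministic for fixed
    input.
    """
    if not qdata.is_determined:
        raise ValueError("quartet has no usable sites (undetermined)")
    b = np.full(5, init)
    ev = _TopologyEvaluator(qdata, topology, b)
    best = ev.loglik()
    converged = False
    for _ in range(max_rounds):
        previous = best
        for edge in range(5):
            res = minimize_scalar(lambda x: -ev.loglik(edge, x),
                                  bounds=(BL_MIN, BL_MAX), method="bounded",
                                  options={"xatol": 1e-6})
            if -res.fun > best:
                best = -res.fun
                b[edge] = res.x
                ev.set_edge(edge, res.x)
        if best - previous < tol:
            converged = True
            break
    return best, b.copy(), converged


def topology_weights(lnl1: float, lnl2: float, lnl3: float) -> tuple:
    """Normalized likelihood weights (p1, p2, p3) of the three topologies."""
    lnl = np.array([lnl1, lnl2, lnl3], dtype=float)
    if not np.isfinite(lnl).all():
        raise ValueError(f"non-finite log-likelihoods: {lnl}")
    w = np.exp(lnl - logsumexp(lnl))
    w /= w.sum()
    return tuple(float(x) for x in w)


def evaluate_quartet(qdata: QuartetData, **opt_kwargs) -> QuartetResult:
    """Optimize all three topologies and convert to likelihood weights."""
    lnls, bls, conv = {}, {}, True
    for topo in TOPOLOGIES:
        lnl, b, ok = optimize_quartet(qdata, topo, **opt_kwargs)
        lnls[topo] = lnl
        bls[topo] = b
        conv = conv and ok
    w = topology_weights(lnls["T1"], lnls["T2"], lnls["T3"])
    return QuartetResult(taxa=qdata.taxa, lnL=lnls, weights=w,
                         n_sites_used=qdata.n_sites_used,
                         branch_lengths=bls, converged=conv)
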