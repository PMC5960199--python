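"""Four-cluster likelihood mapping (FcLM).

Given four disjoint taxon groups, every quartet drawing one taxon per group
is evaluated under the three resolved topologies; the normalized likelihood
weights place each quartet in a 2-simplex whose corners correspond to
T1 = (g1,g2 | g3,g4), T2 = (g1,g3 | g2,g4) and T3 = (g1,g4 | g2,g3).
Quartets are tallied over seven simplex regions: three corners (one
topology clearly favoured), three edges (two topologies tied) and the
center (star-like signal).
"""
from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .core import Alignment, PartitionScheme, TaxonGroupConfig
from .models import SubstitutionModel, gtr, lg, lg_frequencies
from .quartet import QuartetData, evaluate_quartet, optimize_quartet, quartet_loglik

REGIONS = ("C1", "C2", "C3", "E12", "E13", "E23", "center")

#: Equilateral-triangle embedding of the weight simplex.
TRIANGLE_VERTICES = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3.0) / 2.0]])

#: Canonical likelihood-mapping region boundaries: a corner claims a
#: quartet when its weight exceeds 2/3; otherwise an edge claims it when
#: the smallest weight falls below 1/6; the rest is the center.
CORNER_THRESHOLD = 2.0 / 3.0
EDGE_THRESHOLD = 1.0 / 6.0


def simplex_xy(weights) -> tuple:
    p = np.asarray(weights, dtype=float)
    xy = p @ TRIANGLE_VERTICES
    return float(xy[0]), float(xy[1])


def classify_region(weights, corner: float = CORNER_THRESHOLD,
                    edge: float = EDGE_THRESHOLD) -> str:
    """Assign a weight vector to one of the seven simplex regions.

    Ties are broken toward the lower region index (C1 < C2 < C3,
    E12 < E13 < E23).
    """
    p = np.asarray(weights, dtype=float)
    i_max = int(np.argmax(p))  # first max: lower corner index on ties
    if p[i_max] > corner:
        return f"C{i_max + 1}"
    if p.min() < edge:
        # edge between the two largest; on ties in the minimum, drop the
        # highest index so the surviving pair has the lower edge label
        i_min = int(np.where(p == p.min())[0][-1])
        a, b = sorted(i for i in range(3) if i != i_min)
        return f"E{a + 1}{b + 1}"
    return "center"


@dataclass
class SimplexPoint:
    taxa: tuple
    weights: tuple
    xy: tuple
    region: str


@dataclass
class FcLMReport:
    """Region accounting for one hypothesis on one matrix."""

    hypothesis: str
    matrix_label: str  # original | scheme_I | scheme_II | scheme_III | ...
    n_quartets_total: int
    n_undetermined: int
    region_counts: dict
    points: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        self.region_counts = {r: int(self.region_counts.get(r, 0)) for r in REGIONS}
        determined = sum(self.region_counts.values())
        if determined + self.n_undetermined != self.n_quartets_total:
            raise ValueError(
                f"region counts ({determined}) + undetermined ({self.n_undetermined}) "
                f"!= total quartets ({self.n_quartets_total})"
            )

    @property
    def n_determined(self) -> int:
        return self.n_quartets_total - self.n_undetermined

    @property
    def proportions(self) -> dict:
        d = self.n_determined
        if d == 0:
            return {r: float("nan") for r in REGIONS}
        return {r: c / d for r, c in self.region_counts.items()}

    def to_dict(self) -> dict:
        return {
            "hypothesis": self.hypothesis,
            "matrix_label": self.matrix_label,
            "n_quartets_total": self.n_quartets_total,
            "n_undetermined": self.n_undetermined,
            "region_counts": self.region_counts,
            "proportions": self.proportions,
            "points": [
                {"taxa": list(p.taxa), "weights": list(p.weights),
                 "xy": list(p.xy), "region": p.region}
                for p in self.points
            ],
        }

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FcLMReport":
        with open(path) as fh:
            d = json.load(fh)
        points = [SimplexPoint(tuple(p["taxa"]), tuple(p["weights"]),
                               tuple(p["xy"]), p["region"]) for p in d.get("points", [])]
        return cls(d["hypothesis"], d["matrix_label"], d["n_quartets_total"],
                   d["n_undetermined"], d["region_counts"], points)


# -- quartet enumeration -------------------------------------------------


def enumerate_quartets(groups: TaxonGroupConfig, max_quartets: int | None = None,
                       seed: int = 0) -> list:
    """Cartesian product over the four groups (one taxon each), in
    deterministic order; optionally a seeded uniform subsample without
    replacement."""
    if groups.purpose != "fclm_hypothesis":
        raise ValueError("quartet enumeration needs an fclm_hypothesis group config")
    lists = list(groups.groups.values())
    full = list(itertools.product(*lists))
    if max_quartets is None or max_quartets >= len(full):
        return full
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(full), size=max_quartets, replace=False))
    return [full[i] for i in idx]


# -- per-partition model fitting ----------------------------------------


def _empirical_frequencies(codes: np.ndarray, k: int) -> np.ndarray:
    counts = np.bincount(codes[codes >= 0].ravel(), minlength=k).astype(float)
    counts += 1.0  # pseudocount guards empty partitions
    return counts / counts.sum()


def _reference_quartet(aln: Alignment) -> list:
    """The four taxa with the most non-missing cells (deterministic)."""
    observed = (~aln.missing_mask()).sum(axis=1)
    order = np.argsort(-observed, kind="stable")[:4]
    return [aln.taxa[i] for i in sorted(order)]


def fit_partition_models(aln: Alignment, scheme: PartitionScheme,
                         gamma_shape: float = 1.0, n_categories: int = 4,
                         empirical_freqs: bool = True, estimate: bool = True,
                         estimation_rounds: int = 2) -> dict:
    """One substitution model per partition, held fixed across quartets.

    Frequencies are empirical per partition (amino acid matrices may use
    the LG frequencies instead).  With ``estimate=True``, the GTR
    exchangeabilities (nucleotide) and the gamma shape are refined by
    coordinate ascent of the quartet likelihood of the four most complete
    taxa, branch lengths re-optimized between rounds.
    """
    if aln.n_taxa < 4:
        estimate = False
    codes = aln.encode() if (empirical_freqs or estimate) else None
    ref_taxa = _reference_quartet(aln) if estimate else None
    models = {}
    for name, cols in scheme.partitions:
        if aln.alphabet == "nucleotide":
            freqs = (_empirical_frequencies(codes[:, cols], 4)
                     if empirical_freqs else np.full(4, 0.25))
            model = gtr(np.ones(6), freqs, gamma_shape, n_categories)
        else:
            freqs = (_empirical_frequencies(codes[:, cols], 20)
                     if empirical_freqs else lg_frequencies())
            model = lg(freqs, gamma_shape, n_categories)
        if estimate:
            model = _refine_model(aln, ref_taxa, name, cols, model, estimation_rounds)
        models[name] = model
    return models


def _refine_model(aln, ref_taxa, name, cols, model, rounds):
    qdata = QuartetData.from_alignment(aln, ref_taxa, [(name, cols)], {name: model})
    if not qdata.is_determined:
        return model

    def rebuild(rates, shape):
        if model.alphabet == "nucleotide":
            return gtr(rates, model.frequencies, shape, model.n_categories)
        return SubstitutionModel(model.name, model.alphabet, model.exchangeabilities,
                                 model.frequencies, shape, model.n_categories)

    rates = (model.exchangeabilities[np.triu_indices(4, k=1)]
             if model.alphabet == "nucleotide" else None)
    shape = model.gamma_shape
    current = rebuild(rates, shape)
    qdata.partitions[0] = (qdata.partitions[0][0], qdata.partitions[0][1], current)
    _, bl, _ = optimize_quartet(qdata, "T1", max_rounds=20)
    for _ in range(rounds):
        free = list(range(5)) if rates is not None else []  # GT rate fixed at 1
        for p in free:
            def neg(logx, p=p):
                r = rates.copy()
                r[p] = np.exp(logx)
                m = rebuild(r, shape)
                qdata.partitions[0] = (qdata.partitions[0][0], qdata.partitions[0][1], m)
                return -quartet_loglik(qdata, "T1", bl)

            res = minimize_scalar(neg, bounds=(np.log(1e-3), np.log(1e3)),
                                  method="bounded", options={"xatol": 1e-3})
            rates[p] = float(np.exp(res.x))
        if current.n_categories > 1:
            def neg_shape(loga):
                m = rebuild(rates, np.exp(loga))
                qdata.partitions[0] = (qdata.partitions[0][0], qdata.partitions[0][1], m)
                return -quartet_loglik(qdata, "T1", bl)

            res = minimize_scalar(neg_shape, bounds=(np.log(0.05), np.log(50.0)),
                                  method="bounded", options={"xatol": 1e-3})
            shape = float(np.exp(res.x))
        current = rebuild(rates, shape)
        qdata.partitions[0] = (qdata.partitions[0][0], qdata.partitions[0][1], current)
        _, bl, _ = optimize_quartet(qdata, "T1", max_rounds=20)
    return current


# -- the mapping run -----------------------------------------------------


def run_fclm(matrix: Alignment, scheme: PartitionScheme, groups: TaxonGroupConfig,
             models: dict | None = None, max_quartets: int | None = None,
             seed: int = 0, matrix_label: str = "original",
             hypothesis: str | None = None, **model_kwargs) -> FcLMReport:
    """Map every enumerated quartet onto the simplex and tally regions.

    Quartets with zero usable sites are counted as undetermined and
    excluded from the region proportions.
    """
    groups.validate_against(matrix)
    if models is None:
        models = fit_partition_models(matrix, scheme, **model_kwargs)
    quartets = enumerate_quartets(groups, max_quartets=max_quartets, seed=seed)
    counts = {r: 0 for r in REGIONS}
    points = []
    undetermined = 0
    for taxa in quartets:
        qdata = QuartetData.from_alignment(matrix, taxa, scheme.partitions, models)
        if not qdata.is_determined:
            undetermined += 1
            continue
        result = evaluate_quartet(qdata)
        region = classify_region(result.weights)
        counts[region] += 1
        points.append(SimplexPoint(taxa=tuple(taxa), weights=result.weights,
                                   xy=simplex_xy(result.weights), region=region))
    return FcLMReport(
        hypothesis=hypothesis or "+".join(groups.names),
        matrix_label=matrix_label,
        n_quartets_total=len(quartets),
        n_undetermined=undetermined,
        region_counts=counts,
        points=points,
    )


def corrected_support(original: FcLMReport, permuted: FcLMReport) -> dict:
    """Permutation-corrected region support: the permuted proportions are
    subtracted region-wise from the original ones, floored at zero, to
    discount support attributable to confounding (non-phylogenetic)
    signal."""
    if original.hypothesis != permuted.hypothesis:
        raise ValueError("reports test different hypotheses")
    if original.n_quartets_total != permuted.n_quartets_total:
        raise ValueError("reports cover different quartet sets")
    orig, perm = original.proportions, permuted.proportions
    corrected = {r: max(0.0, orig[r] - perm[r]) for r in REGIONS}
    corners = ("C1", "C2", "C3")
    return {
        "raw": orig,
        "permuted": perm,
        "corrected": corrected,
        "top_corner_raw": max(corners, key=lambda r: orig[r]),
        "top_corner_corrected": max(corners, key=lambda r: corrected[r]),
    }


def plot_simplex(report: FcLMReport, path) -> None:
    """Scatter of quartet points in the triangle with the seven regions."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5.5))
    tri = np.vstack([TRIANGLE_VERTICES, TRIANGLE_VERTICES[0]])
    ax.plot(tri[:, 0], tri[:, 1], "k-", lw=1)
    # region boundaries, drawn by classifying a fine barycentric grid
    grid = []
    n = 250
    for a in range(n + 1):
        for b in range(n + 1 - a):
            grid.append((a / n, b / n, (n - a - b) / n))
    grid = np.array(grid)
    xy = grid @ TRIANGLE_VERTICES
    regions = np.array([classify_region(w) for w in grid])
    for r, color in zip(REGIONS, ["#ffd", "#dfd", "#ddf", "#eee", "#eee", "#eee", "#fdd"]):
        sel = regions == r
        ax.scatter(xy[sel, 0], xy[sel, 1], s=1.5, c=color, marker="s", zorder=0)
    pts = np.array([p.xy for p in report.points]) if report.points else np.empty((0, 2))
    if len(pts):
        ax.scatter(pts[:, 0], pts[:, 1], s=6, c="k", alpha=0.6, zorder=2)
    for label, (x, y) in zip(("T1", "T2", "T3"), TRIANGLE_VERTICES):
        ax.annotate(label, (x, y), textcoords="offset points", xytext=(0, 6),
                    ha="center", fontsize=10)
    props = report.proportions
    ax.set_title(f"{report.hypothesis} [{report.matrix_label}] "
                 f"C1={props['C1']:.1%} C2={props['C2']:.1%} C3={props['C3']:.1%}")
    ax.set_aspect("equal")
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
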