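"""Bowker matched-pairs tests of symmetry between aligned sequence pairs.

A substitution process that is globally stationary, reversible and
homogeneous (the SRH conditions) predicts a symmetric expected divergence
table between any two taxa.  Bowker's statistic

    B = sum over unordered state pairs {i,j} with n_ij + n_ji > 0 of
        (n_ij - n_ji)^2 / (n_ij + n_ji)

is asymptotically chi-square with one degree of freedom per contributing
pair, so small p-values flag taxon pairs whose evolution violated at least
one SRH condition.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .core import Alignment, states_for

NO_OVERLAP = "no_overlap"


@dataclass
class PairDivergenceMatrix:
    counts: np.ndarray  # k x k integer table
    taxa: tuple
    n_effective: int


@dataclass
class SymmetryTestResult:
    statistic: float
    df: int
    p_value: float


def divergence_counts(aln: Alignment, taxon_a: str, taxon_b: str) -> PairDivergenceMatrix:
    """Joint state counts over columns where both taxa are non-missing."""
    codes = _pair_codes(aln, taxon_a, taxon_b)
    k = len(states_for(aln.alphabet))
    a, b = codes
    ok = (a >= 0) & (b >= 0)
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (a[ok], b[ok]), 1)
    return PairDivergenceMatrix(counts=counts, taxa=(taxon_a, taxon_b),
                                n_effective=int(ok.sum()))


def _pair_codes(aln, taxon_a, taxon_b):
    for t in (taxon_a, taxon_b):
        if t not in aln._index:
            raise KeyError(f"unknown taxon: {t!r}")
    codes = aln.encode()
    return codes[aln._index[taxon_a]], codes[aln._index[taxon_b]]


def bowker_test(m: PairDivergenceMatrix) -> SymmetryTestResult:
    """Bowker's matched-pairs test; pairs with n_ij + n_ji = 0 contribute
    neither to the statistic nor to the degrees of freedom.  df = 0 (no
    off-diagonal disagreement at all) is reported as p = 1."""
    n = m.counts
    iu, ju = np.triu_indices(n.shape[0], k=1)
    s = n[iu, ju] + n[ju, iu]
    use = s > 0
    d = n[iu, ju] - n[ju, iu]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(use, d.astype(float) ** 2 / np.where(use, s, 1), 0.0)
    stat = float(terms.sum())
    df = int(use.sum())
    p = 1.0 if df == 0 else float(chi2.sf(stat, df))
    return SymmetryTestResult(statistic=stat, df=df, p_value=p)


def pairwise_symmetry_matrix(aln: Alignment) -> pd.DataFrame:
    """Symmetric taxa x taxa table of Bowker p-values.

    The diagonal is NaN; pairs with no jointly observed column carry NaN
    too and are distinguished by :func:`classify_heatmap` as ``no_overlap``.
    """
    if aln.n_taxa < 2:
        raise ValueError("need at least two taxa")
    codes = aln.encode()
    k = len(states_for(aln.alphabet))
    n = aln.n_taxa
    table = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = codes[i], codes[j]
            ok = (a >= 0) & (b >= 0)
            if not ok.any():
                continue
            counts = np.zeros((k, k), dtype=np.int64)
            np.add.at(counts, (a[ok], b[ok]), 1)
            res = bowker_test(PairDivergenceMatrix(counts, (aln.taxa[i], aln.taxa[j]),
                                                   int(ok.sum())))
            table[i, j] = table[j, i] = res.p_value
    return pd.DataFrame(table, index=aln.taxa, columns=aln.taxa)


def classify_heatmap(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Label each off-diagonal pair: ``pass`` (p > alpha, the white cells of
    the diagnostic heat map), ``fail`` (p <= alpha) or ``no_overlap``."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    vals = table.to_numpy()
    labels = np.where(np.isnan(vals), NO_OVERLAP,
                      np.where(vals > alpha, "pass", "fail")).astype(object)
    np.fill_diagonal(labels, "")
    return pd.DataFrame(labels, index=table.index, columns=table.columns)


def symmetry_report(aln: Alignment, alpha: float = 0.05) -> pd.DataFrame:
    """Long-form per-pair report: n_effective, B, df, p and class."""
    rows = []
    for i, a in enumerate(aln.taxa):
        for b in aln.taxa[i + 1:]:
            m = divergence_counts(aln, a, b)
            if m.n_effective == 0:
                rows.append((a, b, 0, np.nan, 0, np.nan, NO_OVERLAP))
                continue
            r = bowker_test(m)
            cls = "pass" if r.p_value > alpha else "fail"
            rows.append((a, b, m.n_effective, r.statistic, r.df, r.p_value, cls))
    return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "n_effective",
                                       "B", "df", "p", "class"])


def plot_heatmap(table: pd.DataFrame, path, alpha: float = 0.05) -> None:
    """p-value heat map in the usual convention: cells with p > alpha drawn
    white, failing cells shaded by -log10(p)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = table.to_numpy(dtype=float).copy()
    with np.errstate(divide="ignore"):
        shade = -np.log10(np.clip(vals, 1e-300, 1.0))
    shade[vals > alpha] = 0.0
    fig, ax = plt.subplots(figsize=(max(4, 0.18 * len(table)),) * 2)
    im = ax.imshow(shade, cmap="Reds", vmin=0.0)
    ax.set_xticks(range(len(table)))
    ax.set_yticks(range(len(table)))
    ax.set_xticklabels(table.columns, rotation=90, fontsize=5)
    ax.set_yticklabels(table.index, fontsize=5)
    fig.colorbar(im, ax=ax, label="-log10 p (0 = pass)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
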