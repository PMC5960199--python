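"""Permutation nulls that progressively destroy signal components while
controlling the missing-data structure.

Scheme I   shuffles the observed residues within each partition (across
           taxa and sites): phylogenetic signal is destroyed, per-partition
           composition and the missingness mask are conserved exactly.
Scheme II  replaces every observed residue by an i.i.d. draw from a
           frequency vector (LG frequencies for amino acids, empirical
           per-partition or uniform otherwise): composition heterogeneity
           across taxa is destroyed too; the mask is still conserved.
Scheme III additionally permutes the missing/observed indicator within
           each partition: the non-random placement of missing data is
           destroyed; only the per-partition missing-cell count survives.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Alignment, PartitionScheme, states_for
from .models import lg_frequencies

FREQ_SOURCES = ("LG", "empirical_partition", "uniform")


@dataclass
class PermutationSpec:
    scheme: str  # I | II | III
    seed: int = 0
    frequency_source: str = "empirical_partition"  # ignored by scheme I

    def __post_init__(self):
        if self.scheme not in ("I", "II", "III"):
            raise ValueError(f"unknown permutation scheme: {self.scheme!r}")
        if self.frequency_source not in FREQ_SOURCES:
            raise ValueError(f"unknown frequency source: {self.frequency_source!r}")


def apply_scheme(matrix: Alignment, scheme: PartitionScheme, spec: PermutationSpec) -> Alignment:
    fn = {"I": scheme_I, "II": scheme_II, "III": scheme_III}[spec.scheme]
    if spec.scheme == "I":
        return fn(matrix, scheme, seed=spec.seed)
    return fn(matrix, scheme, frequency_source=spec.frequency_source, seed=spec.seed)


def scheme_I(matrix: Alignment, scheme: PartitionScheme, seed: int = 0) -> Alignment:
    """Permute observed residues within each partition; missing cells are
    untouched, so the per-partition residue multiset and the missingness
    mask are conserved exactly."""
    rng = np.random.default_rng(seed)
    out = matrix.matrix.copy()
    observed = ~matrix.missing_mask()
    for _, cols in scheme.partitions:
        block = out[:, cols]
        mask = observed[:, cols]
        vals = block[mask]
        rng.shuffle(vals)
        block[mask] = vals
        out[:, cols] = block
    return Alignment(matrix.taxa, out, matrix.alphabet)


def _frequency_vector(matrix, cols, observed, source):
    states = states_for(matrix.alphabet)
    k = len(states)
    if source == "LG":
        if matrix.alphabet != "amino_acid":
            raise ValueError("LG frequencies are defined for amino acid matrices only")
        return np.asarray(lg_frequencies())
    if source == "uniform":
        return np.full(k, 1.0 / k)
    block = matrix.matrix[:, cols]
    vals = block[observed[:, cols]]
    counts = np.array([(vals == s).sum() for s in states], dtype=float) + 1.0
    return counts / counts.sum()


def scheme_II(matrix: Alignment, scheme: PartitionScheme,
              frequency_source: str = "empirical_partition", seed: int = 0) -> Alignment:
    """Replace each observed residue by an i.i.d. draw from the chosen
    frequency vector; the missingness mask is conserved exactly."""
    rng = np.random.default_rng(seed)
    out = matrix.matrix.copy()
    observed = ~matrix.missing_mask()
    states = np.array(list(states_for(matrix.alphabet)), dtype="U1")
    for _, cols in scheme.partitions:
        freqs = _frequency_vector(matrix, cols, observed, frequency_source)
        mask = observed[:, cols]
        n = int(mask.sum())
        if n == 0:
            continue
        block = out[:, cols]
        block[mask] = states[rng.choice(len(states), size=n, p=freqs)]
        out[:, cols] = block
    return Alignment(matrix.taxa, out, matrix.alphabet)


def scheme_III(matrix: Alignment, scheme: PartitionScheme,
               frequency_source: str = "empirical_partition", seed: int = 0,
               granularity: str = "cell") -> Alignment:
    """Scheme II followed by a uniform permutation of the missing/observed
    indicator within each partition (``granularity="cell"``) or of whole
    columns (``granularity="column"``); the per-partition count of missing
    cells is conserved."""
    if granularity not in ("cell", "column"):
        raise ValueError(f"unknown granularity: {granularity!r}")
    rng = np.random.default_rng(seed)
    randomized = scheme_II(matrix, scheme, frequency_source=frequency_source,
                           seed=int(rng.integers(2**31)))
    out = randomized.matrix.copy()
    missing_char = "-"
    observed = ~matrix.missing_mask()
    states = np.array(list(states_for(matrix.alphabet)), dtype="U1")
    for _, cols in scheme.partitions:
        freqs = _frequency_vector(matrix, cols, observed, frequency_source)
        block = out[:, cols]
        mask = observed[:, cols]
        if granularity == "cell":
            flat_mask = mask.ravel().copy()
            rng.shuffle(flat_mask)
            new_mask = flat_mask.reshape(mask.shape)
        else:
            perm = rng.permutation(mask.shape[1])
            new_mask = mask[:, perm]
        # observed cells that moved onto previously missing positions need
        # fresh draws; everything missing under the new mask becomes '-'
        fresh = new_mask & ~mask
        block[~new_mask] = missing_char
        block[fresh] = states[rng.choice(len(states), size=int(fresh.sum()), p=freqs)]
        out[:, cols] = block
    return Alignment(matrix.taxa, out, matrix.alphabet)
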