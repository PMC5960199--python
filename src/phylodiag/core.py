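"""Core data model: alignments, data blocks, partition schemes, taxon groups.

Coordinate convention: all in-memory coordinates are 0-based half-open;
files on disk (partition files) use the 1-based inclusive convention of
RAxML-style partition lines. Converting between the two is lossless.
"""
from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np

from ._lg import AA_ORDER

NT_STATES = "ACGT"
AA_STATES = AA_ORDER

#: Symbols that never contribute signal: alignment gaps, unknowns, and the
#: fully ambiguous state of each alphabet ('N' for nucleotide, 'X' for amino
#: acid).  Stop codons are masked upstream as 'X'/'NNN', so '*' is treated
#: as missing rather than rejected.
MISSING_NT = frozenset("-?NX*RYSWKMBDHV")
MISSING_AA = frozenset("-?X*BZJUO")


def states_for(alphabet: str) -> str:
    if alphabet == "nucleotide":
        return NT_STATES
    if alphabet == "amino_acid":
        return AA_STATES
    raise ValueError(f"unknown alphabet: {alphabet!r}")


def missing_for(alphabet: str) -> frozenset:
    return MISSING_NT if alphabet == "nucleotide" else MISSING_AA


class Alignment:
    """A taxa x columns character matrix over a fixed alphabet.

    Parameters
    ----------
    taxa
        Unique, non-empty, whitespace-free labels; order is preserved.
    matrix
        2D array (or nested sequence) of single characters; stored
        upper-case.
    alphabet
        ``"nucleotide"`` or ``"amino_acid"``.
    """

    def __init__(self, taxa, matrix, alphabet: str):
        taxa = list(taxa)
        if len(set(taxa)) != len(taxa):
            seen = set()
            dup = next(t for t in taxa if t in seen or seen.add(t))
            raise ValueError(f"duplicate taxon label: {dup!r}")
        for t in taxa:
            if not t or re.search(r"\s", t):
                raise ValueError(f"invalid taxon label: {t!r} (empty or contains whitespace)")
        m = np.asarray(matrix, dtype="U1")
        if m.ndim == 1:  # allow list of strings
            m = np.array([list(row) for row in matrix], dtype="U1")
        if m.ndim != 2 or m.shape[0] != len(taxa):
            raise ValueError(f"matrix shape {m.shape} does not match {len(taxa)} taxa")
        m = np.char.upper(m)
        legal = set(states_for(alphabet)) | missing_for(alphabet)
        bad = ~np.isin(m, sorted(legal))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"illegal character {m[i, j]!r} for alphabet {alphabet} "
                f"at taxon {taxa[i]!r}, column {j}"
            )
        self.taxa = taxa
        self.matrix = m
        self.alphabet = alphabet
        self._index = {t: i for i, t in enumerate(taxa)}

    # -- basic queries -------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        try:
            return self.matrix[self._index[taxon]]
        except KeyError:
            raise KeyError(f"unknown taxon: {taxon!r}") from None

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_taxa, n_columns) array, True where data is missing."""
        miss = sorted(missing_for(self.alphabet))
        return np.isin(self.matrix, miss)

    def encode(self) -> np.ndarray:
        """Integer state codes, missing cells coded as -1."""
        states = states_for(self.alphabet)
        codes = np.full(self.matrix.shape, -1, dtype=np.int8)
        for k, s in enumerate(states):
            codes[self.matrix == s] = k
        return codes

    # -- slicing -------------------------------------------------------
    def take_taxa(self, labels) -> "Alignment":
        idx = [self._index[t] if t in self._index else self._missing(t) for t in labels]
        return Alignment(list(labels), self.matrix[idx], self.alphabet)

    def _missing(self, t):
        raise KeyError(f"unknown taxon: {t!r}")

    def take_columns(self, cols) -> "Alignment":
        cols = np.asarray(cols, dtype=int)
        return Alignment(self.taxa, self.matrix[:, cols], self.alphabet)

    def __eq__(self, other):
        return (
            isinstance(other, Alignment)
            and self.taxa == other.taxa
            and self.alphabet == other.alphabet
            and self.matrix.shape == other.matrix.shape
            and bool((self.matrix == other.matrix).all())
        )

    def __repr__(self):
        return f"<Alignment {self.n_taxa} taxa x {self.n_columns} cols ({self.alphabet})>"


@dataclass
class DataBlock:
    """A named set of supermatrix column ranges with provenance.

    ``ranges`` are 0-based half-open ``(start, stop)`` intervals in
    supermatrix coordinates; ``frame_offset`` (nucleotide blocks only) gives
    the codon position (0, 1 or 2) of the first column.
    """

    name: str
    ranges: list
    gene_id: str
    domain_id: str | None = None
    frame_offset: int | None = None

    def __post_init__(self):
        rs = sorted(tuple(r) for r in self.ranges)
        for (a, b) in rs:
            if not (0 <= a < b):
                raise ValueError(f"invalid range ({a}, {b}) in block {self.name!r}")
        for (a1, b1), (a2, b2) in zip(rs, rs[1:]):
            if a2 < b1:
                raise ValueError(f"overlapping ranges in block {self.name!r}: ({a1},{b1}) and ({a2},{b2})")
        self.ranges = rs
        if self.frame_offset is not None:
            if self.frame_offset not in (0, 1, 2):
                raise ValueError(f"frame_offset must be 0, 1 or 2, got {self.frame_offset}")
            if self.frame_offset == 0 and self.length % 3 != 0:
                raise ValueError(
                    f"in-frame block {self.name!r} has length {self.length}, not divisible by 3"
                )

    @property
    def length(self) -> int:
        return sum(b - a for a, b in self.ranges)

    def columns(self) -> np.ndarray:
        if not self.ranges:
            return np.array([], dtype=int)
        return np.concatenate([np.arange(a, b) for a, b in self.ranges])


@dataclass
class PartitionScheme:
    """Disjoint named column sets tiling a supermatrix (or its 1st+2nd
    codon positions in NT12 mode)."""

    mode: str  # AA | NT123 | NT12
    partitions: list  # list of (name, np.ndarray of 0-based columns)
    model_hints: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in ("AA", "NT123", "NT12"):
            raise ValueError(f"unknown partition mode: {self.mode!r}")
        norm = []
        seen = {}
        for name, cols in self.partitions:
            cols = np.unique(np.asarray(cols, dtype=int))
            if cols.size == 0:
                raise ValueError(f"empty partition {name!r}")
            norm.append((name, cols))
        all_cols = np.concatenate([c for _, c in norm]) if norm else np.array([], int)
        uniq, counts = np.unique(all_cols, return_counts=True)
        if (counts > 1).any():
            col = int(uniq[counts > 1][0])
            owners = [n for n, c in norm if col in c]
            raise ValueError(f"column {col} assigned to multiple partitions: {owners}")
        self.partitions = norm

    @property
    def names(self):
        return [n for n, _ in self.partitions]

    def column_universe(self) -> np.ndarray:
        if not self.partitions:
            return np.array([], dtype=int)
        return np.sort(np.concatenate([c for _, c in self.partitions]))


@dataclass
class TaxonGroupConfig:
    """Named, disjoint taxon groups.

    ``purpose`` is either ``"fclm_hypothesis"`` (exactly four non-empty
    groups, order fixes the quartet-corner identity) or ``"block_filter"``
    (any number of required groups).
    """

    groups: dict  # ordered name -> list of taxa
    purpose: str = "fclm_hypothesis"

    def __post_init__(self):
        if self.purpose not in ("fclm_hypothesis", "block_filter"):
            raise ValueError(f"unknown purpose: {self.purpose!r}")
        self.groups = {str(k): list(v) for k, v in self.groups.items()}
        seen = {}
        for name, members in self.groups.items():
            if not members:
                raise ValueError(f"group {name!r} is empty")
            for t in members:
                if t in seen:
                    raise ValueError(f"taxon {t!r} appears in groups {seen[t]!r} and {name!r}")
                seen[t] = name
        if self.purpose == "fclm_hypothesis" and len(self.groups) != 4:
            raise ValueError(
                f"fclm_hypothesis requires exactly 4 groups, got {len(self.groups)}"
            )

    def validate_against(self, aln: Alignment):
        missing = [t for members in self.groups.values() for t in members if t not in aln._index]
        if missing:
            raise ValueError(f"taxa not in alignment: {missing}")

    @property
    def names(self):
        return list(self.groups)

    @classmethod
    def from_json(cls, path) -> "TaxonGroupConfig":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(groups=doc["groups"], purpose=doc.get("purpose", "fclm_hypothesis"))

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump({"groups": self.groups, "purpose": self.purpose}, fh, indent=1)
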