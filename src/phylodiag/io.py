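"""Readers and writers: FASTA, relaxed PHYLIP, Newick trees, RAxML-style
partition files."""
from __future__ import annotations

import re

import dendropy
import numpy as np
from Bio import SeqIO

from .core import Alignment, PartitionScheme


def _to_alignment(names, seqs, alphabet) -> Alignment:
    if len(set(names)) != len(names):
        seen = set()
        dup = next(n for n in names if n in seen or seen.add(n))
        raise ValueError(f"duplicate taxon label: {dup!r}")
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        detail = ", ".join(f"{n}={len(s)}" for n, s in zip(names, seqs))
        raise ValueError(f"ragged alignment rows: {detail}")
    n_cols = lengths.pop() if lengths else 0
    m = np.frombuffer("".join(seqs).encode("ascii"), dtype="S1").astype("U1")
    m = m.reshape(len(names), n_cols) if names else np.empty((0, 0), dtype="U1")
    return Alignment(names, m, alphabet)


def read_alignment(path, alphabet: str, format: str = "fasta") -> Alignment:
    """Read a FASTA or relaxed-PHYLIP alignment.

    Raises ``ValueError`` on duplicate labels, ragged rows or characters
    outside the alphabet-plus-missing set.
    """
    if format == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        names = [r.id for r in records]
        seqs = [str(r.seq) for r in records]
    elif format == "phylip":
        names, seqs = _read_relaxed_phylip(path)
    else:
        raise ValueError(f"unknown alignment format: {format!r}")
    return _to_alignment(names, seqs, alphabet)


def _read_relaxed_phylip(path):
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"bad PHYLIP header in {path}")
        n_taxa, n_cols = int(header[0]), int(header[1])
        names, seqs = [], []
        for line in fh:
            if not line.strip():
                continue
            parts = line.split(None, 1)
            names.append(parts[0])
            seqs.append(re.sub(r"\s", "", parts[1]) if len(parts) > 1 else "")
        if len(names) != n_taxa:
            raise ValueError(f"PHYLIP header claims {n_taxa} taxa, found {len(names)}")
        if any(len(s) != n_cols for s in seqs):
            raise ValueError(f"PHYLIP header claims {n_cols} columns, rows disagree")
    return names, seqs


def write_alignment(aln: Alignment, path, format: str = "fasta") -> None:
    rows = ["".join(r) for r in aln.matrix]
    with open(path, "w") as fh:
        if format == "fasta":
            for name, seq in zip(aln.taxa, rows):
                fh.write(f">{name}\n")
                for i in range(0, max(len(seq), 1), 70):
                    fh.write(seq[i : i + 70] + "\n")
        elif format == "phylip":
            fh.write(f"{aln.n_taxa} {aln.n_columns}\n")
            for name, seq in zip(aln.taxa, rows):
                fh.write(f"{name}  {seq}\n")
        else:
            raise ValueError(f"unknown alignment format: {format!r}")


# -- Newick ------------------------------------------------------------


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)


def read_newick_string(s: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
        real_value_format_specifier=".10g",
    )


# -- RAxML-style partition files ----------------------------------------

_PART_LINE = re.compile(
    r"^\s*(?P<model>[\w+.]+)\s*,\s*(?P<name>\S+)\s*=\s*(?P<ranges>.+?)\s*$"
)
_RANGE = re.compile(r"^(\d+)\s*-\s*(\d+)(?:\\(\d+))?$|^(\d+)$")


def read_partition_file(path, mode: str = "AA") -> PartitionScheme:
    """Parse lines like ``WAG, p1 = 1-6, 10-12\\3`` (1-based inclusive,
    optional codon-stride suffix) into a 0-based PartitionScheme."""
    partitions, hints = [], {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            m = _PART_LINE.match(line)
            if not m:
                raise ValueError(f"{path}:{lineno}: malformed partition line: {line.rstrip()!r}")
            cols = []
            for token in m.group("ranges").split(","):
                rm = _RANGE.match(token.strip())
                if not rm:
                    raise ValueError(f"{path}:{lineno}: bad range token {token.strip()!r}")
                if rm.group(4) is not None:
                    cols.append(np.array([int(rm.group(4)) - 1]))
                else:
                    start, stop = int(rm.group(1)), int(rm.group(2))
                    stride = int(rm.group(3)) if rm.group(3) else 1
                    cols.append(np.arange(start - 1, stop, stride))
            name = m.group("name")
            partitions.append((name, np.concatenate(cols)))
            hints[name] = m.group("model")
    return PartitionScheme(mode=mode, partitions=partitions, model_hints=hints)


def write_partition_file(scheme: PartitionScheme, path) -> None:
    """Emit 1-based inclusive partition lines; runs of stride-3 columns are
    written with the ``\\3`` codon suffix, other columns as plain ranges."""
    with open(path, "w") as fh:
        for name, cols in scheme.partitions:
            model = scheme.model_hints.get(name, "DNA" if scheme.mode.startswith("NT") else "LG")
            fh.write(f"{model}, {name} = {_format_columns(cols)}\n")


def _format_columns(cols: np.ndarray) -> str:
    cols = np.sort(cols)
    if cols.size >= 2 and len(set(np.diff(cols))) == 1 and cols[1] - cols[0] == 3:
        return f"{cols[0] + 1}-{cols[-1] + 1}\\3"
    out = []
    start = prev = int(cols[0])
    for c in cols[1:]:
        c = int(c)
        if c == prev + 1:
            prev = c
            continue
        out.append((start, prev))
        start = prev = c
    out.append((start, prev))
    return ", ".join(f"{a + 1}-{b + 1}" if a != b else f"{a + 1}" for a, b in out)
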