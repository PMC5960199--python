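"""Supermatrix assembly: protein-domain data blocks from masked gene
alignments, block filtering, concatenation, codon-aware partition schemes,
and MCMC sample-budget bookkeeping.

Data blocks are the partition units: after removal of ambiguously aligned
(masked) columns, the columns of each gene that fall inside a protein
domain annotation are pooled across genes into one block per domain, and
the leftover columns form one residual block per gene.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import Alignment, DataBlock, PartitionScheme, TaxonGroupConfig


@dataclass
class GeneRecord:
    """One single-copy gene: amino acid MSA, codon-aligned nucleotide MSA
    (3x the aa length), a mask of ambiguously aligned aa columns, and
    protein-domain annotations as (domain_id, (start, stop)) aa column
    ranges (0-based half-open)."""

    gene_id: str
    aa_alignment: Alignment
    nt_alignment: Alignment
    mask: set = field(default_factory=set)
    domains: list = field(default_factory=list)

    def __post_init__(self):
        n_aa = self.aa_alignment.n_columns
        if self.nt_alignment.n_columns != 3 * n_aa:
            raise ValueError(
                f"gene {self.gene_id!r}: nt length {self.nt_alignment.n_columns} "
                f"!= 3 x aa length {n_aa}"
            )
        if self.aa_alignment.taxa != self.nt_alignment.taxa:
            raise ValueError(f"gene {self.gene_id!r}: aa and nt taxa differ")
        self.mask = set(int(c) for c in self.mask)
        if self.mask and (min(self.mask) < 0 or max(self.mask) >= n_aa):
            raise ValueError(f"gene {self.gene_id!r}: mask index out of bounds")
        doms = sorted(((d, (int(a), int(b))) for d, (a, b) in self.domains),
                      key=lambda x: x[1])
        for d, (a, b) in doms:
            if not (0 <= a < b <= n_aa):
                raise ValueError(f"gene {self.gene_id!r}: domain {d!r} range ({a},{b}) out of bounds")
        for (d1, (a1, b1)), (d2, (a2, b2)) in zip(doms, doms[1:]):
            if a2 < b1:
                raise ValueError(
                    f"gene {self.gene_id!r}: overlapping domains {d1!r} ({a1},{b1}) "
                    f"and {d2!r} ({a2},{b2})"
                )
        self.domains = doms


@dataclass
class Block:
    """A data block before concatenation: a name, the block-local
    alignment, and provenance."""

    name: str
    alignment: Alignment
    gene_ids: list
    domain_id: str | None = None
    frame_offset: int | None = None


def build_blocks(genes: list, level: str = "aa") -> list:
    """Group unmasked columns into data blocks.

    Masked aa columns are removed (with their codons at nucleotide level);
    columns inside a domain annotation are pooled into one block per
    domain across genes, the rest forms one residual block per gene.
    ``level`` selects the amino acid or nucleotide track.
    """
    if level not in ("aa", "nt"):
        raise ValueError(f"level must be 'aa' or 'nt', got {level!r}")
    domain_parts = {}  # domain_id -> list of (gene_id, Alignment)
    blocks = []
    for gene in genes:
        keep = [c for c in range(gene.aa_alignment.n_columns) if c not in gene.mask]
        in_domain = set()
        for domain_id, (a, b) in gene.domains:
            cols = [c for c in keep if a <= c < b]
            in_domain.update(cols)
            if cols:
                domain_parts.setdefault(domain_id, []).append(
                    (gene.gene_id, _slice(gene, cols, level)))
        rest = [c for c in keep if c not in in_domain]
        if rest:
            blocks.append(Block(
                name=f"{gene.gene_id}_rest",
                alignment=_slice(gene, rest, level),
                gene_ids=[gene.gene_id],
                domain_id=None,
                frame_offset=0 if level == "nt" else None,
            ))
    for domain_id in sorted(domain_parts):
        parts = domain_parts[domain_id]
        merged = _merge_alignments([a for _, a in parts])
        blocks.append(Block(
            name=domain_id,
            alignment=merged,
            gene_ids=[g for g, _ in parts],
            domain_id=domain_id,
            frame_offset=0 if level == "nt" else None,
        ))
    return sorted(blocks, key=lambda b: b.name)


def _slice(gene: GeneRecord, aa_cols, level):
    if level == "aa":
        return gene.aa_alignment.take_columns(aa_cols)
    nt_cols = np.repeat(np.asarray(aa_cols) * 3, 3) + np.tile([0, 1, 2], len(aa_cols))
    return gene.nt_alignment.take_columns(nt_cols)


def _merge_alignments(alns: list) -> Alignment:
    taxa = []
    for a in alns:
        for t in a.taxa:
            if t not in taxa:
                taxa.append(t)
    n_cols = sum(a.n_columns for a in alns)
    m = np.full((len(taxa), n_cols), "-", dtype="U1")
    idx = {t: i for i, t in enumerate(taxa)}
    offset = 0
    for a in alns:
        rows = [idx[t] for t in a.taxa]
        m[rows, offset:offset + a.n_columns] = a.matrix
        offset += a.n_columns
    return Alignment(taxa, m, alns[0].alphabet)


# -- block filters -------------------------------------------------------


def _taxa_with_data(block: Block) -> list:
    observed = (~block.alignment.missing_mask()).any(axis=1)
    return [t for t, o in zip(block.alignment.taxa, observed) if o]


def _has_informative_column(block: Block) -> bool:
    codes = block.alignment.encode()
    for col in codes.T:
        vals, counts = np.unique(col[col >= 0], return_counts=True)
        if (counts >= 2).sum() >= 2:
            return True
    return False


def drop_uninformative_blocks(blocks: list) -> list:
    """Remove blocks that cannot inform a quartet: fewer than four taxa
    with data, or no parsimony-informative column (a column with at least
    two states each present in at least two taxa)."""
    return [b for b in blocks
            if len(_taxa_with_data(b)) >= 4 and _has_informative_column(b)]


@dataclass
class RequiredGroupsRule:
    groups: TaxonGroupConfig

    def __post_init__(self):
        if self.groups.purpose != "block_filter":
            raise ValueError("required-groups rule needs a block_filter group config")
        if not self.groups.groups:
            raise ValueError("required-groups rule has no groups")


def filter_required_groups(blocks: list, rule: RequiredGroupsRule) -> list:
    """Keep a block only if every required group has at least one member
    taxon with at least one non-missing character in the block; mere taxon
    presence with fully gapped rows does not count."""
    kept = []
    for b in blocks:
        with_data = set(_taxa_with_data(b))
        if all(any(t in with_data for t in members)
               for members in rule.groups.groups.values()):
            kept.append(b)
    return kept


def block_report(blocks: list, kept: list) -> list:
    """Rows (name, length, n_taxa_with_data, kept) for a block report TSV."""
    kept_names = {b.name for b in kept}
    return [(b.name, b.alignment.n_columns, len(_taxa_with_data(b)),
             b.name in kept_names) for b in blocks]


# -- concatenation -------------------------------------------------------


def concatenate(blocks: list):
    """Concatenate blocks (sorted by name) into a supermatrix.

    Returns ``(supermatrix, datablocks)`` where each
    :class:`~phylodiag.core.DataBlock` records the block's half-open column
    range in supermatrix coordinates.  Taxa absent from a block are filled
    with '-'.
    """
    if not blocks:
        raise ValueError("no blocks to concatenate")
    alphabets = {b.alignment.alphabet for b in blocks}
    if len(alphabets) > 1:
        raise ValueError(f"cannot concatenate mixed alphabets: {sorted(alphabets)}")
    blocks = sorted(blocks, key=lambda b: b.name)
    merged = _merge_alignments([b.alignment for b in blocks])
    datablocks = []
    offset = 0
    for b in blocks:
        n = b.alignment.n_columns
        datablocks.append(DataBlock(
            name=b.name, ranges=[(offset, offset + n)],
            gene_id=",".join(b.gene_ids), domain_id=b.domain_id,
            frame_offset=b.frame_offset,
        ))
        offset += n
    return merged, datablocks


def aa_scheme(datablocks: list) -> PartitionScheme:
    """One partition per data block (amino acid supermatrix)."""
    return PartitionScheme(mode="AA",
                           partitions=[(db.name, db.columns()) for db in datablocks])


def emit_codon_scheme(datablocks: list, mode: str) -> PartitionScheme:
    """Codon-position partitions per data block.

    ``NT123`` models positions 1, 2 and 3 of each block separately;
    ``NT12`` models positions 1 and 2 and drops third positions from the
    scheme's column universe entirely.
    """
    if mode not in ("NT123", "NT12"):
        raise ValueError(f"mode must be NT123 or NT12, got {mode!r}")
    partitions = []
    for db in datablocks:
        if db.frame_offset is None:
            raise ValueError(f"block {db.name!r} has no codon frame metadata")
        cols = db.columns()
        positions = (np.arange(cols.size) + db.frame_offset) % 3
        n_pos = 3 if mode == "NT123" else 2
        for pos in range(n_pos):
            sel = cols[positions == pos]
            if sel.size:
                partitions.append((f"{db.name}_pos{pos + 1}", sel))
    return PartitionScheme(mode=mode, partitions=partitions)


# -- MCMC bookkeeping ----------------------------------------------------


def mcmc_sample_budget(n_runs: int, n_generations: int, sample_every: int,
                       burnin_fraction: float) -> int:
    """Total retained posterior samples over independent MCMC runs.

    Each run yields ``n_generations / sample_every`` samples (generation 0
    excluded); the first ``floor(burnin_fraction x samples)`` of each run
    are discarded as burn-in.
    """
    if n_runs < 1 or n_generations < 1 or sample_every < 1:
        raise ValueError("runs, generations and sampling interval must be positive")
    if not (0.0 <= burnin_fraction < 1.0):
        raise ValueError(f"burnin_fraction must be in [0, 1), got {burnin_fraction}")
    if n_generations % sample_every != 0:
        raise ValueError(
            f"{n_generations} generations not divisible by sampling interval {sample_every}")
    samples = n_generations // sample_every
    retained = samples - math.floor(burnin_fraction * samples)
    return n_runs * retained
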