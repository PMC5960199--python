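"""Synthetic data with the structure of a domain-partitioned
target-enrichment phylogenomic study: per-gene amino acid and nucleotide
alignments simulated on a known tree, protein-domain annotations, alignment
masks, block-structured missing data, and optional lineage-heterogeneous
composition to induce violations of stationarity.

The nucleotide and amino acid tracks are simulated independently under
their own models on the same tree; the 3:1 column correspondence between
them is bookkeeping only, which suffices because every downstream analysis
treats the tracks separately.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .core import Alignment, TaxonGroupConfig, states_for
from .io import write_alignment, write_newick
from .models import SubstitutionModel, gtr, lg
from .supermatrix import GeneRecord

DEFAULT_GTR_RATES = (1.2, 3.0, 0.8, 0.9, 3.2, 1.0)
DEFAULT_NT_FREQS = (0.30, 0.20, 0.20, 0.30)


def default_nt_model(gamma_shape: float = 0.8, n_categories: int = 4) -> SubstitutionModel:
    return gtr(DEFAULT_GTR_RATES, DEFAULT_NT_FREQS, gamma_shape, n_categories)


def default_aa_model(gamma_shape: float = 0.8, n_categories: int = 4) -> SubstitutionModel:
    return lg(gamma_shape=gamma_shape, n_categories=n_categories)


# -- CTMC simulation down a tree ----------------------------------------


def _sample_markov(P: np.ndarray, parent_states: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(P, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(parent_states.size)
    return (u[:, None] > cum[parent_states]).sum(axis=1).astype(np.int64)


def simulate_on_tree(tree: dendropy.Tree, n_sites: int, model: SubstitutionModel,
                     seed: int = 0, frequency_overrides: list | None = None) -> Alignment:
    """Simulate ``n_sites`` characters down ``tree`` under ``model``.

    Per-site rates are drawn uniformly from the model's discrete-gamma
    categories.  ``frequency_overrides`` is a list of ``(taxa, freqs)``
    pairs: all edges in the subtree spanned by ``taxa`` (their MRCA and
    below) evolve under the model rebuilt with the override frequencies,
    inducing non-stationary, lineage-heterogeneous composition.
    """
    rng = np.random.default_rng(seed)
    tree.is_rooted = True  # simulation always descends from the seed node
    edge_model = {}
    if frequency_overrides:
        for taxa, freqs in frequency_overrides:
            sub = model.with_frequencies(np.asarray(freqs, dtype=float))
            if len(taxa) == 1:
                nodes = [tree.find_node_with_taxon_label(taxa[0])]
                if nodes[0] is None:
                    raise ValueError(f"override taxon {taxa[0]!r} not in tree")
            else:
                mrca = tree.mrca(taxon_labels=list(taxa))
                if mrca is None:
                    raise ValueError(f"override taxa {list(taxa)} not all in tree")
                nodes = list(mrca.preorder_iter())
            for nd in nodes:
                for child in nd.preorder_iter():
                    edge_model[id(child)] = sub

    cats = rng.integers(model.n_categories, size=n_sites)
    root = tree.seed_node
    states = {id(root): rng.choice(model.k, size=n_sites, p=model.frequencies)}
    leaves = {}
    for nd in tree.preorder_node_iter():
        if nd is root:
            continue
        m = edge_model.get(id(nd), model)
        t = nd.edge.length or 0.0
        parent = states[id(nd.parent_node)]
        child = np.empty(n_sites, dtype=np.int64)
        for c, rate in enumerate(m.category_rates):
            sel = cats == c
            if sel.any():
                P = m.transition_matrix(t, rate)
                child[sel] = _sample_markov(P, parent[sel], rng)
        states[id(nd)] = child
        if nd.is_leaf():
            leaves[nd.taxon.label] = child
    chars = np.array(list(states_for(model.alphabet)), dtype="U1")
    taxa = [lf.taxon.label for lf in tree.leaf_node_iter()]
    matrix = np.stack([chars[leaves[t]] for t in taxa])
    return Alignment(taxa, matrix, model.alphabet)


# -- trees ---------------------------------------------------------------


def four_cluster_tree(group_sizes, internal_branch: float = 0.3,
                      stem_branch: float = 0.1, tip_branch: float = 0.1,
                      within_branch: float = 0.02,
                      group_names=("g1", "g2", "g3", "g4")):
    """A tree of four monophyletic clusters, ((g1,g2),(g3,g4)), with the
    central internal branch of the stated length.

    Returns ``(tree, TaxonGroupConfig)``; taxa are named
    ``<group>_<index>``.  With ``internal_branch=0`` the central split is
    a hard polytomy-equivalent (zero-length branch): star signal.
    """
    def clade(name, size):
        tips = [f"{name}_{i + 1:03d}" for i in range(size)]
        if size == 1:
            return f"{tips[0]}:{stem_branch + tip_branch:g}", tips
        sub = f"({tips[0]}:{tip_branch:g},{tips[1]}:{tip_branch:g})"
        for t in tips[2:]:
            sub = f"({sub}:{within_branch:g},{t}:{tip_branch:g})"
        return f"{sub}:{stem_branch:g}", tips

    newicks, groups = [], {}
    for name, size in zip(group_names, group_sizes):
        nwk, tips = clade(name, size)
        newicks.append(nwk)
        groups[name] = tips
    half = internal_branch / 2.0
    s = (f"(({newicks[0]},{newicks[1]}):{half:g},"
         f"({newicks[2]},{newicks[3]}):{half:g});")
    tree = dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True)
    return tree, TaxonGroupConfig(groups=groups, purpose="fclm_hypothesis")


def two_taxon_tree(branch_length: float = 0.5):
    s = f"(A:{branch_length / 2:g},B:{branch_length / 2:g});"
    return dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True)


# -- study-shaped gene sets ---------------------------------------------


@dataclass
class SimulationConfig:
    """Shape of a synthetic gene set.

    ``occupancy`` is the probability that a (taxon, gene) pair carries
    sequence (whole-gene dropout otherwise), emulating the block-structured
    missingness of target-enrichment supermatrices.  ``mask_fraction`` is
    the fraction of aa columns flagged ambiguously aligned.  Domain
    annotations are drawn from a shared pool so the same domain recurs
    across genes and pools into cross-gene data blocks.
    """

    tree: dendropy.Tree = None
    n_genes: int = 3
    gene_length_range: tuple = (60, 120)  # aa columns
    nt_model: SubstitutionModel = None
    aa_model: SubstitutionModel = None
    lineage_frequency_overrides_nt: list = field(default_factory=list)
    lineage_frequency_overrides_aa: list = field(default_factory=list)
    occupancy: float = 0.8
    mask_fraction: float = 0.1
    domains_per_gene: float = 1.5
    domain_length_range: tuple = (20, 40)  # aa columns
    domain_pool_size: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.nt_model is None:
            self.nt_model = default_nt_model()
        if self.aa_model is None:
            self.aa_model = default_aa_model()
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError("occupancy must be a probability")
        if not (0.0 <= self.mask_fraction < 1.0):
            raise ValueError("mask_fraction must be in [0, 1)")


def simulate_gene_set(config: SimulationConfig):
    """Simulate per-gene records plus the generating tree.

    Returns ``(genes, tree)`` where each :class:`GeneRecord` carries
    codon-consistent aa and nt alignments (independent tracks, 3:1 column
    bookkeeping), whole-gene taxon dropout, a random aa column mask, and
    domain annotations.
    """
    if config.tree is None:
        raise ValueError("SimulationConfig.tree is required")
    rng = np.random.default_rng(config.seed)
    taxa = [lf.taxon.label for lf in config.tree.leaf_node_iter()]
    genes = []
    for g in range(config.n_genes):
        n_aa = int(rng.integers(config.gene_length_range[0],
                                config.gene_length_range[1] + 1))
        aa = simulate_on_tree(config.tree, n_aa, config.aa_model,
                              seed=int(rng.integers(2**31)),
                              frequency_overrides=config.lineage_frequency_overrides_aa)
        nt = simulate_on_tree(config.tree, 3 * n_aa, config.nt_model,
                              seed=int(rng.integers(2**31)),
                              frequency_overrides=config.lineage_frequency_overrides_nt)
        # whole-gene dropout per taxon
        drop = rng.random(len(taxa)) > config.occupancy
        if drop.all():
            drop[rng.integers(len(taxa))] = False  # keep genes non-empty
        aa_m, nt_m = aa.matrix.copy(), nt.matrix.copy()
        aa_m[drop, :] = "-"
        nt_m[drop, :] = "-"
        aa = Alignment(aa.taxa, aa_m, "amino_acid")
        nt = Alignment(nt.taxa, nt_m, "nucleotide")
        n_masked = int(round(config.mask_fraction * n_aa))
        mask = set(map(int, rng.choice(n_aa, size=n_masked, replace=False)))
        domains = _draw_domains(rng, n_aa, config)
        genes.append(GeneRecord(gene_id=f"gene_{g + 1:03d}", aa_alignment=aa,
                                nt_alignment=nt, mask=mask, domains=domains))
    return genes, config.tree


def _draw_domains(rng, n_aa, config):
    n_domains = min(rng.poisson(config.domains_per_gene), 3)
    domains, cursor = [], 0
    for _ in range(n_domains):
        length = int(rng.integers(config.domain_length_range[0],
                                  config.domain_length_range[1] + 1))
        if cursor + length > n_aa:
            break
        start = int(rng.integers(cursor, n_aa - length + 1))
        pf = f"PF{rng.integers(config.domain_pool_size) + 1:04d}"
        domains.append((pf, (start, start + length)))
        cursor = start + length
    return domains


# -- fixtures ------------------------------------------------------------

FIXTURE_SHAPES = {
    "tiny": dict(group_sizes=(2, 2, 2, 2), n_genes=3, gene_length_range=(40, 80)),
    "small": dict(group_sizes=(4, 6, 6, 8), n_genes=20, gene_length_range=(60, 120)),
    # group sizes mirror the study's first hypothesis: 2 wasp species, a
    # 5-species clade, 42 bee-like species, and the remaining taxa
    "paper_shaped": dict(group_sizes=(2, 5, 42, 134), n_genes=195,
                         gene_length_range=(30, 60)),
}
FIXTURE_GROUP_NAMES = ("ammoplanina", "psenini_odontosphecini", "anthophila", "remaining")


def make_fixture(size: str, out_dir, seed: int = 0, internal_branch: float = 0.3):
    """Write a complete, self-consistent input directory: per-gene FASTA
    pairs, mask files, a domain TSV, a groups JSON and the true tree."""
    if size not in FIXTURE_SHAPES:
        raise ValueError(f"unknown fixture size {size!r}; choose from {sorted(FIXTURE_SHAPES)}")
    shape = FIXTURE_SHAPES[size]
    tree, groups = four_cluster_tree(shape["group_sizes"],
                                     internal_branch=internal_branch,
                                     group_names=FIXTURE_GROUP_NAMES)
    config = SimulationConfig(tree=tree, n_genes=shape["n_genes"],
                              gene_length_range=shape["gene_length_range"], seed=seed)
    genes, _ = simulate_gene_set(config)
    os.makedirs(out_dir, exist_ok=True)
    dom_rows = []
    for gene in genes:
        write_alignment(gene.aa_alignment, os.path.join(out_dir, f"{gene.gene_id}.aa.fasta"))
        write_alignment(gene.nt_alignment, os.path.join(out_dir, f"{gene.gene_id}.nt.fasta"))
        with open(os.path.join(out_dir, f"{gene.gene_id}.mask.txt"), "w") as fh:
            for c in sorted(gene.mask):
                fh.write(f"{c}\n")
        for d, (a, b) in gene.domains:
            dom_rows.append((gene.gene_id, d, a, b))
    with open(os.path.join(out_dir, "domains.tsv"), "w") as fh:
        fh.write("gene_id\tdomain_id\tstart\tend\n")
        for row in dom_rows:
            fh.write("\t".join(map(str, row)) + "\n")
    groups.to_json(os.path.join(out_dir, "groups.json"))
    write_newick(tree, os.path.join(out_dir, "tree.nwk"))
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump({"size": size, "seed": seed, "n_genes": config.n_genes,
                   "internal_branch": internal_branch}, fh, indent=1)
    return genes, groups, tree


def load_fixture(in_dir):
    """Read a fixture directory back into GeneRecords + groups + tree."""
    from .io import read_alignment, read_newick

    genes = []
    names = sorted(f[:-9] for f in os.listdir(in_dir) if f.endswith(".aa.fasta"))
    domains = {}
    with open(os.path.join(in_dir, "domains.tsv")) as fh:
        next(fh)
        for line in fh:
            gene_id, d, a, b = line.split("\t")
            domains.setdefault(gene_id, []).append((d, (int(a), int(b))))
    for name in names:
        aa = read_alignment(os.path.join(in_dir, f"{name}.aa.fasta"), "amino_acid")
        nt = read_alignment(os.path.join(in_dir, f"{name}.nt.fasta"), "nucleotide")
        with open(os.path.join(in_dir, f"{name}.mask.txt")) as fh:
            mask = {int(x) for x in fh.read().split()}
        genes.append(GeneRecord(gene_id=name, aa_alignment=aa, nt_alignment=nt,
                                mask=mask, domains=domains.get(name, [])))
    groups = TaxonGroupConfig.from_json(os.path.join(in_dir, "groups.json"))
    tree = read_newick(os.path.join(in_dir, "tree.nwk"))
    return genes, groups, tree
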