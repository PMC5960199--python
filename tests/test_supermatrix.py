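"""Data-block assembly, filtering, concatenation, codon partition schemes
and MCMC sample bookkeeping."""
import numpy as np
import pytest

from phylodiag.core import Alignment, TaxonGroupConfig
from phylodiag.supermatrix import (Block, GeneRecord, RequiredGroupsRule, aa_scheme,
                                   build_blocks, concatenate,
                                   drop_uninformative_blocks, emit_codon_scheme,
                                   filter_required_groups, mcmc_sample_budget)


def _gene(gene_id="g1", taxa=("a", "b", "c", "d"), n_aa=10, mask=(), domains=(),
          aa_rows=None, nt_rows=None):
    taxa = list(taxa)
    aa = Alignment(taxa, aa_rows or ["M" * n_aa] * len(taxa), "amino_acid")
    nt = Alignment(taxa, nt_rows or ["ATG" * n_aa] * len(taxa), "nucleotide")
    return GeneRecord(gene_id=gene_id, aa_alignment=aa, nt_alignment=nt,
                      mask=set(mask), domains=list(domains))


class TestGeneRecord:
    def test_nt_must_be_three_times_aa(self):
        aa = Alignment(["a"], ["MK"], "amino_acid")
        nt = Alignment(["a"], ["ATGAA"], "nucleotide")
        with pytest.raises(ValueError, match="3 x aa"):
            GeneRecord(gene_id="g", aa_alignment=aa, nt_alignment=nt)

    def test_overlapping_domains_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            _gene(domains=[("PF1", (0, 6)), ("PF2", (4, 9))])


class TestBuildBlocks:
    def test_single_gene_no_domains(self):
        blocks = build_blocks([_gene(n_aa=10)], level="aa")
        assert len(blocks) == 1
        assert blocks[0].name == "g1_rest"
        assert blocks[0].alignment.n_columns == 10
        nt_blocks = build_blocks([_gene(n_aa=10)], level="nt")
        assert nt_blocks[0].alignment.n_columns == 30
        assert nt_blocks[0].frame_offset == 0

    def test_full_mask_yields_no_blocks(self):
        assert build_blocks([_gene(n_aa=5, mask=range(5))]) == []

    def test_masked_codons_removed_on_nt_level(self):
        blocks = build_blocks([_gene(n_aa=10, mask={0, 5})], level="nt")
        assert blocks[0].alignment.n_columns == 24

    def test_domains_pool_across_genes(self):
        g1 = _gene("g1", n_aa=10, domains=[("PF_A", (0, 4))])
        g2 = _gene("g2", n_aa=8, domains=[("PF_A", (2, 6))])
        blocks = build_blocks([g1, g2], level="aa")
        names = {b.name for b in blocks}
        assert names == {"PF_A", "g1_rest", "g2_rest"}
        pf = next(b for b in blocks if b.name == "PF_A")
        assert pf.alignment.n_columns == 8  # 4 from each gene
        assert pf.gene_ids == ["g1", "g2"]


class TestFilters:
    def test_fewer_than_four_taxa_removed(self):
        b = Block("b", Alignment(["a", "b", "c"], ["MK", "MR", "MK"], "amino_acid"),
                  ["g"])
        assert drop_uninformative_blocks([b]) == []

    def test_constant_block_removed(self):
        b = Block("b", Alignment(list("abcd"), ["MMMM"] * 4, "amino_acid"), ["g"])
        assert drop_uninformative_blocks([b]) == []

    def test_parsimony_informative_column_kept(self):
        b = Block("b", Alignment(list("abcd"), ["A", "A", "C", "C"], "nucleotide"),
                  ["g"])
        assert drop_uninformative_blocks([b]) == [b]

    def test_required_group_missing_removes_block(self):
        rule = RequiredGroupsRule(TaxonGroupConfig(
            groups={"left": ["a", "b"], "right": ["x"]}, purpose="block_filter"))
        b = Block("b", Alignment(["a", "b"], ["AC", "AC"], "nucleotide"), ["g"])
        assert filter_required_groups([b], rule) == []

    def test_gapped_member_does_not_represent_group(self):
        rule = RequiredGroupsRule(TaxonGroupConfig(
            groups={"left": ["a"], "right": ["x"]}, purpose="block_filter"))
        b_gapped = Block("b", Alignment(["a", "x"], ["AC", "--"], "nucleotide"), ["g"])
        b_ok = Block("b2", Alignment(["a", "x"], ["AC", "A-"], "nucleotide"), ["g"])
        assert filter_required_groups([b_gapped, b_ok], rule) == [b_ok]

    def test_filter_order_insensitive(self, tiny_gene_set):
        genes, groups, _ = tiny_gene_set
        rule = RequiredGroupsRule(TaxonGroupConfig(
            groups={k: v for k, v in groups.groups.items()}, purpose="block_filter"))
        blocks = build_blocks(genes, level="aa")
        ab = filter_required_groups(drop_uninformative_blocks(blocks), rule)
        ba = drop_uninformative_blocks(filter_required_groups(blocks, rule))
        assert [b.name for b in ab] == [b.name for b in ba]


class TestConcatenate:
    def test_lengths_and_ranges(self):
        b1 = Block("x", Alignment(["a", "b"], ["AC" * 5, "GT" * 5], "nucleotide"), ["g"])
        b2 = Block("y", Alignment(["a", "b"], ["A" * 20, "C" * 20], "nucleotide"), ["g"])
        matrix, dbs = concatenate([b1, b2])
        assert matrix.n_columns == 30
        assert [db.ranges for db in dbs] == [[(0, 10)], [(10, 30)]]

    def test_absent_taxon_filled_missing(self):
        b1 = Block("x", Alignment(["a", "b"], ["ACGT", "ACGT"], "nucleotide"), ["g"])
        b2 = Block("y", Alignment(["a", "c"], ["AAAA", "CCCC"], "nucleotide"), ["g"])
        matrix, _ = concatenate([b1, b2])
        assert "".join(matrix.row("b")) == "ACGT----"
        assert "".join(matrix.row("c")) == "----CCCC"

    def test_single_block_identity(self):
        aln = Alignment(["a", "b"], ["ACGT", "TTAA"], "nucleotide")
        matrix, dbs = concatenate([Block("only", aln, ["g"])])
        assert matrix == aln and dbs[0].ranges == [(0, 4)]

    def test_slice_concat_round_trip(self, tiny_gene_set):
        genes, _, _ = tiny_gene_set
        blocks = build_blocks(genes, level="aa")
        matrix, dbs = concatenate(blocks)
        blocks = sorted(blocks, key=lambda b: b.name)
        for block, db in zip(blocks, dbs):
            sliced = matrix.take_columns(db.columns()).take_taxa(block.alignment.taxa)
            assert np.array_equal(sliced.matrix, block.alignment.matrix)

    def test_mixed_alphabets_rejected(self):
        b1 = Block("x", Alignment(["a"], ["ACGT"], "nucleotide"), ["g"])
        b2 = Block("y", Alignment(["a"], ["MKLV"], "amino_acid"), ["g"])
        with pytest.raises(ValueError, match="alphabet"):
            concatenate([b1, b2])


class TestCodonSchemes:
    def _nt_blocks(self, lengths=(9,)):
        blocks = []
        for i, n in enumerate(lengths):
            aln = Alignment(["a", "b"], ["ACG" * (n // 3)] * 2, "nucleotide")
            blocks.append(Block(f"b{i}", aln, ["g"], frame_offset=0))
        return concatenate(blocks)

    def test_nt123_stride_partitions(self):
        _, dbs = self._nt_blocks((9,))
        scheme = emit_codon_scheme(dbs, "NT123")
        cols = {name: c.tolist() for name, c in scheme.partitions}
        assert cols == {"b0_pos1": [0, 3, 6], "b0_pos2": [1, 4, 7], "b0_pos3": [2, 5, 8]}

    def test_nt12_drops_third_positions(self):
        _, dbs = self._nt_blocks((9,))
        scheme = emit_codon_scheme(dbs, "NT12")
        universe = scheme.column_universe().tolist()
        assert universe == [0, 1, 3, 4, 6, 7]

    def test_nt12_is_two_thirds_of_nt123(self):
        _, dbs = self._nt_blocks((9, 12, 30))
        n123 = emit_codon_scheme(dbs, "NT123").column_universe().size
        n12 = emit_codon_scheme(dbs, "NT12").column_universe().size
        assert n12 * 3 == n123 * 2

    def test_nt123_tiles_supermatrix(self):
        matrix, dbs = self._nt_blocks((9, 12))
        universe = emit_codon_scheme(dbs, "NT123").column_universe()
        assert universe.tolist() == list(range(matrix.n_columns))

    def test_missing_frame_metadata_rejected(self):
        aln = Alignment(["a"], ["MKL"], "amino_acid")
        _, dbs = concatenate([Block("x", aln, ["g"])])
        with pytest.raises(ValueError, match="frame"):
            emit_codon_scheme(dbs, "NT123")

    def test_aa_scheme_one_partition_per_block(self, tiny_gene_set):
        genes, _, _ = tiny_gene_set
        matrix, dbs = concatenate(build_blocks(genes, level="aa"))
        scheme = aa_scheme(dbs)
        assert len(scheme.partitions) == len(dbs)
        assert scheme.column_universe().tolist() == list(range(matrix.n_columns))


class TestMcmcBudget:
    def test_three_runs_three_million_generations(self):
        """Three independent MCMC runs of 3M generations sampled every 500
        with 25% burn-in retain 13,500 trees."""
        assert mcmc_sample_budget(3, 3_000_000, 500, 0.25) == 13_500

    @pytest.mark.parametrize("args,expected", [
        ((1, 1000, 100, 0.0), 10),
        ((2, 1000, 100, 0.5), 10),
    ])
    def test_small_budgets(self, args, expected):
        assert mcmc_sample_budget(*args) == expected

    def test_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divisible"):
            mcmc_sample_budget(1, 1001, 100, 0.0)

    def test_burnin_bounds(self):
        with pytest.raises(ValueError):
            mcmc_sample_budget(1, 1000, 100, 1.0)
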