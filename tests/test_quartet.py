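"""Quartet likelihood engine: pruning vs brute-force enumeration, branch
optimization, and topology weights."""
import numpy as np
import pytest

from phylodiag.core import Alignment
from phylodiag.models import gtr, jc, lg, random_gtr
from phylodiag.quartet import (TOPOLOGIES, TOPOLOGY_SPLITS, QuartetData,
                               evaluate_quartet, optimize_quartet, quartet_loglik,
                               topology_weights)
from phylodiag.simulate import default_nt_model, four_cluster_tree, simulate_on_tree


def brute_force_loglik(codes, topology, model, branch_lengths):
    """Independent oracle: direct summation over the 16 (or 400)
    internal-state pairs for every site, averaged over gamma categories."""
    (i, j), (k, l) = TOPOLOGY_SPLITS[topology]
    b = branch_lengths
    total = 0.0
    for site in codes.T:
        site_like = 0.0
        for rate in model.category_rates:
            P = [model.transition_matrix(b[m], rate) for m in range(4)]
            P5 = model.transition_matrix(b[4], rate)
            s = 0.0
            for x in range(model.k):
                for y in range(model.k):
                    term = model.frequencies[x] * P5[x, y]
                    for leaf, node in ((i, x), (j, x), (k, y), (l, y)):
                        if site[leaf] >= 0:
                            term *= P[leaf][node, site[leaf]]
                    s += term
            site_like += s / model.n_categories
        total += np.log(site_like)
    return total


def _alignment_from_codes(codes, alphabet="nucleotide"):
    from phylodiag.core import states_for
    chars = np.array(list(states_for(alphabet)), dtype="U1")
    m = np.where(codes >= 0, chars[np.clip(codes, 0, None)], "-")
    return Alignment(["a", "b", "c", "d"], m, alphabet)


def _qdata(aln, model):
    n = aln.n_columns
    return QuartetData.from_alignment(aln, aln.taxa,
                                      [("p1", np.arange(n))], {"p1": model})


class TestPruningVsBruteForce:
    def test_single_pattern_jc_fixed_branches(self):
        """Site pattern AACC under JC: pruning equals the 16-term sum."""
        codes = np.array([[0], [0], [1], [1]])
        model = jc()
        aln = _alignment_from_codes(codes)
        b = np.array([0.1, 0.2, 0.3, 0.1, 0.5])
        for topo in TOPOLOGIES:
            expected = brute_force_loglik(codes, topo, model, b)
            assert quartet_loglik(_qdata(aln, model), topo, b) == pytest.approx(
                expected, abs=1e-10)

    @pytest.mark.parametrize("gamma_cats", [1, 4])
    def test_random_gtr_draws(self, rng, gamma_cats):
        for _ in range(10):
            model = random_gtr(rng, gamma_shape=rng.uniform(0.3, 2.0),
                               n_categories=gamma_cats)
            codes = rng.integers(-1, 4, size=(4, 6))
            keep = (codes >= 0).all(axis=0)
            aln = _alignment_from_codes(codes)
            qd = _qdata(aln, model)
            b = rng.uniform(0.01, 2.0, size=5)
            topo = TOPOLOGIES[rng.integers(3)]
            # the engine drops columns where any taxon is missing
            expected = brute_force_loglik(codes[:, keep], topo, model, b)
            assert quartet_loglik(qd, topo, b) == pytest.approx(expected, abs=1e-10)

    def test_amino_acid_lg(self, rng):
        model = lg(gamma_shape=0.8, n_categories=2)
        codes = rng.integers(0, 20, size=(4, 3))
        aln = _alignment_from_codes(codes, "amino_acid")
        b = np.array([0.2, 0.1, 0.4, 0.3, 0.2])
        expected = brute_force_loglik(codes, "T2", model, b)
        assert quartet_loglik(_qdata(aln, model), "T2", b) == pytest.approx(
            expected, abs=1e-10)


class TestQuartetLoglik:
    def test_identical_sequences_topology_symmetric(self):
        aln = Alignment(["a", "b", "c", "d"], ["ACGTAC"] * 4, "nucleotide")
        qd = _qdata(aln, jc())
        b = np.full(5, 0.1)
        lnls = [quartet_loglik(qd, t, b) for t in TOPOLOGIES]
        assert lnls[0] == pytest.approx(lnls[1]) == pytest.approx(lnls[2])

    def test_all_branches_zero_single_site(self):
        model = jc()
        aln = Alignment(["a", "b", "c", "d"], ["A", "A", "A", "A"], "nucleotide")
        lnl = quartet_loglik(_qdata(aln, model), "T1", np.zeros(5))
        assert lnl == pytest.approx(np.log(0.25), abs=1e-10)

    def test_impossible_column_at_zero_branches_is_floored(self):
        aln = Alignment(["a", "b", "c", "d"], ["A", "A", "A", "C"], "nucleotide")
        lnl = quartet_loglik(_qdata(aln, jc()), "T1", np.zeros(5))
        assert np.isfinite(lnl) and lnl < -30  # underflow-protected log

    def test_doubling_alignment_doubles_loglik(self, rng):
        model = random_gtr(rng)
        codes = rng.integers(0, 4, size=(4, 50))
        aln1 = _alignment_from_codes(codes)
        aln2 = _alignment_from_codes(np.hstack([codes, codes]))
        b = rng.uniform(0.05, 1.0, 5)
        l1 = quartet_loglik(_qdata(aln1, model), "T1", b)
        l2 = quartet_loglik(_qdata(aln2, model), "T1", b)
        assert l2 == pytest.approx(2 * l1, rel=1e-12)

    def test_negative_branch_rejected(self, tiny_nt_alignment):
        qd = _qdata(tiny_nt_alignment, jc())
        with pytest.raises(ValueError):
            quartet_loglik(qd, "T1", [-0.1, 0.1, 0.1, 0.1, 0.1])

    def test_partition_additivity(self, rng):
        """Two partitions with different models sum their contributions."""
        m1, m2 = random_gtr(rng), random_gtr(rng)
        codes = rng.integers(0, 4, size=(4, 40))
        aln = _alignment_from_codes(codes)
        b = rng.uniform(0.05, 1.0, 5)
        qd_both = QuartetData.from_alignment(
            aln, aln.taxa, [("p1", np.arange(20)), ("p2", np.arange(20, 40))],
            {"p1": m1, "p2": m2})
        la = quartet_loglik(QuartetData.from_alignment(
            aln, aln.taxa, [("p1", np.arange(20))], {"p1": m1}), "T3", b)
        lb = quartet_loglik(QuartetData.from_alignment(
            aln, aln.taxa, [("p2", np.arange(20, 40))], {"p2": m2}), "T3", b)
        assert quartet_loglik(qd_both, "T3", b) == pytest.approx(la + lb, rel=1e-12)


class TestOptimize:
    def test_recovers_generating_topology(self):
        tree, _ = four_cluster_tree((1, 1, 1, 1), internal_branch=0.5)
        aln = simulate_on_tree(tree, 5000, default_nt_model(), seed=42)
        qd = _qdata(aln, default_nt_model())
        lnls = {t: optimize_quartet(qd, t)[0] for t in TOPOLOGIES}
        assert lnls["T1"] > lnls["T2"] and lnls["T1"] > lnls["T3"]

    def test_identical_sequences_shrink_branches(self):
        aln = Alignment(["a", "b", "c", "d"], ["ACGTACGTAC"] * 4, "nucleotide")
        _, b, _ = optimize_quartet(_qdata(aln, jc()), "T1")
        assert (b < 1e-5).all()

    def test_optimum_consistent_with_reference_loglik(self, rng):
        model = random_gtr(rng)
        codes = rng.integers(0, 4, size=(4, 100))
        qd = _qdata(_alignment_from_codes(codes), model)
        lnl, b, _ = optimize_quartet(qd, "T2")
        assert lnl == pytest.approx(quartet_loglik(qd, "T2", b), abs=1e-9)

    def test_undetermined_quartet_rejected(self):
        aln = Alignment(["a", "b", "c", "d"], ["----", "AAAA", "CCCC", "GGGG"],
                        "nucleotide")
        qd = _qdata(aln, jc())
        assert not qd.is_determined
        with pytest.raises(ValueError, match="undetermined"):
            optimize_quartet(qd, "T1")


class TestTopologyWeights:
    def test_equal_logliks_give_uniform(self):
        assert topology_weights(-5.0, -5.0, -5.0) == pytest.approx((1 / 3,) * 3)

    def test_dominant_topology(self):
        w = topology_weights(0.0, -1e9, -1e9)
        assert w[0] == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_log2(self):
        w = topology_weights(np.log(2.0), 0.0, 0.0)
        assert w == pytest.approx((0.5, 0.25, 0.25), abs=1e-12)

    def test_shift_invariance(self, rng):
        lnl = rng.normal(size=3) * 10
        assert topology_weights(*lnl) == pytest.approx(
            topology_weights(*(lnl + 1234.5)), abs=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            topology_weights(np.nan, 0.0, 0.0)

    def test_leaf_relabeling_permutes_weights(self):
        """Swapping taxa 2 and 3 maps T1=(12|34) to T2=(13|24): weights
        follow."""
        tree, _ = four_cluster_tree((1, 1, 1, 1), internal_branch=0.4)
        aln = simulate_on_tree(tree, 2000, default_nt_model(), seed=9)
        model = default_nt_model()
        qd1 = QuartetData.from_alignment(aln, aln.taxa,
                                         [("p1", np.arange(2000))], {"p1": model})
        swapped = [aln.taxa[0], aln.taxa[2], aln.taxa[1], aln.taxa[3]]
        qd2 = QuartetData.from_alignment(aln, swapped,
                                         [("p1", np.arange(2000))], {"p1": model})
        w1 = evaluate_quartet(qd1).weights
        w2 = evaluate_quartet(qd2).weights
        assert w1[0] == pytest.approx(w2[1], abs=1e-6)
        assert w1[1] == pytest.approx(w2[0], abs=1e-6)
        assert w1[2] == pytest.approx(w2[2], abs=1e-6)
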