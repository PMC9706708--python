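"""Parsimony, information loss, NJ and saturation statistics."""

import itertools

import numpy as np
import pytest

import phylorecode as pr
from _oracles import enumerate_topologies
from phylorecode.treestats import (branch_loss_map, fitch_length,
                                   information_loss, nj_tree,
                                   p_distance_matrix, parsimony_search,
                                   patristic, persite_substitutions,
                                   saturation_index)


class TestFitch:
    def test_single_difference(self, aa_alphabet):
        aln = pr.Alignment(["a", "b"], np.array([list("A"), list("C")]),
                           aa_alphabet)
        tree = pr.Tree([-1, 0, 0], [0.0, 1.0, 1.0], [None, "a", "b"])
        assert fitch_length(aln, tree) == 1

    def test_quartet_split_dependence(self, aa_alphabet):
        aln = pr.Alignment(["1", "2", "3", "4"],
                           np.array([["A"], ["A"], ["C"], ["C"]]), aa_alphabet)
        t12 = pr.Tree.from_newick("((1:1,2:1):1,(3:1,4:1):1);")
        t13 = pr.Tree.from_newick("((1:1,3:1):1,(2:1,4:1):1);")
        assert fitch_length(aln, t12) == 1
        assert fitch_length(aln, t13) == 2

    def test_constant_alignment_zero(self, aa_alphabet):
        aln = pr.Alignment(["a", "b", "c", "d"],
                           np.tile(np.array(list("AR")), (4, 5)), aa_alphabet)
        tree = pr.zone_tree(pr.ZoneTreeSpec(n_taxa=4))
        relabel = dict(zip(["OUT_1", "CTE_1", "POR_1", "BIL_1"],
                           ["a", "b", "c", "d"]))
        tree.label = [relabel.get(l) if l else None for l in tree.label]
        assert fitch_length(aln, tree) == 0

    def test_missing_data_is_free(self, aa_alphabet):
        aln = pr.Alignment(["a", "b", "c", "d"],
                           np.array([["A"], ["-"], ["C"], ["C"]]), aa_alphabet)
        tree = pr.Tree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        assert fitch_length(aln, tree) == 1

    def test_matches_exhaustive_minimum_on_small_trees(self):
        gen = pr.default_study_model(2, 5)
        true_tree = pr.Tree.from_newick(
            "(((A:0.2,B:0.4):0.2,(C:0.3,D:0.2):0.1):0.1,(E:0.5,F:0.2):0.2);")
        aln = pr.simulate_alignment(true_tree, gen, 60, 3)
        best_len = min(fitch_length(aln, t)
                       for t in enumerate_topologies(aln.taxa))
        res = parsimony_search(aln, n_random_additions=5, rng_seed=0)
        assert res.length == best_len


class TestParsimonySearch:
    def test_length_bounded_by_any_topology(self, study_model):
        tree = pr.zone_tree(pr.ZoneTreeSpec(n_taxa=10))
        aln = pr.simulate_alignment(tree, study_model, 100, 2)
        res = parsimony_search(aln, n_random_additions=3, rng_seed=1)
        assert res.length <= fitch_length(aln, tree)

    def test_more_additions_never_worse(self, study_model):
        tree = pr.zone_tree(pr.ZoneTreeSpec(n_taxa=10))
        aln = pr.simulate_alignment(tree, study_model, 80, 4)
        l1 = parsimony_search(aln, n_random_additions=1, rng_seed=3).length
        l5 = parsimony_search(aln, n_random_additions=5, rng_seed=3).length
        assert l5 <= l1

    def test_needs_four_taxa(self, aa_alphabet):
        aln = pr.Alignment(["a", "b", "c"], np.array([["A"], ["C"], ["R"]]),
                           aa_alphabet)
        with pytest.raises(ValueError):
            parsimony_search(aln)

    def test_persite_substitutions(self, aa_alphabet):
        aln = pr.Alignment(["a", "b", "c", "d"],
                           np.tile(np.array(list("AR")), (4, 10)), aa_alphabet)
        assert persite_substitutions(aln, n_random_additions=1) == 0.0


class TestInformationLoss:
    def test_arithmetic(self):
        assert information_loss(100, 51) == pytest.approx(49.0)
        assert information_loss(100, 100) == 0.0
        with pytest.raises(ValueError):
            information_loss(0, 0)

    def test_bounded_for_recoded_data(self, study_model):
        tree = pr.zone_tree(pr.ZoneTreeSpec(n_taxa=10))
        aln = pr.simulate_alignment(tree, study_model, 200, 6)
        rec = pr.apply_recoding(aln, pr.builtin_scheme("dayhoff6"))
        loss = information_loss(fitch_length(aln, tree), fitch_length(rec, tree))
        assert 0.0 <= loss <= 100.0


class TestBranchLossMap:
    def test_identical_alignments_all_zero(self, study_model):
        tree = pr.zone_tree(pr.ZoneTreeSpec(n_taxa=4))
        aln = pr.simulate_alignment(tree, study_model, 100, 7)
        table = branch_loss_map(aln, aln, tree)
        nonzero = table[~table.zero_source]
        assert (nonzero.percent_loss == 0).all()

    def test_step_conservation(self, study_model):
        tree = pr.zone_tree(pr.ZoneTreeSpec(n_taxa=10))
        aln = pr.simulate_alignment(tree, study_model, 150, 8)
        table = branch_loss_map(aln, aln, tree)
        assert table.steps_source.sum() == fitch_length(aln, tree)

    def test_recoded_steps_never_exceed_source(self, study_model):
        tree = pr.zone_tree(pr.ZoneTreeSpec(n_taxa=10))
        aln = pr.simulate_alignment(tree, study_model, 150, 9)
        rec = pr.apply_recoding(aln, pr.builtin_scheme("dayhoff6"))
        table = branch_loss_map(aln, rec, tree)
        assert table.steps_recoded.sum() <= table.steps_source.sum()


class TestDistances:
    def test_p_distance_values(self, aa_alphabet):
        aln = pr.Alignment(["a", "b"], np.array([list("AAAA"), list("AAAC")]),
                           aa_alphabet)
        assert p_distance_matrix(aln)[0, 1] == pytest.approx(0.25)

    def test_identical_rows_zero(self, aa_alphabet):
        aln = pr.Alignment(["a", "b"], np.array([list("ARN"), list("ARN")]),
                           aa_alphabet)
        assert p_distance_matrix(aln)[0, 1] == 0.0

    def test_pairwise_deletion(self, aa_alphabet):
        aln = pr.Alignment(["a", "b"], np.array([list("A-AA"), list("ACAC")]),
                           aa_alphabet)
        assert p_distance_matrix(aln)[0, 1] == pytest.approx(1 / 3)

    def test_no_shared_sites_rejected(self, aa_alphabet):
        aln = pr.Alignment(["a", "b"], np.array([list("A-"), list("-C")]),
                           aa_alphabet)
        with pytest.raises(ValueError):
            p_distance_matrix(aln)


class TestNJ:
    def test_exact_recovery_of_additive_tree(self):
        ref = pr.Tree.from_newick("((A:0.1,B:0.2):0.05,(C:0.1,D:0.3):0.0);")
        taxa = ["A", "B", "C", "D"]
        d = ref.patristic_matrix(taxa)
        out = nj_tree(d, taxa)
        assert out.rf_distance(ref) == 0
        assert np.abs(out.patristic_matrix(taxa) - d).max() < 1e-10

    def test_three_taxa_closed_form(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        out = nj_tree(d, ["a", "b", "c"])
        assert np.abs(out.patristic_matrix(["a", "b", "c"]) - d).max() < 1e-10

    def test_taxon_order_invariance(self):
        ref = pr.Tree.from_newick(
            "((A:0.11,B:0.23):0.07,(C:0.13,(D:0.31,E:0.17):0.06):0.02);")
        taxa = ["A", "B", "C", "D", "E"]
        d = ref.patristic_matrix(taxa)
        t1 = nj_tree(d, taxa)
        perm = [3, 1, 4, 0, 2]
        d2 = d[np.ix_(perm, perm)]
        t2 = nj_tree(d2, [taxa[i] for i in perm])
        assert t1.rf_distance(t2) == 0

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(np.array([[0, 1.0, 1], [2, 0, 1], [1, 1, 0.0]]),
                    ["a", "b", "c"])


class TestSaturation:
    def test_identity_slope(self):
        x = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], float)
        res = saturation_index(x, x)
        assert res.slope == pytest.approx(1.0)
        assert res.sat == pytest.approx(0.0)
        assert res.n_pairs == 3

    def test_forced_arithmetic(self):
        res = saturation_index(np.array([1.0, 2.0]), np.array([0.5, 1.0]))
        assert res.slope == pytest.approx(0.5)
        assert res.sat == pytest.approx(0.5)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            saturation_index(np.zeros(3), np.ones(3))

    def test_saturation_grows_with_branch_lengths(self):
        taxa = None
        sats = []
        for scale in (0.3, 1.0):
            spec = pr.ZoneTreeSpec(long_branch_length=1.0 * scale,
                                   short_branch_length=0.1 * scale,
                                   internal_branch_length=0.2 * scale,
                                   n_taxa=10)
            tree = pr.zone_tree(spec)
            gen = pr.default_study_model(3, 2)
            aln = pr.simulate_alignment(tree, gen, 800, 5)
            taxa = aln.taxa
            njd = patristic(nj_tree(p_distance_matrix(aln), taxa), taxa)
            sats.append(saturation_index(patristic(tree, taxa), njd).sat)
        assert sats[1] > sats[0] > 0.0
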