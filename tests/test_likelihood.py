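"""Pruning likelihoods against exhaustive oracles and closed forms."""

import itertools

import numpy as np
import pytest

import phylorecode as pr
from phylorecode import likelihood as lk
from phylorecode.models import SubstitutionMixtureModel, poisson_exchangeabilities


from _oracles import brute_force_site_likelihoods, random_instance


class TestPruningOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_enumeration(self, seed):
        aln, tree, model = random_instance(seed)
        res = pr.site_likelihoods(aln, tree, model)
        oracle = brute_force_site_likelihoods(aln, tree, model)
        assert np.abs(np.exp(res.per_site_log_likelihoods) - oracle).max() < 1e-10

    def test_numba_kernel_matches_numpy_path(self):
        rng = np.random.default_rng(5)
        model = SubstitutionMixtureModel(
            poisson_exchangeabilities(6), rng.dirichlet(np.ones(6), 3),
            rng.dirichlet(np.ones(3)), alpha=0.7, n_rate_cats=4)
        tree = pr.zone_tree(pr.ZoneTreeSpec(n_taxa=10))
        gen = pr.SubstitutionMixtureModel.poisson(6, alpha=0.8)
        aln = pr.simulate_alignment(tree, gen, 200, 3)
        pats, _, _ = lk._compress(aln)
        rows = lk._leaf_rows(aln, tree)
        fast = lk.per_category_pattern_loglik(pats, tree, rows, model)
        have = lk._HAVE_NUMBA
        try:
            lk._HAVE_NUMBA = False
            slow = lk.per_category_pattern_loglik(pats, tree, rows, model)
        finally:
            lk._HAVE_NUMBA = have
        assert np.abs(fast - slow).max() < 1e-9

    def test_single_leaf_is_stationary_density(self):
        model = SubstitutionMixtureModel.poisson(4, np.array([0.1, 0.2, 0.3, 0.4]),
                                                 n_rate_cats=1)
        tree = pr.Tree([-1, 0], [0.0, 0.5], [None, "x"])
        aln = pr.Alignment(["x"], np.array([list("AD")]), pr.recoded_alphabet(4))
        res = pr.site_likelihoods(aln, tree, model)
        assert np.exp(res.per_site_log_likelihoods[0]) == pytest.approx(0.1)
        assert np.exp(res.per_site_log_likelihoods[1]) == pytest.approx(0.4)

    def test_two_taxon_closed_form(self):
        k, t = 6, 0.4
        model = SubstitutionMixtureModel.poisson(k, n_rate_cats=1)
        tree = pr.Tree([-1, 0, 0], [0.0, t / 2, t / 2], [None, "a", "b"])
        aln = pr.Alignment(["a", "b"], np.array([list("A"), list("A")]),
                           pr.recoded_alphabet(k))
        res = pr.site_likelihoods(aln, tree, model)
        expected = (1 / k) * (1 / k + (1 - 1 / k) * np.exp(-k * t / (k - 1)))
        assert np.exp(res.log_likelihood) == pytest.approx(expected, rel=1e-10)

    def test_total_equals_sum_of_site_values(self, sim_alignment, study_model):
        tree = pr.zone_tree(pr.ZoneTreeSpec(n_taxa=4))
        res = pr.site_likelihoods(sim_alignment, tree, study_model)
        assert res.log_likelihood == pytest.approx(
            float(res.per_site_log_likelihoods.sum()), abs=1e-8)

    def test_rerooting_invariance(self):
        aln, tree, model = random_instance(7, missing=False)
        res1 = pr.site_likelihoods(aln, tree, model)
        # same unrooted tree re-expressed with a different rooting
        alt = pr.Tree.from_newick(
            "(A:0.3,B:0.5,(C:0.7,(D:0.4,E:0.9):0.3):0.2);")
        res2 = pr.site_likelihoods(aln, alt, model)
        assert res1.log_likelihood == pytest.approx(res2.log_likelihood, abs=1e-8)

    def test_column_order_invariance(self):
        aln, tree, model = random_instance(9, n_sites=6)
        res = pr.site_likelihoods(aln, tree, model)
        perm = [3, 0, 5, 1, 4, 2]
        aln2 = aln.subsample_sites(perm)
        res2 = pr.site_likelihoods(aln2, tree, model)
        assert np.allclose(res.per_site_log_likelihoods[perm],
                           res2.per_site_log_likelihoods)

    def test_mismatched_taxa_rejected(self, study_model, sim_alignment):
        bad = pr.Tree.from_newick("((X:1,Y:1):1,(Z:1,W:1):1);")
        with pytest.raises(ValueError):
            pr.site_likelihoods(sim_alignment, bad, study_model)


class TestMLFit:
    def test_identical_sequences_fit_zero_length(self):
        aln = pr.Alignment(["a", "b"],
                           np.array([list("ARNDAR"), list("ARNDAR")]),
                           pr.amino_acid_alphabet())
        topo = pr.Tree([-1, 0, 0], [0.0, 0.1, 0.1], [None, "a", "b"])
        fit = pr.ml_fit(aln, topo, "poisson_g", {"n_rate_cats": 1})
        assert fit.tree.total_length() < 1e-5

    def test_poisson_distance_closed_form(self):
        # fitted distance must equal -(k-1)/k ln(1 - kp/(k-1))
        k, n = 6, 4000
        rng = np.random.default_rng(8)
        s1 = rng.integers(0, k, n)
        s2 = s1.copy()
        flip = rng.random(n) < 0.35
        s2[flip] = (s1[flip] + rng.integers(1, k, int(flip.sum()))) % k
        symbols = np.array(list(pr.recoded_alphabet(k).symbols))
        aln = pr.Alignment(["a", "b"], symbols[np.stack([s1, s2])],
                           pr.recoded_alphabet(k))
        p = float((s1 != s2).mean())
        topo = pr.Tree([-1, 0, 0], [0.0, 0.1, 0.1], [None, "a", "b"])
        fit = pr.ml_fit(aln, topo, "poisson_g", {"n_rate_cats": 1})
        expected = -(k - 1) / k * np.log(1 - k * p / (k - 1))
        assert fit.tree.total_length() == pytest.approx(expected, rel=1e-4)

    def test_em_never_decreases_loglik(self):
        tree = pr.zone_tree(pr.ZoneTreeSpec(n_taxa=4))
        gen = pr.default_study_model(4, 3)
        aln = pr.simulate_alignment(tree, gen, 400, 2)
        lls = []
        for rounds in (1, 2, 4):
            fit = pr.ml_fit(aln, tree, "mix2_g",
                            {"max_rounds": rounds, "n_rate_cats": 2, "seed": 0})
            lls.append(fit.log_likelihood)
        assert lls[0] <= lls[1] + 1e-9 <= lls[2] + 2e-9

    def test_gtr_fit_improves_on_poisson_for_lg_data(self):
        tree = pr.zone_tree(pr.ZoneTreeSpec(n_taxa=4))
        gen = pr.SubstitutionMixtureModel.lg(alpha=1.0, n_rate_cats=1)
        aln = pr.simulate_alignment(tree, gen, 300, 4)
        # 6-state recoding keeps the GTR space small for the test
        rec = pr.apply_recoding(aln, pr.builtin_scheme("dayhoff6"))
        base = pr.ml_fit(rec, tree, "poisson_g",
                         {"n_rate_cats": 1, "freqs": "empirical", "max_rounds": 3})
        gtr = pr.ml_fit(rec, tree, "gtr_g",
                        {"n_rate_cats": 1, "max_rounds": 3})
        assert gtr.log_likelihood >= base.log_likelihood - 1e-6


class TestTopologyScan:
    def test_constant_alignment_gives_equal_likelihood_uniformish_support(self):
        aln = pr.Alignment(["A", "B", "C", "D"],
                           np.tile(np.array(list("R")), (4, 30)),
                           pr.amino_acid_alphabet())
        cands = [pr.zone_tree(pr.ZoneTreeSpec(hypothesis=h, n_taxa=4))
                 for h in ("ctenophora_sister", "porifera_sister")]
        relabel = dict(zip(["OUT_1", "CTE_1", "POR_1", "BIL_1"],
                           ["A", "B", "C", "D"]))
        for t in cands:
            t.label = [relabel.get(l, l) if l else None for l in t.label]
        res = pr.topology_scan(aln, cands, "poisson_g",
                               {"n_rate_cats": 1, "max_rounds": 2},
                               n_bootstrap=60, rng_seed=0)
        assert res["log_likelihoods"][0] == pytest.approx(
            res["log_likelihoods"][1], abs=1e-6)
        assert abs(res["support"][0] - 0.5) < 0.25
        assert res["support"].sum() == pytest.approx(1.0)

    def test_strong_signal_supports_true_topology(self):
        spec = pr.ZoneTreeSpec(hypothesis="ctenophora_sister", n_taxa=4)
        tree = pr.zone_tree(spec)
        gen = pr.default_study_model(3, 6)
        aln = pr.simulate_alignment(tree, gen, 1500, 5)
        cands = [pr.zone_tree(pr.ZoneTreeSpec(hypothesis=h, n_taxa=4))
                 for h in ("ctenophora_sister", "porifera_sister")]
        res = pr.topology_scan(aln, cands, "mix2_g",
                               {"n_rate_cats": 2, "max_rounds": 2, "seed": 0},
                               n_bootstrap=30, rng_seed=1)
        assert res["support"][0] > 0.9

    def test_requires_two_candidates(self, sim_alignment):
        with pytest.raises(ValueError):
            pr.topology_scan(sim_alignment,
                             [pr.zone_tree(pr.ZoneTreeSpec(n_taxa=4))],
                             "poisson_g")
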