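"""Independent oracles shared by the unit and acceptance suites.

These deliberately avoid the package's pruning/search code paths:
likelihoods are brute-force sums over interior-state assignments, and
parsimony optima come from exhaustive topology enumeration.
"""

import itertools

import numpy as np

import phylorecode as pr
from phylorecode.models import SubstitutionMixtureModel
from phylorecode.treestats import _insert_leaf, _star_tree


def brute_force_site_likelihoods(aln, tree, model):
    """Sum over all interior-node state assignments (exponential oracle)."""
    codes = aln.indices()
    leaves = tree.leaf_indices
    internal = [i for i in range(tree.n_nodes) if tree.children[i]]
    rates = model.gamma_rates()
    k = model.k
    lik = np.zeros(aln.n_sites)
    row_of = {tree.label[i]: aln.taxa.index(tree.label[i]) for i in leaves}
    for c in range(model.n_categories):
        pi = model.profiles[c]
        for r in rates:
            pmats = {n: model.transition_matrix(c, float(tree.length[n]) * r)
                     for n in range(1, tree.n_nodes)}
            for s in range(aln.n_sites):
                obs = {i: codes[row_of[tree.label[i]], s] for i in leaves}
                tot = 0.0
                for assign in itertools.product(range(k), repeat=len(internal)):
                    st = dict(zip(internal, assign))
                    for i in leaves:
                        st[i] = obs[i]
                    p = pi[st[0]]
                    for n in range(1, tree.n_nodes):
                        b = st[n]
                        if b < 0:  # missing leaf marginalizes to 1
                            continue
                        p *= pmats[n][st[tree.parent[n]], b]
                    tot += p
                lik[s] += model.weights[c] * tot / len(rates)
    return lik


def enumerate_topologies(taxa):
    """All unrooted binary topologies by sequential leaf insertion."""
    trees = [_star_tree(list(taxa[:3]))]
    for t in taxa[3:]:
        trees = [_insert_leaf(tr, e, t)
                 for tr in trees for e in range(1, tr.n_nodes)]
    return trees


def random_instance(seed, k=4, n_sites=3, n_cats=2, missing=True):
    """A small random mixture-model instance on a fixed 5-leaf tree."""
    rng = np.random.default_rng(seed)
    rho = np.abs(rng.normal(1.0, 0.4, (k, k)))
    rho = (rho + rho.T) / 2
    np.fill_diagonal(rho, 0.0)
    model = SubstitutionMixtureModel(
        rho, rng.dirichlet(np.ones(k) * 2, n_cats), rng.dirichlet(np.ones(n_cats)),
        alpha=float(rng.uniform(0.3, 2.0)), n_rate_cats=2)
    tree = pr.Tree.from_newick("(((A:0.3,B:0.5):0.2,C:0.7):0.1,(D:0.4,E:0.9):0.2);")
    chars = rng.choice(list(pr.recoded_alphabet(k).symbols), size=(5, n_sites))
    if missing:
        chars[rng.random(chars.shape) < 0.2] = "-"
    aln = pr.Alignment(list("ABCDE"), chars, pr.recoded_alphabet(k))
    return aln, tree, model


def brute_force_similarity(a, b):
    """Exhaustive size-respecting bin-correspondence maximization."""
    per_size_a, per_size_b = {}, {}
    for _, m in a.bins:
        per_size_a.setdefault(len(m), []).append(m)
    for _, m in b.bins:
        per_size_b.setdefault(len(m), []).append(m)
    total = 0
    for size, ba in per_size_a.items():
        bb = per_size_b[size]
        best = 0
        for perm in itertools.permutations(range(len(bb))):
            best = max(best, sum(len(ba[i] & bb[perm[i]]) for i in range(len(ba))))
        total += best
    return 100.0 * total / 20.0
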