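"""Mixture-model likelihoods by pruning, and fixed-topology ML fitting.

Per-site likelihoods are computed by Felsenstein's post-order pruning,
summed over profile categories and discrete-Gamma rate classes:

    L_s = sum_c w_c * (1/G) * sum_g L(x_s | tree, Q_c, r_g)

Columns are compressed to unique site patterns before traversal, and an
O(S k) fast path is used for equal-exchangeability (Poisson/F81-type)
categories, for which P(t) = e^{-bt} I + (1 - e^{-bt}) 1 pi^T.

``ml_fit`` optimizes branch lengths, the Gamma shape, and family-specific
free parameters (GTR exchangeabilities; mixture profiles and weights via
a guarded generalized-EM step) by coordinate ascent; every update is
accepted only if it improves the log-likelihood, so the trajectory is
monotone by construction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .core import Alignment, Tree
from .models import (SubstitutionMixtureModel, lg_model_data,
                     poisson_exchangeabilities)

__all__ = ["LikelihoodResult", "site_likelihoods", "ml_fit", "topology_scan"]

_MIN_BRANCH = 1e-9
_MAX_BRANCH = 30.0


@dataclass
class LikelihoodResult:
    log_likelihood: float
    per_site_log_likelihoods: np.ndarray
    model: SubstitutionMixtureModel | None = None
    tree: Tree | None = None
    converged: bool = True
    n_iterations: int = 0


# ---------------------------------------------------------------------
# pattern compression and pruning
# ---------------------------------------------------------------------

def _compress(aln: Alignment) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique site patterns: (patterns[taxa, n_pat], inverse, counts)."""
    codes = aln.indices()
    pats, inv, counts = np.unique(codes.T, axis=0, return_inverse=True,
                                  return_counts=True)
    return pats.T, inv.ravel(), counts.astype(float)


def _is_equal_rates(rho: np.ndarray) -> bool:
    off = rho[~np.eye(rho.shape[0], dtype=bool)]
    return bool(np.allclose(off, off[0]))


def _category_pattern_loglik(pats: np.ndarray, tree: Tree, leaf_rows: np.ndarray,
                             model: SubstitutionMixtureModel, c: int,
                             rates: np.ndarray) -> np.ndarray:
    """(n_rates, n_patterns) log-likelihoods under category c.

    Partials carry an extra trailing rate axis so all Gamma classes are
    pruned in one traversal.
    """
    k = model.k
    n_pat = pats.shape[1]
    n_r = len(rates)
    pi = model.profiles[c]
    equal = _is_equal_rates(model.rho)
    if equal:
        # F81-type closed form after rate-1 normalization:
        # P(t) = e^{-t/(1-sum pi^2)} I + (1 - e^{-t/(1-sum pi^2)}) 1 pi^T
        decay_scale = 1.0 - float(pi @ pi)

    post = tree.postorder()
    partial: list = [None] * tree.n_nodes
    scale = np.zeros((n_pat, n_r))
    eye = np.eye(k)
    for node in post:
        ch = tree.children[node]
        if not ch:
            st = pats[leaf_rows[node]]
            arr = np.ones((n_pat, k))
            obs = st >= 0
            arr[obs] = eye[st[obs]]
            partial[node] = np.broadcast_to(arr[:, :, None], (n_pat, k, n_r))
            continue
        prod = np.ones((n_pat, k, n_r))
        for child in ch:
            ts = float(tree.length[child]) * rates        # (n_r,)
            l_child = partial[child]                      # (n_pat, k, n_r)
            if equal:
                e = np.exp(-ts / decay_scale)             # (n_r,)
                tot = np.einsum("pkr,k->pr", l_child, pi)
                msg = e[None, None, :] * l_child + \
                    (1.0 - e)[None, None, :] * tot[:, None, :]
            else:
                p = np.stack([model.transition_matrix(c, float(t)) for t in ts],
                             axis=-1)                     # (k, k, n_r)
                msg = np.einsum("pjr,ijr->pir", l_child, p)
            prod *= msg
            partial[child] = None
        m = prod.max(axis=1)                              # (n_pat, n_r)
        m[m == 0] = 1e-300
        prod /= m[:, None, :]
        scale += np.log(m)
        partial[node] = prod
    lik = np.einsum("pkr,k->pr", partial[post[-1]], pi)
    return (np.log(np.clip(lik, 1e-300, None)) + scale).T


try:
    from numba import njit as _njit

    @_njit(cache=True, fastmath=True)
    def _f81_mix_kernel(pats, leaf_row, parent, postorder, lengths,
                        profiles, rates):       # pragma: no cover - jitted
        C, k = profiles.shape
        P = pats.shape[1]
        N = parent.shape[0]
        G = rates.shape[0]
        out = np.empty((C, P))
        partial = np.empty((N, P, k))
        perrate = np.empty((G, P))
        root = postorder[N - 1]
        for c in range(C):
            pi = profiles[c]
            sq = 0.0
            for i in range(k):
                sq += pi[i] * pi[i]
            decay = 1.0 - sq
            for g in range(G):
                r = rates[g]
                scale = np.zeros(P)
                for i in range(N):
                    partial[i] = 1.0
                for idx in range(N):
                    node = postorder[idx]
                    if node == root:
                        continue
                    par = parent[node]
                    e = np.exp(-lengths[node] * r / decay)
                    lr = leaf_row[node]
                    if lr >= 0:
                        for p in range(P):
                            s = pats[lr, p]
                            if s >= 0:
                                base = (1.0 - e) * pi[s]
                                for i in range(k):
                                    m = base
                                    if i == s:
                                        m += e
                                    partial[par, p, i] *= m
                    else:
                        for p in range(P):
                            # rescale the completed node, then pass message up
                            mx = partial[node, p, 0]
                            for i in range(1, k):
                                if partial[node, p, i] > mx:
                                    mx = partial[node, p, i]
                            if mx <= 0.0:
                                mx = 1e-300
                            tot = 0.0
                            for i in range(k):
                                partial[node, p, i] /= mx
                                tot += partial[node, p, i] * pi[i]
                            scale[p] += np.log(mx)
                            for i in range(k):
                                partial[par, p, i] *= (e * partial[node, p, i]
                                                       + (1.0 - e) * tot)
                for p in range(P):
                    lik = 0.0
                    for i in range(k):
                        lik += partial[root, p, i] * pi[i]
                    if lik < 1e-300:
                        lik = 1e-300
                    perrate[g, p] = np.log(lik) + scale[p]
            for p in range(P):
                mx = perrate[0, p]
                for g in range(1, G):
                    if perrate[g, p] > mx:
                        mx = perrate[g, p]
                tot = 0.0
                for g in range(G):
                    tot += np.exp(perrate[g, p] - mx)
                out[c, p] = mx + np.log(tot / G)
        return out

    _HAVE_NUMBA = True
except ImportError:                              # pragma: no cover
    _HAVE_NUMBA = False


def per_category_pattern_loglik(pats: np.ndarray, tree: Tree,
                                leaf_rows: np.ndarray,
                                model: SubstitutionMixtureModel) -> np.ndarray:
    """(n_categories, n_patterns) log-likelihoods, Gamma-averaged."""
    rates = model.gamma_rates()
    if _HAVE_NUMBA and _is_equal_rates(model.rho):
        post = np.asarray(tree.postorder(), dtype=np.int64)
        return _f81_mix_kernel(np.ascontiguousarray(pats), leaf_rows,
                               tree.parent, post,
                               np.ascontiguousarray(tree.length, dtype=float),
                               np.ascontiguousarray(model.profiles),
                               np.ascontiguousarray(rates))
    out = np.empty((model.n_categories, pats.shape[1]))
    for c in range(model.n_categories):
        perrate = _category_pattern_loglik(pats, tree, leaf_rows, model, c, rates)
        out[c] = logsumexp(perrate, axis=0) - np.log(len(rates))
    return out


def _leaf_rows(aln: Alignment, tree: Tree) -> np.ndarray:
    rows = np.full(tree.n_nodes, -1, dtype=np.int64)
    tindex = {t: i for i, t in enumerate(aln.taxa)}
    for i in tree.leaf_indices:
        lab = tree.label[i]
        if lab not in tindex:
            raise ValueError(f"tree leaf {lab!r} not found among alignment taxa")
        rows[i] = tindex[lab]
    if sorted(tindex) != sorted(tree.leaf_labels):
        raise ValueError("alignment taxa and tree leaves do not match")
    return rows


def site_likelihoods(aln: Alignment, tree: Tree,
                     model: SubstitutionMixtureModel) -> LikelihoodResult:
    """Per-site log-likelihoods under the mixture model on a fixed tree."""
    if aln.alphabet.size != model.k:
        raise ValueError("alignment alphabet size does not match model state count")
    pats, inv, counts = _compress(aln)
    rows = _leaf_rows(aln, tree)
    percat = per_category_pattern_loglik(pats, tree, rows, model)
    logw = np.log(model.weights)
    pat_ll = logsumexp(percat + logw[:, None], axis=0)
    per_site = pat_ll[inv]
    return LikelihoodResult(float(per_site.sum()), per_site, model=model, tree=tree)


# ---------------------------------------------------------------------
# maximum-likelihood fitting on a fixed topology
# ---------------------------------------------------------------------

def _build_family(aln: Alignment, family: str, options: dict
                  ) -> SubstitutionMixtureModel:
    k = aln.alphabet.size
    n_rate_cats = int(options.get("n_rate_cats", 4))
    alpha0 = float(options.get("alpha0", 0.5))
    codes = aln.indices()

    def empirical_freqs() -> np.ndarray:
        counts = np.bincount(codes[codes >= 0].ravel(), minlength=k) + 1.0
        return counts / counts.sum()

    m = re.fullmatch(r"mix(\d+)_g", family)
    if family == "poisson_g":
        freqs = (empirical_freqs() if options.get("freqs") == "empirical"
                 else np.full(k, 1.0 / k))
        return SubstitutionMixtureModel.poisson(k, freqs, alpha=alpha0,
                                                n_rate_cats=n_rate_cats)
    if family == "lg_g":
        if k != 20:
            raise ValueError("lg_g requires the 20-state amino-acid alphabet")
        rho, freqs, _ = lg_model_data()
        pi = (empirical_freqs() if options.get("freqs") == "empirical" else freqs)
        return SubstitutionMixtureModel(rho, pi[None, :], np.ones(1), alpha=alpha0,
                                        n_rate_cats=n_rate_cats)
    if family == "gtr_g":
        rho = poisson_exchangeabilities(k)
        return SubstitutionMixtureModel(rho, empirical_freqs()[None, :], np.ones(1),
                                        alpha=alpha0, n_rate_cats=n_rate_cats)
    if m:
        n_cat = int(m.group(1))
        profiles, weights = _init_profiles_kmeans(aln, n_cat,
                                                  int(options.get("seed", 0)))
        return SubstitutionMixtureModel(poisson_exchangeabilities(k), profiles,
                                        weights, alpha=alpha0,
                                        n_rate_cats=n_rate_cats)
    raise ValueError(f"unknown model family: {family!r}")


def _init_profiles_kmeans(aln: Alignment, n_cat: int, seed: int
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Initialize mixture profiles by k-means on site frequency vectors."""
    from sklearn.cluster import KMeans

    k = aln.alphabet.size
    codes = aln.indices()
    n_sites = codes.shape[1]
    freq = np.zeros((n_sites, k))
    for s in range(k):
        freq[:, s] = (codes == s).sum(axis=0)
    freq += 0.1
    freq /= freq.sum(axis=1, keepdims=True)
    n_cat = min(n_cat, n_sites)
    km = KMeans(n_clusters=n_cat, n_init=1, random_state=seed).fit(freq)
    profiles = np.zeros((n_cat, k))
    weights = np.zeros(n_cat)
    for c in range(n_cat):
        sel = km.labels_ == c
        weights[c] = sel.sum()
        profiles[c] = freq[sel].mean(axis=0) if sel.any() else 1.0 / k
    profiles = np.clip(profiles, 1e-6, None)
    profiles /= profiles.sum(axis=1, keepdims=True)
    weights = np.clip(weights, 0.5, None)
    weights /= weights.sum()
    return profiles, weights


class _Objective:
    """Cached pattern-level likelihood evaluations for coordinate ascent."""

    def __init__(self, aln: Alignment, tree: Tree,
                 model: SubstitutionMixtureModel):
        self.pats, self.inv, self.counts = _compress(aln)
        self.tree = tree.copy()
        self.rows = _leaf_rows(aln, tree)
        self.model = model

    def loglik(self, model: SubstitutionMixtureModel | None = None,
               tree: Tree | None = None) -> float:
        model = model or self.model
        tree = tree or self.tree
        percat = per_category_pattern_loglik(self.pats, tree, self.rows, model)
        pat_ll = logsumexp(percat + np.log(model.weights)[:, None], axis=0)
        return float(pat_ll @ self.counts)

    def percat(self) -> np.ndarray:
        return per_category_pattern_loglik(self.pats, self.tree, self.rows,
                                           self.model)


def ml_fit(aln: Alignment, topology: Tree, model_family: str,
           options: dict | None = None) -> LikelihoodResult:
    """Coordinate-ascent ML fit of branch lengths and model parameters.

    Convergence when the round-to-round log-likelihood gain drops below
    ``tol`` (default 1e-4); a fit that exhausts ``max_rounds`` is
    returned with ``converged=False`` rather than raising.
    """
    options = dict(options or {})
    tol = float(options.get("tol", 1e-4))
    max_rounds = int(options.get("max_rounds", 20))
    model = options.pop("initial_model", None) or _build_family(aln, model_family,
                                                                options)
    obj = _Objective(aln, topology, model)
    if options.get("initial_lengths") is not None:
        obj.tree.length = np.asarray(options["initial_lengths"], float).copy()
    ll = obj.loglik()
    fit_rho = model_family == "gtr_g"
    is_mix = model_family.startswith("mix")
    n_rounds = 0
    converged = False
    for rounds in range(max_rounds):
        n_rounds = rounds + 1
        ll_prev = ll
        ll = _optimize_branches(obj, ll)
        if obj.model.n_rate_cats > 1:
            ll = _optimize_alpha(obj, ll)
        if fit_rho:
            ll = _optimize_exchangeabilities(obj, ll,
                                             int(options.get("rate_rounds", 1)))
        if is_mix:
            ll = _em_step(obj, ll)
        if ll - ll_prev < tol:
            converged = True
            break
    percat = obj.percat()
    pat_ll = logsumexp(percat + np.log(obj.model.weights)[:, None], axis=0)
    return LikelihoodResult(float(pat_ll @ obj.counts), pat_ll[obj.inv],
                            model=obj.model, tree=obj.tree,
                            converged=converged, n_iterations=n_rounds)


def _optimize_branches(obj: _Objective, ll: float) -> float:
    for node in range(1, obj.tree.n_nodes):
        cur = float(obj.tree.length[node])

        def neg(t: float, node=node) -> float:
            obj.tree.length[node] = t
            return -obj.loglik()

        res = minimize_scalar(neg, bounds=(_MIN_BRANCH, _MAX_BRANCH),
                              method="bounded", options={"xatol": 1e-6})
        if -res.fun > ll:
            obj.tree.length[node] = float(res.x)
            ll = -res.fun
        else:
            obj.tree.length[node] = cur
    return ll


def _optimize_alpha(obj: _Objective, ll: float) -> float:
    def neg(log_a: float) -> float:
        return -obj.loglik(obj.model.with_params(alpha=float(np.exp(log_a))))

    res = minimize_scalar(neg, bounds=(np.log(0.02), np.log(50.0)),
                          method="bounded", options={"xatol": 1e-4})
    if -res.fun > ll:
        obj.model = obj.model.with_params(alpha=float(np.exp(res.x)))
        return -res.fun
    return ll


def _optimize_exchangeabilities(obj: _Objective, ll: float, rounds: int) -> float:
    """Cyclic 1-D updates of free GTR rates (rho[0,1] is the reference)."""
    k = obj.model.k
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)][1:]
    for _ in range(rounds):
        for (i, j) in pairs:
            cur = float(obj.model.rho[i, j])

            def neg(log_r: float) -> float:
                rho = obj.model.rho.copy()
                rho[i, j] = rho[j, i] = float(np.exp(log_r))
                return -obj.loglik(obj.model.with_params(rho=rho))

            res = minimize_scalar(neg, bounds=(np.log(1e-4), np.log(1e4)),
                                  method="bounded", options={"xatol": 1e-3})
            if -res.fun > ll + 1e-12:
                rho = obj.model.rho.copy()
                rho[i, j] = rho[j, i] = float(np.exp(res.x))
                obj.model = obj.model.with_params(rho=rho)
                ll = -res.fun
    return ll


def _em_step(obj: _Objective, ll: float) -> float:
    """One guarded generalized-EM pass over mixture weights and profiles."""
    model = obj.model
    percat = obj.percat()                       # (C, n_pat)
    logw = np.log(model.weights)[:, None]
    log_resp = percat + logw - logsumexp(percat + logw, axis=0, keepdims=True)
    resp = np.exp(log_resp)                     # (C, n_pat)
    # exact M-step for the weights
    new_w = (resp * obj.counts[None, :]).sum(axis=1)
    new_w = np.clip(new_w, 1e-9, None)
    new_w /= new_w.sum()
    cand = model.with_params(weights=new_w)
    cand_ll = obj.loglik(cand)
    if cand_ll > ll:
        obj.model, ll = cand, cand_ll
    # heuristic profile update from responsibility-weighted state counts
    k = model.k
    state_counts = np.zeros((obj.pats.shape[1], k))
    for s in range(k):
        state_counts[:, s] = (obj.pats == s).sum(axis=0)
    new_p = resp @ (state_counts * obj.counts[:, None]) + 0.5
    new_p /= new_p.sum(axis=1, keepdims=True)
    cand = obj.model.with_params(profiles=new_p)
    cand_ll = obj.loglik(cand)
    if cand_ll > ll:                            # guarded: never decrease
        obj.model, ll = cand, cand_ll
    return ll


# ---------------------------------------------------------------------
# topology comparison with nonparametric bootstrap
# ---------------------------------------------------------------------

def topology_scan(aln: Alignment, candidate_topologies: list[Tree],
                  model_family: str, options: dict | None = None,
                  n_bootstrap: int = 100, rng_seed: int = 0
                  ) -> dict:
    """Fit each candidate topology; support by site-resampled refitting.

    Support for a candidate is the proportion of bootstrap replicates in
    which it attains the best refitted log-likelihood (ties split
    uniformly at random); supports sum to 1 over the candidates.
    """
    if len(candidate_topologies) < 2:
        raise ValueError("need at least two candidate topologies")
    options = dict(options or {})
    rng = np.random.default_rng(rng_seed)
    fits = [ml_fit(aln, topo, model_family, options)
            for topo in candidate_topologies]
    # pattern-level site log-likelihood vectors for fast bootstrap refits
    boot_rounds = int(options.get("bootstrap_rounds", 1))
    wins = np.zeros(len(fits))
    n_sites = aln.n_sites
    for _ in range(n_bootstrap):
        idx = rng.integers(n_sites, size=n_sites)
        res = aln.subsample_sites(idx)
        lls = []
        for fit in fits:
            refit = ml_fit(res, fit.tree, model_family,
                           {**options, "max_rounds": boot_rounds,
                            "initial_model": fit.model,
                            "initial_lengths": fit.tree.length})
            lls.append(refit.log_likelihood)
        lls = np.asarray(lls)
        best = np.flatnonzero(lls >= lls.max() - 1e-9)
        wins[rng.choice(best)] += 1
    support = wins / wins.sum()
    return {"log_likelihoods": np.array([f.log_likelihood for f in fits]),
            "support": support, "fits": fits}
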