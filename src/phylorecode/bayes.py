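"""Metropolis-Hastings sampling over candidate topologies and model
parameters.

The topology space is an explicit candidate list (e.g. the two rooting
hypotheses, or the three quartet resolutions); the chain samples jointly
a topology index, one shared branch-length vector (candidate trees have
identical node counts, so the vector maps across topologies by node
index), the Gamma shape, and the mixture weights/profiles (or GTR
exchangeabilities).  Site-to-category allocation is marginalized
analytically in the likelihood.  One cycle is a sweep of every move
class.  Priors: exponential(mean 0.1) branch lengths, exponential(mean
1) Gamma shape, flat Dirichlet on weights, profiles and
exchangeabilities; topologies uniform.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp, gammaln

from .core import Alignment, Tree
from .likelihood import (_build_family, _compress, _leaf_rows,
                         per_category_pattern_loglik)
from .models import SubstitutionMixtureModel

__all__ = ["ChainSettings", "PosteriorSample", "BayesResult",
           "sample_posterior", "convergence_check", "geweke_z"]

_BL_PRIOR_RATE = 10.0          # exponential, mean 0.1
_ALPHA_PRIOR_RATE = 1.0        # exponential, mean 1


@dataclass(frozen=True)
class ChainSettings:
    n_cycles: int = 2000
    burnin_cycles: int = 1000
    subsample_every: int = 10
    rng_seed: int = 0
    branch_step: float = 1.0           # multiplier window (log scale)
    alpha_step: float = 0.7
    dirichlet_concentration: float = 200.0

    def __post_init__(self) -> None:
        if not 0 <= self.burnin_cycles < self.n_cycles:
            raise ValueError("need 0 <= burnin < n_cycles")
        if self.subsample_every < 1:
            raise ValueError("subsample_every must be >= 1")


@dataclass
class PosteriorSample:
    cycle: int
    topology_index: int
    branch_lengths: np.ndarray
    alpha: float
    weights: np.ndarray
    profiles: np.ndarray
    rho: np.ndarray
    log_likelihood: float

    def to_model(self, template: SubstitutionMixtureModel) -> SubstitutionMixtureModel:
        return template.with_params(rho=self.rho, profiles=self.profiles,
                                    weights=self.weights, alpha=self.alpha)

    def to_tree(self, candidates: list[Tree]) -> Tree:
        tree = candidates[self.topology_index].copy()
        tree.length = self.branch_lengths.copy()
        return tree


@dataclass
class BayesResult:
    pp: np.ndarray
    samples: list[PosteriorSample]
    trace: pd.DataFrame
    acceptance: dict[str, float]
    candidates: list[Tree]
    model_family: str
    template: SubstitutionMixtureModel


def _dirichlet_logpdf(x: np.ndarray, conc: np.ndarray) -> float:
    return float(gammaln(conc.sum()) - gammaln(conc).sum()
                 + ((conc - 1.0) * np.log(x)).sum())


class _Chain:
    def __init__(self, aln: Alignment, candidates: list[Tree], model_family: str,
                 settings: ChainSettings, options: dict):
        if not candidates:
            raise ValueError("need at least one candidate topology")
        n_nodes = {t.n_nodes for t in candidates}
        if len(n_nodes) != 1:
            raise ValueError("candidate topologies must share a node count")
        self.settings = settings
        self.rng = np.random.default_rng(settings.rng_seed)
        self.pats, self.inv, self.counts = _compress(aln)
        self.trees = [t.copy() for t in candidates]
        self.rows = [_leaf_rows(aln, t) for t in self.trees]
        self.model = _build_family(aln, model_family, options)
        self.family = model_family
        self.fit_rho = model_family == "gtr_g"
        self.ti = 0
        # one branch length per slot, shared across topologies: leaf edges
        # map by taxon label so a topology jump keeps each tip's length
        labels = sorted(l for l in self.trees[0].label if l is not None)
        slots = {lab: i for i, lab in enumerate(labels)}
        self.n_slots = self.trees[0].n_nodes - 1
        self.slot_of = []
        for t in self.trees:
            mapping = np.full(t.n_nodes, -1, dtype=np.int64)
            nxt = len(labels)
            for node in t.preorder()[1:]:
                if t.label[node] is not None:
                    mapping[node] = slots[t.label[node]]
                else:
                    mapping[node] = nxt
                    nxt += 1
            self.slot_of.append(mapping)
        init = np.full(self.n_slots, 0.1)
        t0 = self.trees[0]
        for node in range(1, t0.n_nodes):
            init[self.slot_of[0][node]] = max(float(t0.length[node]), 0.01)
        self.lengths = init
        self.ll = self.loglik()
        self.accept = {}
        self.tries = {}

    def loglik(self, ti: int | None = None, lengths: np.ndarray | None = None,
               model: SubstitutionMixtureModel | None = None) -> float:
        ti = self.ti if ti is None else ti
        model = model or self.model
        tree = self.trees[ti]
        slot_lengths = self.lengths if lengths is None else lengths
        saved = tree.length
        branch = np.zeros(tree.n_nodes)
        branch[1:] = slot_lengths[self.slot_of[ti][1:]]
        tree.length = branch
        try:
            percat = per_category_pattern_loglik(self.pats, tree, self.rows[ti],
                                                 model)
            pat_ll = logsumexp(percat + np.log(model.weights)[:, None], axis=0)
            return float(pat_ll @ self.counts)
        finally:
            tree.length = saved

    def _bump(self, move: str, accepted: bool) -> None:
        self.tries[move] = self.tries.get(move, 0) + 1
        self.accept[move] = self.accept.get(move, 0) + int(accepted)

    # -- move classes --------------------------------------------------
    def move_branches(self) -> None:
        for slot in range(self.n_slots):
            t = float(self.lengths[slot])
            t_new = t * float(np.exp(self.settings.branch_step
                                     * (self.rng.random() - 0.5)))
            prop = self.lengths.copy()
            prop[slot] = t_new
            ll_new = self.loglik(lengths=prop)
            log_r = (ll_new - self.ll
                     - _BL_PRIOR_RATE * (t_new - t)      # exp prior
                     + np.log(t_new / t))                # multiplier Hastings
            ok = np.log(self.rng.random()) < log_r
            if ok:
                self.lengths = prop
                self.ll = ll_new
            self._bump("branch", ok)

    def move_alpha(self) -> None:
        if self.model.n_rate_cats <= 1:
            return
        a = self.model.alpha
        a_new = a * float(np.exp(self.settings.alpha_step
                                 * (self.rng.random() - 0.5)))
        cand = self.model.with_params(alpha=a_new)
        ll_new = self.loglik(model=cand)
        log_r = (ll_new - self.ll - _ALPHA_PRIOR_RATE * (a_new - a)
                 + np.log(a_new / a))
        ok = np.log(self.rng.random()) < log_r
        if ok:
            self.model, self.ll = cand, ll_new
        self._bump("alpha", ok)

    def _simplex_move(self, x: np.ndarray) -> tuple[np.ndarray, float]:
        c0 = self.settings.dirichlet_concentration
        fwd = c0 * x + 0.5
        y = self.rng.dirichlet(fwd)
        y = np.clip(y, 1e-10, None)
        y /= y.sum()
        bwd = c0 * y + 0.5
        log_h = _dirichlet_logpdf(x, bwd) - _dirichlet_logpdf(y, fwd)
        return y, log_h

    def move_weights(self) -> None:
        if self.model.n_categories <= 1:
            return
        w_new, log_h = self._simplex_move(self.model.weights)
        cand = self.model.with_params(weights=w_new)
        ll_new = self.loglik(model=cand)
        ok = np.log(self.rng.random()) < ll_new - self.ll + log_h
        if ok:
            self.model, self.ll = cand, ll_new
        self._bump("weights", ok)

    def move_profiles(self) -> None:
        for c in range(self.model.n_categories):
            self._move_one_profile(c)

    def _move_one_profile(self, c: int) -> None:
        p_new, log_h = self._simplex_move(self.model.profiles[c])
        profiles = self.model.profiles.copy()
        profiles[c] = p_new
        cand = self.model.with_params(profiles=profiles)
        ll_new = self.loglik(model=cand)
        ok = np.log(self.rng.random()) < ll_new - self.ll + log_h
        if ok:
            self.model, self.ll = cand, ll_new
        self._bump("profile", ok)

    def move_exchangeabilities(self) -> None:
        if not self.fit_rho:
            return
        k = self.model.k
        iu = np.triu_indices(k, 1)
        r = self.model.rho[iu]
        x = r / r.sum()
        y, log_h = self._simplex_move(x)
        rho = np.zeros((k, k))
        rho[iu] = y * r.sum()
        rho = rho + rho.T
        cand = self.model.with_params(rho=rho)
        ll_new = self.loglik(model=cand)
        ok = np.log(self.rng.random()) < ll_new - self.ll + log_h
        if ok:
            self.model, self.ll = cand, ll_new
        self._bump("rho", ok)

    def move_topology(self) -> None:
        if len(self.trees) <= 1:
            return
        others = [i for i in range(len(self.trees)) if i != self.ti]
        ti_new = int(self.rng.choice(others))
        ll_new = self.loglik(ti=ti_new)
        ok = np.log(self.rng.random()) < ll_new - self.ll
        if ok:
            self.ti, self.ll = ti_new, ll_new
        self._bump("topology", ok)

    def sweep(self) -> None:
        self.move_branches()
        self.move_alpha()
        self.move_weights()
        self.move_profiles()
        self.move_exchangeabilities()
        self.move_topology()


def sample_posterior(aln: Alignment, candidates: list[Tree], model_family: str,
                     settings: ChainSettings, options: dict | None = None
                     ) -> BayesResult:
    """Run one MH chain; returns topology posterior probabilities and
    post-burnin subsampled parameter draws."""
    chain = _Chain(aln, candidates, model_family, settings, dict(options or {}))
    if not np.isfinite(chain.ll):
        raise RuntimeError("non-finite initial likelihood; chain aborted")
    trace_rows = []
    samples: list[PosteriorSample] = []
    for cycle in range(1, settings.n_cycles + 1):
        chain.sweep()
        if not np.isfinite(chain.ll):
            raise RuntimeError(f"chain diverged at cycle {cycle}")
        trace_rows.append((cycle, chain.ll, chain.model.alpha, chain.ti,
                           time.time()))
        if (cycle > settings.burnin_cycles
                and cycle % settings.subsample_every == 0):
            branch = np.zeros(chain.trees[chain.ti].n_nodes)
            branch[1:] = chain.lengths[chain.slot_of[chain.ti][1:]]
            samples.append(PosteriorSample(
                cycle, chain.ti, branch, chain.model.alpha,
                chain.model.weights.copy(), chain.model.profiles.copy(),
                chain.model.rho.copy(), chain.ll))
    trace = pd.DataFrame(trace_rows, columns=["cycle", "log_likelihood",
                                              "alpha", "topology", "timestamp"])
    post = trace[trace.cycle > settings.burnin_cycles]
    pp = np.array([(post.topology == i).mean() for i in range(len(candidates))])
    acceptance = {k: chain.accept.get(k, 0) / n
                  for k, n in chain.tries.items() if n}
    return BayesResult(pp, samples, trace, acceptance, [t.copy() for t in candidates],
                       model_family, chain.model)


def geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke-style mean comparison between early and late trace windows."""
    x = np.asarray(x, float)
    a = x[: max(2, int(len(x) * first))]
    b = x[-max(2, int(len(x) * last)):]
    denom = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def convergence_check(result_a: BayesResult, result_b: BayesResult,
                      pp_tolerance: float = 0.1) -> dict:
    """Compare two independent chains run with identical settings.

    Reports the per-topology posterior-probability differences and the
    difference in posterior-mean Gamma shape; flags when any PP
    difference exceeds ``pp_tolerance``.
    """
    if len(result_a.candidates) != len(result_b.candidates):
        raise ValueError("chains were run on different candidate sets")
    pp_diff = np.abs(result_a.pp - result_b.pp)
    alpha_a = np.mean([s.alpha for s in result_a.samples])
    alpha_b = np.mean([s.alpha for s in result_b.samples])
    return {"pp_difference": pp_diff,
            "max_pp_difference": float(pp_diff.max()),
            "alpha_difference": float(abs(alpha_a - alpha_b)),
            "flagged": bool(pp_diff.max() > pp_tolerance)}
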