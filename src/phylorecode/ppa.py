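"""Posterior-predictive model adequacy: PPA-Div and PPA-Mean Z-scores.

Two alignment statistics summarize compositional heterogeneity:

* ``div_stat`` — mean number of distinct (non-missing) states per site,
  the across-site heterogeneity statistic (PPA-Div);
* ``mean_comp_stat`` — mean over taxa of the summed absolute deviations
  between taxon-specific and global state frequencies, the
  across-lineage statistic (PPA-Mean).

The posterior-predictive check simulates replicate alignments of the
observed dimensions from posterior parameter draws and reports the
signed Z-score (observed minus predictive mean, over the predictive
standard deviation).  Observed missing cells are masked at the same
positions in every predictive replicate so that both statistics are
computed on identical cell sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bayes import BayesResult, PosteriorSample
from .core import Alignment
from .simulate import simulate_alignment

__all__ = ["PPAResult", "div_stat", "mean_comp_stat", "ppa", "fit_band"]


def div_stat(aln: Alignment) -> float:
    """Mean number of distinct non-missing states per column (PPA-Div)."""
    codes = aln.indices()
    k = aln.alphabet.size
    present = np.zeros((k, codes.shape[1]), dtype=bool)
    for s in range(k):
        present[s] = (codes == s).any(axis=0)
    return float(present.sum(axis=0).mean())


def mean_comp_stat(aln: Alignment) -> float:
    """Mean over taxa of sum_state |f_taxon - f_global| (PPA-Mean)."""
    codes = aln.indices()
    k = aln.alphabet.size
    obs = codes >= 0
    if (obs.sum(axis=1) == 0).any():
        bad = aln.taxa[int(np.flatnonzero(obs.sum(axis=1) == 0)[0])]
        raise ValueError(f"taxon {bad!r} has no observed sites")
    global_counts = np.bincount(codes[obs].ravel(), minlength=k).astype(float)
    f_global = global_counts / global_counts.sum()
    devs = []
    for row, mask in zip(codes, obs):
        f = np.bincount(row[mask], minlength=k).astype(float) / mask.sum()
        devs.append(np.abs(f - f_global).sum())
    return float(np.mean(devs))


_STATS = {"div": div_stat, "mean_comp": mean_comp_stat, "mean": mean_comp_stat}


@dataclass
class PPAResult:
    statistic: str
    observed: float
    predictive_mean: float
    predictive_sd: float
    z: float
    n_predictive_sims: int
    band: str
    flagged: bool = False


def fit_band(z: float) -> str:
    """The interpretation band for a PPA Z-score magnitude."""
    if not np.isfinite(z):
        raise ValueError("Z-score must be finite")
    a = abs(z)
    if a <= 2:
        return "adequate"
    if a <= 3:
        return "acceptable"
    if a <= 5:
        return "acceptable-to-fairly-poor"
    if a <= 10:
        return "poor"
    return "very poor"


def ppa(observed: Alignment, result: BayesResult | list[PosteriorSample],
        statistic: str = "div", n_sims: int | None = None, rng_seed: int = 0,
        candidates=None, template=None) -> PPAResult:
    """Posterior-predictive Z-score of an adequacy statistic.

    ``result`` is normally a :class:`BayesResult`; a bare sample list
    may be given together with ``candidates`` and a ``template`` model.
    By default one predictive replicate is simulated per retained
    posterior sample; ``n_sims`` resamples the draws with replacement.
    """
    if statistic not in _STATS:
        raise ValueError(f"unknown statistic {statistic!r}")
    if isinstance(result, BayesResult):
        samples, candidates, template = result.samples, result.candidates, result.template
    else:
        samples = result
        if candidates is None or template is None:
            raise ValueError("candidates and template are required with a sample list")
    if len(samples) < 2:
        raise ValueError("need at least two posterior samples")
    rng = np.random.default_rng(rng_seed)
    stat_fn = _STATS[statistic]
    obs_val = stat_fn(observed)
    if n_sims is None:
        picks = list(range(len(samples)))
    else:
        if n_sims < 2:
            raise ValueError("n_sims must be at least 2")
        picks = rng.integers(len(samples), size=n_sims).tolist()
    missing_mask = observed.indices() < 0
    vals = []
    for i in picks:
        s = samples[i]
        tree = s.to_tree(candidates)
        model = s.to_model(template)
        rep = simulate_alignment(tree, model, observed.n_sites, rng_seed=rng)
        rep = rep.subset_taxa(observed.taxa)
        if missing_mask.any():
            matrix = rep.matrix.copy()
            matrix[missing_mask] = "-"
            rep = Alignment(rep.taxa, matrix, rep.alphabet)
        vals.append(stat_fn(rep))
    vals = np.asarray(vals)
    mean, sd = float(vals.mean()), float(vals.std(ddof=1))
    if sd == 0:
        return PPAResult(statistic, obs_val, mean, 0.0, float("nan"),
                         len(picks), "undefined", flagged=True)
    z = (obs_val - mean) / sd
    return PPAResult(statistic, obs_val, mean, sd, float(z), len(picks),
                     fit_band(z))
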