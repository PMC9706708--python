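"""Parsimony tree lengths, information loss, and saturation indices.

Fitch parsimony counts the minimal number of state changes a tree
requires for an alignment; comparing the counts of an amino-acid
alignment and its recoded version measures how many substitutions the
recoding masks (the information cost of recoding).  Saturation is
quantified by regressing Neighbor-Joining p-distance tip-to-tip path
lengths against model-tree path lengths through the origin: the slope M
shrinks below 1 as multiple hits accumulate, and Sat = 1 - M.

State sets are held as bit masks, columns are compressed to unique
patterns, and trees are assumed binary (a basal trifurcation standing
for the unrooted root is handled exactly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Alignment, Tree

__all__ = [
    "ParsimonyResult", "SaturationResult", "fitch_length", "parsimony_search",
    "information_loss", "branch_loss_map", "persite_substitutions",
    "p_distance_matrix", "nj_tree", "patristic", "saturation_index",
]


@dataclass
class ParsimonyResult:
    tree: Tree
    length: int
    n_random_additions: int
    rng_seed: int


@dataclass
class SaturationResult:
    slope: float                 # M, the through-origin regression gradient
    sat: float                   # 1 - M
    n_pairs: int


# ---------------------------------------------------------------------
# Fitch parsimony
# ---------------------------------------------------------------------

def _pattern_masks(aln: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """Bit-mask site patterns (taxa x n_patterns) and pattern counts."""
    codes = aln.indices()
    k = aln.alphabet.size
    full = np.uint32((1 << k) - 1)
    masks = np.where(codes >= 0, np.uint32(1) << codes.clip(0).astype(np.uint32),
                     full).astype(np.uint32)
    pats, counts = np.unique(masks.T, axis=0, return_counts=True)
    return pats.T, counts.astype(np.int64)


def _fitch_changes(tree: Tree, leaf_rows: np.ndarray, masks: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Per-pattern change counts and per-node first-pass state sets."""
    n_pat = masks.shape[1]
    sets = np.zeros((tree.n_nodes, n_pat), dtype=np.uint32)
    changes = np.zeros(n_pat, dtype=np.int64)
    for node in tree.postorder():
        ch = tree.children[node]
        if not ch:
            sets[node] = masks[leaf_rows[node]]
            continue
        m = sets[ch[0]]
        for child in ch[1:]:
            inter = m & sets[child]
            empty = inter == 0
            changes += empty
            m = np.where(empty, m | sets[child], inter)
        sets[node] = m
    return changes, sets


def _rows_for(aln: Alignment, tree: Tree) -> np.ndarray:
    tindex = {t: i for i, t in enumerate(aln.taxa)}
    missing = set(tree.leaf_labels) - set(tindex)
    if missing:
        raise ValueError(f"tree leaves missing from alignment: {sorted(missing)}")
    rows = np.full(tree.n_nodes, -1, dtype=np.int64)
    for i in tree.leaf_indices:
        rows[i] = tindex[tree.label[i]]
    return rows


def fitch_length(aln: Alignment, tree: Tree) -> int:
    """Minimal number of state changes (Fitch count) on a fixed tree.

    Missing symbols contribute the full state set at their leaf.
    """
    masks, counts = _pattern_masks(aln)
    rows = _rows_for(aln, tree)
    changes, _ = _fitch_changes(tree, rows, masks)
    return int(changes @ counts)


# ---------------------------------------------------------------------
# heuristic search: random stepwise addition + NNI
# ---------------------------------------------------------------------

def _star_tree(taxa: list[str]) -> Tree:
    parent = [-1] + [0] * len(taxa)
    length = [0.0] + [1.0] * len(taxa)
    label = [None] + list(taxa)
    return Tree(parent, length, label, rooted=False)


def _insert_leaf(tree: Tree, edge_child: int, taxon: str) -> Tree:
    """Attach a new leaf by subdividing the edge above ``edge_child``."""
    n = tree.n_nodes
    parent = np.concatenate([tree.parent, [tree.parent[edge_child], n]])
    length = np.concatenate([tree.length, [1.0, 1.0]])
    label = list(tree.label) + [None, taxon]
    parent[edge_child] = n
    return Tree(parent, length, label, rooted=False)


def _nni_neighbors(tree: Tree):
    """Yield NNI rearrangements across every internal edge."""
    for v in range(1, tree.n_nodes):
        if not tree.children[v]:
            continue
        u = int(tree.parent[v])
        a, b = tree.children[v][0], tree.children[v][1]
        others = [c for c in tree.children[u] if c != v]
        swaps = ([(b, others[0]), (b, others[1])] if len(others) == 2
                 else [(a, others[0]), (b, others[0])])
        for x, y in swaps:
            parent = tree.parent.copy()
            parent[x], parent[y] = u, v
            yield Tree(parent, tree.length.copy(), list(tree.label),
                       rooted=False)


def parsimony_search(aln: Alignment, n_random_additions: int = 10,
                     rng_seed: int = 0, keep_single_best: bool = True
                     ) -> ParsimonyResult:
    """Best tree over random stepwise-addition starts refined by NNI.

    A single best tree is retained (ties broken by search order).
    """
    if aln.n_taxa < 4:
        raise ValueError("parsimony search needs at least four taxa")
    rng = np.random.default_rng(rng_seed)
    masks, counts = _pattern_masks(aln)

    def length_of(tree: Tree) -> int:
        rows = _rows_for(aln, tree)
        changes, _ = _fitch_changes(tree, rows, masks)
        return int(changes @ counts)

    best_tree, best_len = None, None
    for _ in range(n_random_additions):
        order = rng.permutation(aln.n_taxa)
        tree = _star_tree([aln.taxa[i] for i in order[:3]])
        for t in order[3:]:
            taxon = aln.taxa[t]
            cands = [(length_of(_insert_leaf(tree, e, taxon)), e)
                     for e in range(1, tree.n_nodes)]
            cands.sort(key=lambda le: (le[0], le[1]))
            tree = _insert_leaf(tree, cands[0][1], taxon)
        cur_len = length_of(tree)
        improving = True
        while improving:
            improving = False
            for nb in _nni_neighbors(tree):
                l = length_of(nb)
                if l < cur_len:
                    tree, cur_len, improving = nb, l, True
                    break
        if best_len is None or cur_len < best_len:
            best_tree, best_len = tree, cur_len
    return ParsimonyResult(best_tree, int(best_len), n_random_additions, rng_seed)


def persite_substitutions(aln: Alignment, **search_options) -> float:
    """Best parsimony length divided by the number of sites."""
    res = parsimony_search(aln, **search_options)
    return res.length / aln.n_sites


def information_loss(len_source: float, len_recoded: float) -> float:
    """Percent of parsimony steps masked by recoding."""
    if len_source <= 0:
        raise ValueError("source tree length must be positive")
    return 100.0 * (len_source - len_recoded) / len_source


def _branch_steps(aln: Alignment, tree: Tree) -> np.ndarray:
    """Per-branch step counts from one deterministic minimal reconstruction.

    Ties resolve toward the parent state when it is in the Fitch set,
    otherwise to the lowest-index state; the counts sum to the Fitch
    length of the tree.
    """
    masks, counts = _pattern_masks(aln)
    rows = _rows_for(aln, tree)
    _, sets = _fitch_changes(tree, rows, masks)
    n_pat = masks.shape[1]
    lowest = (sets & (~sets + np.uint32(1)))       # lowest set bit
    states = np.zeros((tree.n_nodes, n_pat), dtype=np.uint32)
    steps = np.zeros(tree.n_nodes, dtype=np.int64)
    for node in tree.preorder():
        if node == 0:
            states[0] = lowest[0]
            continue
        pstate = states[tree.parent[node]]
        keep = (sets[node] & pstate) != 0
        states[node] = np.where(keep, pstate, lowest[node])
        steps[node] = int(counts[states[node] != pstate].sum())
    return steps


def branch_loss_map(aln_source: Alignment, aln_recoded: Alignment,
                    topology: Tree) -> pd.DataFrame:
    """Per-branch percent reduction in parsimony steps after recoding.

    Branches with zero source steps are flagged (NaN percent).
    """
    if aln_source.taxa != aln_recoded.taxa:
        raise ValueError("source and recoded alignments must share taxa")
    steps_src = _branch_steps(aln_source, topology)
    steps_rec = _branch_steps(aln_recoded, topology)
    rows = []
    for node in range(1, topology.n_nodes):
        s, r = int(steps_src[node]), int(steps_rec[node])
        pct = 100.0 * (s - r) / s if s > 0 else float("nan")
        rows.append({"branch": node,
                     "leaf": topology.label[node] or "",
                     "steps_source": s, "steps_recoded": r,
                     "percent_loss": pct, "zero_source": s == 0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# distances, NJ, saturation
# ---------------------------------------------------------------------

def p_distance_matrix(aln: Alignment) -> np.ndarray:
    """Observed-difference (P) distances with pairwise deletion."""
    if aln.n_taxa < 2:
        raise ValueError("need at least two taxa")
    codes = aln.indices()
    obs = codes >= 0
    n = aln.n_taxa
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comp = obs[i] & obs[j]
            m = int(comp.sum())
            if m == 0:
                raise ValueError(
                    f"taxa {aln.taxa[i]!r}/{aln.taxa[j]!r} share no observed sites")
            out[i, j] = out[j, i] = float((codes[i, comp] != codes[j, comp]).sum()) / m
    return out


def nj_tree(dist: np.ndarray, taxa: list[str]) -> Tree:
    """Saitou-Nei Neighbor Joining via scikit-bio; negatives clamped to 0."""
    from skbio import DistanceMatrix
    from skbio.tree import nj as _nj

    dist = np.asarray(dist, float)
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be symmetric")
    tn = _nj(DistanceMatrix(dist, ids=list(taxa)))
    for node in tn.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return Tree.from_newick(str(tn))


def patristic(tree: Tree, taxa: list[str] | None = None) -> np.ndarray:
    """Tip-to-tip path-length matrix of a tree."""
    return tree.patristic_matrix(taxa)


def saturation_index(model_tree_dists: np.ndarray, nj_dists: np.ndarray
                     ) -> SaturationResult:
    """Through-origin regression of NJ distances on model-tree distances.

    M = sum(x*y) / sum(x^2) with x the model-tree patristic distances;
    Sat = 1 - M.
    """
    x = np.asarray(model_tree_dists, float)
    y = np.asarray(nj_dists, float)
    if x.shape != y.shape:
        raise ValueError("distance matrices must have matching shapes")
    if x.ndim == 2:
        iu = np.triu_indices(x.shape[0], 1)
        x, y = x[iu], y[iu]
    if np.all(x == 0):
        raise ValueError("model-tree distances are all zero")
    m = float((x * y).sum() / (x * x).sum())
    return SaturationResult(m, 1.0 - m, int(len(x)))
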