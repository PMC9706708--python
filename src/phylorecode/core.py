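"""Core domain objects: state alphabets, character alignments and trees.

The package works with two alphabets — the 20 canonical amino acids and
reduced 6-state alphabets produced by recoding — and with rooted/unrooted
phylogenies carrying branch lengths in expected substitutions per site.
Trees are stored as a parent-indexed structure of arrays so that the
likelihood, parsimony and simulation engines can traverse them cheaply;
Newick parsing and serialisation are delegated to dendropy.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "Alphabet",
    "AMINO_ACIDS",
    "amino_acid_alphabet",
    "recoded_alphabet",
    "Alignment",
    "Tree",
]

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

#: residue codes silently converted to missing (ambiguity / rare residues)
AMBIGUOUS_RESIDUES = frozenset("BZJUO")


@dataclass(frozen=True)
class Alphabet:
    """An ordered set of single-character state codes plus missing codes."""

    symbols: str
    missing_symbols: frozenset[str] = frozenset({"-", "?", "X"})

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")
        if set(self.symbols) & self.missing_symbols:
            raise ValueError("missing symbols must be disjoint from state symbols")

    @property
    def size(self) -> int:
        return len(self.symbols)

    def index_map(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.symbols)}

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols or symbol in self.missing_symbols


def amino_acid_alphabet() -> Alphabet:
    """The canonical 20-state amino-acid alphabet."""
    return Alphabet(AMINO_ACIDS)


def recoded_alphabet(n_states: int = 6) -> Alphabet:
    """Reduced alphabet with bin labels 'A', 'B', ... (FASTA-compatible)."""
    if not 2 <= n_states <= 20:
        raise ValueError("reduced alphabets have between 2 and 20 states")
    return Alphabet("ABCDEFGHIJKLMNOPQRST"[:n_states])


@dataclass
class Alignment:
    """A taxa-by-sites character matrix over a declared alphabet.

    ``matrix`` is a 2-D numpy array of dtype ``<U1``; rows follow ``taxa``.
    """

    taxa: list[str]
    matrix: np.ndarray
    alphabet: Alphabet

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if len(self.taxa) == 0:
            raise ValueError("alignment must contain at least one taxon")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.taxa):
            raise ValueError("matrix shape does not match taxa")
        if self.matrix.shape[1] < 1:
            raise ValueError("alignment must contain at least one site")
        allowed = set(self.alphabet.symbols) | self.alphabet.missing_symbols
        observed = set(np.unique(self.matrix))
        bad = observed - allowed
        if bad:
            raise ValueError(f"symbols outside alphabet: {sorted(bad)}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return int(self.matrix.shape[1])

    def sequence(self, taxon: str) -> str:
        return "".join(self.matrix[self.taxa.index(taxon)])

    def indices(self) -> np.ndarray:
        """Integer-coded matrix; missing cells are -1."""
        lut = np.full(256, -1, dtype=np.int64)
        for i, s in enumerate(self.alphabet.symbols):
            lut[ord(s)] = i
        codes = self.matrix.view(np.uint32).reshape(self.matrix.shape)
        return lut[np.minimum(codes, 255)]

    def subsample_sites(self, site_idx: Sequence[int]) -> "Alignment":
        idx = np.asarray(site_idx, dtype=int)
        return Alignment(list(self.taxa), self.matrix[:, idx], self.alphabet)

    def subset_taxa(self, taxa: Sequence[str]) -> "Alignment":
        rows = [self.taxa.index(t) for t in taxa]
        return Alignment(list(taxa), self.matrix[rows], self.alphabet)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.alphabet.symbols == other.alphabet.symbols
            and bool(np.array_equal(self.matrix, other.matrix))
        )


class Tree:
    """A phylogeny as a parent-indexed structure of arrays.

    Node 0 is the root.  ``parent[i]`` is -1 for the root; ``length[i]`` is
    the branch length of the edge above node ``i`` (0.0 at the root).
    ``label[i]`` is the taxon label for leaves, ``None`` for internal nodes.
    The structure is rooted for traversal purposes; ``rooted`` records
    whether the root is biological or an arbitrary basal trifurcation.
    """

    def __init__(
        self,
        parent: Sequence[int],
        length: Sequence[float],
        label: Sequence[str | None],
        rooted: bool = False,
    ) -> None:
        self.parent = np.asarray(parent, dtype=np.int64)
        self.length = np.asarray(length, dtype=float)
        self.label = list(label)
        self.rooted = rooted
        if np.any(self.length < 0):
            raise ValueError("branch lengths must be non-negative")
        n = len(self.parent)
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(1, n):
            self.children[self.parent[i]].append(i)
        leaves = [l for l in self.label if l is not None]
        if len(set(leaves)) != len(leaves):
            raise ValueError("duplicate leaf labels")

    # -- construction -------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, rooted: bool | None = None,
                    default_length: float = 0.0) -> "Tree":
        try:
            dt = dendropy.Tree.get(data=newick, schema="newick",
                                   preserve_underscores=True)
        except Exception as err:
            raise ValueError(f"invalid Newick: {err}") from err
        return cls.from_dendropy(dt, rooted=rooted, default_length=default_length)

    @classmethod
    def from_dendropy(cls, dt: dendropy.Tree, rooted: bool | None = None,
                      default_length: float = 0.0) -> "Tree":
        nodes = list(dt.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent, length, label = [], [], []
        for nd in nodes:
            parent.append(-1 if nd.parent_node is None else index[id(nd.parent_node)])
            length.append(nd.edge.length if nd.edge.length is not None else default_length)
            label.append(nd.taxon.label if nd.taxon is not None else None)
        if rooted is None:
            rooted = len(dt.seed_node.child_nodes()) == 2
        return cls(parent, length, label, rooted=rooted)

    def to_dendropy(self, taxon_namespace: dendropy.TaxonNamespace | None = None
                    ) -> dendropy.Tree:
        tns = taxon_namespace or dendropy.TaxonNamespace()
        dt = dendropy.Tree(taxon_namespace=tns)
        dnodes = [dendropy.Node() for _ in range(self.n_nodes)]
        for i in range(self.n_nodes):
            dnodes[i].edge.length = float(self.length[i])
            if self.label[i] is not None:
                dnodes[i].taxon = tns.require_taxon(label=self.label[i])
        for i in range(1, self.n_nodes):
            dnodes[self.parent[i]].add_child(dnodes[i])
        dt.seed_node = dnodes[0]
        dt.is_rooted = self.rooted
        return dt

    def to_newick(self, precision: int = 10) -> str:
        def rec(i: int) -> str:
            if not self.children[i]:
                name = self.label[i] or ""
            else:
                name = "(" + ",".join(rec(c) for c in self.children[i]) + ")"
            if i == 0:
                return name + ";"
            return f"{name}:{self.length[i]:.{precision}g}"

        return rec(0)

    def copy(self) -> "Tree":
        return Tree(self.parent.copy(), self.length.copy(), list(self.label),
                    rooted=self.rooted)

    # -- queries ------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def leaf_indices(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def leaf_labels(self) -> list[str]:
        return [self.label[i] for i in self.leaf_indices]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_indices)

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [0]
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(self.children[i])
        order.reverse()
        return order

    def total_length(self) -> float:
        return float(self.length[1:].sum())

    def patristic_matrix(self, taxa: Sequence[str] | None = None) -> np.ndarray:
        """Tip-to-tip path-length matrix, ordered as ``taxa``."""
        if taxa is None:
            taxa = self.leaf_labels
        # node depths from root, then distance via lowest common ancestor
        depth = np.zeros(self.n_nodes)
        for i in self.preorder()[1:]:
            depth[i] = depth[self.parent[i]] + self.length[i]
        anc: list[set[int]] = [set() for _ in range(self.n_nodes)]
        for i in self.preorder():
            anc[i] = (anc[self.parent[i]] | {self.parent[i]}) if i else set()
            anc[i].add(i)
        leaf_of = {self.label[i]: i for i in self.leaf_indices}
        n = len(taxa)
        out = np.zeros((n, n))
        for a in range(n):
            for b in range(a + 1, n):
                i, j = leaf_of[taxa[a]], leaf_of[taxa[b]]
                common = anc[i] & anc[j]
                lca = max(common, key=lambda x: depth[x])
                out[a, b] = out[b, a] = depth[i] + depth[j] - 2 * depth[lca]
        return out

    def preorder(self) -> list[int]:
        order: list[int] = []
        stack = [0]
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(reversed(self.children[i]))
        return order

    def rf_distance(self, other: "Tree") -> int:
        """Unrooted Robinson-Foulds distance (symmetric difference)."""
        tns = dendropy.TaxonNamespace()
        a = dendropy.Tree.get(data=self.to_newick(), schema="newick",
                              taxon_namespace=tns, preserve_underscores=True)
        b = dendropy.Tree.get(data=other.to_newick(), schema="newick",
                              taxon_namespace=tns, preserve_underscores=True)
        a.encode_bipartitions()
        b.encode_bipartitions()
        return int(dendropy.calculate.treecompare.symmetric_difference(a, b))

    def topology_key(self) -> frozenset[frozenset[str]]:
        """Canonical unrooted topology identifier (set of non-trivial splits)."""
        labels = set(self.leaf_labels)
        below: dict[int, frozenset[str]] = {}
        splits: set[frozenset[frozenset[str]]] = set()
        for i in self.postorder():
            if not self.children[i]:
                below[i] = frozenset([self.label[i]])
            else:
                below[i] = frozenset().union(*(below[c] for c in self.children[i]))
            if i != 0:
                side = below[i]
                if 1 < len(side) < len(labels) - 1:
                    splits.add(frozenset([side, frozenset(labels - side)]))
        return frozenset(splits)

    def __repr__(self) -> str:
        return f"<Tree {self.n_leaves} leaves, {self.n_nodes} nodes>"
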