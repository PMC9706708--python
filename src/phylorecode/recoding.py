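"""Six-state amino-acid recoding schemes and their application.

A recoding scheme partitions the 20 amino acids into bins; applying it to
an alignment replaces each residue by its bin label, masking within-bin
substitutions.  Besides the classical Dayhoff-6 scheme (and SR6/KGB6
variants), the module generates random schemes with the Dayhoff-6 bin-size
template and scores the similarity between two schemes, enabling searches
for random schemes at a controlled residual similarity to a reference.

Similarity is a size-constrained optimal bin matching: bins may only be
paired with reference bins of equal size, the total intersection
cardinality is maximized over such pairings, and the score is the matched
fraction of the 20 amino acids in percent (always a multiple of 5).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import AMINO_ACIDS, Alignment, amino_acid_alphabet, recoded_alphabet

logger = logging.getLogger("phylorecode")

_BIN_LABELS = "ABCDEFGHIJKLMNOPQRST"

#: Dayhoff-6 bins: one 5-bin, two 4-bins, two 3-bins and the cysteine singleton
DAYHOFF6_BINS = ("AGPST", "DENQ", "HKR", "ILMV", "FWY", "C")


@dataclass(frozen=True)
class RecodingScheme:
    """A labeled partition of the 20 amino acids into bins."""

    name: str
    bins: tuple[tuple[str, frozenset[str]], ...]

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.bins]
        if len(set(labels)) != len(labels):
            raise ValueError("bin labels must be unique")
        members = [aa for _, bs in self.bins for aa in bs]
        if sorted(members) != sorted(AMINO_ACIDS):
            raise ValueError("bins must partition the 20 amino acids exactly")

    @classmethod
    def from_bins(cls, name: str, bins: list[str] | tuple[str, ...]) -> "RecodingScheme":
        return cls(name, tuple((_BIN_LABELS[i], frozenset(b))
                               for i, b in enumerate(bins)))

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def bin_sizes(self) -> tuple[int, ...]:
        return tuple(sorted(len(bs) for _, bs in self.bins))

    def mapping(self) -> dict[str, str]:
        return {aa: lab for lab, bs in self.bins for aa in bs}

    def partition_key(self) -> frozenset[frozenset[str]]:
        """Bin contents ignoring labels and order."""
        return frozenset(frozenset(bs) for _, bs in self.bins)


def builtin_scheme(name: str) -> RecodingScheme:
    """Return one of the published 6-state schemes: dayhoff6, sr6 or kgb6."""
    key = name.lower()
    if key == "dayhoff6":
        return RecodingScheme.from_bins("dayhoff6", DAYHOFF6_BINS)
    if key in ("sr6", "kgb6"):
        text = resources.files("phylorecode.data").joinpath(f"{key}.txt").read_text()
        return _parse_scheme_text(text, name=key)
    raise ValueError(f"unknown recoding scheme: {name!r}")


def apply_recoding(aln: Alignment, scheme: RecodingScheme) -> Alignment:
    """Replace each amino acid by its bin label; missing symbols unchanged."""
    if aln.alphabet.size != 20:
        raise ValueError("apply_recoding expects a 20-state amino-acid alignment")
    mapping = scheme.mapping()
    lut = {**mapping, **{m: m for m in aln.alphabet.missing_symbols}}
    out = np.vectorize(lut.__getitem__, otypes=["<U1"])(aln.matrix)
    alphabet = recoded_alphabet(scheme.n_bins)
    # bin labels must be the reduced alphabet's codes
    assert set(lab for lab, _ in scheme.bins) <= set(alphabet.symbols), \
        "scheme bin labels are not FASTA-compatible reduced-state codes"
    return Alignment(list(aln.taxa), out, alphabet)


def random_scheme(bin_sizes=(5, 4, 4, 3, 3, 1), rng_seed: int | np.random.Generator = 0
                  ) -> RecodingScheme:
    """A uniformly random partition of the amino acids into the size template."""
    sizes = tuple(int(s) for s in bin_sizes)
    if sum(sizes) != 20:
        raise ValueError("bin sizes must sum to 20")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    perm = rng.permutation(list(AMINO_ACIDS))
    bins, k = [], 0
    for s in sizes:
        bins.append("".join(perm[k:k + s]))
        k += s
    return RecodingScheme.from_bins("random", bins)


def similarity(a: RecodingScheme, b: RecodingScheme) -> float:
    """Percent of amino acids in agreement under size-constrained matching.

    Bins are paired only with equal-size bins; within each size class the
    pairing maximizing the total intersection cardinality is found
    (optimal assignment), and the score is 100 x matched / 20.
    """
    if a.bin_sizes != b.bin_sizes:
        raise ValueError("schemes have different bin-size multisets")
    by_size_a: dict[int, list[frozenset[str]]] = {}
    by_size_b: dict[int, list[frozenset[str]]] = {}
    for _, bs in a.bins:
        by_size_a.setdefault(len(bs), []).append(bs)
    for _, bs in b.bins:
        by_size_b.setdefault(len(bs), []).append(bs)
    total = 0
    for size, bins_a in by_size_a.items():
        bins_b = by_size_b[size]
        m = len(bins_a)
        if m == 1:
            total += len(bins_a[0] & bins_b[0])
            continue
        inter = np.array([[len(x & y) for y in bins_b] for x in bins_a])
        if m <= 3:  # tiny classes: explicit maximization
            total += max(sum(inter[i, p[i]] for i in range(m))
                         for p in itertools.permutations(range(m)))
        else:
            r, c = linear_sum_assignment(-inter)
            total += int(inter[r, c].sum())
    return 100.0 * total / 20.0


def find_schemes_at_similarity(target_percent: float, reference: RecodingScheme,
                               n_wanted: int, rng_seed: int = 0,
                               max_draws: int = 2_000_000,
                               shortcut: bool = True) -> list[RecodingScheme]:
    """Random schemes whose similarity to ``reference`` equals the target.

    Uses rejection sampling over uniform random schemes with the
    reference's bin-size template.  For a 90% target a constructive
    shortcut (displace exactly two amino acids between two bins, then
    verify by re-scoring) is available because such schemes are rare
    under uniform sampling.
    """
    if target_percent % 5 != 0 or not 0 <= target_percent <= 100:
        raise ValueError("target similarity must be a multiple of 5 in [0, 100]")
    if target_percent == 100 and n_wanted > 1:
        raise ValueError("only the reference itself has 100% similarity")
    rng = np.random.default_rng(rng_seed)
    sizes = reference.bin_sizes
    found: list[RecodingScheme] = []
    seen: set[frozenset[frozenset[str]]] = set()

    if shortcut and target_percent == 90.0:
        ref_bins = [set(bs) for _, bs in reference.bins]
        draws = 0
        while len(found) < n_wanted and draws < max_draws:
            draws += 1
            i, j = rng.choice(len(ref_bins), size=2, replace=False)
            bins = [set(b) for b in ref_bins]
            x = rng.choice(sorted(bins[i]))
            y = rng.choice(sorted(bins[j]))
            bins[i].discard(x); bins[i].add(y)
            bins[j].discard(y); bins[j].add(x)
            cand = RecodingScheme.from_bins("random90",
                                            ["".join(sorted(b)) for b in bins])
            if similarity(cand, reference) == 90.0 and cand.partition_key() not in seen:
                seen.add(cand.partition_key())
                found.append(cand)
        if len(found) < n_wanted:
            logger.warning("constructive 90%% search exhausted after %d draws", draws)
        return found

    for draw in range(max_draws):
        if len(found) >= n_wanted:
            break
        cand = random_scheme(sizes, rng)
        if similarity(cand, reference) == target_percent:
            if cand.partition_key() in seen:
                continue
            seen.add(cand.partition_key())
            found.append(cand)
    if len(found) < n_wanted:
        logger.warning("rejection search returned %d/%d schemes after %d draws",
                       len(found), n_wanted, max_draws)
    return found


# -- scheme text files -------------------------------------------------

def _parse_scheme_text(text: str, name: str) -> RecodingScheme:
    bins: list[tuple[str, frozenset[str]]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        label, _, members = line.partition(":")
        bins.append((label.strip(), frozenset(members.split())
                     if " " in members.strip() else frozenset(members.strip())))
    return RecodingScheme(name, tuple(bins))


def read_scheme(path: str | Path) -> RecodingScheme:
    """Read a scheme file: one line per bin, ``label: MEMBERS``."""
    path = Path(path)
    return _parse_scheme_text(path.read_text(), name=path.stem)


def write_scheme(scheme: RecodingScheme, path: str | Path) -> Path:
    path = Path(path)
    lines = [f"{lab}: {''.join(sorted(bs))}" for lab, bs in scheme.bins]
    path.write_text("\n".join(lines) + "\n")
    return path
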