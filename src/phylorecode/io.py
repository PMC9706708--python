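"""Reading and writing alignments, trees, configs and run logs.

Alignment parsing is delegated to Biopython's AlignIO (FASTA, relaxed
PHYLIP — both sequential and interleaved — and the NEXUS DATA block,
read-only for NEXUS).  Trees are Newick via dendropy.  Sites are 0-based
internally; any user-facing report is 1-based.
"""

from __future__ import annotations

import hashlib
import logging
import time
from contextlib import contextmanager
from pathlib import Path

import numpy as np
import yaml
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import AMBIGUOUS_RESIDUES, Alignment, Alphabet, Tree, amino_acid_alphabet

logger = logging.getLogger("phylorecode")

_READ_FORMATS = {"fasta": ["fasta"],
                 "phylip": ["phylip-relaxed", "phylip-sequential", "phylip"],
                 "nexus": ["nexus"]}
_WRITE_FORMATS = {"fasta": "fasta", "phylip": "phylip-relaxed"}


def read_alignment(path: str | Path, format: str, alphabet: Alphabet | None = None
                   ) -> Alignment:
    """Parse an alignment file into an :class:`Alignment`.

    Amino-acid ambiguity codes (B, Z, J, U, O) are converted to the
    missing symbol '?' with a logged warning; lowercase residues are
    uppercased.  Ragged rows raise a parse error naming the offending
    taxon.
    """
    if format not in _READ_FORMATS:
        raise ValueError(f"unsupported alignment format: {format!r}")
    alphabet = alphabet or amino_acid_alphabet()
    path = Path(path)
    last_err: Exception | None = None
    msa = None
    for dialect in _READ_FORMATS[format]:
        try:
            msa = AlignIO.read(str(path), dialect)
            break
        except Exception as err:  # try the next dialect
            last_err = err
    if msa is None:
        raise ValueError(f"could not parse {path} as {format}: {last_err}")
    taxa = [rec.id for rec in msa]
    rows = [str(rec.seq).upper() for rec in msa]
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        bad = taxa[[len(r) for r in rows].index(max(lengths))]
        raise ValueError(f"ragged alignment: taxon {bad!r} has a deviant row length")
    matrix = np.array([list(r) for r in rows], dtype="<U1")
    if alphabet.size == 20:
        mask = np.isin(matrix, sorted(AMBIGUOUS_RESIDUES))
        if mask.any():
            logger.warning("converted %d ambiguous residues (B/Z/J/U/O) to missing",
                           int(mask.sum()))
            matrix[mask] = "?"
    allowed = set(alphabet.symbols) | alphabet.missing_symbols
    bad_syms = set(np.unique(matrix)) - allowed
    if bad_syms:
        raise ValueError(f"symbols outside alphabet in {path}: {sorted(bad_syms)}")
    return Alignment(taxa, matrix, alphabet)


def write_alignment(aln: Alignment, path: str | Path, format: str = "fasta") -> Path:
    """Write an alignment; byte-stable for identical inputs."""
    if format not in _WRITE_FORMATS:
        raise ValueError(f"unsupported output format: {format!r}")
    records = [SeqRecord(Seq("".join(row)), id=t, description="")
               for t, row in zip(aln.taxa, aln.matrix)]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    AlignIO.write(MultipleSeqAlignment(records), str(path), _WRITE_FORMATS[format])
    return path


def read_tree(path: str | Path) -> Tree:
    """Read a Newick tree; branches without lengths default to 0.0."""
    text = Path(path).read_text()
    if ":" not in text:
        logger.warning("tree %s has no branch lengths; defaulting to 0.0", path)
    return Tree.from_newick(text)


def write_tree(tree: Tree, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(tree.to_newick() + "\n")
    return path


# -- configuration and run logging ------------------------------------

def read_config(path: str | Path) -> dict:
    """Load a nested key/value experiment configuration (YAML)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(yaml.safe_dump(cfg, sort_keys=True).encode()).hexdigest()[:12]


def spawn_seed(master_seed: int, *keys) -> int:
    """Derive a reproducible child seed (< 2^31) from a master seed and keys."""
    h = hashlib.sha256(repr((int(master_seed),) + tuple(keys)).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


class RunLog:
    """Per-stage wall-time accounting ('green phylogenomics' bookkeeping)."""

    def __init__(self, seed: int | None = None, config: dict | None = None):
        self.seed = seed
        self.config_digest = config_hash(config) if config else None
        self.stages: list[tuple[str, float]] = []

    @contextmanager
    def stage(self, name: str):
        t0 = time.perf_counter()
        try:
            yield
        finally:
            dt = time.perf_counter() - t0
            self.stages.append((name, dt))
            logger.info("stage %-20s %.2fs", name, dt)

    def as_dict(self) -> dict:
        return {"seed": self.seed, "config": self.config_digest,
                "stage_seconds": {k: round(v, 3) for k, v in self.stages}}

    def write(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=False))
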