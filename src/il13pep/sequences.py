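"""Peptide records, validation, and FASTA / plain-text sequence I/O.

A :class:`Peptide` is the atomic unit of the toolkit: a free-text identifier
plus an uppercase sequence over the 20 canonical amino-acid letters.
Non-standard residues (B, J, O, U, X, Z, gaps) are rejected rather than
silently dropped or mutated — the downstream feature space is defined only
over the canonical alphabet, and silently rewriting input would corrupt
composition features.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 canonical amino acids, alphabetical by one-letter code.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET_SET = frozenset(ALPHABET)

#: Peptide length bounds enforced in benchmark mode (the benchmark datasets
#: retain peptides of 8-35 residues).
BENCHMARK_LENGTH_RANGE: Tuple[int, int] = (8, 35)


class SequenceError(ValueError):
    """Invalid peptide sequence (non-canonical residue or bad length)."""


class ParseError(ValueError):
    """Malformed sequence file."""


@dataclass(frozen=True)
class Peptide:
    """A validated peptide: identifier plus uppercase canonical sequence."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        bad = [
            (i + 1, ch)
            for i, ch in enumerate(self.sequence)
            if ch not in ALPHABET_SET
        ]
        if bad:
            pos, ch = bad[0]
            raise SequenceError(
                f"peptide {self.id!r}: non-standard residue {ch!r} at "
                f"position {pos}"
            )
        if not self.sequence:
            raise SequenceError(f"peptide {self.id!r}: empty sequence")


def validate_peptide(
    raw: str, benchmark_mode: bool = False, id: str = "seq_1"
) -> Peptide:
    """Validate a raw sequence string and return a :class:`Peptide`.

    Lowercase input is accepted and uppercased. In ``benchmark_mode`` the
    length must lie in :data:`BENCHMARK_LENGTH_RANGE` (8-35 residues).
    Idempotent: validating an already-validated sequence is a no-op.
    """
    seq = raw.strip().upper()
    pep = Peptide(id=id, sequence=seq)
    if benchmark_mode:
        lo, hi = BENCHMARK_LENGTH_RANGE
        if not lo <= pep.length <= hi:
            raise SequenceError(
                f"peptide {id!r}: length {pep.length} outside benchmark "
                f"range [{lo}, {hi}]"
            )
    return pep


def _read_plain(path: str | os.PathLike) -> List[Peptide]:
    peptides: List[Peptide] = []
    with open(path) as fh:
        n = 0
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            n += 1
            peptides.append(validate_peptide(line, id=f"seq_{n}"))
    return peptides


def _read_fasta(path: str | os.PathLike) -> List[Peptide]:
    peptides: List[Peptide] = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            peptides.append(validate_peptide(str(rec.seq), id=rec.id))
    except ValueError as exc:  # malformed header / junk before first record
        raise ParseError(f"{path}: {exc}") from exc
    return peptides


def read_sequences(
    path: str | os.PathLike, format: str = "fasta"
) -> List[Peptide]:
    """Read peptides from ``path``.

    ``format`` is ``"fasta"`` (multi-line wrapped records supported) or
    ``"plain"`` (one sequence per line, ``#`` comment lines ignored, ids
    auto-generated as ``seq_1``, ``seq_2``, ...). Order is preserved and
    sequences are uppercased. An empty file yields an empty list.
    """
    if format == "fasta":
        return _read_fasta(path)
    if format == "plain":
        return _read_plain(path)
    raise ValueError(f"unknown format {format!r}; expected 'fasta' or 'plain'")


def write_fasta(peptides: Iterable[Peptide], path: str | os.PathLike) -> None:
    """Write peptides as FASTA; round-trips through :func:`read_sequences`."""
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description="") for p in peptides
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")


def load_benchmark(
    pos_path: str | os.PathLike,
    neg_path: str | os.PathLike,
    format: str = "fasta",
    benchmark_mode: bool = False,
) -> Tuple[List[Peptide], List[int]]:
    """Load a positive/negative benchmark pair.

    Returns ``(peptides, labels)`` with label 1 for IL-13-inducing
    (positive-file) peptides and 0 for the negatives, positives first.
    """
    pos = read_sequences(pos_path, format=format)
    neg = read_sequences(neg_path, format=format)
    if benchmark_mode:
        pos = [validate_peptide(p.sequence, True, p.id) for p in pos]
        neg = [validate_peptide(p.sequence, True, p.id) for p in neg]
    return pos + neg, [1] * len(pos) + [0] * len(neg)
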