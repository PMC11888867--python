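"""FASTA input/output, sequence canonicalization, and integer tokenization.

Protein sequences are mapped onto a 21-symbol vocabulary: the 20 canonical
residues plus a single combined pad/unknown symbol at index 0.  Ambiguous or
non-standard residue codes (B, J, O, U, Z, X and ``*``) are replaced by the
unknown symbol during canonicalization; downstream layers mask padded
positions so the pad index never influences predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("amylstm")

#: The 20 canonical amino acids, alphabetical one-letter order.
CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Symbol used both for padding and for unknown/non-canonical residues.
UNKNOWN_TOKEN = "?"

#: Residue codes replaced by :data:`UNKNOWN_TOKEN` during canonicalization.
NON_CANONICAL_CODES = frozenset("BJOUZX*")


class FastaParseError(ValueError):
    """Raised when a FASTA file is malformed."""


class EmptyInputError(ValueError):
    """Raised when an operation receives no sequences."""


@dataclass
class ProteinRecord:
    """One protein: a FASTA identifier, a residue string, an optional label.

    ``label`` is 1 for amyloid (positive) and 0 for non-amyloid (negative).
    """

    id: str
    sequence: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class Alphabet:
    """Ordered 21-token vocabulary with the pad/unknown symbol at index 0."""

    tokens: str = UNKNOWN_TOKEN + CANONICAL_RESIDUES
    index: dict = field(init=False)

    def __post_init__(self) -> None:
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("alphabet tokens must be distinct")
        if self.tokens[0] != UNKNOWN_TOKEN:
            raise ValueError("pad/unknown token must sit at index 0")
        object.__setattr__(
            self, "index", {t: i for i, t in enumerate(self.tokens)}
        )

    def __len__(self) -> int:
        return len(self.tokens)

    def index_of(self, symbol: str) -> int:
        return self.index[symbol]


DEFAULT_ALPHABET = Alphabet()


@dataclass
class TokenizedBatch:
    """Padded integer token matrix with per-row lengths and a boolean mask.

    ``indices`` is (n_sequences, L); padding positions hold index 0 and are
    False in ``mask``.  Real residues occupy the leading positions of each
    row.
    """

    indices: np.ndarray
    lengths: np.ndarray
    mask: np.ndarray
    ids: list = field(default_factory=list)
    labels: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return self.indices.shape[0]


def canonicalize(sequence: str) -> tuple[str, int]:
    """Uppercase a sequence and replace non-canonical codes.

    Returns the canonical sequence and the number of substitutions made.
    Characters outside the canonical alphabet (including the explicitly
    ambiguous codes B, J, O, U, Z, X, ``*``) become the unknown token.
    """
    seq = sequence.upper()
    out = []
    n_subs = 0
    for ch in seq:
        if ch in CANONICAL_RESIDUES:
            out.append(ch)
        else:
            out.append(UNKNOWN_TOKEN)
            n_subs += 1
    return "".join(out), n_subs


def _prescan_fasta(path: Path) -> None:
    """Reject files with sequence data before any header, naming the line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                return
            raise FastaParseError(
                f"{path}: line {lineno}: sequence data before any '>' header"
            )


def read_fasta(
    path, label: Optional[int] = None, canonical: bool = True
) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects, order preserved.

    Sequences are uppercased and non-canonical residues replaced by the
    unknown token (a warning logs the substitution count).  ``label`` is
    attached to every record, supporting the positive-file/negative-file
    labeling convention.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prescan_fasta(path)
    records: list[ProteinRecord] = []
    total_subs = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if canonical:
            seq, n_subs = canonicalize(seq)
            total_subs += n_subs
        records.append(ProteinRecord(id=rec.id, sequence=seq, label=label))
    if not records:
        raise EmptyInputError(f"{path}: no FASTA records found")
    if total_subs:
        logger.warning(
            "%s: replaced %d non-canonical residue(s) with %r",
            path, total_subs, UNKNOWN_TOKEN,
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    """Write records to FASTA (sequences on a single line per record)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=None)
        writer.write_file(seq_records)


def read_labels_tsv(path) -> dict[str, int]:
    """Read a two-column (id, label) TSV into a mapping."""
    labels: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            parts = stripped.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns"
                )
            labels[parts[0]] = int(parts[1])
    return labels


def tokenize(
    records: Sequence[ProteinRecord],
    alphabet: Alphabet = DEFAULT_ALPHABET,
    max_len: Optional[int] = None,
) -> TokenizedBatch:
    """Map records to a padded integer matrix with lengths and mask.

    Rows are padded with index 0 up to the longest (possibly
    ``max_len``-truncated) sequence; truncation keeps the sequence prefix.
    """
    if len(records) == 0:
        raise EmptyInputError("tokenize: empty record list")
    if max_len is not None and max_len < 1:
        raise ValueError("max_len must be positive")
    seqs = [r.sequence for r in records]
    if max_len is not None:
        seqs = [s[:max_len] for s in seqs]
    lengths = np.array([len(s) for s in seqs], dtype=np.int64)
    L = int(lengths.max())
    indices = np.zeros((len(seqs), L), dtype=np.int64)
    for i, s in enumerate(seqs):
        indices[i, : len(s)] = [alphabet.index_of(ch) for ch in s]
    mask = np.arange(L)[None, :] < lengths[:, None]
    labels = None
    if all(r.label is not None for r in records):
        labels = np.array([r.label for r in records], dtype=np.int64)
    return TokenizedBatch(
        indices=indices,
        lengths=lengths,
        mask=mask,
        ids=[r.id for r in records],
        labels=labels,
    )


def detokenize(
    batch: TokenizedBatch, alphabet: Alphabet = DEFAULT_ALPHABET
) -> list[str]:
    """Recover sequences from a batch, honoring the mask."""
    out = []
    for row, length in zip(batch.indices, batch.lengths):
        out.append("".join(alphabet.tokens[i] for i in row[:length]))
    return out
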