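"""Alignment input/output and integer encoding.

Sequences are encoded over a fixed 21-letter alphabet: state 1 is the
alignment gap ``-``, states 2..21 are the 20 standard amino acids in
alphabetical order (A, C, D, ..., Y).  The gap is deliberately the *first*
state: downstream the covariance matrix is built over the first ``q - 1``
states (the last state is dropped to remove the normalization redundancy),
and gap statistics must survive that projection because coevolutionary
signal — e.g. terminal gap stretches in real alignments — lives on the gap
symbol.

Unknown or ambiguous residues (X, B, Z, U, O and anything else outside the
alphabet) are mapped to the gap state, as are ``.`` characters and lowercase
insert-state letters from Stockholm files.  This keeps ``q = 21`` as in
standard mean-field direct coupling analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import AlignIO

logger = logging.getLogger(__name__)

#: state 1 = gap, states 2..21 = amino acids alphabetically
ALPHABET: str = "-ACDEFGHIKLMNPQRSTVWY"
Q: int = len(ALPHABET)  # 21
GAP_STATE: int = 1

_CHAR_TO_STATE: dict[str, int] = {c: i + 1 for i, c in enumerate(ALPHABET)}


class AlignmentShapeError(ValueError):
    """Aligned sequences do not all share the same length."""


class EmptyInputError(ValueError):
    """The alignment file contains no sequences."""


def encode_symbol(c: str) -> int:
    """Map a single character to its state index in ``1..q``.

    Total on all characters: uppercase amino-acid letters map to states
    2..21; ``-``, ``.``, lowercase letters (insert states) and every
    unknown symbol map to the gap state 1.
    """
    if c.islower():
        return GAP_STATE
    return _CHAR_TO_STATE.get(c, GAP_STATE)


@dataclass
class EncodedMSA:
    """Integer-encoded multiple sequence alignment.

    Attributes
    ----------
    data : (M, L) int array with entries in ``1..q``
    labels : per-sequence identifiers
    alphabet : ordered symbols; position ``s-1`` is the character of state ``s``
    """

    data: np.ndarray
    labels: list[str] = field(default_factory=list)
    alphabet: str = ALPHABET

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int64)
        if self.data.ndim != 2:
            raise AlignmentShapeError("alignment matrix must be 2-dimensional")
        if self.data.shape[1] < 2:
            raise AlignmentShapeError("alignment must have at least 2 columns")
        if self.data.shape[0] < 1:
            raise EmptyInputError("alignment must contain at least one sequence")
        q = self.q
        if len(set(self.alphabet)) != q or "-" not in self.alphabet:
            raise ValueError("alphabet must hold q distinct symbols incl. the gap")
        if self.data.min() < 1 or self.data.max() > q:
            raise ValueError(f"state indices must lie in [1, {q}]")
        if not self.labels:
            self.labels = [f"seq{b + 1}" for b in range(self.M)]
        if len(self.labels) != self.M:
            raise ValueError("one label per sequence required")

    @property
    def M(self) -> int:
        """Number of sequences."""
        return self.data.shape[0]

    @property
    def L(self) -> int:
        """Number of aligned positions."""
        return self.data.shape[1]

    @property
    def q(self) -> int:
        """Alphabet size."""
        return len(self.alphabet)

    def sequence_string(self, b: int) -> str:
        """Decode row ``b`` (0-based) back to characters."""
        return "".join(self.alphabet[s - 1] for s in self.data[b])


def encode_sequences(seqs: Sequence[str], labels: Sequence[str] | None = None) -> EncodedMSA:
    """Encode raw aligned strings into an :class:`EncodedMSA`."""
    if not seqs:
        raise EmptyInputError("no sequences given")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise AlignmentShapeError(f"unequal sequence lengths: {sorted(lengths)}")
    data = np.array([[encode_symbol(c) for c in s] for s in seqs], dtype=np.int64)
    n_unknown = sum(
        1 for s in seqs for c in s if c not in _CHAR_TO_STATE and c not in ".-" and not c.islower()
    )
    msa = EncodedMSA(data, labels=list(labels) if labels else [])
    logger.info(
        "encoded alignment: M=%d, L=%d, unknown residues mapped to gap: %d",
        msa.M, msa.L, n_unknown,
    )
    return msa


def read_alignment(path: str | Path, format: str = "fasta") -> EncodedMSA:
    """Read a FASTA or Stockholm alignment into an :class:`EncodedMSA`.

    ``.`` and lowercase insert states become the gap state; unknown residues
    become the gap state.  Raises :class:`EmptyInputError` for an empty file,
    :class:`AlignmentShapeError` for ragged alignments, and ``ValueError``
    for unparsable content.
    """
    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format: {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        records = list(AlignIO.read(str(path), format))
    except ValueError as exc:
        # Bio.AlignIO signals both empty input and ragged rows via ValueError
        text = path.read_text().strip()
        if not text:
            raise EmptyInputError(f"empty alignment file: {path}") from exc
        if "length" in str(exc).lower():
            raise AlignmentShapeError(str(exc)) from exc
        raise ValueError(f"could not parse {path} as {format}: {exc}") from exc
    if not records:
        raise EmptyInputError(f"no sequences in {path}")
    return encode_sequences([str(r.seq) for r in records], [r.id for r in records])


def write_alignment(msa: EncodedMSA, path: str | Path) -> None:
    """Write an :class:`EncodedMSA` as plain FASTA."""
    with open(path, "w") as fh:
        for b in range(msa.M):
            fh.write(f">{msa.labels[b]}\n{msa.sequence_string(b)}\n")


def write_encoded_tsv(msa: EncodedMSA, path: str | Path) -> None:
    """Write the encoded matrix as TSV (1-based positions and states)."""
    with open(path, "w") as fh:
        fh.write("sequence\t" + "\t".join(str(i + 1) for i in range(msa.L)) + "\n")
        for b in range(msa.M):
            fh.write(msa.labels[b] + "\t" + "\t".join(map(str, msa.data[b])) + "\n")
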