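"""Pairwise sequence identity from a multiple alignment.

The mitochondrial stage of the pipeline consumes an externally computed
multiple sequence alignment (e.g. MUSCLE output) and reduces it to a
species-by-species identity matrix, which then feeds the same clustering
and tree machinery as the k-mer correlation matrix.

Counting conventions differ between alignment viewers, so they are
explicit and switchable here (:class:`IdentityDialect`). The defaults:
columns where both rows are gaps are excluded from the denominator, a gap
aligned to a letter counts as a mismatch, and ambiguous bases (anything
outside A/C/G/T/-) match nothing, not even themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .compare import CorrelationMatrix
from .exceptions import DegenerateInputError, InvalidInputError

__all__ = ["AlignmentBlock", "IdentityDialect", "identity_pair", "identity_matrix"]

_GAP = ord("-")
_ACGT = frozenset(b"ACGT")


@dataclass(frozen=True)
class AlignmentBlock:
    """A multiple alignment: equal-length uppercase rows with unique labels."""

    labels: tuple[str, ...]
    rows: tuple[str, ...]

    def __init__(self, labels, rows):
        labels = tuple(str(l) for l in labels)
        rows = tuple(str(r).upper() for r in rows)
        if len(labels) != len(rows):
            raise InvalidInputError(f"{len(labels)} labels but {len(rows)} rows")
        if not rows:
            raise InvalidInputError("alignment has no rows")
        if len(set(labels)) != len(labels):
            raise InvalidInputError("alignment labels must be unique")
        width = len(rows[0])
        if width < 1:
            raise InvalidInputError("alignment rows must be non-empty")
        for label, row in zip(labels, rows):
            if len(row) != width:
                raise InvalidInputError(
                    f"row {label!r} has length {len(row)}, expected {width}"
                )
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "rows", rows)

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0])


@dataclass(frozen=True)
class IdentityDialect:
    """Switchable counting conventions for alignment identity.

    both_gap: "exclude" drops columns gapped in both rows from the
        denominator; "match" counts them as identical positions.
    gap_letter: "mismatch" counts gap-vs-letter columns in the denominator
        as differences; "exclude" drops them.
    ambiguous: "mismatch" makes any non-ACGT letter (N, IUPAC codes) match
        nothing; "match" lets equal letters match regardless.
    """

    both_gap: Literal["exclude", "match"] = "exclude"
    gap_letter: Literal["mismatch", "exclude"] = "mismatch"
    ambiguous: Literal["mismatch", "match"] = "mismatch"


DEFAULT_DIALECT = IdentityDialect()


def _row_bytes(row: str) -> np.ndarray:
    return np.frombuffer(row.upper().encode("ascii", "replace"), dtype=np.uint8)


def _identity_from_bytes(a: np.ndarray, b: np.ndarray, dialect: IdentityDialect) -> float:
    gap_a, gap_b = a == _GAP, b == _GAP
    both_gap = gap_a & gap_b
    one_gap = gap_a ^ gap_b
    counted = np.ones(a.shape[0], dtype=bool)
    if dialect.both_gap == "exclude":
        counted &= ~both_gap
    if dialect.gap_letter == "exclude":
        counted &= ~one_gap
    matches = a == b
    if dialect.ambiguous == "mismatch":
        valid = np.isin(a, np.frombuffer(b"ACGT", dtype=np.uint8))
        # both-gap "matches" are governed by the gap switch, not this one
        matches &= valid | both_gap
    denom = int(counted.sum())
    if denom == 0:
        raise DegenerateInputError("no counted columns: identity undefined")
    return float((matches & counted).sum() / denom)


def identity_pair(row_a: str, row_b: str, dialect: IdentityDialect = DEFAULT_DIALECT) -> float:
    """Fraction of counted alignment columns where two rows agree, in [0, 1]."""
    if len(row_a) != len(row_b):
        raise InvalidInputError(
            f"aligned rows differ in length: {len(row_a)} vs {len(row_b)}"
        )
    return _identity_from_bytes(_row_bytes(row_a), _row_bytes(row_b), dialect)


def identity_matrix(
    alignment: AlignmentBlock, dialect: IdentityDialect = DEFAULT_DIALECT
) -> CorrelationMatrix:
    """All-pairs identity matrix of an alignment (kind="identity")."""
    if alignment.n < 2:
        raise InvalidInputError("need at least two aligned sequences")
    rows = [_row_bytes(r) for r in alignment.rows]
    n = alignment.n
    M = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = _identity_from_bytes(rows[i], rows[j], dialect)
    return CorrelationMatrix(labels=alignment.labels, values=M, kind="identity")
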