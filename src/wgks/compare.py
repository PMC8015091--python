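"""All-pairs Pearson correlation of signature vectors.

Two species' signatures are compared with the ordinary product-moment
correlation over the full 4**k score vector; correlations close to 1 mark
closely related species. The matrix container is shared with the identity
stage (``kind="identity"``), so the downstream clustering and tree code is
agnostic to which similarity was used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, InvalidInputError
from .kmer import SignatureVector

__all__ = ["CorrelationMatrix", "pearson", "pcc_matrix"]

_SYM_TOL = 1e-12


@dataclass(frozen=True)
class CorrelationMatrix:
    """Square symmetric similarity matrix with species labels.

    ``kind`` is "pcc" for signature correlations (values in [-1, 1]) or
    "identity" for alignment identity fractions (values in [0, 1]). The
    diagonal is exactly 1.
    """

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    kind: str = "pcc"

    def __post_init__(self):
        labels = tuple(str(x) for x in self.labels)
        values = np.asarray(self.values, dtype=np.float64)
        n = len(labels)
        if len(set(labels)) != n:
            raise InvalidInputError("species labels must be unique")
        if values.shape != (n, n):
            raise InvalidInputError(
                f"matrix shape {values.shape} does not match {n} labels"
            )
        if self.kind not in ("pcc", "identity"):
            raise InvalidInputError(f"unknown matrix kind {self.kind!r}")
        if n and np.abs(values - values.T).max() > _SYM_TOL:
            raise InvalidInputError("matrix is not symmetric")
        if n and np.abs(np.diag(values) - 1.0).max() > _SYM_TOL:
            raise InvalidInputError("matrix diagonal must be 1")
        lo = -1.0 if self.kind == "pcc" else 0.0
        if n and ((values < lo - _SYM_TOL).any() or (values > 1.0 + _SYM_TOL).any()):
            raise InvalidInputError(f"{self.kind} values out of [{lo}, 1]")
        values = np.clip((values + values.T) / 2.0, lo, 1.0)
        np.fill_diagonal(values, 1.0)
        values.flags.writeable = False
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return len(self.labels)

    def distances(self) -> np.ndarray:
        """Distance transform d = 1 - similarity (zero diagonal)."""
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return d

    def pair(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def submatrix(self, labels: Sequence[str]) -> "CorrelationMatrix":
        idx = [self.labels.index(l) for l in labels]
        return CorrelationMatrix(
            labels=tuple(labels), values=self.values[np.ix_(idx, idx)], kind=self.kind
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))


def pearson(a: SignatureVector, b: SignatureVector) -> float:
    """Pearson correlation of two signatures over all 4**k entries."""
    if a.k != b.k:
        raise InvalidInputError(f"signatures have different k: {a.k} vs {b.k}")
    x, y = a.scores, b.scores
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise DegenerateInputError(
            "zero-variance signature: Pearson correlation undefined "
            f"({a.species_label!r} vs {b.species_label!r})"
        )
    return float(np.corrcoef(x, y)[0, 1])


def pcc_matrix(signatures: Sequence[SignatureVector]) -> CorrelationMatrix:
    """Correlate every pair of signatures into a square PCC matrix.

    Label order is preserved from the input. Signatures must share k and
    carry unique labels; any zero-variance signature is rejected rather
    than silently producing NaN rows.
    """
    if len(signatures) < 2:
        raise InvalidInputError("need at least two signatures")
    ks = {s.k for s in signatures}
    if len(ks) > 1:
        raise InvalidInputError(f"signatures mix word lengths: {sorted(ks)}")
    labels = [s.species_label for s in signatures]
    if len(set(labels)) != len(labels):
        raise InvalidInputError("duplicate species labels among signatures")
    X = np.vstack([s.scores for s in signatures])
    sd = X.std(axis=1)
    if (sd == 0.0).any():
        flat = [l for l, s in zip(labels, sd) if s == 0.0]
        raise DegenerateInputError(f"zero-variance signature(s): {flat}")
    C = np.corrcoef(X)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return CorrelationMatrix(labels=tuple(labels), values=C, kind="pcc")
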