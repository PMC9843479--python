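"""Labelled square dissimilarity matrices."""
from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

_SYM_TOL = 1e-9


class DissimilarityMatrix:
    """A symmetric, zero-diagonal, non-negative matrix with row/column labels.

    Used both for patristic (phylogenetic) distances and Gower (functional)
    dissimilarities, and consumed by MPD/MFD and the randomization nulls.
    """

    def __init__(self, labels: Sequence[str], values: np.ndarray, validate: bool = True):
        self.labels = [str(x) for x in labels]
        self.values = np.asarray(values, dtype=float)
        self._index = {lab: i for i, lab in enumerate(self.labels)}
        if validate:
            self._validate()

    def _validate(self) -> None:
        n = len(self.labels)
        if len(self._index) != n:
            raise ValidationError("duplicate labels in dissimilarity matrix")
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("dissimilarity matrix contains non-finite entries")
        if np.any(self.values < 0):
            raise ValidationError("dissimilarity matrix contains negative entries")
        if not np.allclose(self.values, self.values.T, atol=_SYM_TOL):
            raise ValidationError("dissimilarity matrix is not symmetric")
        if np.any(np.abs(np.diag(self.values)) > _SYM_TOL):
            raise ValidationError("dissimilarity matrix diagonal is not zero")
        # force exact symmetry / zero diagonal so downstream code need not care
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, labels: Sequence[str]) -> np.ndarray:
        missing = [l for l in labels if l not in self._index]
        if missing:
            raise ValidationError(f"labels not in matrix: {missing}")
        return np.array([self._index[l] for l in labels], dtype=np.int64)

    def submatrix(self, labels: Sequence[str]) -> "DissimilarityMatrix":
        idx = self.index_of(labels)
        return DissimilarityMatrix(list(labels), self.values[np.ix_(idx, idx)], validate=False)

    def offdiagonal(self) -> np.ndarray:
        """All off-diagonal entries (each unordered pair twice)."""
        mask = ~np.eye(self.n, dtype=bool)
        return self.values[mask]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DissimilarityMatrix":
        if list(df.index) != list(df.columns):
            raise ValidationError("dissimilarity data frame must have identical index and columns")
        return cls(list(df.index), df.to_numpy(dtype=float))

    def __repr__(self) -> str:  # pragma: no cover
        return f"DissimilarityMatrix(n={self.n})"
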