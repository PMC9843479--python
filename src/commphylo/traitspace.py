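"""Mixed-type trait tables, Gower dissimilarity and UPGMA dendrograms."""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .errors import ValidationError
from .matrix import DissimilarityMatrix
from .treeio import Phylogeny

__all__ = ["TraitTable", "gower_matrix", "upgma", "grouped_weights"]

TRAIT_TYPES = ("continuous", "binary")


class TraitTable:
    """Species x traits table where every column is typed ``continuous`` or
    ``binary``.

    The on-disk format is a CSV whose first column holds species labels and
    whose first data row, labelled ``#type``, types each column.
    """

    def __init__(self, data: pd.DataFrame, types: Mapping[str, str], validate: bool = True):
        self.data = data.copy()
        self.data.index = self.data.index.astype(str)
        self.data.index.name = "species"
        self.types = {str(k): str(v) for k, v in types.items()}
        if validate:
            self._validate()

    def _validate(self) -> None:
        df = self.data
        if df.shape[0] < 2:
            raise ValidationError("trait table needs at least 2 species")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate species in trait table: {dups}")
        missing_types = [c for c in df.columns if c not in self.types]
        if missing_types:
            raise ValidationError(f"columns without a declared type: {missing_types}")
        bad = {c: t for c, t in self.types.items() if t not in TRAIT_TYPES}
        if bad:
            raise ValidationError(f"unknown trait types {bad}; expected one of {TRAIT_TYPES}")
        arr = df.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            cols = df.columns[~np.isfinite(arr).all(axis=0)].tolist()
            raise ValidationError(f"missing/non-finite values in trait columns: {cols}")
        for c in df.columns:
            if self.types[c] == "binary":
                vals = set(np.unique(df[c].to_numpy(dtype=float)))
                if not vals <= {0.0, 1.0}:
                    raise ValidationError(f"binary column {c!r} contains values other than 0/1")

    @property
    def species(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def columns(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    def continuous_columns(self) -> list[str]:
        return [c for c in self.columns if self.types[c] == "continuous"]

    def binary_columns(self) -> list[str]:
        return [c for c in self.columns if self.types[c] == "binary"]

    def to_csv(self, path: str) -> None:
        out = pd.concat(
            [pd.DataFrame([self.types], index=["#type"]), self.data], axis=0
        )
        out.to_csv(path, index_label="species")

    @classmethod
    def from_csv(cls, path: str) -> "TraitTable":
        raw = pd.read_csv(path, index_col=0)
        if "#type" not in raw.index:
            raise ValidationError(
                "trait CSV must contain a '#type' row typing each column as continuous|binary"
            )
        types = raw.loc["#type"].to_dict()
        data = raw.drop(index="#type").astype(float)
        data.index = data.index.astype(str)
        return cls(data, types)


def grouped_weights(groups: Mapping[str, str]) -> dict[str, float]:
    """Weights that give each named column *group* a total weight of 1
    (e.g. to downweight an 8-column binary family to the weight of a single
    continuous trait)."""
    sizes: dict[str, int] = {}
    for g in groups.values():
        sizes[g] = sizes.get(g, 0) + 1
    return {col: 1.0 / sizes[g] for col, g in groups.items()}


def gower_matrix(
    traits: TraitTable,
    weights: Mapping[str, float] | Sequence[float] | None = None,
) -> DissimilarityMatrix:
    """Gower dissimilarity over a mixed continuous/binary trait table.

    ``d(i,j) = sum_k w_k * delta_k(i,j) / sum_k w_k`` with
    ``delta_k = |x_ik - x_jk| / range_k`` for continuous columns and the
    simple mismatch indicator for binary columns (0/0 counts as agreement).
    Default weights are equal per column.
    """
    cols = traits.columns
    if weights is None:
        w = np.ones(len(cols))
    elif isinstance(weights, Mapping):
        missing = [c for c in cols if c not in weights]
        if missing:
            raise ValidationError(f"weights missing for columns: {missing}")
        w = np.array([float(weights[c]) for c in cols])
    else:
        w = np.asarray(weights, dtype=float)
        if w.size != len(cols):
            raise ValidationError("weight vector length does not match column count")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValidationError("weights must be non-negative with positive sum")

    X = traits.data.to_numpy(dtype=float)
    n = X.shape[0]
    acc = np.zeros((n, n))
    for k, c in enumerate(cols):
        col = X[:, k]
        if traits.types[c] == "continuous":
            rng = col.max() - col.min()
            if rng <= 0:
                raise ValidationError(
                    f"continuous trait {c!r} has zero range; drop or rescale it explicitly"
                )
            delta = np.abs(col[:, None] - col[None, :]) / rng
        else:
            delta = (col[:, None] != col[None, :]).astype(float)
        acc += w[k] * delta
    d = acc / w.sum()
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(traits.species, d, validate=False)


def upgma(d: DissimilarityMatrix) -> Phylogeny:
    """UPGMA dendrogram of a dissimilarity matrix, returned as an
    ultrametric :class:`Phylogeny` whose merge heights are half the merge
    dissimilarity (so cophenetic tip-to-tip distance equals the merge value).

    Ties are broken by the underlying nearest-neighbor-chain linkage; the
    resolution is deterministic for a given input ordering.
    """
    if d.n < 2:
        raise ValidationError("UPGMA needs at least 2 items")
    Z = linkage(squareform(d.values, checks=False), method="average")
    n = d.n
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    ages = np.zeros(n_nodes)
    labels: list[str | None] = list(d.labels) + [None] * (n - 1)
    for i in range(n - 1):
        a, b, height = int(Z[i, 0]), int(Z[i, 1]), Z[i, 2] / 2.0
        new = n + i
        parent[a] = new
        parent[b] = new
        ages[new] = height
    lengths = np.zeros(n_nodes)
    for i in range(n_nodes - 1):  # root is the last-created node
        lengths[i] = ages[parent[i]] - ages[i]
    # guard against tiny negative values from floating error (UPGMA itself
    # cannot produce inversions)
    lengths = np.maximum(lengths, 0.0)
    return Phylogeny(parent, lengths, labels)
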