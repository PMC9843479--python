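"""Per-site diversity indices: species richness, branch-length diversity
(Faith PD on a phylogeny, dendrogram FD on a functional tree), mean pairwise
distances (MPD/MFD) and index intercorrelations."""
from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .matrix import DissimilarityMatrix
from .treeio import Phylogeny

__all__ = [
    "CommunityMatrix",
    "species_richness",
    "branch_length_diversity",
    "mean_pairwise_distance",
    "index_correlations",
    "diversity_table",
]


class CommunityMatrix:
    """Sites x species 0/1 incidence matrix."""

    def __init__(self, data: pd.DataFrame, validate: bool = True):
        self.data = data.copy()
        if validate:
            self._validate()
        self.data = self.data.astype(np.int64)

    def _validate(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise ValidationError("duplicate site labels in community matrix")
        if df.columns.has_duplicates:
            raise ValidationError("duplicate species labels in community matrix")
        arr = df.to_numpy(dtype=float)
        if not np.all(np.isin(arr, (0.0, 1.0))):
            raise ValidationError("community matrix entries must be 0 or 1")

    @property
    def sites(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def species(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    def incidence(self) -> np.ndarray:
        return self.data.to_numpy(dtype=np.int64)

    def to_csv(self, path: str) -> None:
        self.data.to_csv(path, index_label="site")

    @classmethod
    def from_csv(cls, path: str) -> "CommunityMatrix":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        return cls(df)


def species_richness(cm: CommunityMatrix) -> pd.Series:
    """Row sums of the incidence matrix."""
    sr = cm.data.sum(axis=1)
    sr.name = "SR"
    return sr


def branch_length_diversity(
    tree: Phylogeny, cm: CommunityMatrix, include_root: bool = True
) -> pd.Series:
    """Faith-style branch-length diversity per site: total branch length of
    the minimal subtree spanning each site's species.

    With ``include_root`` (default) the path from the spanning subtree up to
    the root is counted, so a single-species site scores that tip's
    root-path length; without it, edges above the site MRCA are excluded.
    Works identically on a phylogeny (PD) and a functional dendrogram (FD).
    """
    tipmap = set(tree.tip_labels)
    missing = [s for s in cm.species if s not in tipmap]
    if missing:
        raise ValidationError(f"species absent from tree: {missing}")
    A = tree.descendant_tip_matrix()  # (n_nodes, n_tips)
    order = {lab: j for j, lab in enumerate(tree.tip_labels)}
    cols = np.array([order[s] for s in cm.species], dtype=np.int64)
    inc = cm.incidence().astype(bool)
    values = np.zeros(len(cm.sites))
    empty = []
    for i in range(inc.shape[0]):
        present = cols[inc[i]]
        if present.size == 0:
            empty.append(cm.sites[i])
            values[i] = 0.0
            continue
        sub = A[:, present]
        any_below = sub.any(axis=1)
        if include_root:
            keep = any_below
        else:
            keep = any_below & ~sub.all(axis=1)
        values[i] = tree.lengths[keep].sum()
    if empty:
        warnings.warn(f"empty sites scored 0 branch-length diversity: {empty}")
    return pd.Series(values, index=cm.sites, name="BLD")


def mean_pairwise_distance(d: DissimilarityMatrix, cm: CommunityMatrix) -> pd.Series:
    """Unweighted mean pairwise dissimilarity among each site's species.

    Sites with fewer than two species are undefined and reported as NaN
    (with a warning) rather than aborting a batch run.
    """
    idx = d.index_of(cm.species)
    inc = cm.incidence().astype(float)
    sub = d.values[np.ix_(idx, idx)]
    r = inc.sum(axis=1)
    tot = np.einsum("ip,pq,iq->i", inc, sub, inc)
    with np.errstate(divide="ignore", invalid="ignore"):
        mpd = tot / (r * (r - 1.0))
    mpd = np.where(r >= 2, mpd, np.nan)
    low = [s for s, k in zip(cm.sites, r) if k < 2]
    if low:
        warnings.warn(f"MPD undefined for sites with <2 species: {low}")
    return pd.Series(mpd, index=cm.sites, name="MPD")


def index_correlations(
    dt: pd.DataFrame, columns: Sequence[str] = ("SR", "PD", "FD")
) -> pd.DataFrame:
    """Pairwise Pearson correlations (with two-sided p-values) among
    diversity indices, returned long-form with columns a, b, r, p."""
    if dt.shape[0] < 3:
        raise ValidationError("need at least 3 sites for correlations")
    missing = [c for c in columns if c not in dt.columns]
    if missing:
        raise ValidationError(f"columns missing from diversity table: {missing}")
    rows = []
    for i, a in enumerate(columns):
        for b in columns[i + 1:]:
            x = dt[a].to_numpy(dtype=float)
            y = dt[b].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append({"a": a, "b": b, "r": np.nan, "p": np.nan,
                             "note": "zero variance"})
                continue
            r, p = stats.pearsonr(x, y)
            rows.append({"a": a, "b": b, "r": r, "p": p, "note": ""})
    return pd.DataFrame(rows)


def diversity_table(
    tree: Phylogeny,
    dendrogram: Phylogeny,
    d_phylo: DissimilarityMatrix,
    d_func: DissimilarityMatrix,
    cm: CommunityMatrix,
    include_root: bool = True,
) -> pd.DataFrame:
    """SR, PD, FD, MPD and MFD per site in one table."""
    out = pd.DataFrame(index=pd.Index(cm.sites, name="site"))
    out["SR"] = species_richness(cm).to_numpy()
    out["PD"] = branch_length_diversity(tree, cm, include_root=include_root).to_numpy()
    out["FD"] = branch_length_diversity(dendrogram, cm, include_root=include_root).to_numpy()
    out["MPD"] = mean_pairwise_distance(d_phylo, cm).to_numpy()
    out["MFD"] = mean_pairwise_distance(d_func, cm).to_numpy()
    return out
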