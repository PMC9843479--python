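"""Phylogeny container, Newick/NEXUS I/O, pruning, patristic distances and
maximum clade credibility summarization of tree samples.

The internal representation is array-based: a parent pointer, a branch length
and an optional label per node.  ``lengths[root]`` holds a retained root-path
(stem) length, zero for freshly parsed trees unless the Newick string carries
a root edge length.
"""
from __future__ import annotations

import math
import re
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .errors import NewickParseError, ValidationError
from .matrix import DissimilarityMatrix

__all__ = [
    "Phylogeny",
    "TreeSample",
    "parse_newick",
    "write_newick",
    "read_tree",
    "read_trees",
    "prune_to",
    "patristic_matrix",
    "phylo_covariance",
    "mcc_tree",
]


class Phylogeny:
    """A rooted tree with branch lengths and labelled tips.

    Parameters
    ----------
    parent:
        Integer array; ``parent[i]`` is the parent node of ``i`` and ``-1``
        marks the single root.
    lengths:
        Branch length of the edge above each node (the root entry is the
        retained stem length, usually 0).  All entries must be finite and
        non-negative; zero-length branches are allowed.
    labels:
        Per-node label or ``None``.  Tips must carry unique non-empty labels.
    """

    def __init__(
        self,
        parent: Sequence[int],
        lengths: Sequence[float],
        labels: Sequence[str | None],
        validate: bool = True,
    ):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=float)
        self.labels = list(labels)
        n = self.parent.size
        self.children: list[list[int]] = [[] for _ in range(n)]
        roots = []
        for i, p in enumerate(self.parent):
            if p < 0:
                roots.append(i)
            else:
                self.children[p].append(i)
        if validate:
            if n == 0:
                raise ValidationError("empty tree")
            if len(roots) != 1:
                raise ValidationError(f"tree must have exactly one root, found {len(roots)}")
            if self.lengths.size != n or len(self.labels) != n:
                raise ValidationError("parent, lengths and labels must have equal size")
            if not np.all(np.isfinite(self.lengths)):
                raise ValidationError("branch lengths must be finite")
            if np.any(self.lengths < 0):
                raise ValidationError("negative branch lengths are not allowed")
        self.root = roots[0]
        self._tips = np.array(
            [i for i in range(n) if not self.children[i]], dtype=np.int64
        )
        if validate:
            self._validate_tips()
            self._check_connected()

    def _validate_tips(self) -> None:
        seen: set[str] = set()
        for t in self._tips:
            lab = self.labels[t]
            if lab is None or lab == "":
                raise ValidationError(f"tip node {t} has no label")
            if lab in seen:
                raise ValidationError(f"duplicate tip label: {lab!r}")
            seen.add(lab)

    def _check_connected(self) -> None:
        order = self.preorder()
        if order.size != self.n_nodes:
            raise ValidationError("tree graph is not connected (cycle or orphan nodes)")

    # -- basic structure -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_tips(self) -> int:
        return self._tips.size

    @property
    def tips(self) -> np.ndarray:
        return self._tips

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[t] for t in self._tips]

    def tip_index(self) -> dict[str, int]:
        return {self.labels[t]: int(t) for t in self._tips}

    def preorder(self) -> np.ndarray:
        order = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(reversed(self.children[node]))
        return np.array(order, dtype=np.int64)

    def postorder(self) -> np.ndarray:
        return self.preorder()[::-1]

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths, including the retained stem length."""
        d = np.zeros(self.n_nodes)
        for node in self.preorder():
            p = self.parent[node]
            d[node] = self.lengths[node] + (d[p] if p >= 0 else 0.0)
        return d

    def total_length(self) -> float:
        return float(self.lengths.sum())

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        td = self.depths()[self._tips]
        return bool(np.ptp(td) <= tol) if td.size else True

    def descendant_tip_matrix(self) -> np.ndarray:
        """Boolean (n_nodes, n_tips): entry [v, j] true iff tip j descends
        from (or is) node v.  Tip columns follow ``tip_labels`` order."""
        A = np.zeros((self.n_nodes, self.n_tips), dtype=bool)
        tip_pos = {int(t): j for j, t in enumerate(self._tips)}
        for node in self.postorder():
            if not self.children[node]:
                A[node, tip_pos[int(node)]] = True
            else:
                for c in self.children[node]:
                    A[node] |= A[c]
        return A

    # -- serialization ---------------------------------------------------
    def to_newick(self, precision: int = 12) -> str:
        def fmt_len(x: float) -> str:
            return format(float(x), f".{precision}g")

        def fmt_label(lab: str | None) -> str:
            if lab is None:
                return ""
            if re.search(r"[\s()\[\]{}:;,']", lab):
                return "'" + lab.replace("'", "''") + "'"
            return lab

        def rec(node: int) -> str:
            if not self.children[node]:
                body = fmt_label(self.labels[node])
            else:
                body = "(" + ",".join(rec(c) for c in self.children[node]) + ")" + fmt_label(
                    self.labels[node]
                )
            if node == self.root:
                if self.lengths[node] != 0.0:
                    return body + ":" + fmt_len(self.lengths[node])
                return body
            return body + ":" + fmt_len(self.lengths[node])

        return rec(self.root) + ";"

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.parent.copy(), self.lengths.copy(), list(self.labels), validate=False)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny(n_tips={self.n_tips}, total_length={self.total_length():.4g})"


class TreeSample:
    """An ordered collection of trees over an identical tip-label set."""

    def __init__(self, trees: Iterable[Phylogeny]):
        self.trees = list(trees)
        if not self.trees:
            raise ValidationError("tree sample must be non-empty")
        ref = set(self.trees[0].tip_labels)
        for i, t in enumerate(self.trees[1:], start=1):
            if set(t.tip_labels) != ref:
                raise ValidationError(f"tree {i} has a different tip set from tree 0")
        self.tip_labels = sorted(ref)

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i: int) -> Phylogeny:
        return self.trees[i]


# ---------------------------------------------------------------------------
# parsing / writing
# ---------------------------------------------------------------------------

def _from_dendropy(dtree: "dendropy.Tree") -> Phylogeny:
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=np.int64)
    lengths = np.zeros(len(nodes))
    labels: list[str | None] = [None] * len(nodes)
    for nd in nodes:
        i = index[id(nd)]
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
        if nd.edge.length is not None:
            lengths[i] = float(nd.edge.length)
        if nd.taxon is not None:
            labels[i] = nd.taxon.label
        elif nd.label:
            labels[i] = nd.label
    return Phylogeny(parent, lengths, labels)


def parse_newick(text: str) -> Phylogeny:
    """Parse a single Newick tree from a string.

    Accepts quoted labels, scientific-notation branch lengths and ignores
    square-bracket comments.  Raises :class:`NewickParseError` on malformed
    input (reporting the offending position where available) and
    :class:`ValidationError` on duplicate tip labels or negative lengths.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        if "Duplicate taxon labels" in str(exc):
            raise ValidationError(f"duplicate tip labels in Newick input: {exc}") from exc
        offset = ""
        line = getattr(exc, "line_num", None)
        col = getattr(exc, "col_num", None)
        if line is not None and col is not None:
            offset = f" (line {line}, column {col})"
        raise NewickParseError(f"malformed Newick{offset}: {exc}") from exc
    return _from_dendropy(dtree)


def write_newick(tree: Phylogeny) -> str:
    return tree.to_newick()


def read_tree(path: str) -> Phylogeny:
    with open(path) as fh:
        return parse_newick(fh.read())


def read_trees(path: str, schema: str | None = None) -> TreeSample:
    """Read a multi-tree file (concatenated Newick, or a NEXUS trees block)."""
    if schema is None:
        with open(path) as fh:
            head = fh.read(512).lstrip().lower()
        schema = "nexus" if head.startswith("#nexus") else "newick"
    try:
        dtrees = dendropy.TreeList.get(
            path=path, schema=schema, preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickParseError(f"could not read trees from {path!r}: {exc}") from exc
    return TreeSample(_from_dendropy(t) for t in dtrees)


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def prune_to(tree: Phylogeny, species: Iterable[str]) -> Phylogeny:
    """Restrict a tree to ``species``: the induced subtree with unbranched
    internal nodes suppressed (lengths summed) and the root path retained as
    the new stem length."""
    keep = set(species)
    if not keep:
        raise ValidationError("cannot prune to an empty species set")
    tipmap = tree.tip_index()
    unknown = sorted(k for k in keep if k not in tipmap)
    if unknown:
        raise ValidationError(f"species not in tree: {unknown}")

    kept = np.zeros(tree.n_nodes, dtype=bool)
    for node in tree.postorder():
        if not tree.children[node]:
            kept[node] = tree.labels[node] in keep
        else:
            kept[node] = any(kept[c] for c in tree.children[node])

    parent_out: list[int] = []
    lengths_out: list[float] = []
    labels_out: list[str | None] = []

    def add_node(par: int, length: float, label: str | None) -> int:
        parent_out.append(par)
        lengths_out.append(length)
        labels_out.append(label)
        return len(parent_out) - 1

    def descend(node: int, acc: float, par: int) -> None:
        """Walk down from ``node`` (whose accumulated pending edge length is
        ``acc``) collapsing unary retained chains."""
        kids = [c for c in tree.children[node] if kept[c]]
        while len(kids) == 1 and tree.children[node]:
            node = kids[0]
            acc += tree.lengths[node]
            kids = [c for c in tree.children[node] if kept[c]]
        new = add_node(par, acc, tree.labels[node] if not tree.children[node] else None)
        for c in kids:
            descend(c, tree.lengths[c], new)

    descend(tree.root, tree.lengths[tree.root], -1)
    return Phylogeny(parent_out, lengths_out, labels_out)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def patristic_matrix(tree: Phylogeny) -> DissimilarityMatrix:
    """Tip-to-tip path-length (patristic) distances, ordered by ``tip_labels``."""
    n = tree.n_tips
    tip_pos = {int(t): j for j, t in enumerate(tree.tips)}
    D = np.zeros((n, n))
    # per-node: (tip positions, distance from each tip up to this node)
    store: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for node in tree.postorder():
        if not tree.children[node]:
            store[node] = (np.array([tip_pos[int(node)]]), np.zeros(1))
            continue
        groups = []
        for c in tree.children[node]:
            ids, dist = store.pop(c)
            groups.append((ids, dist + tree.lengths[c]))
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                ia, da = groups[a]
                ib, db = groups[b]
                block = da[:, None] + db[None, :]
                D[np.ix_(ia, ib)] = block
                D[np.ix_(ib, ia)] = block.T
        store[node] = (
            np.concatenate([g[0] for g in groups]),
            np.concatenate([g[1] for g in groups]),
        )
    return DissimilarityMatrix(tree.tip_labels, D, validate=False)


def phylo_covariance(tree: Phylogeny) -> tuple[list[str], np.ndarray]:
    """Brownian-motion covariance matrix implied by the tree: shared
    root-to-MRCA path length for each tip pair, tip depth on the diagonal."""
    depths = tree.depths()
    n = tree.n_tips
    tip_pos = {int(t): j for j, t in enumerate(tree.tips)}
    C = np.zeros((n, n))
    store: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if not tree.children[node]:
            j = tip_pos[int(node)]
            C[j, j] = depths[node]
            store[node] = np.array([j])
            continue
        groups = [store.pop(c) for c in tree.children[node]]
        h = depths[node]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                C[np.ix_(groups[a], groups[b])] = h
                C[np.ix_(groups[b], groups[a])] = h
        store[node] = np.concatenate(groups)
    return tree.tip_labels, C


# ---------------------------------------------------------------------------
# MCC summarization
# ---------------------------------------------------------------------------

def _clades_and_ages(tree: Phylogeny, pos: dict[str, int]) -> dict[int, float]:
    """Map bitmask-of-tips -> node age (mean path length to descendant tips)
    for every internal node (including the root)."""
    out: dict[int, float] = {}
    # (bitmask, tip count, summed tip distance) accumulated tip-ward
    store: dict[int, tuple[int, int, float]] = {}
    for node in tree.postorder():
        if not tree.children[node]:
            store[node] = (1 << pos[tree.labels[node]], 1, 0.0)
            continue
        mask, cnt, dist = 0, 0, 0.0
        for c in tree.children[node]:
            m, k, s = store.pop(c)
            mask |= m
            cnt += k
            dist += s + k * tree.lengths[c]
        store[node] = (mask, cnt, dist)
        out[mask] = dist / cnt
    return out


def mcc_tree(sample: TreeSample, heights: str = "mean") -> Phylogeny:
    """Maximum clade credibility summary of a tree sample.

    Selects the *member* tree maximizing the product of clade credibilities
    (frequency of each internal-node tip bipartition across the sample) and
    replaces node heights by the mean age of the matching clade over the
    trees that contain it.  Never builds a consensus topology.
    """
    if heights != "mean":
        raise ValueError("only heights='mean' is supported")
    pos = {lab: i for i, lab in enumerate(sample.tip_labels)}
    per_tree = [_clades_and_ages(t, pos) for t in sample]
    counts: dict[int, int] = {}
    age_sum: dict[int, float] = {}
    for clades in per_tree:
        for mask, age in clades.items():
            counts[mask] = counts.get(mask, 0) + 1
            age_sum[mask] = age_sum.get(mask, 0.0) + age
    nt = len(sample)
    # tie-break on a canonical clade-set key so the choice is invariant to
    # sample order
    best_i, best_score, best_key = 0, -math.inf, None
    for i, clades in enumerate(per_tree):
        score = sum(math.log(counts[m] / nt) for m in clades)
        key = tuple(sorted(clades))
        if score > best_score + 1e-12 or (
            abs(score - best_score) <= 1e-12 and (best_key is None or key < best_key)
        ):
            best_i, best_score, best_key = i, score, key
    best = sample[best_i].copy()

    # mean ages for the chosen tree's clades, then rebuild branch lengths
    store: dict[int, int] = {}
    ages = np.zeros(best.n_nodes)
    for node in best.postorder():
        if not best.children[node]:
            store[node] = 1 << pos[best.labels[node]]
            ages[node] = 0.0
        else:
            mask = 0
            for c in best.children[node]:
                mask |= store.pop(c)
            store[node] = mask
            ages[node] = age_sum[mask] / counts[mask]
    lengths = best.lengths.copy()
    for node in range(best.n_nodes):
        p = best.parent[node]
        if p >= 0:
            lengths[node] = max(ages[p] - ages[node], 0.0)
    return Phylogeny(best.parent, lengths, best.labels, validate=False)


def clade_credibility_score(tree: Phylogeny, sample: TreeSample) -> float:
    """Log product of clade credibilities of ``tree`` w.r.t. ``sample``.
    Clades absent from the sample score ``-inf``."""
    pos = {lab: i for i, lab in enumerate(sample.tip_labels)}
    counts: dict[int, int] = {}
    for t in sample:
        for mask in _clades_and_ages(t, pos):
            counts[mask] = counts.get(mask, 0) + 1
    nt = len(sample)
    score = 0.0
    for mask in _clades_and_ages(tree, pos):
        if mask not in counts:
            return -math.inf
        score += math.log(counts[mask] / nt)
    return score
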