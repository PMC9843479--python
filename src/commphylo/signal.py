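"""Phylogenetic signal tests.

* :func:`blomberg_k` — Blomberg's K for continuous traits, with the
  Brownian-motion expectation computed in closed form from the tree
  covariance matrix and a permutation p-value.
* :func:`fritz_purvis_d` — the D statistic for binary traits, scoring the
  observed sum of sister-clade state differences against shuffled-trait and
  threshold-Brownian reference simulations that preserve trait prevalence.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .errors import ValidationError
from .traitspace import TraitTable
from .treeio import Phylogeny, phylo_covariance

__all__ = ["SignalResult", "blomberg_k", "fritz_purvis_d", "signal_table"]


@dataclass
class SignalResult:
    trait: str
    statistic_name: str  # "K" or "D"
    statistic: float
    p_random: float
    p_brownian: float | None
    n_species: int
    n_reps: int
    seed: int | None
    extras: dict = field(default_factory=dict)


def _align_trait(tree: Phylogeny, trait) -> np.ndarray:
    """Trait values in tip-label order; accepts Series, dict or array."""
    labels = tree.tip_labels
    if isinstance(trait, pd.Series):
        missing = [l for l in labels if l not in trait.index]
        if missing:
            raise ValidationError(f"trait missing for tips: {missing}")
        return trait.loc[labels].to_numpy(dtype=float)
    if isinstance(trait, dict):
        missing = [l for l in labels if l not in trait]
        if missing:
            raise ValidationError(f"trait missing for tips: {missing}")
        return np.array([float(trait[l]) for l in labels])
    x = np.asarray(trait, dtype=float)
    if x.size != len(labels):
        raise ValidationError("trait vector length does not match tip count")
    return x


def _k_ratio(X: np.ndarray, Lfac, Ci_one: np.ndarray, one_Ci_one: float) -> np.ndarray:
    """Observed MSE0/MSE for each trait column of X (n x m)."""
    a_hat = (Ci_one @ X) / one_Ci_one
    R = X - a_hat[None, :]
    mse0 = (R * R).sum(axis=0)
    Z = linalg.cho_solve(Lfac, R)
    mse = (R * Z).sum(axis=0)
    return mse0 / mse


def blomberg_k(
    tree: Phylogeny, trait, n_perm: int = 999, seed: int | None = None,
    name: str = "trait",
) -> SignalResult:
    """Blomberg's K with a tip-shuffling permutation test.

    ``K = (MSE0/MSE)_obs / E[MSE0/MSE]`` where MSE0 is the error about the
    phylogenetically corrected mean, MSE the generalized least-squares error
    under the tree's Brownian covariance C, and
    ``E[MSE0/MSE] = (tr(C) - n / sum(C^-1)) / (n - 1)``.
    K is invariant to affine transformation of the trait.  ``p_random`` is
    the add-one-corrected proportion of permutations whose MSE0/MSE reaches
    the observed value.
    """
    x = _align_trait(tree, trait)
    n = x.size
    if np.ptp(x) == 0:
        raise ValidationError("trait is constant; K undefined")
    _, C = phylo_covariance(tree)
    try:
        Lfac = linalg.cho_factor(C, lower=True)
    except linalg.LinAlgError as exc:
        raise ValidationError(
            "singular phylogenetic covariance (coincident zero-length tips?); "
            "jitter branch lengths or collapse duplicates"
        ) from exc
    one = np.ones(n)
    Ci_one = linalg.cho_solve(Lfac, one)
    one_Ci_one = float(one @ Ci_one)
    expected = (np.trace(C) - n / one_Ci_one) / (n - 1.0)
    # the 1/(n-1) factors of MSE0 and MSE cancel in the observed ratio
    ratio_obs = float(_k_ratio(x[:, None], Lfac, Ci_one, one_Ci_one)[0])
    k = ratio_obs / expected

    p = np.nan
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        perms = np.empty((n, n_perm))
        for j in range(n_perm):
            perms[:, j] = x[rng.permutation(n)]
        ratios = _k_ratio(perms, Lfac, Ci_one, one_Ci_one)
        p = (np.sum(ratios >= ratio_obs) + 1.0) / (n_perm + 1.0)
    return SignalResult(
        trait=name, statistic_name="K", statistic=float(k), p_random=float(p),
        p_brownian=None, n_species=n, n_reps=n_perm, seed=seed,
        extras={"mse0_over_mse": ratio_obs, "expected_ratio": expected},
    )


def _node_change_sum(tree: Phylogeny, values: np.ndarray) -> np.ndarray:
    """Sum over edges of |parent estimate - child estimate| where internal
    estimates are the means of child estimates (columns = replicates)."""
    V = np.zeros((tree.n_nodes, values.shape[1]))
    for j, t in enumerate(tree.tips):
        V[t] = values[j]
    for node in tree.postorder():
        kids = tree.children[node]
        if kids:
            V[node] = V[kids].mean(axis=0)
    d = np.zeros(values.shape[1])
    for node in range(tree.n_nodes):
        p = tree.parent[node]
        if p >= 0:
            d += np.abs(V[node] - V[p])
    return d


def _brownian_tips(tree: Phylogeny, rng: np.random.Generator, m: int) -> np.ndarray:
    """m Brownian-motion realizations at the tips, shape (n_tips, m)."""
    V = np.zeros((tree.n_nodes, m))
    sd = np.sqrt(tree.lengths)
    for node in tree.preorder():
        p = tree.parent[node]
        eps = rng.standard_normal(m) * sd[node]
        V[node] = eps if p < 0 else V[p] + eps
    return V[tree.tips]


def fritz_purvis_d(
    tree: Phylogeny, trait, n_sim: int = 1000, seed: int | None = None,
    name: str = "trait",
) -> SignalResult:
    """Fritz–Purvis D for a binary trait.

    The observed sum of sister-clade state differences ``d_obs`` is scaled
    between the means of two prevalence-preserving references:
    random shuffles (``d_r``) and threshold-Brownian simulations (``d_b``),
    ``D = (d_obs - mean d_b) / (mean d_r - mean d_b)``.  D ~ 1 for
    phylogenetically random traits, ~0 under Brownian threshold evolution,
    < 0 for extreme conservatism.  ``p_random`` and ``p_brownian`` are
    ``P(d_sim <= d_obs)`` under each reference (small = conserved).
    """
    x = _align_trait(tree, trait)
    vals = set(np.unique(x))
    if not vals <= {0.0, 1.0}:
        raise ValidationError("trait must be binary 0/1")
    k = int(x.sum())
    n = x.size
    if k == 0 or k == n:
        raise ValidationError("binary trait is invariant; D undefined")
    if k == 1 or k == n - 1:
        warnings.warn(f"trait {name!r} has prevalence 1 tip; D is unstable")

    rng = np.random.default_rng(seed)
    d_obs = float(_node_change_sum(tree, x[:, None])[0])

    shuffles = np.empty((n, n_sim))
    for j in range(n_sim):
        shuffles[:, j] = x[rng.permutation(n)]
    d_r = _node_change_sum(tree, shuffles)

    liab = _brownian_tips(tree, rng, n_sim)
    # threshold each replicate at its own prevalence quantile: top-k tips -> 1
    order = np.argsort(liab, axis=0)
    binary = np.zeros_like(liab)
    np.put_along_axis(binary, order[n - k:], 1.0, axis=0)
    d_b = _node_change_sum(tree, binary)

    mean_r, mean_b = float(d_r.mean()), float(d_b.mean())
    if mean_r == mean_b:
        raise ValidationError("degenerate references: mean d_r equals mean d_b")
    D = (d_obs - mean_b) / (mean_r - mean_b)
    p_random = (np.sum(d_r <= d_obs) + 1.0) / (n_sim + 1.0)
    p_brownian = (np.sum(d_b <= d_obs) + 1.0) / (n_sim + 1.0)
    return SignalResult(
        trait=name, statistic_name="D", statistic=float(D),
        p_random=float(p_random), p_brownian=float(p_brownian),
        n_species=n, n_reps=n_sim, seed=seed,
        extras={"d_obs": d_obs, "mean_d_random": mean_r, "mean_d_brownian": mean_b},
    )


def signal_table(
    tree: Phylogeny,
    traits: TraitTable,
    n_perm: int = 999,
    n_sim: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Run K on every continuous column and D on every binary column."""
    ss = np.random.SeedSequence(seed)
    rows = []
    for col, child in zip(traits.columns, ss.spawn(len(traits.columns))):
        sub_seed = int(child.generate_state(1)[0])
        series = traits.data[col].copy()
        series.index = series.index.astype(str)
        if traits.types[col] == "continuous":
            res = blomberg_k(tree, series, n_perm=n_perm, seed=sub_seed, name=col)
        else:
            try:
                res = fritz_purvis_d(tree, series, n_sim=n_sim, seed=sub_seed, name=col)
            except ValidationError as exc:
                rows.append({"trait": col, "type": "binary", "statistic": "D",
                             "value": np.nan, "p_random": np.nan,
                             "p_brownian": np.nan, "note": str(exc)})
                continue
        rows.append({
            "trait": col,
            "type": traits.types[col],
            "statistic": res.statistic_name,
            "value": res.statistic,
            "p_random": res.p_random,
            "p_brownian": res.p_brownian if res.p_brownian is not None else np.nan,
            "note": "",
        })
    return pd.DataFrame(rows)
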