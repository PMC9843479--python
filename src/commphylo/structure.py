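"""Randomization nulls and standardized effect sizes (SESmpd / SESmfd) for
community phylogenetic and functional structure.

The default null (``taxa_labels``) permutes species labels on the
dissimilarity matrix, preserving each site's richness and the overall
distance distribution; ``richness_random`` draws each site's species
uniformly from the pool instead.  The default sign convention is
``ses = (obs - null_mean) / null_sd`` (negative = clustered, positive =
dispersed); ``nri`` negates it.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .matrix import DissimilarityMatrix
from .metrics import CommunityMatrix, mean_pairwise_distance

__all__ = ["NullConfig", "null_replicates", "ses"]

SCHEMES = ("taxa_labels", "richness_random")
SIGN_CONVENTIONS = ("ses", "nri")


@dataclass
class NullConfig:
    n_reps: int = 999
    scheme: str = "taxa_labels"
    seed: int | None = None
    sign_convention: str = "ses"

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValidationError("n_reps must be >= 1")
        if self.scheme not in SCHEMES:
            raise ValidationError(f"unknown null scheme {self.scheme!r}; expected {SCHEMES}")
        if self.sign_convention not in SIGN_CONVENTIONS:
            raise ValidationError(
                f"unknown sign convention {self.sign_convention!r}; expected {SIGN_CONVENTIONS}"
            )


def _site_indices(d: DissimilarityMatrix, cm: CommunityMatrix) -> list[np.ndarray]:
    cols = d.index_of(cm.species)
    inc = cm.incidence().astype(bool)
    return [cols[inc[i]] for i in range(inc.shape[0])]


def null_replicates(
    d: DissimilarityMatrix, cm: CommunityMatrix, cfg: NullConfig
) -> np.ndarray:
    """Null mean-pairwise-distance values, shape ``(n_reps, n_sites)``.

    The replicate stream is a pure function of ``cfg.seed``.
    """
    sites = _site_indices(d, cm)
    pool = d.n
    richness = np.array([s.size for s in sites])
    if richness.max(initial=0) > pool:
        raise ValidationError("species pool smaller than the largest site richness")
    rng = np.random.default_rng(cfg.seed)
    out = np.empty((cfg.n_reps, len(sites)))
    out.fill(np.nan)

    denom = richness * (richness - 1.0)
    if cfg.scheme == "taxa_labels":
        # one label permutation per replicate, shared by all sites
        inc = np.zeros((len(sites), pool))
        for j, idx in enumerate(sites):
            inc[j, idx] = 1.0
        for rep in range(cfg.n_reps):
            perm = rng.permutation(pool)
            P = d.values[np.ix_(perm, perm)]
            tot = ((inc @ P) * inc).sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                out[rep] = np.where(richness >= 2, tot / denom, np.nan)
    else:  # richness_random
        for j, idx in enumerate(sites):
            r = idx.size
            if r < 2:
                continue
            # vectorized sampling without replacement: lowest-r random keys
            keys = rng.random((cfg.n_reps, pool))
            if r < pool:
                draws = np.argpartition(keys, r, axis=1)[:, :r]
            else:
                draws = np.tile(np.arange(pool), (cfg.n_reps, 1))
            M = np.zeros((cfg.n_reps, pool))
            M[np.arange(cfg.n_reps)[:, None], draws] = 1.0
            tot = ((M @ d.values) * M).sum(axis=1)
            out[:, j] = tot / (r * (r - 1.0))
    return out


def ses(
    d: DissimilarityMatrix,
    cm: CommunityMatrix,
    cfg: NullConfig | None = None,
    metric: str = "MPD",
) -> pd.DataFrame:
    """Standardized effect size of the mean pairwise distance per site.

    Returns a table with observed value, null mean/sd, ses, and the
    add-one-corrected rank p-value ``(count(null <= obs) + 1)/(n_reps + 1)``
    (small p = clustered, large p = dispersed, two-sided significance at
    p < .025 or p > .975).
    """
    cfg = cfg or NullConfig()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        obs = mean_pairwise_distance(d, cm).to_numpy()
    nulls = null_replicates(d, cm, cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-NaN columns for sites with SR < 2
        null_mean = np.nanmean(nulls, axis=0)
        null_sd = np.nanstd(nulls, axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - null_mean) / null_sd
    z = np.where(null_sd > 0, z, np.nan)
    if cfg.sign_convention == "nri":
        z = -z
    p = (np.sum(nulls <= obs[None, :], axis=0) + 1.0) / (cfg.n_reps + 1.0)
    p = np.where(np.isfinite(obs), p, np.nan)
    degenerate = np.isfinite(obs) & ~(null_sd > 0)
    if degenerate.any():
        bad = [s for s, f in zip(cm.sites, degenerate) if f]
        warnings.warn(f"null sd is zero; ses undefined for sites: {bad}")
    out = pd.DataFrame(
        {
            "site": cm.sites,
            "metric": metric,
            "obs": obs,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "ses": z,
            "p": p,
            "n_reps": cfg.n_reps,
            "scheme": cfg.scheme,
            "seed": cfg.seed if cfg.seed is not None else "",
        }
    )
    return out
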