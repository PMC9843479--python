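"""Synthetic study generator: Yule trees, Brownian traits, community
assembly under random / environmental-filtering / competition regimes, and
site tables with spatially autocorrelated responses.  Every generator is a
pure function of its seed."""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import AssemblyError, ValidationError
from .metrics import CommunityMatrix
from .spatialstats import build_weights, great_circle_distances
from .traitspace import TraitTable
from .treeio import Phylogeny, patristic_matrix

__all__ = [
    "SynthStudy",
    "simulate_yule_tree",
    "simulate_traits",
    "assemble_communities",
    "simulate_site_table",
    "simulate_study",
    "write_bundle",
]

SITE_FACTORS = [
    "longitude", "latitude", "Area", "Plant.ric", "MAT", "MAP", "ASH", "AT",
    "Altitude.min", "Altitude.max", "Altitude.mean", "Altitude.HD",
]


@dataclass
class SynthStudy:
    tree: Phylogeny
    traits: TraitTable
    communities: CommunityMatrix
    sites: pd.DataFrame
    responses: pd.DataFrame
    truth: dict = field(default_factory=dict)


def simulate_yule_tree(
    n_tips: int, birth_rate: float = 1.0, seed: int | None = None
) -> Phylogeny:
    """Pure-birth tree grown from a single stem lineage with exponential
    waiting times; ultrametric, tips labelled t1..tn."""
    if n_tips < 2:
        raise ValidationError("need n_tips >= 2")
    if birth_rate <= 0:
        raise ValidationError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    parent = [-1]
    birth = [0.0]
    active = [0]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        which = rng.integers(len(active))
        node = active.pop(which)
        for _ in range(2):
            parent.append(node)
            birth.append(t)
            active.append(len(parent) - 1)
    t_end = t + rng.exponential(1.0 / (birth_rate * n_tips))
    n_nodes = len(parent)
    lengths = np.zeros(n_nodes)
    labels: list[str | None] = [None] * n_nodes
    children = [[] for _ in range(n_nodes)]
    for i, p in enumerate(parent):
        if p >= 0:
            children[p].append(i)
    split_time = {}
    for i, p in enumerate(parent):
        if p >= 0:
            split_time[p] = birth[i]
    tip_counter = 0
    for i in range(n_nodes):
        end = split_time.get(i, t_end)
        lengths[i] = end - birth[i]
        if not children[i]:
            tip_counter += 1
            labels[i] = f"t{tip_counter}"
    return Phylogeny(parent, lengths, labels)


def simulate_traits(
    tree: Phylogeny,
    n_continuous: int = 6,
    n_binary: int = 20,
    sigma2: float = 1.0,
    seed: int | None = None,
) -> TraitTable:
    """Continuous traits evolve by Brownian motion on the tree (variance
    ``sigma2`` per unit branch length); binary traits threshold an
    independent Brownian liability at its median (prevalence ~ 0.5)."""
    rng = np.random.default_rng(seed)
    m = n_continuous + n_binary
    if m == 0:
        raise ValidationError("need at least one trait column")
    V = np.zeros((tree.n_nodes, m))
    sd = np.sqrt(sigma2 * tree.lengths)
    for node in tree.preorder():
        eps = rng.standard_normal(m) * sd[node]
        p = tree.parent[node]
        V[node] = eps if p < 0 else V[p] + eps
    tips = V[tree.tips]
    cols = {}
    types = {}
    for j in range(n_continuous):
        name = f"cont_{j + 1}"
        cols[name] = tips[:, j]
        types[name] = "continuous"
    for j in range(n_binary):
        name = f"bin_{j + 1}"
        liab = tips[:, n_continuous + j]
        cols[name] = (liab > np.median(liab)).astype(float)
        types[name] = "binary"
    df = pd.DataFrame(cols, index=pd.Index(tree.tip_labels, name="species"))
    if sigma2 == 0:
        # constant traits are degenerate but permitted for testing
        return TraitTable(df, types, validate=False)
    return TraitTable(df, types)


def assemble_communities(
    tree: Phylogeny,
    n_sites: int = 37,
    richness_range: tuple[int, int] = (30, 91),
    process: str = "random",
    strength: float = 0.0,
    seed: int | None = None,
    distances=None,
    max_tries_per_draw: int = 500,
) -> tuple[CommunityMatrix, dict]:
    """Assemble 0/1 site x species incidence under a chosen process.

    ``random``
        uniform draws of the site's richness from the pool.
    ``filtering``
        tips sampled with probability decaying exponentially in patristic
        distance from a site-specific focal tip (rate = ``strength``).
    ``competition``
        iterative draws rejecting candidates closer (patristic) than
        ``strength`` times the median pairwise distance to any member;
        raises :class:`AssemblyError` when infeasible.

    ``distances`` may supply a precomputed/alternative dissimilarity matrix
    (e.g. trait-based) aligned to the tree's tip labels; by default the
    patristic matrix is used.
    """
    if process not in ("random", "filtering", "competition"):
        raise ValidationError(f"unknown assembly process {process!r}")
    lo, hi = richness_range
    if not 1 <= lo <= hi <= tree.n_tips:
        raise ValidationError("richness_range must satisfy 1 <= lo <= hi <= n_tips")
    rng = np.random.default_rng(seed)
    labels = tree.tip_labels
    n = len(labels)
    D = patristic_matrix(tree).values if distances is None else np.asarray(distances, float)
    off = D[~np.eye(n, dtype=bool)]
    scale = off.mean()
    median = np.median(off)

    inc = np.zeros((n_sites, n), dtype=np.int64)
    richness = rng.integers(lo, hi + 1, size=n_sites)
    focals = np.full(n_sites, -1)
    for s in range(n_sites):
        r = int(richness[s])
        if process == "random" or strength == 0.0:
            chosen = rng.choice(n, size=r, replace=False)
        elif process == "filtering":
            focal = int(rng.integers(n))
            focals[s] = focal
            wts = np.exp(-strength * D[focal] / scale)
            wts /= wts.sum()
            chosen = rng.choice(n, size=r, replace=False, p=wts)
        else:  # competition
            threshold = strength * median
            members = [int(rng.integers(n))]
            tries = 0
            while len(members) < r:
                cand = int(rng.integers(n))
                if cand not in members and D[cand, members].min() >= threshold:
                    members.append(cand)
                    tries = 0
                else:
                    tries += 1
                    if tries > max_tries_per_draw:
                        raise AssemblyError(
                            f"site {s}: cannot reach richness {r} with competition "
                            f"strength {strength}; lower the strength or richness"
                        )
            chosen = np.array(members)
        inc[s, chosen] = 1
    cm = CommunityMatrix(pd.DataFrame(
        inc, index=pd.Index([f"s{c + 1}" for c in range(n_sites)], name="site"),
        columns=labels,
    ))
    truth = {
        "process": process, "strength": strength, "seed": seed,
        "richness": richness.tolist(), "focal_tips": focals.tolist(),
    }
    return cm, truth


def simulate_site_table(
    n_sites: int = 37,
    effect_spec: Mapping[str, Mapping[str, float]] | None = None,
    lambda_spatial: float = 0.0,
    noise_sd: float = 0.5,
    seed: int | None = None,
    bbox: tuple[float, float, float, float] = (103.0, 110.0, 24.0, 29.0),
    weights_style: str = "inverse_distance",
    knn_k: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Site coordinates, the 12 habitat factors and one or more responses
    generated as ``response = X beta + u`` with spatially autoregressive
    errors ``u = lambda W u + eps`` on row-standardized inverse-distance
    weights of the simulated coordinates."""
    if not abs(lambda_spatial) < 1:
        raise ValidationError("|lambda_spatial| must be < 1")
    rng = np.random.default_rng(seed)
    lon = rng.uniform(bbox[0], bbox[1], n_sites)
    lat = rng.uniform(bbox[2], bbox[3], n_sites)
    sites = pd.DataFrame(index=pd.Index([f"s{i + 1}" for i in range(n_sites)], name="site"))
    sites["longitude"] = lon
    sites["latitude"] = lat
    sites["Area"] = np.exp(rng.normal(3.0, 1.0, n_sites))
    sites["Plant.ric"] = np.round(np.exp(rng.normal(7.0, 0.5, n_sites)))
    sites["MAT"] = rng.normal(15.0, 2.0, n_sites)
    sites["MAP"] = rng.normal(1200.0, 100.0, n_sites)
    sites["ASH"] = rng.normal(1300.0, 150.0, n_sites)
    sites["AT"] = rng.normal(4500.0, 400.0, n_sites)
    alt_min = rng.uniform(150.0, 1500.0, n_sites)
    alt_hd = rng.uniform(200.0, 1500.0, n_sites)
    sites["Altitude.min"] = alt_min
    sites["Altitude.max"] = alt_min + alt_hd
    sites["Altitude.mean"] = alt_min + alt_hd * rng.uniform(0.3, 0.7, n_sites)
    sites["Altitude.HD"] = alt_hd

    dist = great_circle_distances(lon, lat)
    W = build_weights(dist, style=weights_style,
                      k=knn_k if weights_style == "knn" else None)
    effect_spec = dict(effect_spec or {})
    responses = pd.DataFrame(index=sites.index)
    A = np.eye(n_sites) - lambda_spatial * W.values
    for resp, betas in effect_spec.items():
        mu = np.zeros(n_sites)
        for pred, beta in betas.items():
            if pred not in sites.columns:
                raise ValidationError(f"unknown predictor {pred!r} in effect_spec")
            col = sites[pred].to_numpy(dtype=float)
            mu += beta * (col - col.mean()) / col.std(ddof=1)
        eps = rng.normal(0.0, noise_sd, n_sites)
        u = np.linalg.solve(A, eps)
        responses[resp] = mu + u
    truth = {
        "lambda_spatial": lambda_spatial, "noise_sd": noise_sd, "seed": seed,
        "weights_style": weights_style,
        "effects": {r: dict(b) for r, b in effect_spec.items()},
    }
    return sites, responses, truth


def simulate_study(
    n_species: int = 164,
    n_sites: int = 37,
    richness_range: tuple[int, int] = (30, 91),
    process: str = "random",
    strength: float = 0.0,
    lambda_spatial: float = 0.0,
    effect_spec: Mapping[str, Mapping[str, float]] | None = None,
    seed: int | None = None,
) -> SynthStudy:
    """A complete internally consistent synthetic study bundle."""
    ss = np.random.SeedSequence(seed)
    s_tree, s_traits, s_comm, s_sites = (
        int(c.generate_state(1)[0]) for c in ss.spawn(4)
    )
    tree = simulate_yule_tree(n_species, seed=s_tree)
    traits = simulate_traits(tree, seed=s_traits)
    cm, truth_cm = assemble_communities(
        tree, n_sites=n_sites, richness_range=richness_range,
        process=process, strength=strength, seed=s_comm,
    )
    sites, responses, truth_sites = simulate_site_table(
        n_sites=n_sites, effect_spec=effect_spec,
        lambda_spatial=lambda_spatial, seed=s_sites,
    )
    sites.index = cm.data.index
    responses.index = cm.data.index
    truth = {"seed": seed, "communities": truth_cm, "sites": truth_sites}
    return SynthStudy(tree, traits, cm, sites, responses, truth)


def write_bundle(study: SynthStudy, outdir: str) -> None:
    """Write tree.nwk, traits.csv, communities.csv, sites.csv and truth.json."""
    os.makedirs(outdir, exist_ok=True)
    study.tree.write(os.path.join(outdir, "tree.nwk"))
    study.traits.to_csv(os.path.join(outdir, "traits.csv"))
    study.communities.to_csv(os.path.join(outdir, "communities.csv"))
    sites = study.sites.copy()
    for col in study.responses.columns:
        sites[f"response_{col}"] = study.responses[col]
    sites.to_csv(os.path.join(outdir, "sites.csv"), index_label="site")
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(study.truth, fh, indent=2, default=str)
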