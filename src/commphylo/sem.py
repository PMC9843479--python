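"""Piecewise structural equation modelling: per-node component regressions,
standardized path coefficients, the d-separation basis set and Fisher's C."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as smapi
from scipy import stats

from .errors import ValidationError

__all__ = ["PathModel", "IndependenceClaim", "dsep_basis_set",
           "SEMFit", "fit_piecewise_sem", "default_dag"]


class IndependenceClaim(NamedTuple):
    x: str
    y: str  # tested by regressing y (the topologically later node) on x
    conditioning: tuple[str, ...]


class PathModel:
    """A DAG of directed effects; one linear component model per endogenous
    node (node ~ its parents)."""

    def __init__(self, graph: nx.DiGraph):
        if not isinstance(graph, nx.DiGraph):
            raise ValidationError("PathModel requires a networkx DiGraph")
        if graph.number_of_nodes() == 0:
            raise ValidationError("empty path model")
        if not nx.is_directed_acyclic_graph(graph):
            raise ValidationError("path model contains a cycle")
        self.graph = graph

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "PathModel":
        g = nx.DiGraph()
        g.add_edges_from(edges)
        return cls(g)

    @classmethod
    def from_text(cls, text: str) -> "PathModel":
        """Parse a plain-text block of ``parent -> child`` lines (blank lines
        and ``#`` comments ignored)."""
        edges = []
        for ln, line in enumerate(text.splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "->" not in line:
                raise ValidationError(f"line {ln}: expected 'parent -> child', got {line!r}")
            left, right = line.split("->", 1)
            edges.append((left.strip(), right.strip()))
        if not edges:
            raise ValidationError("no edges found in path model text")
        return cls.from_edges(edges)

    @property
    def variables(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self.graph))

    def parents(self, node: str) -> list[str]:
        return sorted(self.graph.predecessors(node))

    def endogenous(self) -> list[str]:
        return [v for v in self.variables if self.graph.in_degree(v) > 0]


def dsep_basis_set(model: PathModel) -> list[IndependenceClaim]:
    """The standard d-separation basis set: every non-adjacent pair of
    variables, conditioned on the union of both variables' parents.  The
    topologically later variable of each pair is the regression response."""
    order = model.variables
    rank = {v: i for i, v in enumerate(order)}
    g = model.graph
    claims = []
    for i, a in enumerate(order):
        for b in order[i + 1:]:
            if g.has_edge(a, b) or g.has_edge(b, a):
                continue
            cond = (set(model.parents(a)) | set(model.parents(b))) - {a, b}
            x, y = (a, b) if rank[a] < rank[b] else (b, a)
            claims.append(IndependenceClaim(x, y, tuple(sorted(cond))))
    return claims


@dataclass
class SEMFit:
    paths: pd.DataFrame       # per-edge standardized coefficient + p
    claims: pd.DataFrame      # per-claim partial coefficient + p
    fisher_c: float
    df: int
    p: float

    @property
    def accepted(self) -> bool:
        return self.p > 0.05


def _zscore_frame(data: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    sub = data[cols].astype(float)
    sd = sub.std(ddof=1)
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise ValidationError(f"zero-variance variables cannot enter the SEM: {zero}")
    return (sub - sub.mean()) / sd


def fit_piecewise_sem(model: PathModel, data: pd.DataFrame) -> SEMFit:
    """Fit each component regression on z-scored variables, test every
    d-separation claim via the p-value of the conditioned partial
    coefficient, and combine claim p-values into Fisher's
    C = -2 * sum(ln p) ~ chi-square with 2k degrees of freedom."""
    missing = [v for v in model.variables if v not in data.columns]
    if missing:
        raise ValidationError(f"variables absent from the data: {missing}")
    z = _zscore_frame(data, model.variables)
    n = z.shape[0]
    max_parents = max((len(model.parents(v)) for v in model.endogenous()), default=0)
    if n <= max_parents + 1:
        raise ValidationError("too few observations for the largest component model")

    path_rows = []
    for node in model.endogenous():
        parents = model.parents(node)
        X = smapi.add_constant(z[parents].to_numpy())
        try:
            fit = smapi.OLS(z[node].to_numpy(), X).fit()
        except Exception as exc:
            raise ValidationError(f"singular component fit for {node!r} ~ {parents}") from exc
        for j, par in enumerate(parents, start=1):
            path_rows.append({
                "response": node, "predictor": par,
                "coef": float(fit.params[j]), "p": float(fit.pvalues[j]),
            })

    claims = dsep_basis_set(model)
    claim_rows = []
    for cl in claims:
        rhs = [cl.x, *cl.conditioning]
        X = smapi.add_constant(z[rhs].to_numpy())
        fit = smapi.OLS(z[cl.y].to_numpy(), X).fit()
        claim_rows.append({
            "x": cl.x, "y": cl.y, "conditioning": ";".join(cl.conditioning),
            "coef": float(fit.params[1]), "p": float(fit.pvalues[1]),
        })
    claims_df = pd.DataFrame(claim_rows)
    if claim_rows:
        pvals = np.clip(claims_df["p"].to_numpy(), 1e-300, 1.0)
        C = float(-2.0 * np.log(pvals).sum())
        df = 2 * len(claim_rows)
        p_global = float(stats.chi2.sf(C, df))
    else:
        C, df, p_global = 0.0, 0, 1.0
    return SEMFit(pd.DataFrame(path_rows), claims_df, C, df, p_global)


def default_dag(responses: Iterable[str] = ("SR",)) -> PathModel:
    """Default study-shaped DAG: nine exogenous habitat factors with direct
    edges to each response, and the altitude-difference effect routed through
    plant species richness (Altitude.HD -> Plant.ric -> response)."""
    exo = ["longitude", "latitude", "Area", "MAP", "ASH", "AT",
           "Altitude.min", "Altitude.HD", "Plant.ric"]
    edges = [("Altitude.HD", "Plant.ric")]
    for r in responses:
        for e in exo:
            edges.append((e, r))
    return PathModel.from_edges(edges)
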