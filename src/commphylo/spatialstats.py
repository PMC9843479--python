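"""Spatially explicit regression utilities: great-circle distances, spatial
weights, Moran's I, standardized bivariate OLS, maximum-likelihood
spatial-error SAR fitting, variance inflation factors and the batch
response x predictor regression grid."""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ValidationError

__all__ = [
    "great_circle_distances",
    "WeightsMatrix",
    "build_weights",
    "MoranResult",
    "morans_i",
    "OLSFit",
    "ols_standardized",
    "SARFit",
    "sar_error_ml",
    "vif",
    "regression_table",
]

EARTH_RADIUS_KM = 6371.0088


def great_circle_distances(lon, lat) -> np.ndarray:
    """Pairwise haversine distances in km from decimal-degree coordinates."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lon) > 180) or np.any(np.abs(lat) > 90):
        raise ValidationError("coordinates out of range (|lon|<=180, |lat|<=90)")
    lam = np.radians(lon)
    phi = np.radians(lat)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    return d


class WeightsMatrix:
    """Spatial weights: a symmetric non-negative base matrix, optionally
    row-standardized.  Eigenvalues of the row-standardized matrix are real
    (it is similar to a symmetric matrix) and are exposed for SAR
    log-determinants."""

    def __init__(self, base: np.ndarray, style: str, row_standardized: bool = True):
        base = np.asarray(base, dtype=float)
        if base.ndim != 2 or base.shape[0] != base.shape[1]:
            raise ValidationError("weights base must be square")
        if not np.allclose(base, base.T):
            raise ValidationError("weights base must be symmetric")
        if np.any(base < 0) or np.any(np.diag(base) != 0):
            raise ValidationError("weights must be non-negative with zero diagonal")
        self.base = base
        self.style = style
        self.row_standardized = row_standardized
        rs = base.sum(axis=1)
        if np.any(rs == 0):
            isolated = np.flatnonzero(rs == 0).tolist()
            raise ValidationError(f"isolated sites (zero weight rows): {isolated}")
        self._rowsums = rs
        self.values = base / rs[:, None] if row_standardized else base
        self._eigvals: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.base.shape[0]

    @property
    def eigvals(self) -> np.ndarray:
        if self._eigvals is None:
            if self.row_standardized:
                s = 1.0 / np.sqrt(self._rowsums)
                sym = self.base * s[:, None] * s[None, :]
                self._eigvals = np.linalg.eigvalsh(sym)
            else:
                self._eigvals = np.linalg.eigvalsh(self.base)
        return self._eigvals


def build_weights(
    distances: np.ndarray,
    style: str = "inverse_distance",
    k: int | None = None,
    row_standardize: bool = True,
) -> WeightsMatrix:
    """Build spatial weights from a distance matrix.

    ``inverse_distance``: w_ij = 1/d_ij.  ``knn``: binary k-nearest-neighbor
    weights symmetrized by max.
    """
    D = np.asarray(distances, dtype=float)
    n = D.shape[0]
    off = ~np.eye(n, dtype=bool)
    if style == "inverse_distance":
        if np.any(D[off] == 0):
            raise ValidationError(
                "coincident sites give infinite inverse-distance weights; "
                "jitter coordinates or use knn weights"
            )
        base = np.zeros_like(D)
        base[off] = 1.0 / D[off]
    elif style == "knn":
        if k is None or not 1 <= k < n:
            raise ValidationError(f"knn weights need 1 <= k < n, got k={k}")
        base = np.zeros_like(D)
        Dd = D + np.diag(np.full(n, np.inf))
        nn = np.argsort(Dd, axis=1)[:, :k]
        rows = np.repeat(np.arange(n), k)
        base[rows, nn.ravel()] = 1.0
        base = np.maximum(base, base.T)
    else:
        raise ValidationError(f"unknown weights style {style!r}")
    return WeightsMatrix(base, style, row_standardize)


@dataclass
class MoranResult:
    I: float
    expected: float
    variance: float
    z: float
    p: float
    p_perm: float | None = None


def morans_i(
    values, W: WeightsMatrix, n_perm: int = 0, seed: int | None = None
) -> MoranResult:
    """Moran's I with its normal-approximation test (and an optional
    permutation test).  E[I] = -1/(n-1); invariant to affine transformation
    of the values."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if np.std(x) == 0:
        raise ValidationError("Moran's I undefined for constant input")
    w = W.values
    z = x - x.mean()
    s0 = w.sum()
    num = z @ w @ z
    I = (n / s0) * num / (z @ z)
    eI = -1.0 / (n - 1.0)
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    rowcol = w.sum(axis=1) + w.sum(axis=0)
    s2 = (rowcol**2).sum()
    # variance under the normality assumption
    varI = (n * n * s1 - n * s2 + 3 * s0 * s0) / (s0 * s0 * (n * n - 1.0)) - eI * eI
    zscore = (I - eI) / np.sqrt(varI)
    p = 2 * stats.norm.sf(abs(zscore))
    p_perm = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        sims = np.empty(n_perm)
        for i in range(n_perm):
            zp = z[rng.permutation(n)]
            sims[i] = (n / s0) * (zp @ w @ zp) / (zp @ zp)
        p_perm = (np.sum(np.abs(sims - eI) >= abs(I - eI)) + 1.0) / (n_perm + 1.0)
    return MoranResult(float(I), float(eI), float(varI), float(zscore), float(p), p_perm)


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValidationError("zero-variance variable cannot be standardized")
    return (v - v.mean()) / sd


@dataclass
class OLSFit:
    response: str
    predictor: str
    coef: float          # fully standardized slope (= Pearson r)
    coef_x_only: float   # predictor-standardized slope on the raw response
    r2: float
    p: float
    residuals: np.ndarray = field(repr=False)


def ols_standardized(y, x, response: str = "y", predictor: str = "x") -> OLSFit:
    """Bivariate OLS with both variables z-scored; the slope then equals the
    Pearson correlation and r-squared its square.  ``coef_x_only`` reports
    the slope with only the predictor standardized (response left on its
    original scale), since published tables sometimes use that scaling."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.size != x.size or y.size < 3:
        raise ValidationError("need equal-length y and x with n >= 3")
    zy, zx = _zscore(y), _zscore(x)
    res = stats.linregress(zx, zy)
    residuals = zy - (res.intercept + res.slope * zx)
    coef_x_only = float(res.slope * y.std(ddof=1))
    return OLSFit(
        response=response, predictor=predictor, coef=float(res.slope),
        coef_x_only=coef_x_only, r2=float(res.rvalue**2), p=float(res.pvalue),
        residuals=residuals,
    )


@dataclass
class SARFit:
    response: str
    predictor: str
    coef: float
    intercept: float
    lam: float
    sigma2: float
    loglik: float
    aic: float
    k_params: int
    residuals: np.ndarray = field(repr=False)  # innovations (I - lam W)(y - Xb)
    raw_residuals: np.ndarray = field(repr=False)
    converged: bool = True


def _sar_profile(lam: float, y: np.ndarray, X: np.ndarray, w: np.ndarray,
                 eigs: np.ndarray) -> tuple[float, np.ndarray, float]:
    """Concentrated log-likelihood of the spatial-error model at lam."""
    n = y.size
    Ay = y - lam * (w @ y)
    AX = X - lam * (w @ X)
    beta, *_ = np.linalg.lstsq(AX, Ay, rcond=None)
    e = Ay - AX @ beta
    sigma2 = float(e @ e) / n
    logdet = float(np.sum(np.log(1.0 - lam * eigs)))
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet
    return ll, beta, sigma2


def sar_error_ml(
    y, x, W: WeightsMatrix,
    response: str = "y", predictor: str = "x",
    lam: float | None = None, standardize: bool = True,
) -> SARFit:
    """Spatial-error SAR ``y = Xb + u, u = lam W u + eps`` fitted by profile
    maximum likelihood over lam (log-determinant via the precomputed
    eigenvalues of W).  AIC counts k = p + 2 parameters (coefficients
    including the intercept, lam, sigma^2)."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if standardize:
        y, x = _zscore(y), _zscore(x)
    n = y.size
    X = np.column_stack([np.ones(n), x])
    w = W.values
    eigs = W.eigvals
    lo = 1.0 / eigs.min() if eigs.min() < 0 else -np.inf
    hi = 1.0 / eigs.max() if eigs.max() > 0 else np.inf
    eps = 1e-6
    lo = max(lo + eps, -0.999999) if np.isfinite(lo) else -0.999999
    hi = min(hi - eps, 0.999999) if np.isfinite(hi) else 0.999999

    if lam is None:
        opt = optimize.minimize_scalar(
            lambda l: -_sar_profile(l, y, X, w, eigs)[0],
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8},
        )
        if not opt.success:
            raise ValidationError(f"SAR profile likelihood failed to converge: {opt.message}")
        lam_hat = float(opt.x)
        if min(lam_hat - lo, hi - lam_hat) < 1e-2:
            warnings.warn(f"SAR lambda estimate {lam_hat:.4f} is at the parameter boundary")
    else:
        lam_hat = float(lam)
    ll, beta, sigma2 = _sar_profile(lam_hat, y, X, w, eigs)
    k = X.shape[1] + 2
    aic = 2.0 * k - 2.0 * ll
    raw = y - X @ beta
    innov = raw - lam_hat * (w @ raw)
    return SARFit(
        response=response, predictor=predictor, coef=float(beta[1]),
        intercept=float(beta[0]), lam=lam_hat, sigma2=sigma2, loglik=float(ll),
        aic=float(aic), k_params=k, residuals=innov, raw_residuals=raw,
    )


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor of each column regressed on the others.
    Perfect collinearity reports inf."""
    if X.shape[0] <= X.shape[1] + 1:
        raise ValidationError("VIF needs n > number of columns + 1")
    cols = list(X.columns)
    out = {}
    M = X.to_numpy(dtype=float)
    for j, c in enumerate(cols):
        yj = M[:, j]
        others = np.delete(M, j, axis=1)
        A = np.column_stack([np.ones(M.shape[0]), others])
        beta, *_ = np.linalg.lstsq(A, yj, rcond=None)
        resid = yj - A @ beta
        sst = ((yj - yj.mean()) ** 2).sum()
        if sst == 0:
            raise ValidationError(f"column {c!r} has zero variance")
        r2 = 1.0 - (resid @ resid) / sst
        out[c] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


def regression_table(
    responses: pd.DataFrame, predictors: pd.DataFrame, W: WeightsMatrix
) -> pd.DataFrame:
    """Bivariate OLS + residual Moran's I + spatial-error SAR for every
    response x predictor pair; one row per pair with the published-table
    statistics (Coef_ols, r2_ols, I_ols, Coef_sar, AIC, I_sar)."""
    if list(responses.index) != list(predictors.index):
        raise ValidationError("responses and predictors must share the same site index")
    rows = []
    for rname in responses.columns:
        yv = responses[rname].to_numpy(dtype=float)
        if np.isnan(yv).any():
            warnings.warn(f"response {rname!r} has missing values; rows dropped pairwise")
        for pname in predictors.columns:
            xv = predictors[pname].to_numpy(dtype=float)
            mask = np.isfinite(yv) & np.isfinite(xv)
            if mask.sum() < 4 or mask.sum() < len(yv):
                if mask.sum() < 4:
                    rows.append({"response": rname, "predictor": pname, "note": "too few sites"})
                    continue
            ols = ols_standardized(yv[mask], xv[mask], rname, pname)
            sub_W = W
            if mask.sum() < len(yv):
                sub_W = WeightsMatrix(W.base[np.ix_(mask, mask)], W.style, W.row_standardized)
            i_ols = morans_i(ols.residuals, sub_W)
            sar = sar_error_ml(yv[mask], xv[mask], sub_W, rname, pname)
            i_sar = morans_i(sar.residuals, sub_W)
            rows.append({
                "response": rname, "predictor": pname,
                "coef_ols": ols.coef, "coef_ols_x_only": ols.coef_x_only,
                "r2_ols": ols.r2, "p_ols": ols.p,
                "I_ols": i_ols.I, "p_I_ols": i_ols.p,
                "coef_sar": sar.coef, "lambda_sar": sar.lam,
                "loglik_sar": sar.loglik, "AIC_sar": sar.aic,
                "I_sar": i_sar.I, "p_I_sar": i_sar.p,
                "note": "",
            })
    return pd.DataFrame(rows)
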