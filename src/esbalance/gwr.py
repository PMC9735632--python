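"""OLS baseline with VIF screening, and geographically weighted regression.

GWR solves a weighted least-squares problem at every observation location
with a fixed Gaussian kernel w_ij = exp(-0.5 (d_ij / b)^2); the bandwidth b
is chosen by golden-section search on the corrected Akaike criterion

    AICc = 2n ln(sigma_hat) + n ln(2 pi) + n (n + tr(S)) / (n - 2 - tr(S))

where S is the hat matrix and sigma_hat^2 = RSS / n. As the bandwidth grows
the kernel flattens and every local fit converges to the global OLS
solution; the same AICc formula with tr(S) = p + 1 scores the OLS model, so
the two are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DesignMatrix:
    """Response, named predictors, and planar coordinates per observation."""

    y: np.ndarray
    X: pd.DataFrame
    coords: np.ndarray  # n x 2
    intercept: bool = True

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        n, p = self.X.shape
        if self.y.shape[0] != n or self.coords.shape != (n, 2):
            raise ValueError("inconsistent design dimensions")
        if np.isnan(self.y).any() or self.X.isna().any().any():
            raise ValueError("missing values in design")
        if n <= p + 2:
            raise ValueError("need n > p + 2 observations")

    def matrix(self) -> np.ndarray:
        X = self.X.to_numpy(dtype=float)
        if self.intercept:
            X = np.column_stack([np.ones(len(X)), X])
        return X

    @property
    def columns(self) -> list[str]:
        cols = list(self.X.columns)
        return (["intercept"] + cols) if self.intercept else cols


@dataclass
class OlsFit:
    coefficients: pd.Series
    r2: float
    aicc: float
    p_values: pd.Series
    residuals: np.ndarray


@dataclass
class GwrFit:
    bandwidth: float
    coefficients: pd.DataFrame  # n x (p+1), named columns
    fitted: np.ndarray
    residuals: np.ndarray
    trace_s: float
    aicc: float
    r2: float

    def coefficient_summary(self) -> pd.DataFrame:
        return self.coefficients.agg(["min", "mean", "max"]).T


def _aicc(rss: float, n: int, trace_s: float) -> float:
    if n - 2 - trace_s <= 0:
        return np.inf
    sigma = np.sqrt(max(rss, 1e-300) / n)
    return 2 * n * np.log(sigma) + n * np.log(2 * np.pi) \
        + n * (n + trace_s) / (n - 2 - trace_s)


def ols_fit(design: DesignMatrix) -> OlsFit:
    """Global least squares with classical t-test p-values and AICc."""
    X = design.matrix()
    y = design.y
    n, p1 = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p1:
        # name the offending columns via near-zero singular directions
        _, s, vt = np.linalg.svd(X, full_matrices=False)
        bad = np.abs(vt[rank:]).max(axis=0) > 1e-8
        cols = [c for c, b in zip(design.columns, bad) if b]
        raise np.linalg.LinAlgError(f"rank-deficient design; collinear columns: {cols}")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    dof = n - p1
    sigma2 = rss / dof if dof > 0 else np.nan
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf)
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    return OlsFit(
        pd.Series(beta, index=design.columns),
        r2,
        _aicc(rss, n, p1),
        pd.Series(pvals, index=design.columns),
        resid,
    )


@dataclass
class VifReport:
    table: pd.DataFrame  # predictor, vif, p_value, retained
    retained: list[str]


def vif_screen(design: DesignMatrix, vif_max: float = 7.5,
               alpha: float = 0.01) -> tuple[VifReport, DesignMatrix]:
    """Collinearity and significance screen.

    VIF_j = 1 / (1 - R_j^2) from regressing predictor j on the others
    (with intercept); predictors with VIF > vif_max or an OLS p-value
    >= alpha are dropped. Returns the report and the reduced design.
    """
    cols = list(design.X.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 predictors to screen")
    ols = ols_fit(design)
    X = design.X.to_numpy(dtype=float)
    n = X.shape[0]
    vifs = {}
    for j, col in enumerate(cols):
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        xj = X[:, j]
        beta, _, _, _ = np.linalg.lstsq(others, xj, rcond=None)
        resid = xj - others @ beta
        tss = float(((xj - xj.mean()) ** 2).sum())
        r2j = 1.0 - float(resid @ resid) / tss if tss > 0 else 1.0
        vifs[col] = np.inf if r2j >= 1.0 - 1e-12 else 1.0 / (1.0 - r2j)
    rows = []
    retained = []
    for col in cols:
        ok = vifs[col] <= vif_max and ols.p_values[col] < alpha
        rows.append({"predictor": col, "vif": vifs[col],
                     "p_value": ols.p_values[col], "retained": ok})
        if ok:
            retained.append(col)
    report = VifReport(pd.DataFrame(rows), retained)
    reduced = DesignMatrix(design.y, design.X[retained], design.coords,
                           design.intercept)
    return report, reduced


def _pairwise_distances(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))


def gwr_fit(design: DesignMatrix, bandwidth: float) -> GwrFit:
    """Local WLS at every location with Gaussian weights exp(-0.5 (d/b)^2)."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    X = design.matrix()
    y = design.y
    n, p1 = X.shape
    d = _pairwise_distances(design.coords)
    kernel = np.exp(-0.5 * (d / bandwidth) ** 2)
    betas = np.empty((n, p1))
    fitted = np.empty(n)
    trace = 0.0
    for i in range(n):
        w = kernel[i]
        Xw = X * w[:, None]
        xtwx = X.T @ Xw
        try:
            xtwx_inv = np.linalg.inv(xtwx)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular local design at observation {i}; widen the bandwidth"
            ) from exc
        beta_i = xtwx_inv @ (Xw.T @ y)
        betas[i] = beta_i
        fitted[i] = X[i] @ beta_i
        # hat-row diagonal: x_i' (X'WX)^-1 X'W e_i
        trace += float(X[i] @ xtwx_inv @ (X[i] * w[i]))
    resid = y - fitted
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return GwrFit(
        bandwidth,
        pd.DataFrame(betas, columns=design.columns),
        fitted,
        resid,
        trace,
        _aicc(rss, n, trace),
        r2,
    )


def select_bandwidth(design: DesignMatrix, search_range: tuple[float, float] | None = None,
                     tol: float = 1e-3) -> float:
    """Golden-section search for the AICc-minimizing fixed bandwidth.

    The default range spans the smallest positive inter-point distance to
    twice the domain diameter. Deterministic; a flat profile (within tol of
    AICc everywhere) returns the upper bound with a warning.
    """
    d = _pairwise_distances(design.coords)
    pos = d[d > 0]
    if pos.size == 0:
        raise ValueError("need at least 2 distinct coordinate locations")
    if search_range is None:
        search_range = (float(pos.min()), 2.0 * float(d.max()))
    lo, hi = search_range
    if not (0 < lo < hi):
        raise ValueError("invalid search range")

    def score(b: float) -> float:
        return gwr_fit(design, b).aicc

    phi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c1 = b - phi * (b - a)
    c2 = a + phi * (b - a)
    f1, f2 = score(c1), score(c2)
    f_lo, f_hi = score(lo), score(hi)
    while b - a > tol * (hi - lo):
        if f1 < f2:
            b, c2, f2 = c2, c1, f1
            c1 = b - phi * (b - a)
            f1 = score(c1)
        else:
            a, c1, f1 = c1, c2, f2
            c2 = a + phi * (b - a)
            f2 = score(c2)
    best = (a + b) / 2.0
    f_best = score(best)
    if abs(f_lo - f_hi) < 1e-9 and abs(f_best - f_hi) < 1e-9:
        import warnings

        warnings.warn("flat AICc profile; returning the upper bound")
        return hi
    # a global profile can beat the interior optimum at the boundary
    if f_hi <= f_best:
        return hi
    return best
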