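"""Geographical-detector factor and interaction detection.

The q-statistic measures how much of the spatial variance of an outcome a
stratified factor explains:

    q = 1 - sum_h N_h sigma_h^2 / (N sigma^2)

with population variances within strata (sigma_h^2) and overall (sigma^2).
q = 0 when stratum means and variances match the whole region; q = 1 when
the factor removes all within-stratum variance. Significance follows the
noncentral-F test of the geodetector literature; it is reported but never
used to drop factors. Interaction detection overlays two stratifications
(Cartesian intersection of labels) and classifies the joint q against the
single-factor values (enhancement / weakening categories).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class FactorPartition:
    """A factor reduced to stratum labels, with discretization metadata."""

    name: str
    labels: np.ndarray
    method: str = "supplied"
    k: int | None = None
    breaks: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        counts = pd.Series(self.labels).value_counts()
        if (counts == 0).any():
            raise ValueError("empty stratum")

    @property
    def n_strata(self) -> int:
        return len(np.unique(self.labels))


@dataclass
class QResult:
    q: float
    n_strata: int
    stratum_sizes: dict
    stratum_variances: dict
    n: int
    variance: float
    p: float


def discretize(values, method: str = "quantile", k: int = 5,
               name: str = "factor") -> FactorPartition:
    """Stratify a continuous driver into k classes.

    ``quantile`` (default) uses empirical quantile edges with duplicate
    edges merged; ``equal_interval`` splits [min, max] evenly;
    ``natural_breaks`` is a 1-D k-means (Jenks-style) on sorted values.
    Fewer distinct values than k merge strata with a warning.
    """
    x = np.asarray(values, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if x.size < k:
        raise ValueError("need at least k observations")
    distinct = np.unique(x)
    if distinct.size == 1:
        warnings.warn("constant factor: single stratum")
        return FactorPartition(name, np.zeros(x.size, dtype=int), method, 1,
                               np.asarray([x[0], x[0]]))
    if method == "quantile":
        edges = np.unique(np.quantile(x, np.linspace(0, 1, k + 1)))
        if edges.size - 1 < k:
            warnings.warn(f"{name}: duplicate quantile edges merged "
                          f"({edges.size - 1} strata instead of {k})")
    elif method == "equal_interval":
        edges = np.linspace(x.min(), x.max(), k + 1)
    elif method == "natural_breaks":
        edges = _jenks_edges(x, k)
    else:
        raise ValueError(f"unknown method {method!r}")
    labels = np.clip(np.searchsorted(edges, x, side="right") - 1, 0,
                     edges.size - 2)
    return FactorPartition(name, labels.astype(int), method, edges.size - 1, edges)


def _jenks_edges(x: np.ndarray, k: int) -> np.ndarray:
    """1-D k-means on sorted values as a natural-breaks approximation."""
    xs = np.sort(x)
    centers = np.quantile(xs, (np.arange(k) + 0.5) / k)
    for _ in range(100):
        assign = np.argmin(np.abs(xs[:, None] - centers[None, :]), axis=1)
        new = np.asarray([xs[assign == j].mean() if np.any(assign == j) else centers[j]
                          for j in range(k)])
        if np.allclose(new, centers):
            break
        centers = new
    edges = [xs[0]]
    for j in range(k - 1):
        sel_hi = xs[assign == j]
        sel_lo = xs[assign == j + 1]
        if sel_hi.size and sel_lo.size:
            edges.append((sel_hi.max() + sel_lo.min()) / 2)
    edges.append(xs[-1])
    return np.unique(edges)


def factor_q(y, partition: FactorPartition) -> QResult:
    """q-statistic of a stratified factor with noncentral-F significance."""
    y = np.asarray(y, dtype=float)
    labels = partition.labels
    if y.shape[0] != labels.shape[0]:
        raise ValueError("y and partition length mismatch")
    var = y.var(ddof=0)
    if var == 0.0:
        raise ValueError("outcome is constant; q undefined")
    n = y.size
    strata = np.unique(labels)
    sizes, variances, means = {}, {}, {}
    within = 0.0
    for h in strata:
        sel = y[labels == h]
        sizes[h] = int(sel.size)
        variances[h] = float(sel.var(ddof=0))
        means[h] = float(sel.mean())
        within += sel.size * variances[h]
    q = 1.0 - within / (n * var)
    L = strata.size
    p = _q_pvalue(q, n, L, var, sizes, means)
    return QResult(float(q), L, sizes, variances, n, float(var), p)


def _q_pvalue(q: float, n: int, L: int, var: float, sizes: dict, means: dict) -> float:
    """Noncentral-F tail probability for the q-statistic."""
    if L < 2 or n - L <= 0 or q >= 1.0:
        return 0.0 if q >= 1.0 else 1.0
    F = (n - L) / (L - 1) * q / (1.0 - q)
    lam = (sum(means[h] ** 2 * sizes[h] for h in sizes)
           - (sum(np.sqrt(sizes[h]) * means[h] for h in sizes)) ** 2 / n) / var
    lam = max(lam, 0.0)
    return float(stats.ncf.sf(F, L - 1, n - L, lam))


#: Interaction classes, in the field's standard terminology.
NONLINEAR_WEAKEN = "nonlinear weaken"
SINGLE_WEAKEN = "single-factor nonlinear weaken"
BIVARIATE_ENHANCE = "bivariate enhancement"
INDEPENDENT = "independent"
NONLINEAR_ENHANCE = "nonlinear enhancement"


def classify_interaction(q1: float, q2: float, q12: float,
                         tol: float = 1e-9) -> str:
    if abs(q12 - (q1 + q2)) <= tol:
        return INDEPENDENT
    if q12 > q1 + q2:
        return NONLINEAR_ENHANCE
    if q12 > max(q1, q2):
        return BIVARIATE_ENHANCE
    if q12 < min(q1, q2):
        return NONLINEAR_WEAKEN
    return SINGLE_WEAKEN


def overlay(a: FactorPartition, b: FactorPartition) -> FactorPartition:
    """Cartesian intersection of two stratifications (empty cells dropped)."""
    pairs = pd.Series(list(zip(a.labels, b.labels)))
    codes = pairs.astype("category").cat.codes.to_numpy()
    return FactorPartition(f"{a.name}*{b.name}", codes, method="overlay")


def interaction_q(y, a: FactorPartition, b: FactorPartition):
    """Overlay q plus its classification against the single-factor values."""
    joint = overlay(a, b)
    if joint.n_strata == len(np.asarray(y)):
        warnings.warn("overlay produced only singleton strata; q is inflated")
    q1 = factor_q(y, a).q
    q2 = factor_q(y, b).q
    res = factor_q(y, joint)
    return res, classify_interaction(q1, q2, res.q)


def interaction_matrix(y, partitions: list[FactorPartition]) -> pd.DataFrame:
    """Lower-triangular q matrix: diagonal = single-factor q, off-diagonal =
    overlay q, with the classification table attached as ``attrs['classes']``."""
    if len(partitions) < 2:
        raise ValueError("need at least 2 factors")
    names = [p.name for p in partitions]
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    classes = []
    singles = {p.name: factor_q(y, p).q for p in partitions}
    for p in partitions:
        mat.loc[p.name, p.name] = singles[p.name]
    for a, b in itertools.combinations(partitions, 2):
        res, cls = interaction_q(y, a, b)
        mat.loc[b.name, a.name] = res.q
        classes.append({"factor_a": a.name, "factor_b": b.name,
                        "q12": res.q, "classification": cls})
    mat.attrs["classes"] = pd.DataFrame(classes)
    return mat
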