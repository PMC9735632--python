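"""Spatial weights and autocorrelation statistics.

Row-standardized contiguity / k-nearest-neighbour weights, global Moran's I
with normal-approximation, randomization and permutation inference, and the
local Moran (LISA) decomposition with conditional-permutation pseudo
p-values and high/high - low/low - high/low - low/high cluster labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats


class DegenerateInputError(ValueError):
    """Raised when a statistic is undefined (e.g. constant values)."""


class SpatialWeights:
    """Neighbour structure with row-standardized weights.

    Adjacency is stored symmetric and without self-neighbours; weights are
    1/degree for non-isolated units. Units with no neighbours (islands) are
    flagged and receive zero weights.
    """

    def __init__(self, ids: list[str], neighbors: dict[str, list[str]]):
        self.ids = list(ids)
        self._index = {u: i for i, u in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            raise ValueError("duplicate unit ids")
        self.neighbors = {u: sorted(neighbors.get(u, []), key=self._index.__getitem__)
                          for u in self.ids}
        for u, nbrs in self.neighbors.items():
            if u in nbrs:
                raise ValueError(f"self-neighbour at {u}")
            for v in nbrs:
                if u not in self.neighbors[v]:
                    raise ValueError(f"asymmetric adjacency: {u}->{v}")
        self.islands = {u for u, nbrs in self.neighbors.items() if not nbrs}

    # -- constructors ---------------------------------------------------

    @classmethod
    def lattice(cls, n_rows: int, n_cols: int, scheme: str = "rook",
                ids: list[str] | None = None) -> "SpatialWeights":
        """Contiguity weights on an n_rows x n_cols grid (rook or queen)."""
        if scheme not in {"rook", "queen"}:
            raise ValueError(f"unknown scheme {scheme!r}")
        if ids is None:
            ids = [f"u{r:03d}{c:03d}" for r in range(n_rows) for c in range(n_cols)]
        if len(ids) != n_rows * n_cols:
            raise ValueError("ids length must equal n_rows * n_cols")
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
        if scheme == "queen":
            steps += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
        nbrs: dict[str, list[str]] = {}
        for r in range(n_rows):
            for c in range(n_cols):
                out = []
                for dr, dc in steps:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < n_rows and 0 <= cc < n_cols:
                        out.append(ids[rr * n_cols + cc])
                nbrs[ids[r * n_cols + c]] = out
        return cls(ids, nbrs)

    @classmethod
    def from_polygons(cls, geometries: dict[str, object], scheme: str = "queen") -> "SpatialWeights":
        """Contiguity from shapely polygons: queen = any shared point,
        rook = shared boundary of positive length."""
        if scheme not in {"rook", "queen"}:
            raise ValueError(f"unknown scheme {scheme!r}")
        ids = list(geometries)
        if len(ids) < 2:
            raise ValueError("need at least 2 units")
        nbrs: dict[str, list[str]] = {u: [] for u in ids}
        for i, u in enumerate(ids):
            gu = geometries[u]
            for v in ids[i + 1:]:
                gv = geometries[v]
                if not gu.intersects(gv) or gu.overlaps(gv):
                    touch = False
                elif scheme == "queen":
                    touch = gu.touches(gv)
                else:
                    inter = gu.boundary.intersection(gv.boundary)
                    touch = gu.touches(gv) and inter.length > 0
                if touch:
                    nbrs[u].append(v)
                    nbrs[v].append(u)
        w = cls(ids, nbrs)
        if len(w.islands) == len(ids):
            raise ValueError("all units are islands under this scheme")
        return w

    @classmethod
    def knn(cls, coords: dict[str, tuple[float, float]], k: int = 4) -> "SpatialWeights":
        """Symmetrized k-nearest-neighbour graph on centroid coordinates."""
        ids = list(coords)
        if k < 1 or k >= len(ids):
            raise ValueError("require 1 <= k < n")
        pts = np.asarray([coords[u] for u in ids], dtype=float)
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        nbrs: dict[str, set[str]] = {u: set() for u in ids}
        for i, u in enumerate(ids):
            for j in np.argsort(d[i], kind="stable")[:k]:
                nbrs[u].add(ids[j])
                nbrs[ids[j]].add(u)  # symmetrize
        return cls(ids, {u: sorted(v) for u, v in nbrs.items()})

    @classmethod
    def from_gal(cls, path: str) -> "SpatialWeights":
        """Read a GAL-style adjacency list (header: n; then id/degree + ids)."""
        with open(path) as fh:
            tokens = fh.read().split("\n")
        lines = [ln.split() for ln in tokens if ln.strip()]
        n = int(lines[0][0])
        ids, nbrs = [], {}
        i = 1
        while i < len(lines):
            u, deg = lines[i][0], int(lines[i][1])
            ids.append(u)
            nbrs[u] = lines[i + 1] if deg > 0 else []
            if deg > 0 and len(nbrs[u]) != deg:
                raise ValueError(f"degree mismatch for {u}")
            i += 2 if deg > 0 else 1
        if len(ids) != n:
            raise ValueError("GAL header count mismatch")
        return cls(ids, nbrs)

    # -- export / algebra ----------------------------------------------

    def to_gal(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for u in self.ids:
                nbrs = self.neighbors[u]
                fh.write(f"{u} {len(nbrs)}\n")
                if nbrs:
                    fh.write(" ".join(nbrs) + "\n")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def cardinalities(self) -> np.ndarray:
        return np.asarray([len(self.neighbors[u]) for u in self.ids])

    def matrix(self) -> sparse.csr_matrix:
        """Row-standardized weight matrix W (islands give all-zero rows)."""
        rows, cols, vals = [], [], []
        for i, u in enumerate(self.ids):
            nbrs = self.neighbors[u]
            if not nbrs:
                continue
            w = 1.0 / len(nbrs)
            for v in nbrs:
                rows.append(i)
                cols.append(self._index[v])
                vals.append(w)
        return sparse.csr_matrix((vals, (rows, cols)), shape=(self.n, self.n))

    def lag(self, values: np.ndarray) -> np.ndarray:
        """Spatial lag Wx (average of neighbours; 0 for islands)."""
        return self.matrix() @ np.asarray(values, dtype=float)

    def row_sums(self) -> np.ndarray:
        return np.asarray(self.matrix().sum(axis=1)).ravel()


@dataclass
class MoranResult:
    I: float
    expected: float
    z: float
    p: float
    method: str
    n: int
    permutations: int | None = None


@dataclass
class LisaResult:
    table: pd.DataFrame  # unit_id, local_I, pseudo_p, label
    alpha: float
    permutations: int

    @property
    def labels(self) -> pd.Series:
        return self.table.set_index("unit_id")["label"]


def _moran_terms(values: np.ndarray, W: sparse.csr_matrix):
    z = values - values.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise DegenerateInputError("Moran's I undefined for constant values")
    s0 = float(W.sum())
    num = float(z @ (W @ z))
    return z, s0, num / denom * len(values) / s0


def global_moran(values, w: SpatialWeights, method: str = "randomization",
                 n_permutations: int = 999, seed: int | None = None) -> MoranResult:
    """Global Moran's I with the chosen null.

    ``normal`` and ``randomization`` use the closed-form variance of I under
    the respective assumption; ``permutation`` ranks the observed I among
    ``n_permutations`` full random relabelings (pseudo-p, two-tailed by
    folding the smaller tail).
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != w.n:
        raise ValueError("values length does not match weights")
    W = w.matrix()
    n = w.n
    z, s0, I = _moran_terms(values, W)
    e_i = -1.0 / (n - 1)

    if method == "permutation":
        rng = np.random.default_rng(seed)
        sims = np.empty(n_permutations)
        for k in range(n_permutations):
            perm = rng.permutation(values)
            _, _, sims[k] = _moran_terms(perm, W)
        p_hi = (np.sum(sims >= I) + 1) / (n_permutations + 1)
        p_lo = (np.sum(sims <= I) + 1) / (n_permutations + 1)
        p = min(1.0, 2.0 * min(p_hi, p_lo))
        sd = sims.std(ddof=0)
        zscore = (I - sims.mean()) / sd if sd > 0 else np.nan
        return MoranResult(I, e_i, zscore, p, "permutation", n, n_permutations)

    Wd = W.toarray()
    s1 = 0.5 * float(((Wd + Wd.T) ** 2).sum())
    s2 = float(((Wd.sum(axis=1) + Wd.sum(axis=0)) ** 2).sum())
    if method == "normal":
        var = (n * n * s1 - n * s2 + 3 * s0 * s0) / (s0 * s0 * (n * n - 1)) - e_i**2
    elif method == "randomization":
        b2 = n * float((z**4).sum()) / float((z**2).sum()) ** 2
        num = (n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0)
               - b2 * ((n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0))
        var = num / ((n - 1) * (n - 2) * (n - 3) * s0 * s0) - e_i**2
    else:
        raise ValueError(f"unknown method {method!r}")
    zscore = (I - e_i) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(zscore))
    return MoranResult(I, e_i, zscore, p, method, n)


def local_moran(values, w: SpatialWeights, n_permutations: int = 999,
                alpha: float = 0.05, seed: int | None = None) -> LisaResult:
    """Local Moran I_i with conditional-permutation pseudo p-values.

    I_i = z_i * lag(z)_i with z standardized by the population SD; the null
    for unit i permutes the other n-1 values into i's neighbour slots while
    holding z_i fixed. Labels follow the Moran-scatterplot quadrant of
    (z_i, lag_i) when pseudo_p <= alpha; islands are never significant.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != w.n:
        raise ValueError("values length does not match weights")
    sd = values.std(ddof=0)
    if sd == 0.0:
        raise DegenerateInputError("LISA undefined for constant values")
    z = (values - values.mean()) / sd
    lag = w.lag(z)
    local_i = z * lag

    rng = np.random.default_rng(seed)
    n = w.n
    pseudo_p = np.ones(n)
    card = w.cardinalities
    for i in range(n):
        k = card[i]
        if k == 0:
            continue
        others = np.delete(z, i)
        # draw neighbour values for each permutation without replacement
        idx = np.argsort(rng.random((n_permutations, n - 1)), axis=1)[:, :k]
        sim_lag = others[idx].mean(axis=1)
        sim_i = z[i] * sim_lag
        p_hi = (np.sum(sim_i >= local_i[i]) + 1) / (n_permutations + 1)
        p_lo = (np.sum(sim_i <= local_i[i]) + 1) / (n_permutations + 1)
        pseudo_p[i] = min(p_hi, p_lo)

    labels = []
    for i in range(n):
        if card[i] == 0 or pseudo_p[i] > alpha:
            labels.append("not significant")
        elif z[i] > 0 and lag[i] > 0:
            labels.append("high/high")
        elif z[i] <= 0 and lag[i] <= 0:
            labels.append("low/low")
        elif z[i] > 0:
            labels.append("high/low")
        else:
            labels.append("low/high")

    table = pd.DataFrame(
        {"unit_id": w.ids, "local_I": local_i, "pseudo_p": pseudo_p, "label": labels}
    )
    return LisaResult(table, alpha, n_permutations)
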