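"""Supply-demand coordination: z-scores, quadrants, ESDR, bands, curve fit.

Supply and demand are standardized per year with the population standard
deviation (divide by n). Units are typed by the signs of standardized
supply S (x-axis) and demand D (y-axis):

    I  high supply / high demand     II low supply / high demand
    III low supply / low demand      IV high supply / low demand

The coordination degree ESDR = (S - D) / ((S_max + D_max) / 2) is positive
in surplus and negative in deficit, and is banded into k equal-width
intervals per year for mapping. A boundary z of exactly 0 is assigned to
the "low" side (II/III), a deterministic tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


class DegenerateInputError(ValueError):
    pass


def zscore(values) -> np.ndarray:
    """Standardize with the population SD: (x - mean) / sqrt(sum(x-mean)^2 / n)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DegenerateInputError("need at least 2 values to standardize")
    s = x.std(ddof=0)
    if s == 0.0:
        raise DegenerateInputError("cannot z-score a constant vector")
    return (x - x.mean()) / s


def classify_quadrant(S: float, D: float) -> str:
    """Quadrant of a (standardized supply, standardized demand) pair."""
    if S > 0:
        return "I" if D > 0 else "IV"
    return "II" if D > 0 else "III"


def esdr(S, D, S_max: float, D_max: float):
    """Coordination degree (S - D) / ((S_max + D_max) / 2)."""
    denom = (S_max + D_max) / 2.0
    if denom <= 0:
        raise DegenerateInputError("S_max + D_max must be positive")
    return (np.asarray(S, dtype=float) - np.asarray(D, dtype=float)) / denom


def classify_esdr_bands(values, k: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width bands over [min, max]; returns (labels 1..k, k+1 breaks).

    Intervals are half-open on the right except the last, which is closed
    so the maximum falls in band k. A constant vector collapses to a single
    band (labels all 1) with a two-point break vector.
    """
    x = np.asarray(values, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.ones(x.size, dtype=int), np.asarray([lo, hi])
    breaks = np.linspace(lo, hi, k + 1)
    labels = np.minimum(np.searchsorted(breaks, x, side="right"), k)
    return labels.astype(int), breaks


def compute_coordination(supply: pd.DataFrame, demand: pd.DataFrame,
                         k_bands: int = 5) -> pd.DataFrame:
    """Join per-unit supply totals and demand, standardize per year, and
    return unit_id, year, S, D, quadrant, esdr, band.

    Standardization, the ESDR denominator (the per-year maxima of S and D)
    and the equal-interval bands are all computed within each year, the
    per-map convention.
    """
    df = supply.merge(demand[["unit_id", "year", "demand"]],
                      on=["unit_id", "year"], validate="one_to_one")
    out = []
    all_breaks: dict[int, list[float]] = {}
    for year, grp in df.groupby("year", sort=True):
        S = zscore(grp["supply"].to_numpy())
        D = zscore(grp["demand"].to_numpy())
        vals = esdr(S, D, S.max(), D.max())
        bands, breaks = classify_esdr_bands(vals, k_bands)
        all_breaks[int(year)] = [float(b) for b in breaks]
        out.append(pd.DataFrame(
            {
                "unit_id": grp["unit_id"].to_numpy(),
                "year": year,
                "S": S,
                "D": D,
                "quadrant": [classify_quadrant(s, d) for s, d in zip(S, D)],
                "esdr": vals,
                "band": bands,
            }
        ))
    result = pd.concat(out, ignore_index=True)
    result.attrs["breaks"] = all_breaks
    return result


@dataclass
class CurveFit:
    """Parameters of y = a + b * exp(c * x) with fit diagnostics."""

    a: float
    b: float
    c: float
    rss: float
    converged: bool


def fit_supply_demand_curve(x, y, n_starts: int = 12, seed: int = 0) -> CurveFit:
    """Least-squares fit of the exponential supply-demand relation
    y = a + b e^{cx} from multiple starting points; returns the best fit.

    Starts combine sign and scale guesses for the rate c with moment-based
    guesses for a and b; non-convergence from every start is flagged, not
    raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 points")

    def resid(p):
        a, b, c = p
        return a + b * np.exp(np.clip(c * x, -50, 50)) - y

    span = x.max() - x.min()
    scale = 1.0 / span if span > 0 else 1.0
    rng = np.random.default_rng(seed)
    starts = [(y.mean(), y.std() + 1e-6, c0)
              for c0 in (-4 * scale, -scale, scale, 4 * scale)]
    while len(starts) < n_starts:
        starts.append((y.mean() + rng.normal(0, y.std() + 1e-6),
                       rng.normal(0, 2 * (y.std() + 1e-6)),
                       rng.normal(0, 6 * scale)))

    best = None
    for p0 in starts:
        try:
            sol = least_squares(resid, p0, method="lm", max_nfev=5000)
        except Exception:
            continue
        rss = float(sol.fun @ sol.fun)
        if np.isfinite(rss) and (best is None or rss < best[0]):
            best = (rss, sol)
    if best is None:
        return CurveFit(np.nan, np.nan, np.nan, np.inf, False)
    rss, sol = best
    a, b, c = sol.x
    return CurveFit(float(a), float(b), float(c), rss, bool(sol.success))
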