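"""Synthetic county-panel generator.

Emulates the statistical structure a county-scale ecosystem-services
supply-demand assessment assumes: a planar lattice of equal-area units
observed at three snapshot years, with a supply-favourable gradient running
northwest -> southeast, an opposing demand gradient, spatially smoothed
noise, and land-use composition / population density / GDP per land
coherently tied to those gradients.  Unit-square cells stand in for county
polygons: every downstream computation needs only areas, attributes,
neighbours and centroid distances.

All randomness flows from a single integer seed; each operation draws from
its own named child stream, so the same spec always yields a bit-identical
panel.
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reference import LAND_CLASSES
from .spatial import SpatialWeights

AREA_COLUMNS = tuple(f"area_{c}" for c in LAND_CLASSES)

PANEL_COLUMNS = ("unit_id", "year") + AREA_COLUMNS + (
    "pop_density",
    "gdp_per_land",
    "x",
    "y",
)


class InvalidSpecError(ValueError):
    """Raised when a RegionSpec fails validation."""


@dataclass(frozen=True)
class RegionSpec:
    """Parameters of a synthetic lattice region.

    Parameters
    ----------
    n_rows, n_cols
        Lattice dimensions; ``n_rows * n_cols >= 4``.
    years
        Strictly increasing snapshot years (default three, decade-spaced).
    seed
        Master seed; all streams are derived from it.
    gradient_strength
        Amplitude of the NW->SE latent gradients (0 disables them).
    noise_rho
        Spatial-smoothing weight in [0, 1): share of the neighbour average
        mixed into the i.i.d. noise field on each smoothing pass.
    demand_growth
        Per-snapshot multiplicative drift of the demand covariates (>= 0).
    cell_area
        Area of one lattice cell in hm^2 (1 km^2 = 100 hm^2 by default).
    """

    n_rows: int
    n_cols: int
    years: tuple[int, ...] = (2000, 2010, 2020)
    seed: int = 0
    gradient_strength: float = 1.0
    noise_rho: float = 0.5
    demand_growth: float = 0.15
    cell_area: float = 100.0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise InvalidSpecError("lattice dimensions must be positive")
        if self.n_rows * self.n_cols < 4:
            raise InvalidSpecError("lattice must contain at least 4 units")
        years = tuple(self.years)
        object.__setattr__(self, "years", years)
        if len(years) == 0 or any(b <= a for a, b in zip(years, years[1:])):
            raise InvalidSpecError("years must be non-empty and strictly increasing")
        if not 0.0 <= self.noise_rho < 1.0:
            raise InvalidSpecError("noise_rho must lie in [0, 1)")
        if self.gradient_strength < 0 or self.demand_growth < 0:
            raise InvalidSpecError("gradient_strength and demand_growth must be >= 0")
        if self.cell_area <= 0:
            raise InvalidSpecError("cell_area must be positive")

    @property
    def n_units(self) -> int:
        return self.n_rows * self.n_cols

    def unit_ids(self) -> list[str]:
        return [
            f"u{r:03d}{c:03d}"
            for r in range(self.n_rows)
            for c in range(self.n_cols)
        ]

    def _stream(self, name: str) -> np.random.Generator:
        # zlib.crc32 is stable across processes, unlike builtin str hashing
        key = zlib.crc32(name.encode("utf-8")) % (2**31)
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)


def _centroids(spec: RegionSpec) -> tuple[np.ndarray, np.ndarray]:
    # row 0 is the northern edge; y increases northward, x eastward
    rows, cols = np.divmod(np.arange(spec.n_units), spec.n_cols)
    x = cols + 0.5
    y = (spec.n_rows - 1 - rows) + 0.5
    return x.astype(float), y.astype(float)


def _smooth(values: np.ndarray, spec: RegionSpec, rho: float, passes: int = 5) -> np.ndarray:
    """Mix a rook-neighbour average into the field, `passes` times."""
    if rho == 0.0:
        return values
    w = SpatialWeights.lattice(spec.n_rows, spec.n_cols, scheme="rook",
                               ids=spec.unit_ids())
    out = values.astype(float)
    for _ in range(passes):
        out = (1.0 - rho) * out + rho * w.lag(out)
    return out


def latent_fields(spec: RegionSpec) -> pd.DataFrame:
    """Latent supply and demand surfaces g_s, g_d per unit.

    g_s declines NW -> SE (high where y is large and x small); g_d is its
    mirror image.  Both carry spatially smoothed Gaussian noise; with
    ``gradient_strength = 0`` and ``noise_rho = 0`` the fields are i.i.d.
    """
    x, y = _centroids(spec)
    nw_axis = y / spec.n_rows - x / spec.n_cols  # in (-1, 1), large in the NW
    rng_s = spec._stream("latent_supply")
    rng_d = spec._stream("latent_demand")
    eps_s = _smooth(rng_s.normal(0.0, 0.5, spec.n_units), spec, spec.noise_rho)
    eps_d = _smooth(rng_d.normal(0.0, 0.5, spec.n_units), spec, spec.noise_rho)
    g_s = spec.gradient_strength * nw_axis + eps_s
    g_d = -spec.gradient_strength * nw_axis + eps_d
    return pd.DataFrame(
        {"unit_id": spec.unit_ids(), "x": x, "y": y, "g_s": g_s, "g_d": g_d}
    )


# land-class softmax affinities: intercept + loading on g_s + loading on g_d.
# Ecological classes load on the supply surface, built-up on demand;
# intercepts set the mix of a mid-gradient cell (agriculture-dominated,
# little wetland/water, as in a semi-arid basin).
_AFFINITY = {
    "agricultural": (0.9, 0.0, 0.3),
    "woodland": (0.1, 1.0, 0.0),
    "grassland": (0.5, 0.8, 0.0),
    "wetland": (-1.6, 0.6, 0.0),
    "water": (-1.6, 0.6, 0.0),
    "construction": (-0.6, 0.0, 1.4),
    "unutilized": (-1.0, 0.0, 0.0),
}

#: Extra construction-affinity shift per snapshot step (urban expansion).
_URBAN_DRIFT = 0.15


def generate_units(spec: RegionSpec) -> pd.DataFrame:
    """Generate the unit panel: one record per lattice cell per year.

    Land-class areas are a softmax allocation of the cell area driven by the
    latent fields; population density (persons/km^2) and GDP per land
    (10^4 CNY/km^2) are log-normal with location increasing in demand and
    in construction share, drifting upward by ``demand_growth`` per
    snapshot.  Covariates are truncated below at 1.01 so that the base-10
    logs in the demand index stay positive.
    """
    fields = latent_fields(spec)
    g_s = fields["g_s"].to_numpy()
    g_d = fields["g_d"].to_numpy()
    n = spec.n_units

    rng_shares = spec._stream("land_shares")
    rng_pop = spec._stream("pop_density")
    rng_gdp = spec._stream("gdp_per_land")

    records = []
    for t, year in enumerate(spec.years):
        logits = np.empty((n, len(LAND_CLASSES)))
        for j, cls in enumerate(LAND_CLASSES):
            a0, bs, bd = _AFFINITY[cls]
            if cls == "construction":
                a0 = a0 + _URBAN_DRIFT * t
            logits[:, j] = a0 + bs * g_s + bd * g_d
        logits += rng_shares.normal(0.0, 0.1, logits.shape)
        logits -= logits.max(axis=1, keepdims=True)
        shares = np.exp(logits)
        shares /= shares.sum(axis=1, keepdims=True)
        areas = shares * spec.cell_area

        growth = (1.0 + spec.demand_growth) ** t
        constr = shares[:, LAND_CLASSES.index("construction")]
        pop = np.exp(
            np.log(200.0) + 1.2 * g_d + 2.0 * constr
            + rng_pop.normal(0.0, 0.3, n)
        ) * growth
        gdp = np.exp(
            np.log(500.0) + 1.2 * g_d + 2.0 * constr
            + rng_gdp.normal(0.0, 0.3, n)
        ) * growth
        pop = np.maximum(pop, 1.01)
        gdp = np.maximum(gdp, 1.01)

        df = pd.DataFrame(areas, columns=list(AREA_COLUMNS))
        df.insert(0, "unit_id", fields["unit_id"])
        df.insert(1, "year", year)
        df["pop_density"] = pop
        df["gdp_per_land"] = gdp
        df["x"] = fields["x"]
        df["y"] = fields["y"]
        records.append(df)

    panel = pd.concat(records, ignore_index=True)
    return panel[list(PANEL_COLUMNS)]


def generate_lattice_weights(spec: RegionSpec, scheme: str = "rook") -> SpatialWeights:
    """Row-standardized contiguity weights for the spec's lattice."""
    return SpatialWeights.lattice(spec.n_rows, spec.n_cols, scheme=scheme,
                                  ids=spec.unit_ids())


def _cell_polygon(x: float, y: float, half: float = 0.5) -> dict:
    ring = [
        [x - half, y - half],
        [x + half, y - half],
        [x + half, y + half],
        [x - half, y + half],
        [x - half, y - half],
    ]
    return {"type": "Polygon", "coordinates": [ring]}


def write_fixtures(panel: pd.DataFrame, weights: SpatialWeights, path: str) -> dict[str, str]:
    """Write units.csv, units.geojson and weights.gal under `path`.

    Returns the mapping of artefact name to file path.  Reading the files
    back with :func:`read_fixtures` reproduces the panel exactly.
    """
    if panel is None or len(panel) == 0:
        raise ValueError("refusing to write an empty panel")
    os.makedirs(path, exist_ok=True)
    paths = {
        "units": os.path.join(path, "units.csv"),
        "geojson": os.path.join(path, "units.geojson"),
        "weights": os.path.join(path, "weights.gal"),
    }
    panel.to_csv(paths["units"], index=False, float_format="%.17g")

    first_year = panel["year"].min()
    cells = panel.loc[panel["year"] == first_year, ["unit_id", "x", "y"]]
    features = [
        {
            "type": "Feature",
            "properties": {"unit_id": row.unit_id},
            "geometry": _cell_polygon(row.x, row.y),
        }
        for row in cells.itertuples()
    ]
    with open(paths["geojson"], "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)

    weights.to_gal(paths["weights"])
    return paths


def read_fixtures(path: str) -> tuple[pd.DataFrame, SpatialWeights]:
    """Read a fixture directory written by :func:`write_fixtures`."""
    panel = pd.read_csv(os.path.join(path, "units.csv"))
    weights = SpatialWeights.from_gal(os.path.join(path, "weights.gal"))
    return panel[list(PANEL_COLUMNS)], weights
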