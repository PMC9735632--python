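"""Equivalent-factor supply valuation.

Monetizes ecosystem-service supply per unit per service: the base value
E_a of one equivalent (1/7 of the grain-production value per unit farmland
area), the service x land-class equivalence coefficients with an optional
regional correction, per-unit service values ESV_j = sum_i E_a e_ij M_i,
and aggregate change-rate reporting between snapshot years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reference import LAND_CLASSES, SERVICES


@dataclass(frozen=True)
class CropRecord:
    """One food crop: average price P (currency/kg), total yield G (kg),
    sown area A (hm^2)."""

    crop_id: str
    price: float
    yield_total: float
    area: float

    def __post_init__(self) -> None:
        if self.price <= 0 or self.area <= 0:
            raise ValueError(f"crop {self.crop_id}: price and area must be positive")
        if self.yield_total < 0:
            raise ValueError(f"crop {self.crop_id}: yield must be >= 0")


def compute_ea(crops, divisor: float = 7.0) -> float:
    """Economic value of one equivalent: E_a = (1/divisor) * sum(P_i G_i) / A_total.

    The conventional divisor 7 encodes that an unmanaged ecosystem provides
    1/7 of the food-production value of the same area of farmland.
    """
    crops = list(crops)
    if not crops:
        raise ValueError("need at least one crop record")
    total_area = sum(c.area for c in crops)
    if total_area <= 0:
        raise ValueError("total crop area must be positive")
    return sum(c.price * c.yield_total for c in crops) / (divisor * total_area)


def deflate_price(nominal: float, annual_rate: float, n_years: int) -> float:
    """Deflate a nominal price geometrically: nominal / (1 + rate)^n_years."""
    if annual_rate <= -1:
        raise ValueError("annual_rate must exceed -1")
    return nominal / (1.0 + annual_rate) ** n_years


def apply_correction(table: pd.DataFrame, factor: float) -> pd.DataFrame:
    """Scale every equivalence coefficient by a regional yield-ratio factor."""
    if factor <= 0:
        raise ValueError("correction factor must be positive")
    out = table * factor
    out.attrs["correction_factor"] = table.attrs.get("correction_factor", 1.0) * factor
    return out


def _check_table(table: pd.DataFrame) -> None:
    missing = set(LAND_CLASSES) - set(table.columns)
    if missing:
        raise KeyError(f"coefficient table missing land classes: {sorted(missing)}")
    missing_s = set(SERVICES) - set(table.index)
    if missing_s:
        raise KeyError(f"coefficient table missing services: {sorted(missing_s)}")


@dataclass
class SupplyResult:
    """Per-unit-per-year service values plus aggregates.

    ``values``: long table (unit_id, year, service, value);
    ``unit_totals``: (unit_id, year, supply) summed over services;
    ``aggregates``: service x year totals.
    """

    values: pd.DataFrame
    unit_totals: pd.DataFrame
    aggregates: pd.DataFrame
    currency: str = "CNY/year"


def compute_supply(panel: pd.DataFrame, table: pd.DataFrame,
                   ea_by_year: dict[int, float]) -> SupplyResult:
    """Monetize supply: ESV_j(unit, year) = sum_i E_a(year) e_ij M_i(unit, year)."""
    _check_table(table)
    years = sorted(panel["year"].unique())
    missing = [y for y in years if y not in ea_by_year]
    if missing:
        raise KeyError(f"no E_a supplied for years {missing}")
    area_cols = [f"area_{c}" for c in LAND_CLASSES]
    unknown = [c for c in panel.columns
               if c.startswith("area_") and c not in area_cols]
    if unknown:
        raise KeyError(f"unknown land classes in panel: {unknown}")

    areas = panel[area_cols].to_numpy(dtype=float)  # n x 7, M_i
    coef = table.loc[list(SERVICES), list(LAND_CLASSES)].to_numpy(dtype=float)
    ea = panel["year"].map(ea_by_year).to_numpy(dtype=float)
    esv = ea[:, None] * (areas @ coef.T)  # n x 11

    values = pd.DataFrame(esv, columns=list(SERVICES))
    values.insert(0, "unit_id", panel["unit_id"].to_numpy())
    values.insert(1, "year", panel["year"].to_numpy())
    long = values.melt(id_vars=["unit_id", "year"], var_name="service",
                       value_name="value")
    unit_totals = (
        values.set_index(["unit_id", "year"]).sum(axis=1)
        .rename("supply").reset_index()
    )
    aggregates = (
        long.groupby(["service", "year"])["value"].sum().unstack("year")
        .loc[list(SERVICES)]
    )
    return SupplyResult(long, unit_totals, aggregates)


def change_rates(aggregates: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Percent change between consecutive and end-point years.

    rate(y1 -> y2) = 100 (V_y2 - V_y1) / V_y1, rounded to ``decimals``;
    a zero baseline yields NaN (flagged, not raised). A ``total`` row over
    all services is appended.
    """
    years = sorted(aggregates.columns)
    if len(years) < 2:
        raise ValueError("need at least two years for change rates")
    agg = aggregates.copy()
    agg.loc["total"] = agg.sum()
    pairs = list(zip(years, years[1:]))
    if (years[0], years[-1]) not in pairs:
        pairs.append((years[0], years[-1]))
    out = agg.copy()
    for y1, y2 in pairs:
        base = agg[y1].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            rate = np.where(base != 0.0,
                            100.0 * (agg[y2].to_numpy(dtype=float) - base) / base,
                            np.nan)
        out[f"pct_{y1}_{y2}"] = np.round(rate, decimals)
    return out
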