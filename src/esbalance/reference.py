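"""Reference tables for the equivalent-factor valuation and demand index.

Ships the published per-unit-area equivalence coefficients (11 ecosystem
services x 7 land classes), the land-use-degree parameters, and the
regional reference values for the Yellow River Basin resource-based-city
assessment (per-service supply totals and geodetector q-values), used by
the worked examples and the acceptance checks.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Canonical land-class order used throughout the package.
LAND_CLASSES = (
    "agricultural",
    "woodland",
    "grassland",
    "wetland",
    "water",
    "construction",
    "unutilized",
)

#: Canonical service order (provisioning, regulating, supporting, cultural).
SERVICES = (
    "food_production",
    "raw_materials",
    "water_supply",
    "atmospheric_regulation",
    "climate_regulation",
    "waste_treatment",
    "water_regulation",
    "soil_formation",
    "nutrient_cycling",
    "biodiversity",
    "recreation",
)

#: Regional correction factor: ratio of study-area to national grain yield
#: per unit area, applied to the national equivalent table.
REGIONAL_CORRECTION = 0.93

#: Average grain price (CNY/kg) per snapshot year in the reference region.
GRAIN_PRICE = {2000: 1.14, 2010: 1.81, 2020: 2.38}

#: Annual currency depreciation rate used to deflate prices, 2000-2020.
ANNUAL_DEPRECIATION = 0.0683


def _load(name: str) -> pd.DataFrame:
    with resources.files("esbalance.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def equivalence_coefficients() -> pd.DataFrame:
    """Equivalence coefficient table, services as rows, land classes as columns.

    The table is the regionally corrected one (the 0.93 yield correction is
    already folded in); pass it to :func:`esbalance.supply.apply_correction`
    with a factor only when re-deriving from a different base table.
    """
    df = _load("equivalence_coefficients.csv").set_index("service")
    return df.loc[list(SERVICES), list(LAND_CLASSES)]


def land_use_degree_params() -> dict[str, float]:
    """Land-use-degree weights P_i per land class (expert-scored, in [0, 1])."""
    df = _load("land_use_degree_params.csv")
    return dict(zip(df["land_class"], df["weight"]))


def reference_supply_by_service() -> pd.DataFrame:
    """Published per-service supply totals (billion CNY) for 2000/2010/2020."""
    df = _load("yrb_supply_by_service.csv").set_index("service")
    df.columns = df.columns.astype(int)
    return df.loc[list(SERVICES)]


def reference_factor_q() -> pd.DataFrame:
    """Published geodetector q-values per driver for 2000/2010/2020."""
    df = _load("yrb_factor_q.csv").set_index("factor")
    df.columns = df.columns.astype(int)
    return df
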