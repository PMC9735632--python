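import numpy as np
import pandas as pd
import pytest

from esbalance import demand as demand_mod
from esbalance import reference, supply as supply_mod, synth
from esbalance.coordination import compute_coordination


@pytest.fixture(scope="session")
def spec10():
    return synth.RegionSpec(n_rows=10, n_cols=10, seed=7)


@pytest.fixture(scope="session")
def panel10(spec10):
    return synth.generate_units(spec10)


@pytest.fixture(scope="session")
def weights10(spec10):
    return synth.generate_lattice_weights(spec10, "rook")


@pytest.fixture(scope="session")
def coordination10(panel10):
    table = reference.equivalence_coefficients()
    ea = {2000: 1000.0, 2010: 1100.0, 2020: 1200.0}
    sup = supply_mod.compute_supply(panel10, table, ea)
    dem = demand_mod.compute_demand(panel10)
    return compute_coordination(sup.unit_totals, dem)
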