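"""Standardize supply and demand, type each county by quadrant, compute
the ESDR coordination degree with its five equal-interval bands, and fit
the exponential supply-demand curve on the pooled standardized values."""

import json
import os
import sys

sys.path.insert(0, os.path.dirname(__file__))
from _common import config, outdir

from esbalance import pipeline, reference, synth
from esbalance.coordination import compute_coordination, fit_supply_demand_curve
from esbalance.demand import compute_demand
from esbalance.supply import compute_supply

cfg = config()
panel = synth.generate_units(cfg.region)
years = sorted(int(y) for y in panel["year"].unique())
sup = compute_supply(panel, reference.equivalence_coefficients(),
                     pipeline.ea_by_year(cfg, years))
dem = compute_demand(panel)
coo = compute_coordination(sup.unit_totals, dem, cfg.k_bands)

out = outdir("coordination")
coo.to_csv(os.path.join(out, "coordination.csv"), index=False)
with open(os.path.join(out, "breaks.json"), "w") as fh:
    json.dump({str(y): b for y, b in coo.attrs["breaks"].items()}, fh, indent=1)

for year, grp in coo.groupby("year"):
    counts = grp["quadrant"].value_counts().to_dict()
    deficit = int((grp["esdr"] < 0).sum())
    print(f"{year}: quadrants {counts}; {deficit} units in deficit (ESDR < 0)")

fit = fit_supply_demand_curve(coo["S"].to_numpy(), coo["D"].to_numpy())
print(f"exponential fit D = a + b*exp(c*S): a = {fit.a:.3f}, "
      f"b = {fit.b:.3f}, c = {fit.c:.3f} (converged = {fit.converged})")
with open(os.path.join(out, "curve_fit.json"), "w") as fh:
    json.dump({"a": fit.a, "b": fit.b, "c": fit.c, "rss": fit.rss,
               "converged": fit.converged}, fh, indent=1)
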