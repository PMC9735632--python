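# esbalance

County-scale assessment of the balance between ecosystem-service (ES)
supply and demand, for spatial ecologists and regional planners who need a
tested, reproducible version of the standard Chinese-literature workflow:
equivalent-factor supply valuation, a composite demand index, supply–demand
coordination (ESDR) with quadrant typing, spatial autocorrelation,
geodetector driver analysis, and geographically weighted regression (GWR).
A synthetic-region generator provides panels with the spatial structure the
workflow assumes, so the whole pipeline is testable without land-cover
rasters or statistical yearbooks.

## The model

**Supply.** Each land-use class *i* carries a dimensionless equivalence
coefficient *e<sub>ij</sub>* per service *j* (11 services × 7 classes).
One equivalent is worth

&nbsp;&nbsp;*E<sub>a</sub>* = (1/7) · Σ<sub>i</sub> *P<sub>i</sub>G<sub>i</sub>* / *A*,

one seventh of the grain-production value per unit farmland area (price
*P*, yield *G*, sown area *A*), regionally corrected by the yield ratio
(0.93 for the reference region). Monetized supply per unit is
ESV<sub>j</sub> = Σ<sub>i</sub> *E<sub>a</sub>* · *e<sub>ij</sub>* · *M<sub>i</sub>*
with *M<sub>i</sub>* the class area.

**Demand.** With development degree
*x*₁ = 100 · Σ *A<sub>i</sub>P<sub>i</sub>* / *A<sub>T</sub>*
(expert-scored class weights *P<sub>i</sub>*, 0.063–0.936), demand is
*X* = *x*₁ · lg(pop density) · lg(GDP per land); both covariates must
exceed 1 so the base-10 logs stay positive.

**Coordination.** Supply and demand are z-scored per year with the
population SD; units are typed by the signs of (S, D) into quadrants
I high/high … IV high/low, and the coordination degree

&nbsp;&nbsp;ESDR = (S − D) / ((S<sub>max</sub> + D<sub>max</sub>)/2)

is positive in surplus, negative in deficit, and banded into five
equal-width intervals per year.

**Drivers.** Global Moran's I and LISA measure spatial clustering of the
ESDR surface; the geodetector q-statistic
q = 1 − Σ<sub>h</sub> N<sub>h</sub>σ<sub>h</sub>² / (Nσ²) decomposes its
variance over stratified drivers (with pairwise interaction detection);
GWR with a fixed Gaussian kernel and AICc-optimal bandwidth maps where
each screened driver matters.

## Worked example

```python
import esbalance as eb

spec = eb.synth.RegionSpec(n_rows=20, n_cols=20, seed=20260101)
panel = eb.synth.generate_units(spec)
w = eb.synth.generate_lattice_weights(spec, "rook")

sup = eb.supply.compute_supply(
    panel, eb.reference.equivalence_coefficients(),
    {2000: 814.3, 2010: 1292.9, 2020: 1700.0})     # E_a in CNY/hm^2
dem = eb.demand.compute_demand(panel)
coo = eb.coordination.compute_coordination(sup.unit_totals, dem)
m = eb.spatial.global_moran(
    coo.loc[coo.year == 2000, "esdr"].to_numpy(), w)
print(coo.loc[coo.year == 2000, "quadrant"].value_counts().to_dict())
print(f"Moran's I = {m.I:.4f}, z = {m.z:.2f}")
```

prints

```
{'IV': 186, 'II': 165, 'III': 44, 'I': 5}
Moran's I = 0.9553, z = 26.36
```

— most units sit in quadrants II (low supply / high demand, the built-up
southeast) and IV (high supply / low demand, the ecological northwest),
and the ESDR surface is strongly positively clustered, the structure the
generator builds in.

The numbered scripts under `analysis/` run the same steps one stage at a
time (`python analysis/01_simulate.py`, … `08_full_pipeline.py`), writing
their tables under `results/`. The `esbalance` console script exposes the
same stages (`esbalance pipeline --config cfg.yaml`).

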