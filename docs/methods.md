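# Methods

## Scope and design

The package implements the county-scale ES supply–demand workflow as a
library (`src/esbalance`) with thin numbered drivers (`analysis/`) and a
CLI. All statistics are computed on plain numpy/pandas containers; spatial
weights, Moran/LISA, the geodetector q-statistic and GWR are implemented
in-package (no spatial-econometrics dependency), with statsmodels-style
conventions and closed-form or brute-force oracles in the test suite.

## Synthetic region

`synth.RegionSpec` defines a planar lattice of unit-square cells (default
cell area 100 hm², i.e. 1 km²) observed at three decade-spaced snapshots.
Unit squares stand in for county polygons because every downstream
computation needs only areas, attributes, neighbours and centroid
distances; coordinates are planar and distances Euclidean.

Two latent surfaces drive everything: a supply surface g_s that declines
from northwest to southeast and a demand surface g_d that mirrors it, each
the sum of a linear gradient (amplitude `gradient_strength`, default 1)
and Gaussian noise smoothed by mixing in the rook-neighbour average with
weight `noise_rho` (default 0.5, five passes). Land-class shares are a
softmax over class affinities — woodland/grassland/wetland/water load on
g_s, construction (plus a small per-snapshot urban drift) on g_d — so the
shares form an exact probability simplex before area scaling. Population
density and GDP per land are log-normal with location increasing in g_d
and in construction share (rank correlation with g_d ≥ 0.5 by test),
drifting upward by `demand_growth` = 0.15 per snapshot, and truncated
below at 1.01 to keep the demand index's base-10 logs positive. All
randomness derives from one seed through named, CRC-keyed child streams,
so equal specs give bit-identical panels.

What the generator does *not* emulate: irregular county geometries and
areas, terrain covariates (elevation/slope/precipitation), land-use
conversion trajectories, and administrative-boundary effects. Passing
tests therefore demonstrate correctness of the statistical machinery and
of the qualitative supply–demand geography, not calibration to any real
region.

## Supply valuation

E_a = (1/7)·Σ P_i G_i / A_total; the divisor and the division by the
summed crop area follow the standard equivalent-factor convention (the
value of an unmanaged ecosystem is 1/7 of the farmland food value per unit
area). The shipped 11×7 coefficient table is regionally corrected already
(yield-ratio factor 0.93); `apply_correction` is for re-deriving from a
different base table and defaults to 1.0. `deflate_price` is geometric:
nominal/(1+r)^years with r = 6.83 %/yr for the reference period. The
pipeline's default E_a uses nominal per-snapshot prices (1.14/1.81/2.38
CNY/kg at an assumed 5,000 kg/hm² yield): deflating all prices to the
first snapshot would make E_a — and hence aggregate supply — fall across
snapshots, the opposite of the expanding-supply setting the workflow
targets; deflation remains available via `base_year`. Change rates are
100·(V₂−V₁)/V₁ rounded only at report time (2 decimals); zero baselines
flag NaN rather than raising.

Note on the shipped reference supply table: five of its printed 2000–2020
change cells (and the 2000/2010 column totals) were evidently computed
from unrounded intermediates — recomputing them from the printed
per-service values lands one unit of the last printed digit away. The
acceptance suite asserts exact agreement wherever the printed table is
self-consistent and one-ULP agreement on those cells.

## Demand index

x₁ = 100·Σ A_i P_i / A_T with the expert-scored weights (0.063–0.936), so
x₁ ∈ [6.3, 93.6]; X = x₁·lg(pop)·lg(gdp) with lg read as log₁₀ (the only
reading on which the index is positive and monotone on the valid domain).
Covariates ≤ 1 raise an error naming the unit — clamping would silently
corrupt the quadrant analysis.

## Coordination

Z-scores use the population SD (divide by n), per the workflow's printed
formula, and are computed within each year, never pooled, so every year
independently satisfies mean 0 / SD 1. Boundary z = 0 is assigned to the
"low" side (quadrants II/III): the convention is arbitrary but must be
deterministic and documented. The ESDR denominator uses that year's maxima
of the standardized vectors. Bands are k = 5 equal-width intervals on that
year's ESDR range (per-map legend convention), half-open on the right with
the last closed; a constant vector collapses to one band. The exponential
curve y = a + b·e^{cx} is fitted by Levenberg–Marquardt from 12 starts
(sign/scale grid on c plus seeded random restarts); exponent arguments are
clipped at ±50 for overflow safety, and failure from every start is
flagged, not raised.

## Spatial statistics

Weights are symmetric contiguity (lattice rook/queen, polygon touching via
shapely, or symmetrized k-NN), row-standardized; islands get zero rows and
are flagged. Global Moran's I uses the cross-product form with E[I] =
−1/(n−1); inference defaults to the randomization-variance z (the
convention of the GIS tooling this workflow is usually run in), with
normal-approximation and full-permutation modes available. Permutation and
LISA pseudo-p values use (count + 1)/(n_perm + 1) with the smaller tail,
two-tailed by folding for the global test. Local Moran I_i = z_i·lag(z)_i
(population-SD standardization) with conditional permutation: unit i's
value is held fixed while the other n−1 values fill its neighbour slots.
Labels follow the Moran-scatterplot quadrant when pseudo-p ≤ α (default
0.05); islands are always "not significant". With row-standardized,
island-free weights the mean of local values equals global I (tested to
1e-9).

## Geodetector

q = 1 − Σ N_h σ_h²/(Nσ²) with population variances throughout, consistent
with the z-score convention. Significance uses the noncentral-F test of
the geodetector literature (reported, never used to drop factors).
Continuous drivers default to quantile discretization with k = 5;
duplicate quantile edges merge with a warning, and `equal_interval` and a
1-D k-means `natural_breaks` are provided. Interaction detection overlays
the label pairs (empty cells simply never occur as strata; realized cells
only), classifying q₁₂ against q₁, q₂ with the standard five categories;
an overlay of singletons warns that q is inflated. The independence
category uses a 1e-9 tolerance on |q₁₂ − (q₁+q₂)|.

## GWR

Fixed Gaussian kernel w = exp(−0.5(d/b)²) on Euclidean distances; local
WLS at every observation; tr(S) accumulated from the hat-row diagonals;
AICc = 2n·ln σ̂ + n·ln 2π + n(n+tr S)/(n−2−tr S). The same formula with
tr(S) = p+1 scores OLS, making the comparison direction (GWR R² ≥ OLS R²,
AICc lower under spatial coefficient variation) well defined. Bandwidth is
a golden-section search on AICc over [min positive inter-point distance,
2× domain diameter], tolerance 1e-3 of the range (5e-3 in the pipeline);
the search is deterministic, a flat profile returns the upper bound with a
warning, and a boundary minimum is honoured. The VIF screen regresses each
predictor on the others (VIF = 1/(1−R²)) and drops predictors with VIF
> 7.5 or OLS p ≥ 0.01; both joint-model and per-factor GWR modes are
supported since published comparisons appear in both layouts.

## Pipeline and problem sizes

`run_pipeline` chains all stages from one config; outputs are pure
functions of (inputs, config, seed), and the echoed config omits the
output path so identical analyses produce byte-identical reports. The
analysis scripts and the acceptance script use a 20×20 lattice (400 units,
3 snapshots) with 199–999 permutations — large enough for stable spatial
inference, small enough that the full pipeline runs in seconds; unit tests
use 2×2 to 10×10 lattices. The geodetector driver set on synthetic panels
is the available covariates (land-class shares, log population, log GDP,
axis coordinates standing in for the terrain gradient) since the generator
has no terrain fields.

## Known limitations

- Contiguity on real (non-lattice) polygons assumes valid, non-overlapping
  geometries; no CRS handling — coordinates must already be planar.
- The demand index has no per-service decomposition, and no additional
  normalization is applied before banding.
- The noncentral-F p-value for q follows the common large-sample
  approximation; it is reported for completeness, not used for selection.
- GWR is fixed-bandwidth only (no adaptive, multiscale or semiparametric
  variants), and local fits can go singular at very small bandwidths, in
  which case the fit raises rather than silently widening.
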