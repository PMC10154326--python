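# Methods

This note records the model, its assumptions, the defaults that matter and
the choices made where the design was genuinely open. Units are SI unless
stated; temperatures in °C, fluxes in W.

## Microclimate reconstruction

Monthly normals are interpolated to 24 hourly states for one mid-month model
day per month (12 model days per year).

* **Air temperature.** A piecewise sinusoid with its minimum at sunrise and
  maximum at solar noon + 2 h: a rising half-cosine from sunrise to the peak,
  and a symmetric falling branch over the remainder of the cycle, returning
  to tmin at the next sunrise. The phase lags are a declared convention — the
  reference curve of this package, not an inference of any particular
  interpolator. Values never leave `[tmin, tmax]`.
* **Humidity.** Absolute water content is constant over the day: vapor
  pressure is fixed at Tetens saturation at tmin, so
  `RH(h) = 100·e_sat(tmin)/e_sat(T(h))`, capped at 100 %.
* **Solar.** Clear-sky beam at normal incidence `S0·τ^m` with `S0 = 1361
  W/m²`, broadband transmittance `τ = 0.70` and Kasten–Young optical air
  mass; diffuse = 0.30 of the scattered flux times cos(zenith). The beam is
  projected on the slope/aspect plane; cloud multiplies the total by
  `1 − 0.75·cloud` (overcast floor 0.25). Hours are local solar time (noon at
  12); declination from Cooper's formula.
* **Long-wave.** Sky temperature from an emissivity blend
  `ε = (1−c)·(0.72 + 0.005·T_air) + c·1`, so an overcast sky radiates at air
  temperature and a clear sky colder. Ground surface temperature is air
  temperature plus `0.010 °C per W/m²` of absorbed solar (albedo 0.2),
  clamped to ≤ 0 °C when snow is present; at night it equals air
  temperature. There is no transient soil heat conduction — the ground
  temperature is a diagnostic offset model.
* **Wind.** Reference (2 m) wind × land-cover factor (forest 0.50,
  shrub/herb 0.90, urban 0.75, other 1.00), then a neutral log profile with
  roughness length 0.01 m to the animal's height. Heights default to 1.50 m
  (parrots), 1.20 m (estrildid-type finches), 0.20 m (pheasants), 0.10 m
  (starlings).
* **Activity window.** Daylight plus civil twilight (sun ≤ 6° below the
  horizon).

## Endotherm heat balance

Body parts (torso 2:1:1 ellipsoid, head sphere, neck/legs/beak cylinders)
share one core temperature; there is no part-to-part conduction. Per part,
core→surface conduction crosses, in series,

* flesh over half the part radius at conductivity `k_flesh`
  (0.41–2.80 W/m·°C, the vasomotor control variable);
* subcutaneous fat (torso, neck) of thickness `fat_fraction × radius` at
  0.20 W/m·°C;
* plumage of depth `d × ptiloerection multiplier` (multiplier 1.0–1.5 in 0.1
  steps) at an effective conductivity interpolated between still air
  (0.0255 W/m·°C) and keratin (0.20), weighted by a packing fraction
  `φ = clip(0.02 · (barb diameter / 30 µm) · length/depth, 0.002, 0.5)`.

Bare appendages (legs, beak) carry flesh only, over a path ×30 longer than
the feathered-part convention: this is the package's one-parameter stand-in
for counter-current heat exchange and regional heterothermy, calibrated so
whole-bird minimal conductance lands in the measured range for small
passerines (≈ 12–25 mW/°C at 9 g). Convection uses `Nu = 0.62·Re^0.5` with a
free-convection floor of 4 W/m²·K. Long-wave exchange is linearized through
a radiative conductance `h_r = 4εσT_film³` (ε = 0.95, film = mean of air and
core temperature), which makes each part's surface temperature closed-form
and every solution exactly energy-conserving; the radiant sink is the mean
of sky and ground temperatures (view factor ½ each). Solar interception uses
half the part area for the direct beam (dorsal reflectivity) and half for
the ground-reflected beam at albedo 0.2 (ventral reflectivity); legs and
beak reflect 0.33. Shade removes solar only.

Cutaneous evaporation is charged to the metabolic budget at the torso skin
temperature: `E = w·A_total·(0.622λ/c_p P)·h_torso·max(0, e_sat(T_skin) −
e_air)` with the wetted fraction `w` between 1 % and 5 %. Respiratory loss
is a fraction of M — 5 % at the default 2 °C exhaled-air warming, scaling
linearly with that warming. During activity a `muscle_efficiency = 0.25`
share of (post-respiratory) metabolic power is exported as mechanical work
and is unavailable for thermoregulation; this work-export reading of muscle
efficiency is a declared convention. The skin-node offset
(`core_skin_delta_c`, default 0) subtracts from the conduction driving
temperature so the core–skin differential can be varied as a trait.

**Cascade.** From the neutral state (mid-range `k_flesh`, flat plumage,
minimal skin wetness, no shade): if the required rate exceeds 1.05× the
hourly target, vasoconstrict to 0.41 W/m·°C, then ptiloerect stepwise to
1.5×; if below 0.95×, vasodilate to 2.80, wet the skin to 5 %, then seek
shade; stop at the first state inside the band, else return the extreme
state. If even the extreme hot state leaves the allowable rate below BMR the
hour is lethal (overheating); cold failure is judged by the intake ceiling
at the monthly level.

## Suitability rules

Hourly targets: BMR at rest, `2.5×BMR` during the activity window, all
multiplied by 1.5 in breeding runs (the multiplicative reading of the
breeding overhead is a convention; it is exposed as a trait). Hours whose
allowable rate is negative contribute zero to the daily mean. A month passes
survival when the daily-mean requirement ≤ `4.6×BMR` (daily energy window)
and no hour overheats (hourly window); the two aggregation windows are
deliberate defaults, exposed in the trait set. A pixel is at risk iff all
12 survival months pass and a circular run of ≥ `breeding_duration_months`
(integer, rounded up) consecutive breeding months exists; dimorphic species
AND over sexes.

The landscape engine repeats the scalar arithmetic as compiled (numba)
loops; equality with the scalar path is asserted by the test suite. With no
solar load the cold ladder is strictly monotone in insulation, so the engine
may jump to the extreme state when even that one is cold-stressed — the
returned state is identical to walking the ladder.

## Synthetic world (study conditions)

The generators emulate the statistical structure the analysis assumes, not
any particular data product. Defaults, chosen once as a plausible
Europe-like gradient and then left alone: 50×50 grid over 30–65° N, annual
mean 19 °C at the southern sea-level edge, 0.8 °C per degree latitude
cooling, 6 °C seasonal amplitude (minimum in January; grids are
northern-hemisphere by convention), 8 °C diurnal range, mean wind 3 m/s with
smoothed spatial noise (σ = 3 cells Gaussian kernel — the documented
autocorrelation scale for all noise fields), cloud 0.5, snow where monthly
tmax < 0 °C. Terrain: smoothed-noise elevation (relief 400 m), slopes from
its gradient (≤ 60°), i.i.d. land-cover mixture (forest 0.35, shrub/herb
0.45, urban 0.05, other 0.15), soils random among sand/rock/soil with urban
cells always concrete.

Archetypes: 9 g finch, 170 g parakeet, 1 kg pheasant, with `T_b ≈ 41 °C`,
allometric BMR `6.25·m^0.724` W, density 875 kg/m³, and measured-style torso
plumage depths (9, 12, 20 mm) rather than a single isometric rescaling —
small birds carry relatively deeper plumage, and the finch's analytic cold
limit then falls inside the default grid, which the oracle-based tests
require. Within the trait-variant machinery, feather depth and length do
rescale isometrically with variant mass.

**Truth map.** The analytic oracle deliberately uses the no-solar,
no-evaporation conductance form: a cell is at risk iff
`G·(T_b − tmin_coldest) ≤ 4.6·BMR`, with `G` the whole-bird conductance at
maximal cold defence, grid-mean wind, and the radiative conductance
evaluated at the grid-mean coldest tmin. It is a closed form in the
coldest-month tmin (one critical isotherm), independent of the hourly
pipeline. Under matched conditions (isothermal days, overcast sky, flat
terrain, no wind noise, work export and evaporation disabled) the full model
reproduces its cold edge exactly; tests demand agreement within one grid
cell. Occurrence samples draw cells (with replacement) uniformly from the
at-risk region, or weighted by `exp(−bias·d_urban/10 cells)` when
accessibility bias is requested, with uniform within-cell jitter.

What the synthetic world does **not** emulate: real covariance between
cloud, wind and temperature; coastlines and oceans; day-to-day weather;
dispersal limitation or biotic interactions. Passing tests therefore show
the machinery is correct and internally consistent, not that any particular
real species' risk map is right.

## Sensitivity analysis

Twelve varied traits: BMR, activity multiplier, mass, body density, fat
fraction, core temperature, core–skin differential, feather barb diameter,
feather length/depth/reflectivity (as multiplicative scales on the measured
per-part values), and exhaled-air warming. Latin Hypercube designs
(scipy's `qmc.LatinHypercube`; exactly one sample per equal-probability
stratum per axis), 1000 variants at species level, 100 for the
intraspecific ensemble over the six most influential traits. Variable
importance is permutation importance from a 500-tree random-forest
regression of TSS on the trait matrix (nonnegative, normalized to sum 1;
3 permutation repeats, seeded). Ranges of traits with > 5 % importance are
trimmed to the min–max envelope of variants with TSS > 0.3; iteration stops
when the largest relative range reduction drops below 5 % (the max-over-
parameters norm is the package's reading of "reduction in range"), when no
variant passes, or at an iteration cap. Ranges are nested by construction,
which guarantees termination.

The intraspecific rule records, per pixel, the minimum over variants of the
largest monthly daily-mean multiple of BMR ("lowest energy needed"), and
classifies the pixel at risk when any variant does — the union reading.
Whether the minimum should instead be taken in absolute watts, and whether
breeding should relax per variant, are open readings; both are options with
these defaults.

TSS during sensitivity runs is presence–background (occurrence cells vs a
seeded background cell sample), and the recovery workflow evaluates
survival-only suitability under the truth map's own regime (solar and
evaporation disabled, no work export) so that the trait signal is the one
the truth encodes. The per-iteration problem size in the acceptance test —
1000 variants × ~150 evaluation cells × 288 hours, 20 replicates — is the
package's chosen operating point for parameter recovery.

## Niche metrics

PCA on centered, unit-variance climates of the pooled backgrounds; axes
signed so the largest-magnitude loading is positive. Kernel densities
(Gaussian, Silverman plug-in bandwidth) for occurrences and availability on
an R×R grid (default 100) bounded by the background scores; occurrence
density normalized to sum 1. "Occupied" cells are the densest cells holding
95 % of occurrence mass; each range's analysed climate region is the densest
availability cells holding 75 % of availability mass, and
expansion/stability/unfilling are computed on the intersection of the two
regions, normalizing by occupied mass within it (this keeps identical grids
at expansion exactly 0). Schoener's D uses availability-corrected densities
`z/z_env`, with cells below 10⁻³ of peak availability treated as
unavailable (the correction is otherwise numerically explosive on the
fringe of climate space). Equivalency pools and re-splits occurrences;
similarity relocates one range's occurrences within its background;
`p = (1 + #extreme)/(1 + reps)` with the extreme direction ≤ for
equivalency (small p: niches differ) and ≥ for similarity (small p: more
similar than chance). The PNTI binarizes occupied (95 % mass) and available
(99 % mass) regions and reports the share of occupied-boundary cells that
lie outside, touch (4-neighbourhood), or sit on the grid edge of available
space. Expansion is a density-mass share; the share of invasive occurrence
*points* outside the native occupied region is a different readout and can
be computed from `occupied_mask` directly.

## Evaluation

Great-circle distances with Earth radius 6371.0088 km. Thinning is a greedy
pass in seeded random order (retained counts depend on the order, hence the
seed travels with the outputs); 50 km default, 10 km fallback radius.
Omission thresholds are lower-interpolation quantiles of training presence
scores. The partial ROC plots sensitivity against the proportion of the
score surface predicted present, restricted to sensitivity ≥ 1−E
(E ∈ {0.025, 0.05}); the AUC ratio divides the model's partial area by the
diagonal's over the same interval, bootstrapping half the presences with
replacement per iteration (default 1000); p is the share of iterations with
ratio ≤ 1. For binary mechanistic maps the continuous score is the negated
maximal monthly multiple (lower requirement = more suitable). MOP normalizes
variables by the calibration range, takes each projection point's mean
distance to its nearest 10 % of calibration points, and flags strict
extrapolation outside any calibration min–max.

## Monotonicity and its limits

At-risk area grows with feather depth and BMR and shrinks with core
temperature, and those directions are tested map-level. Mass alone is not
monotone in any conductance model: more mass at fixed BMR means more
surface area against the same intake ceiling. The cross-species reading —
heavier species are hardier — holds once mass carries its allometric BMR,
and that is what the tests vary.

## Numerical notes

All randomness flows through `numpy.random.default_rng` seeds; maps,
designs and samples are bit-reproducible. The linearized radiation makes
the per-part solve exact (no iteration, no convergence failures); energy
closure holds to machine precision and is asserted at 10⁻⁶ of the largest
flux. Degenerate inputs are rejected with `ValueError` (inverted ranges,
empty occupied regions, rank-deficient climate matrices, single-class
evaluations). The daily mean clips negative allowable rates at zero.
Problem sizes in the test suite (30–50 grids, 16–1000 variants, 99–1000
randomization/bootstrap iterations) are the package's chosen operating
points for its own verification.

## Known limitations

Steady-state hours (flesh heat capacity is carried as a constant but no
transient storage is modelled); no torpor, no nest microclimate or juvenile
development, no water budget, no rain-wetted plumage, no snow depth, no
horizon shading, no part-to-part conduction; shade removes solar only. The
appendage path factor is a calibrated stand-in, not a vessel-level
counter-current model.
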