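# Methods

`rxsmoke` quantifies the air-quality trade-off between a wildfire and a
counterfactual program of prescribed burns on the same landscape, under
three cases:

* **WF** — the factual wildfire on the untreated fuel bed;
* **Rx** — prescribed burns treating the (future) wildfire footprint,
  one unit per eligible day, before the wildfire date;
* **post-Rx WF** — a wildfire on the same footprint and dates as WF but
  burning the residual fuels left by the treatment.

Smoke impacts are scenario-minus-baseline concentration fields; the
baseline has zero fire emissions, so for the linear transport model used
here the subtraction is exact bookkeeping. The trade-off statistic is
the person-days benefit `PD_Rx_benefit = PD_WF − PD_Rx − PD_postRxWF`.

## Burn-day screening

A day is eligible when 24-h rain < 6.35 mm, RH > 30 %, temperature
< 29.4 °C, PBL height ∈ [503, 1981] m, wind speed ∈ [3.6, 6.3] m/s and
transport wind ∈ [4.0, 8.9] m/s. The three threshold criteria are
strict inequalities and the three "between" criteria closed intervals,
following the operators in the guideline wording; both conventions are
boundary-tested. Days are taken earliest-first until the required count
is reached — the policy maximizes the regrowth-free interval before the
wildfire and is deterministic. No spacing constraint between eligible
days is imposed.

## Unit delineation

Firebreak cells are land-cover classes {open water, developed, barren}.
The mask is dilated with a 3×3 square element (radius 1 by default) to
simplify ragged boundaries; burnable cells are the complement, and
candidate units are their 8-connected components. Components above the
1000-acre/day guideline are split recursively:

1. endpoints are the two perimeter cells farthest apart along the
   component's principal axis (PCA of cell coordinates), snapped to the
   nearest gentle-slope (< 20°) perimeter cells when any exist;
2. a uniform-cost search routes a boundary between them. Step cost is
   1 onto a gentle-slope cell and `1 + off_target_penalty` (default
   1000) onto a steep cell, diagonals scaled by √2; ties expand in
   lexicographic (row, col) order, so paths are bit-reproducible;
3. the path is thickened to a 4-connected chain (an 8-connected chain
   does not block 8-connected passage across its diagonal steps) and
   carved out as internal, non-burning firebreak;
4. recursion is depth-limited (10). Components that cannot be split —
   no gentle corridor under an infinite penalty, a path that fails to
   disconnect, or the depth limit — are returned whole with
   `oversize_flag`, mirroring real plans where the occasional unit
   exceeds the guideline.

A related, provable form of path-adherence monotonicity holds and is
property-tested: raising the off-target penalty never increases the
penalty-weighted off-target step cost of the returned path. The
count-of-target-cells version of this statement is not guaranteed under
the √2-weighted cost model.

Scheduling is a serpentine ("zigzag") traversal of centroid row-bands
(⌈√n⌉ bands; odd bands right-to-left), which keeps consecutive burns
close. If the caller's input order is already strictly shorter in total
consecutive-centroid distance, it is kept, so the scheduled order is
never worse than the input.

## Fuels, consumption, emissions

Fuel is tracked in six categories (canopy, ground fuel, litter-lichen-
moss, nonwoody, shrub, woody). Consumption is `fraction × load` per
category, with fractions per fire type supplied as configuration rather
than re-derived combustion physics. The shipped defaults are back-solved
from the published CONSUME accounting for the 2016 Gatlinburg wildfire
region — WF and Rx fractions against the full load, post-Rx WF fractions
against the residual bed after treatment — so the package reproduces the
regional totals (794,638.1 t load; 356,483.3 t WF; 179,779.2 t Rx;
147,476.2 t post-Rx WF; a 58.6 % reduction) by summation. Prescribed
fire has a structurally zero canopy fraction (understory burns only).
No regrowth is assumed between treatment and the later wildfire;
negative residuals from user-supplied tables are clamped to zero and
logged.

Emission factors (kg per ton consumed) are a surrogate table in the
magnitude range of published wildland-fire factors (PM2.5 16/13,
NOx 2.5/2.0, VOC 18/15 for wildfire/prescribed modes); every downstream
statistic is linear in them and they are fully replaceable.

Hourly allocation: prescribed burns emit on one date between ignition at
10:00 and completion before 17:00; wildfires split the total equally
across their contiguous day range, each day shaped by a symmetric
mid-afternoon-peaked 24-h profile with a nonzero nighttime floor
(wildfires burn through the night). Hourly sums reproduce totals to
float precision.

Plume extent uses a Briggs-form buoyant rise: `top = C · F^(1/3) / u`
with buoyancy flux `F = 8.8 × heat (MW)` and `bottom = 0.5 × top`.
Heat release is hourly fuel consumption × 18.6 GJ/t (a typical wildland
higher heating value). `C = 140` is chosen so synthetic plume tops are
O(1–3 km); pushing `C` high enough to reproduce multi-km published
maxima would put every plume bottom permanently above the synthetic
boundary layer and starve the single-layer surrogate of ground impact,
so plume heights here are indicative, not calibrated.

## Dispersion surrogate

Each emitted hour becomes a puff advected by the hourly wind, with
horizontal spread σ(age) = (0.5 + 0.3·age) cells and uniform mixing from
the ground to max(PBL, plume top). Horizontal weights are exact cell
integrals of the Gaussian (differences of error functions per axis), so
the discrete field conserves mass on an unbounded grid; conservation to
1e-6 relative is asserted for in-domain, no-decay puffs. Entrainment is
binary by default — a puff whose plume bottom rides above the PBL
contributes nothing at ground level until the PBL first overtakes it,
and then stays mixed (sticky) — with a proportional mode that instead
grounds, each hour, the slab fraction below the PBL. Puffs are dropped
after 48 h; an optional first-order decay is off by default. MDA8 uses
the 17 complete 8-h windows within a calendar day (no cross-midnight
windows); days shorter than 8 hours fall back to the plain mean.

The model is a **linear tracer**: it has no chemistry, so the "O3" and
"NO2" outputs are transported proxies (VOC and NOx tracers aggregated
with MDA8 and 1-h max operators), not photochemical predictions.
Secondary ozone enhancement in NOx-rich downwind air, aerosol aging,
deposition, and terrain effects are out of scope.

## Exposure statistics

Population is regridded fine→coarse by nearest cell center, assigning
each fine cell wholly to one coarse cell: totals are conserved exactly,
which sampling would not do and which person-day counts require. The
population-weighted concentration is the standard weighted mean over a
region (numerator and denominator over the same mask); zero regional
population raises rather than returning a silent zero. Person-days use
a strict exceedance (`c > threshold`, H(0)=0), with an inclusive flag
since step-function conventions differ. Thresholds in the person-days
curve are cumulative; exclusive bins follow by differencing. Analysis
windows are each burn date plus 2 lag days (regional smoke transport
rarely persists longer): 5 consecutive wildfire days give a 7-day
window, and a 19-burn schedule can merge to 45 days.

## Synthetic study conditions

The generators are seeded (one global seed fans out through a fixed
stream-index table, so adding a generator never perturbs the others) and
emulate: a land-cover raster with two forest classes (smoothed-noise
mosaic) cut by connected random-walk corridors of water, developed and
barren land; slope as the gradient of a smoothed elevation surface
(degrees in [0, 60], with both gentle and steep terrain); a daily met
series in which days are eligible with a target probability (eligible
days drawn inside every criterion window, others with a forced RH
violation); a clustered population (1e6 people; one town pinned beside
the fire, the other centers random) over a thin rural floor; AR(1)
transport winds with a diurnal PBL cycle (~250 m nights, ~1600 m
afternoons).

The end-to-end default conditions: burn units designed on a 64×64 grid
at 150 m (~23,000-acre fire area) embedded at the center of a 60×60
concentration domain at 8 km; a 210-day met series (June–December) with
a 0.2 eligible-day target; fuel densities equal to the case-study
regional loads spread over 10,000 acres; a 5-day wildfire window with a
4× transport-wind storm factor (the factual fire was wind-driven); PD
thresholds 1–15 µg/m³. Problem sizes were chosen so a full comparison
runs in seconds on one core.

What the synthetic tests do **not** show: the generators have no fuel
moisture physics, vegetation succession, or weather dynamics, and the
tracer model has no chemistry — so passing tests demonstrate the
correctness of the design/accounting/exposure machinery, not predictive
skill on real smoke episodes. In particular, under these conditions the
benefit line is negative at low thresholds and positive at high ones:
the many one-day prescribed burns beside the synthetic town dominate
low-threshold person-days, whereas full chemistry-transport studies of
the factual case put wildfire far-field exposure on top at 1 µg/m³.
The crossover structure — the sign of the benefit depending on the
threshold — is reproduced; its orientation is condition- and
model-dependent.

## Numerical choices

* Area: 1 acre = 4046.8564224 m² exactly; unit area = cell count × cell
  area.
* Raster convention: 0-based (row, col), row 0 at the north edge, cell
  centers at half offsets; ESRI ASCII grids for raster I/O, GeoJSON for
  unit polygons, NetCDF3 for gridded impacts.
* Uniform-cost search ties break lexicographically; zigzag band count is
  ⌈√n⌉; polygon outlines are simplified with zero tolerance (removes
  collinear vertices only).
* PWC undefined (error) on zero population; NMB/NME undefined on zero
  observation sum; Pearson R undefined on zero variance; regression CIs
  flagged undefined at n = 2.
* Degenerate inputs: `treatment_fraction = 0` reproduces the wildfire
  case bit-for-bit; zero-heat hours give zero-extent plumes; empty
  burnable landscapes return an empty unit list with a warning.
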