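# Methods

`tundraline` simulates the migration of the Siberian larch treeline into
tundra under warming scenarios, at desk scale. It has four scientific
layers: construction of millennium-scale climate forcing on latitudinal
transects, an individual-based larch life-cycle simulator, extraction of
treeline positions and their comparison against a climate-analogue
(isotherm-tracking) baseline, and conversion of treeline advances into
tundra-area change along a treeline polyline.

## Climate forcing

A transect is a line of climate nodes spaced exactly 10 km apart, node 0
at the modern treeline and positions increasing poleward. The forcing for
501–3000 CE is assembled from six steps:

1. An instrumental-era monthly series per node (1901–2005). The synthetic
   stand-in combines a Siberian-treeline seasonal climatology (July ≈
   +12 °C, January ≈ −33 °C, ~220 mm yr⁻¹), a linear poleward July
   gradient, an AR(1) annual anomaly (φ = 0.6, innovation SD 0.6 °C) and
   monthly weather noise (SD 1.2 °C) that is *shared* across nodes with a
   small node-local residual (SD 0.2 °C). Sharing the synoptic noise keeps
   node-to-node temperature profiles monotone, as real 10–100-km transect
   extractions are; fully independent node noise would make isotherm
   positions ill-defined.
2. An annual ice-core-like proxy (value + layer thickness) is extended
   back to 501 CE by resampling 25-year blocks of its pre-industrial
   (< 1800 CE) portion, uniformly with replacement, stitched without join
   smoothing.
3. Per-node ordinary least squares of annual mean temperature and annual
   precipitation on proxy value over the 1901–1998 overlap; the fits
   applied to the extended proxy give per-node annual means for 501–1900.
   A zero-variance proxy is refused rather than silently fitted.
4. Monthly structure for 501–1900 comes from 15-year blocks resampled
   from the instrumental series; each year's months are shifted so the
   annual mean matches the reconstruction — additively for temperature,
   multiplicatively for precipitation (the proportional choice keeps
   monthly precipitation non-negative and preserves its seasonal shape).
5. 2006–2300 lays a scenario July-anomaly curve over modern years
   resampled from the last 30 instrumental years. The synthetic curves
   are logistic ramps in time (midpoint 2060, scale 18 yr) normalised to
   the scenario's median July warming at 2100 — +1.8 °C (RCP 2.6),
   +2.1 °C (RCP 4.5), +5 °C (RCP 8.5) — then linear to the 2300 levels
   (+0.5, +3.1, +14.4 °C). RCP 2.6* is defined as *half the RCP 2.6
   anomaly* at every year; note this construction (0.9 °C at 2100) takes
   precedence over the nominal +1.2 °C median sometimes quoted for the
   half-rate scenario — the two are mutually inconsistent and the
   half-rate definition is the one we keep exact. Precipitation scales
   with the anomaly at the Clausius–Clapeyron rate of 7 %/°C — with a
   drier coupling the strongly extrapolated RCP 8.5 climate turns into a
   chronic-drought desert in which no forest survives, which is an
   artifact of the extrapolation rather than a treeline response. Real
   ESM output can replace the synthetic curve via the same
   `{year, anomaly}` interface.
6. 2301–2500 continues the per-(node, month) linear trend fitted to
   2100–2300, recycling detrended residual years. 2501–3000 either loops
   the 1901–1978 data ("20th-century cooling") or copies the 2300–2500
   block ("continued"). Because 78 does not divide 500, raw tiling would
   bias the post-peak mean state by the partial final cycle (~0.1–0.2 °C
   given realistic interannual variability); we therefore apply a uniform
   per-(node, month) correction — additive for temperature,
   multiplicative for precipitation — so that the 2501–3000 mean state
   equals the 1901–1978 mean state exactly. The cooling climate is thus
   the 20th-century climate by construction, not approximately.

Regional lapse-rate offsets shift January and July temperatures by the
tuned per-region amounts, other months by cosine interpolation over the
annual cycle, and rescale annual precipitation multiplicatively; targets
below zero clamp to zero with a warning.

Annual auxiliaries are derived from monthly values by linear interpolation
between mid-month anchors (periodic across the year boundary) to 365 daily
values: NDD0 = Σ max(T_day, 0), AAT10 = Σ T_day·1[T_day > 10], plus
coldest/warmest month, annual precipitation, and a drought index defined
as annual precipitation over growing-season degree days (the ratio is a
stand-in; only its low tail enters mortality).

Wind is a 6-hourly-like sample set: Weibull speeds (scale 5 m s⁻¹, shape
2) and von Mises transport bearings around a prevailing direction (45°,
concentration 0.8) — a broad, slightly poleward-of-east transport typical
of summer synoptics at the Siberian treeline.

## Life-cycle simulator

The transect strip is `length × 20 m`; x wraps at the east–west margins
(a slice of a continuous treeline), y never wraps. Each year runs, in
order: environment update, growth, seed dispersal, seed production,
establishment, mortality, ageing. All functional forms are explicit
parameterisations with every constant in `LifeCycleParams` (YAML-loadable);
they were calibrated once, as a package design task, to reproduce the
qualitative treeline behaviours — a viability edge near the 10 °C July
isotherm, decades from germination to the 1.3-m stem threshold, long
adult persistence through cold spells, and competition-limited stand
densities of order 10²–10³ stems ha⁻¹ — not to be bit-compatible with any
prior model implementation.

* **Environment.** Every tree deposits a triangular kernel of peak equal
  to its basal diameter (cm) and radius 0.6 m + 0.25·height, capped at
  3 m, onto a 0.5-m gridded density field; a tree's density index is the
  field at its cell minus its own central deposit. Active-layer depth per
  node is a Stefan-type `edaphic_factor·√NDD0` (cm); establishment
  requires at least 10 cm of thaw.
* **Growth.** Potential basal-diameter increment (max 0.2 cm yr⁻¹) is a
  product of logistic responses to 10-year-mean July temperature
  (midpoint 10.5 °C, scale 0.7 °C, hard zero below 9 °C) and NDD0
  (midpoint 400, scale 120 °C·day), divided by (1 + 0.3·density index).
  Height follows h = 15·(1 − e^(−0.0302·d)) m, so the 1.3-m stem
  threshold is crossed near d ≈ 3 cm; breast-height diameter is the
  linear-taper value d·(1 − 1.3/h), positive only above 1.3 m.
* **Dispersal.** Seeds produced in year t wait in cones and fly in year
  t+1: per seed a wind sample is drawn and the flight distance is
  `release_height · speed / fall_velocity` (fall velocity 0.8 m s⁻¹), the
  ballistic model whose distance tail inherits the wind-speed tail.
* **Production.** Trees seed only above an individual maturation height
  (normal, mean 2.5 m, SD 0.6 m, floor 1.3 m); expected counts (≤ 8 yr⁻¹)
  rise with diameter, fall with competition, and scale with the current
  July weather factor; realised counts are Poisson.
* **Establishment.** Ground seeds germinate with probability
  0.03·logistic((T_Jul − 10)/0.4)·e^(−1.2·density index), gated by thaw
  depth; germinants enter as 0.05-cm seedlings.
* **Mortality.** Tree death probability is 1 − exp(−Σ hazards), floored
  at a 0.002 background: cold July deficit below 10 °C fading with size
  (established trees endure unfavourable spells — the mechanism behind
  overshoot persistence), drought-index shortfall, density-driven shading
  (strongest for small trees), an age-senescence hazard (scale 500 yr),
  and a juvenile size hazard. Seeds die at a constant 0.45 yr⁻¹ whether
  on trees or the ground, and ground seeds are removed after 3 years.
* **Boundary input.** During the first 50 stabilization years, 100,000
  seeds yr⁻¹ (desk: 1,000) enter from the southern boundary with
  exponentially decaying distance (mean 1 km); every year 1000 seeds per
  200 km of transect fall uniformly (extinction insurance); and the first
  500 m receive a climate-scaled hinterland seed rain whose release
  height is tied to the climate-predicted tree height at the boundary.

Runs start with a 200-year stabilization under the first 30 forcing years
looped, then step through the forcing. Stems (trees > 1.3 m) are
snapshotted every 10 years; a structured log records yearly population
sizes and the northernmost stem. All stochastic processes draw from named
RNG streams derived from (master seed, repeat, fixed label), so a master
seed fully determines a run and process reordering cannot silently change
results.

## Metrics

Stand density uses 1-km bins (between the 10-km node spacing and the
individual scale; a bin-refinement test documents sensitivity). Positions
are the northern edge of half-open, south-inclusive bins: single-tree
stand = northernmost bin ≥ 1 stem ha⁻¹ anywhere; treeline stand =
northern edge of the contiguous ≥ 1 stem ha⁻¹ run connected to the
southern boundary (gaps of ≥ 1 bin break the run); forestline stand =
northernmost bin > 100 stems ha⁻¹. With no qualifying bin the positions
are explicitly absent, not zero.

The climate analogue tracks the position whose trailing-10-year-mean July
temperature equals the baseline treeline's value, by linear interpolation
between nodes and clamped to [0, shoreline]; smoothing suppresses
interannual jitter that the instantaneous definition would inject.
Migration rates are decadal first differences from the year-2000 baseline.
The lag/overshoot trajectory rescales simulated and analogue positions to
fractions of the baseline-to-shoreline corridor and averages them in
25-year segments; below the diagonal is lag, above is overshoot, and the
equilibrium-crossing year is the first segment at which the simulated
fraction reaches the analogue fraction.

## Area accounting

Per-region advances are interpolated at 10-km arc stations along the
treeline polyline (linear between the two flanking anchors, end stations
clamped to the nearest anchor), then extruded poleward along local
normals into quadrilaterals whose union, clipped to the tundra side of
the land polygon, is the forested extent. The extent is recomputed from
the current advances each output step — no running union — so tundra can
partly recover when advances shrink under cooling. On the synthetic
rectangular corridor the construction is exact (uniform advance a gives
area W·a), enabling closed-form tests. Computations assume an equal-area
planar projection applied upstream; the module never reprojects. Regions
are arc-length intervals split at midpoints between anchors, with end
regions running to the polyline ends.

## The desk-scale experiment

The default experiment compresses the study layout onto one synthetic
region: a 50-km transect with 5 climate nodes, 600 simulated years
(1901–2500 CE, baseline 2000), 3 repeats. Distance compression preserves
the corridor's temperature span: the ~1 °C/100 km July gradient over a
~600-km corridor becomes 6 °C/100 km over 50 km. Initial-pulse and
hinterland seed counts are divided by 100; the permanent background rain
stays at 1000 seeds per 200 km since it already scales with length. The
problem sizes (600 years, 21 simulation runs, ~10⁴–10⁵ agents) were
chosen so the full experiment completes in minutes on a single core.

Alongside the four RCP scenarios (continued mode), three diagnostic
forcings are run: a constant-climate control; a +2.5 °C step warming at
2001; and the same step cooled back at 2201. The step size is chosen
large against the ~0.5 °C decadal noise of 10-year means on the
compressed gradient, so the analogue's jump is unambiguous, while staying
inside the scenario range. These exhibit the simulator's headline
phenomena: a stationary treeline under constant climate; a multi-decadal
migration lag behind the analogue after the step (stems must establish
from sparse seed rain and grow past 1.3 m before any bin registers);
eventual analogue overtake under sustained warming once infilling
saturates the corridor; and overshoot persistence after cooling, carried
by established adults whose cold mortality fades with size.

The full-scale plan (four regions — Taimyr 573 km, Buor Khaya 137 km,
Kolyma 146 km, Chukotka 626 km — on 800-km/300-km transects, eight
scenario variants, 501–3000 CE) ships as configuration; executing it
requires real forcing inputs supplied through the same tabular
interfaces and is not part of the test suite.

## What the synthetic generators do and do not emulate

The generators reproduce the statistical shape of the real inputs —
seasonal cycle, poleward gradient, AR(1) interannual variability,
proxy–instrumental coupling, Weibull/von Mises winds, rectangular
corridor geometry with known area — but not their particulars: no
topography (the mountainous Chukotka case is absorbed by regional
offsets), no spatially varying precipitation, no ENSO-like decadal
structure, no coastline complexity. Passing tests therefore demonstrate
that the pipeline's mechanics and the simulator's dynamical repertoire
are correct under controlled conditions; they do not validate the
quantitative migration rates or area losses for real Siberian transects,
which depend on the real forcing and geometry.

## Numerical choices and degenerate inputs

Daily interpolation uses a fixed 365-day year (no leap days). Positions
outside the climate-node span clamp to the nearest node. A dry source
year in the precipitation rescaling distributes the target total evenly
over months. Polygon unions are repaired by zero-buffer cleanup when
invalid. Ties in the crossing-year scan resolve to the earlier segment.
Snapshots store float32 arrays to bound memory. The density field
re-uses one buffer across years; its 0.5-m cell balances kernel
resolution (minimum influence radius 0.6 m) against rebuild cost.

## Known limitations

Fire, permafrost-thaw feedbacks, mycorrhiza, herbivory, interspecific
shrub competition and albedo feedback are not represented. A single
larch-like species is simulated. The life-cycle constants are a
qualitative calibration, not a fit to stand inventories; absolute rates
at desk scale should be read as scaled-down analogues, not predictions.
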