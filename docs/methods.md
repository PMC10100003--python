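# Methods

This note documents the models implemented in `amazonagc`, the defaults and
why they were chosen, what the synthetic scenes do and do not emulate, and
the numerical conventions a user should know before trusting or extending
the results.

## The accounting problem

Coarse (~0.25°) L-VOD retrievals give a top-down estimate of total
above-ground carbon (AGC) per grid cell; 30 m-class annual land-cover and
disturbance maps give the *where and why* but not the carbon dynamics of
standing forest. The package books bottom-up fluxes for four processes —
deforestation, forest-edge degradation, non-edge (mapped-event) degradation
and secondary-forest growth — and attributes the remainder of the top-down
change to old-growth forest by residual. The result is a per-cell,
per-year, per-process stock-change table (Mg C) with 1-σ uncertainties.

## Top-down chain

**Filters**, in fixed order, with every threshold a strict inequality:

1. quality flags (water/urban/terrain bitmask ≠ 0 dropped) and cells more
   than 25 % inundated dropped entirely;
2. TB-RMSE > 8 K dropped (RFI contamination);
3. orbit reconciliation per cell-trimester (calendar quarters): if
   |mean(ASC) − mean(DESC)| > 0.05, observations with TB-RMSE > 5 K are
   dropped — from both orbits by default; an alternative mode drops only the
   orbit farther from the pooled mean. Same-day ASC/DESC duplicates keep
   the lower TB-RMSE record;
4. observations beyond 2 standard deviations of their cell-trimester mean
   dropped. The moments are computed **once** on the incoming set, never
   re-estimated: the filter is deliberately single-pass, so re-applying it
   can remove further points (a trimmed set has new moments). A series that
   is constant to rounding precision (SD ≤ 10⁻¹² of its mean) is left
   untouched.

**Decomposition.** Per cell, VOD(t) is fitted by least squares with a
quadratic polynomial plus two annual harmonics; the residuals are linearly
interpolated to a daily grid and low-pass filtered (smooth quartic roll-off
in frequency space, half-power at the cutoff). The *smoothed* series is the
full fit plus the 80-day-cutoff residual; the *trend* series is the
polynomial plus the 667-day-cutoff residual, i.e. seasonality removed. The
cutoffs and polynomial/harmonic orders follow the classic flask-record
curve-fitting lineage and are exposed in `FitConfig`. The long cutoff
suppresses the annual harmonic in the trend to < 0.1 % of its amplitude in
the smoothed series.

**Annual indices.** Over the closed January 1 – April 30 window (wet season;
maximal soil moisture, before the mid-year deforestation/fire peak): the
maximum and the mean of the smoothed curve, and the mean of the trend curve.
A cell-year needs ≥ 20 retained observations in the window, otherwise it is
missing (never zero).

**Calibration.** Each index is calibrated *separately* against the
reference-year biomass map (aggregated to the coarse grid by area-weighted
mean) with the four-parameter logistic, fitted by nonlinear least squares
from 8 deterministic starts spanning the data range; non-finite curve
evaluations become the 10¹⁰ sentinel; standard errors come from the fit
covariance. Fitting per method matters: the smoothed-curve indices include
a constant seasonal uplift, and a per-method fit absorbs it into the curve —
re-using a single curve across methods attenuates year-over-year changes by
the ratio of curve slopes (~15 % under the default seasonal amplitude).
The per-cell AGC is the mean of the three per-method estimates, their
standard deviation enters the uncertainty, and any cell with a
year-over-year increase > 20 Mg C ha⁻¹ (far above the ~6 Mg C ha⁻¹ yr⁻¹
plausible accumulation bound) is masked for all years.

## Land-cover engine

Annual class rasters (forest kinds, pasture, agriculture, bare; remappable
vocabulary) and disturbance-event rasters are processed at native fine
resolution, in this within-year order:

1. **deforestation**: forest in year t−1 → pasture/agriculture/bare in
   year t. Clearing resets the pixel's forest history; all changes are
   booked to the detection year.
2. **secondary forest**: a pixel non-forest in some observed year and forest
   continuously since; age 1 in the first forest year. Regrowth predating
   the record is unidentifiable, so pixels forested throughout are treated
   as old-growth candidates.
3. **edge zones**: forest pixels whose center lies within 120 m (inclusive,
   Euclidean, 4 pixels at the 30 m default) of currently-cleared,
   previously-forest land. Edge membership is a ratchet; edge age
   increments only while the pixel remains inside the active zone and
   freezes if the adjacent clearing regrows (the biomass loss already
   incurred is not erased).
4. **degradation events**: events on forest outside edge zones and not on
   secondary or already-degraded pixels join the sticky degraded set;
   events on edge pixels are excluded from the degradation record; repeat
   events are not double-counted by default
   (`recurrent_degradation_losses` books them again).
5. **old-growth**: everything else that is forest.

**Precedence.** Degraded and secondary status shield a pixel from the edge
class (effective precedence: non-forest > secondary/degraded > edge >
old-growth). The alternative — letting the edge class capture secondary or
degraded pixels — would debit an old-growth-referenced edge loss from a
pixel whose carbon is far below the old-growth reference, breaking
per-pixel conservation and allowing negative densities. The event-exclusion
side (edge areas never generate non-edge degradation losses) is kept
as stated.

Fractional covers per coarse cell are exact pixel counts (the synthetic
grids nest perfectly); the secondary fraction carries an age histogram.

## Bookkeeping

Reference densities: the old-growth reference per cell is the 1°-radius
circular median of the biomass map over > 90 %-old-growth cells (window
widened once to 2°, then flagged); the degraded reference is
(1 − loss factor) × old-growth reference. The non-edge loss factor default
is 0.353, the value implied by reference medians of 126.4 (old-growth) and
81.78 (degraded) Mg C ha⁻¹.

Per year and cell (losses negative, area = pixel count × pixel area):

* deforestation: −area × density of the pixel's prior state — old-growth
  reference, degraded reference, ref × (1 − edge_loss(age)), or
  growth(age) for secondary;
* edge degradation: −ref × [loss(age) − loss(age−1)] per pixel whose edge
  age advanced; increments telescope to −ref × loss(A);
* non-edge degradation: −ref × loss_factor per accepted event pixel;
* secondary growth: +[growth(age) − growth(age−1)] per ageing pixel
  (growth(0) = 0 covers new regrowth); clearing losses of secondary forest
  are booked under deforestation;
* old-growth: residual density × old-growth area. In > 90 %-old-growth
  cells the cell's **own** residual ΔAGC_LVOD − (Δdef + Δdeg + ΔSF) is
  used — this is what makes the modeled total equal the top-down change
  exactly there; other cells take the circular median of reference-cell
  residual densities at 2.5°, then 5°, then are flagged and excluded.

Curve families: Chapman–Richards growth
AGC(t) = A(1 − e^(−kt))^θ with defaults A = 90 Mg C ha⁻¹, k = 0.06 yr⁻¹,
θ = 1.5 (≈ 52 Mg C ha⁻¹ at age 20, a mid-range Amazon regrowth trajectory);
edge loss loss(a) = L∞(1 − e^(−ra)) with L∞ = 0.4, r = 0.8 yr⁻¹ (rapid
loss in the first years after edge creation, saturating well below total
loss). Both are pluggable.

Uncertainties (1 σ): loss terms scale the affected area by the biomass-map
SD (default 27.3 Mg C ha⁻¹, times the loss factor or first-year edge loss
where appropriate); growth increments carry a 20 % relative SD; the
old-growth term propagates the three-index spread of the two years in
quadrature. Totals combine by root sum of squares (plain summation
available as the conservative alternative).

## Statistics

Theil–Sen slope (median of all pairwise slopes, via `scipy.stats.
theilslopes`) with two-sided Mann–Kendall significance at 95 %
(tie-corrected variance, continuity correction; cross-checked in tests
against the exact Kendall distribution). Model-vs-observation comparison
over cells with < 90 % old-growth cover in the final year: Pearson r, r²,
mean absolute deviation, and strict-sign agreement (zero agrees only with
zero), computable on trend slopes or on total-period changes. Regional
totals use per-cell membership weights in [0, 1] summing to ≤ 1, with gross
loss and the degradation share derived per region.

## Synthetic scenes

The generator simulates, on the fine grid: clustered clearing patches whose
location is steered by a static large-scale "pressure" field (an
arc-of-deforestation analogue — without it, scattered clearing puts a 120 m
edge zone over everything and no > 90 % old-growth reference cells survive,
which would make residual attribution inapplicable, unlike the real basin);
clustered disturbance events and regrowth; and per-pixel carbon carried
forward with exactly the bookkeeping parameterisation above, so per-process
truth is closed-form. The daily L-VOD stream inverts the calibration curve
on the piecewise-linear interpolation of annual cell densities (anchored at
the middle of the Jan–Apr window), then adds a sinusoidal seasonal cycle
(amplitude 0.05 VOD, peaking near day 90), Gaussian noise (SD 0.02 VOD),
a constant ±offset/2 split between orbits (0.01), RFI spikes with TB-RMSE
drawn in [8, 20] K on 5 % of observations, and 2 % flagged records; each
orbit samples every 2 days (ASC even days, DESC odd). Densities outside
the curve's invertible range are clamped with a 3 % margin — the
observation operator saturates, as a real retrieval does. Default rates
(1.5 % yr⁻¹ of forest cleared, 1 % disturbed, 3 % of cleared land
regrowing) are frontier-like conditions that exercise every process.

Default base biomass is uniform at 126.4 Mg C ha⁻¹. This makes the
regional reference medians equal the pixel densities, so a bookkeeping run
with matched parameters recovers every per-process total *exactly* — the
closed-loop tests rely on this. A smooth spatial gradient option exists
for non-exact realism checks. Old-growth drift defaults to zero for the
same reason; the residual-attribution recovery test sets a 1.0 Mg C ha⁻¹
yr⁻¹ drift (the order of the basin-wide 2011 wet-year anomaly) in a
no-clearing scene, where the scene-averaged recovery is accurate to a few
percent — per-cell-year, the drift signal is below the retrieval noise.

What the generator does **not** emulate: radiative-transfer physics of the
retrieval (VOD is an exact curve inverse plus additive terms), sub-canopy
flooding (inundation enters only as a static mask), plant-water-content
interannual variability, spatially varying seasonal phase, classification
error in the land-cover maps, and real geographic projections (the lattice
is abstract; rasters carry an affine transform so georeferenced data can
substitute). Passing tests therefore demonstrate structure-preserving
recovery — filters behave as specified, the bookkeeping conserves carbon,
attribution closes, trends match oracles — not that the error magnitudes
match what real SMOS/Mapbiomas/TMF/CCI inputs would produce. Headline
observational magnitudes (biome-scale Pg C declines, country shares,
observed r² against real maps) are only obtainable with those datasets,
which this package deliberately does not ship.

## Numerical conventions and edge cases

* Annual truth densities are anchored mid-window (day 59); the retrieval
  measures window statistics, so annual changes carry a small deterministic
  window bias (second differences of the flux trajectory × ~0.04) that is
  part of the observation operator, not a bug.
* Missing data propagate as missing (NaN/flagged), never as zero: sparse
  index windows, cells without all three index methods, masked anomaly
  cells, and cells without a residual reference within 5° are all excluded
  and logged.
* `sigma` columns are 1 SD, always non-negative; stock/density conversions
  use exact cell areas (sum of fine-pixel areas).
* The overflow sentinel for non-finite curve evaluations is 10¹⁰; negative
  AGC conversions clip to zero with a warning.
* Closure in reference cells holds to floating precision (~10⁻¹³ Mg on
  10⁵ Mg fluxes); tests assert 10⁻⁹ relative.
* Problem sizes in the tests and acceptance script (8×8×64 for closure,
  16×16×32 for the noisy closed loop, 500-pair calibration fits with 100
  replicates) were chosen so that noise-limited checks have comfortable
  statistical margins at the default conditions.

## Known limitations

* The residual attribution inherits any common-mode L-VOD bias: a
  systematic error shared by all reference cells transfers one-for-one
  into the old-growth flux. On real data this is the dominant caveat
  (water-content fluctuations); in the synthetic loop it appears as the
  window bias above.
* The bookkeeping books all transition carbon in the detection year — no
  committed/delayed emissions, decay pools, soil carbon or belowground
  biomass.
* Degraded pixels never recover carbon (no post-disturbance regrowth of
  standing degraded forest), and repeat disturbances add no further loss
  by default.
* Country/region weights are exogenous inputs; no real boundary data are
  included.
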