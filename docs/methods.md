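# Methods

`agriwx` estimates the probability and severity of adverse weather conditions
for winter wheat at a site under a baseline climate and under perturbed
(climate-change) scenarios. This note documents the models, the parameters
that matter, the synthetic study conditions, and the numerical and design
choices, in the order the pipeline applies them.

## Stochastic weather generation (`wxgen`)

A Richardson-type parametric generator is fitted per calendar month from a
daily record of tmax, tmin, precipitation and sunshine hours (or radiation):

* **Occurrence.** Wet/dry days follow a first-order two-state Markov chain
  with monthly wet-after-wet and wet-after-dry probabilities. A day is
  classified wet when it records >= 0.1 mm.
* **Amounts.** Wet-day depths are Gamma(shape, scale), fitted by moments
  (shape = mean^2/variance, scale = variance/mean). Amounts are sampled as a
  plain gamma, so a generated wet day may rarely carry less than the 0.1 mm
  classification threshold; this keeps the expected monthly total an exact
  algebraic function of the parameters (below) at the cost of a small, known
  reclassification effect when a generated series is refitted (~4-5% of wet
  days fall below the threshold; expected totals and temperatures are
  unaffected).
* **Temperature.** tmax and tmin are normal conditionally on the wet/dry
  state, with a bivariate AR(1) standardised residual: lag-1 autocorrelation
  0.6 (typical of mid-latitude daily series; configurable) and a tmax-tmin
  innovation correlation of 0.7. `tmin <= tmax` is enforced by clipping; with
  realistic parameters the clip fires on O(10^-5) of days, biasing monthly
  means by far less than the generator's own sampling noise.
* **Sunshine.** The daily sunshine fraction (bright sunshine over
  astronomical daylength) is a clipped normal conditioned on the wet/dry
  state, making radiation anticorrelated with rain.

The calendar has 365 days everywhere (29 February is dropped on ingest), so
every simulated year is structurally identical and multi-year event counting
is trivial.

Generation is vectorised across years: each simulated year starts its
occurrence chain and AR(1) residual from the January stationary distribution
and the day loop runs over the 365 calendar days. Relative to one long
chain, the only difference is a ~1-day relaxation at year boundaries, orders
of magnitude below the fidelity bounds tested.

**Expected values used in tests.** With stationary wet probability
pi_m = p01 / (1 + p01 - p11), the implied monthly expectations are

    E[precip_m] = n_days_m * pi_m * shape_m * scale_m
    E[tmax_m]   = pi_m * mu_wet,m + (1 - pi_m) * mu_dry,m

**Change factors.** A scenario is a per-month additive shift of the tmax and
tmin means (wet and dry conditionals alike) and a multiplicative ratio on
the gamma scale. Because occurrence is untouched, E[precip_m] scales
*exactly* by the ratio — an algebraic identity the acceptance suite asserts
at machine precision. Variability and spell-length changes are deliberately
not represented: scenarios carry monthly-mean information only. Scenario CO2
concentrations (364 ppm baseline; 487/541 ppm mid-century and 533/844 ppm
late-century for the midrange/high pathways) are carried as metadata and
have no physiological effect in the crop model.

**Quality control.** Physically impossible records (tmax < tmin, negative or
extreme precipitation, out-of-range magnitudes, sunshine beyond daylength)
are flagged, removed and gap-filled from the calendar-day climatology; a
site whose essential variables are missing on more than 10% of days is
rejected outright.

**Synthetic study conditions.** Because the pipeline's reference inputs are
station records and climate-model projections that cannot be redistributed,
the package ships a parametric temperate-maritime site
(`synthetic_site_climatology`): ~650 mm annual rainfall with weak
seasonality, wet-after-wet ~0.65 in winter, gamma shape 0.75, January mean
tmax/tmin ~7/1.5 degC, July ~21.5/11.8 degC, cloudy winters. `wetness`
scales rainfall (0.85 for a dry eastern site, 1.3 for a wet western one) and
`warmth` shifts temperatures. A pseudo-GCM ensemble
(`make_synthetic_ensemble`) spans the mid-century envelope reported for this
climate: winter precipitation -10%..+40%, summer +/-30%, annual warming
0.2-3.0 degC with amplified summer warming, plus designated wettest and
driest members. What these fixtures do *not* emulate: interannual variance
beyond what the daily model produces, weather fronts/spatial correlation
between sites, spell-length change under scenarios, and observed-data
artefacts. Tests passing on them demonstrate the machinery and its
sensitivities, not site-specific UK risk values.

## Radiation and reference evapotranspiration (`metforcing`)

Sunshine hours convert to global radiation through the Angstrom-Prescott
relation Rs = (a + b n/N) Ra with the FAO-56 default coefficients a = 0.25,
b = 0.50 (configurable per site; local calibrations are not published for
the reference stations). Ra and daylength come from standard solar
geometry; latitudes poleward of 66.5 deg are rejected. Daily reference
evapotranspiration is the full FAO-56 Penman-Monteith computation with the
FAO fallbacks for unobserved inputs: wind speed fixed at 2 m/s, dew point
approximated by tmin (humid-climate assumption), elevation defaulting to
50 m, soil heat flux zero at the daily step. An independently coded
step-by-step implementation in the test suite agrees to < 0.01 mm/day on
random days.

## Soil water balance (`soilwater`)

A two-layer bucket tracks plant-available water: a 40 mm top layer (35 mm on
the light soil) and the remainder of the profile. Named profiles: 180 mm
(event indices), 177 mm "Hafren" medium and 127 mm light (crop stress).
Each day, in order:

1. **Snow.** Precipitation accumulates as snow water equivalent when the
   daily mean temperature is at or below 0 degC; above it, a degree-day melt
   (2.5 mm per degC per day) releases stored water. Snow depth for the
   frost index maps from water equivalent at 10:1 (1 mm SWE = 1 cm depth).
2. **Infiltration.** 15% of infiltration bypasses the top layer
   (preferential flow) into the lower store; top-layer overflow cascades
   down.
3. **Evapotranspiration and drainage.** Actual ET is the reference demand
   scaled by min(1, 2 x relative profile moisture) — full supply above half
   capacity, linear ramp below — withdrawn top layer first; whatever then
   exceeds total capacity drains.

The daily budget precip = d(SWE) + ETa + drainage + d(storage) closes to
floating-point accuracy (asserted < 1e-6 mm over 300 years).

**"At or above field capacity"** is operationalised as: the day drained
(drainage > 0, i.e. the store touched capacity during the day) or ended at
>= 99.9% of capacity. End-of-day state alone is the wrong observable here —
a bucket that withdraws ET after refilling ends every day one ET increment
below capacity, which would make waterlogged days unobservable. The
percentage thresholds of the sowing/harvest workability rules (90%, 85%,
5%) are fractions of *top-layer* available water capacity; whether the
waterlogging rule should read a layer or the whole profile is not
documented for the reference implementation, so the whole profile is used
(configurable).

Simulations run 50 spin-up years before any season is scored; the paired
full-start/empty-start acceptance check confirms the trajectory and all
event probabilities are independent of the initial store well before the
spin-up ends.

## Phenology (`phenology`)

Development is thermal time only: daily max(0, (tmax+tmin)/2 - base)
accumulated from the day after sowing, with stages (emergence, anthesis,
maturity) reached at cumulative targets. Defaults: base 0 degC, targets
150 / 1700 / 900 degC day, sowing fixed at 20 October (day 293). The
targets were calibrated once so the synthetic baseline gives mean anthesis
~9 June and maturity ~2 August, the behaviour expected of a
medium-ripening winter cultivar in this climate; they are plain
configuration for other cultivars. No vernalisation or photoperiod response
is modelled — a known fidelity gap: thermal-time-only development
overstates the advance of anthesis under strong warming (~28 days under a
uniform +2 degC here, versus ~12-14 days reported by calibrated models with
photoperiod terms; the direction is what the package's directional checks
assert). Seasons that fail to reach maturity within 365 days of sowing are
excluded with a warning and counted.

## Adverse-event indices (`adverse_indices`)

Seven binary events per season (sowing to maturity, with margins for the
sowing and harvest windows), aggregated to probabilities over the retained
years. Thresholds: frost <= -20 degC on < 1 cm snow; late frost <= -2 degC
after winter hardiness is lost (>= 5 consecutive days with mean temperature
>= 10 degC, regained after > 2 consecutive days below); > 60 days at/above
field capacity (mean temperature >= 3 degC) between sowing and anthesis;
>= 2 days with > 40 mm rain (or > 20 mm onto soil at field capacity) from
anthesis to 5 days before maturity; >= 3 days above 35 degC from 5 days
after anthesis to maturity; fewer than 3 workable days in the 31-day sowing
window (top-layer saturation in (5%, 90%), rain < 5 mm, preceding day
<= 10 mm) or in the maturity+5..+25 harvest window (saturation < 85%, rain
< 0.5 mm, preceding day <= 5 mm). Day counts are cumulative, not
consecutive, except where the late-frost trigger itself demands a run; the
hardiness state machine resets at each sowing. Every detector is verified
against an independent naive day-by-day scan on 1000 random seasons.

## Crop model and stress indices (`crop_stress`)

A reduced radiation-use-efficiency wheat model stands in for a full
leaf-layer simulator; the stress indices are *ratios* of paired runs, which
makes them far less sensitive to absolute calibration than yields. Daily,
from emergence to maturity: leaf area expands with thermal time
(max LAI 6.5 reached after 1100 degC day) and senesces over grain fill;
intercepted PAR = 0.5 Rs (1 - exp(-0.6 LAI)); biomass accrues at RUE
1.5 g DM per MJ PAR; yield = biomass x harvest index 0.5. The defaults give
~8 t/ha potential yield under the synthetic baseline (the national-average
calibration point). In rainfed mode the daily water stress factor
ETa/ET0 (clipped to [0,1]) multiplies assimilation and leaf expansion and
accelerates senescence (rate x (2 - factor)).

Four runs per season: potential Y (water stress forced off), water-limited
Yw, and Yw with one grain-number multiplier each for the drought-sensitive
(Ywd) and heat-sensitive (Ywh) cultivars:

* drought: product over the window anthesis-10..anthesis+5 of
  min(1, ratio/0.9), where ratio is actual over potential transpiration,
  proxied by ETa/ET0 from the soil model (the reference model's
  transpiration partitioning is not published);
* heat: per day above 30 degC in anthesis-10..anthesis or
  anthesis+5..anthesis+12, a sterile fraction 0.05 x (tmax - 30) (clipped),
  surviving fractions multiplying.

Indices: HSI = 1 - Ywh/Yw, DSI = 1 - Ywd/Yw, WSI = 1 - Yw/Y, each defined 0
when its denominator is 0, summarised by the mean and the 95th percentile
(numpy's linear order-statistic interpolation; >= 20 years required). By
construction 0 <= Ywh <= Yw <= Y and Ywd <= Yw every year, so all indices
lie in [0, 1].

**Magnitude caveat.** The multiplicative drought window is aggressive: a
fortnight of transpiration ratio ~0.7 collapses the grain-number multiplier
to ~0.02, so DSI95 saturates near 1 in dry years on these soils, where
calibrated field models report one-in-twenty-year reproductive losses of
0.1-0.3. Mean WSI (~0.11) and its 95th percentile (~0.23) on the medium
soil, and the direction and ordering of every contrast (light < medium
soil, wet < dry site), are the quantities this package is built to get
right; absolute DSI levels inherit the severity of the prescribed response
shape and the ETa/ET0 proxy and should be read comparatively.

## Ensemble and spatial summarisation (`ensemble_report`, `pipeline`)

Each site x scenario cell generates its own 300-year series (plus one extra
calendar year so the final sown season completes), yielding exactly
n_years - spin_up = 250 scored seasons. All scenario cells of a site share
one seed stream derived from (master_seed, site index): scenario contrasts
are paired (common random numbers), a neutral change-factor cell reproduces
the baseline bit-for-bit, and cells are order-independent and
reproducible. Ensemble results per site reduce to median, quartiles and
range across members; site values interpolate to a regular grid by inverse
distance weighting (power 2, all stations, exact at station coordinates)
with distances on a local equirectangular projection — adequate at
single-country extent. Outputs are per-year CSVs, a summary JSON, Esri
ASCII grids and a run log echoing configuration and seed.

## Scaled problem sizes

Study-scale defaults (300 years, 50-year spin-up, 250 retained seasons, 16
ensemble members) run in seconds per cell, and the acceptance script runs
the full set at those sizes. The test suite uses the same study sizes for
the acceptance-grade checks and smaller runs (40-120 years, 2-4 members)
for orchestration tests, sizes chosen to keep the whole suite fast while
leaving every statistical bound comfortably resolvable.

## Known limitations

No vernalisation/photoperiod phenology; grass-reference ET with fixed wind
and tmin-dew-point in place of observed humidity; a bucket soil (no water
table, runoff routing or soil temperature); stress responses reduced to
multiplicative factors; no pest/disease or nitrogen effects; no CO2
fertilisation of water-use efficiency; scenario perturbations limited to
monthly means. Within those bounds, every behaviour claimed above is
asserted by the test suite or recomputed by `scripts/acceptance.py`.
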