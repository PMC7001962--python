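# agriwx

Adverse-weather risk analysis for winter wheat under local climate
scenarios: a stochastic daily weather generator with GCM-style monthly
change factors, FAO-56 reference evapotranspiration, a two-layer soil water
balance with snow, thermal-time phenology, seven agroclimatic adverse-event
indices, and a reduced crop model yielding heat/drought/water stress
indices — with ensemble and spatial (IDW) summarisation.

It is written for agro-climatologists and crop modellers who want to ask,
for a site and a set of climate projections: *how often do conditions that
damage winter wheat occur, and how severe are the resulting yield losses,
now and under a changed climate?*

## The method

For each site and scenario the pipeline:

1. fits monthly generator parameters from daily weather (Markov-chain rain
   occurrence, gamma wet-day amounts, wet/dry-conditioned AR(1)
   temperatures, sunshine fraction), optionally perturbs them with monthly
   change factors (ΔTmax, ΔTmin additive; precipitation ratio
   multiplicative, so E[monthly precip] scales exactly), and generates 300
   synthetic years;
2. converts sunshine to radiation (Ångström, a=0.25, b=0.50) and computes
   FAO-56 Penman–Monteith ET₀;
3. runs a two-layer soil water balance with snow accumulation/degree-day
   melt and preferential flow, closing the daily water budget to machine
   precision;
4. predicts sowing→emergence→anthesis→maturity by thermal time (20 October
   sowing, base 0 °C);
5. evaluates, per season, seven adverse-event triggers (severe frost on
   bare ground, late frost after hardiness loss, extremely wet early
   season, lodging rain, grain-filling heat, adverse sowing and harvest
   windows) and their occurrence probabilities over the 250 post-spin-up
   seasons;
6. runs a radiation-use-efficiency crop model four ways per season —
   potential Y, water-limited Yw, drought-sensitive Ywd, heat-sensitive
   Ywh — and reports the stress indices

       HSI = 1 − Ywh/Yw,  DSI = 1 − Ywd/Yw,  WSI = 1 − Yw/Y

   as means and 95th percentiles (the one-in-twenty-year loss);
7. summarises across a climate-model ensemble (median, quartiles, range)
   and interpolates site values to a map grid by inverse distance
   weighting.

Because the reference station records and climate-model projections are not
redistributable, the package ships synthetic study conditions: a parametric
temperate-maritime site climatology and a 16-member pseudo-GCM
change-factor ensemble spanning winter precipitation −10%..+40%, summer
±30% and 0.2–3.0 °C warming. See `docs/methods.md` for every model,
parameter and limitation.

## A worked example

`examples/stress_indices.py` runs 250 retained seasons at the baseline site
on a medium (177 mm available water capacity) and a light (127 mm) soil:

```
mean potential yield: 8.2 t/ha (UK-average calibration)

index      medium 177mm   light 127mm
HSI               0.002         0.002
DSI               0.227         0.560
WSI               0.113         0.182
HSI95             0.000         0.000
DSI95             0.969         1.000
WSI95             0.228         0.308
```

WSI = 0.113 means water limitation costs 11.3% of potential yield in an
average season; WSI95 = 0.228 is the loss expected once every 20 years.
Heat stress around anthesis is negligible in this climate, and the light
soil — storing less winter rain — is consistently more stressed. The other
examples cover the generator round trip (`generate_weather.py`), the seven
event probabilities at a wet versus a dry site
(`adverse_event_probabilities.py`), and the scenario ensemble with an IDW
risk map (`ensemble_scenarios.py`); each prints a short interpretation of
its numbers.

A thin CLI wraps the same library calls:

```sh
agriwx synth --out fixtures --seed 3            # synthetic weather + change factors
agriwx fit --weather fixtures/baseline_weather.csv --latitude 52 --out clim.json
agriwx run --config experiment.yaml --seed 42 --out results/
agriwx map --stations values.csv --out risk.asc
```

The YAML config declares sites (latitude, wetness or a weather CSV), the
ensemble (synthetic or a change-factor CSV), years (default 300), spin-up
(50), sowing day, cultivar thermal-time targets and soil profiles; see
`tests/test_pipeline.py::TestConfigIO` for a complete file.

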