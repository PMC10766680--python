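# firelarch

Individual-based simulation of boreal larch forest dynamics coupled to a
climate-driven wildfire module, for studying how fire regimes shape forest
structure in the permafrost lowlands of eastern Siberia.

The package is aimed at fire ecologists and vegetation modellers who want a
self-contained, reproducible testbed for fire–vegetation feedbacks: every
input (monthly climate, landscape rasters, species traits) can be produced
by built-in synthetic generators, and external forcings can be supplied
through the same CSV / ESRI-ASCII interfaces.

## The model

**Fire weather.** Monthly mean temperature T and precipitation sum P are
converted to a monthly fire probability rating by a linear model,
`FPR_mon = a + b·T + c·P` (b > 0, c < 0), evaluated only for months above
0 °C. Ratings are categorized by fixed thresholds — mild (≥ 6.6), severe
(≥ 7.0), extreme (≥ 7.46) — and a year's category counts are combined into
an annual ignition probability

```
FPR_ann = clamp(s · (1·n_mild + 2·n_severe + 4·n_extreme), 0, 1)
```

where the scale `s` is calibrated so the series mean equals a target
ignition rate (default 0.03 yr⁻¹, about one fire per 33 years).

**Fire.** At most one fire per year: ignition is a uniform draw against
FPR_ann; the fire center is uniform over the area; the burned diameter is
`FPR_ann × area width`. Each 0.2 m cell inside the disk receives an
intensity `FI = FPR_ann · max(0, 1 − (TWI − TWI_min)/(TWI_wet − TWI_min))`
— wetter cells (high topographic wetness index) burn less, and cells at or
above the wetness cutoff, or covered by water, do not burn at all.

**Impacts.** Tree death combines stem heating, damped exponentially by
height-proportional bark thickness, with crown scorch from a flame-height
power law; killed larches may resprout at reduced height. Ground seeds are
destroyed wherever FI > 0, cone seeds with probability FI, and litter is
removed proportionally (completely at FI ≥ 0.8).

**Vegetation and soil.** Trees grow with growing-season temperature,
height, and neighborhood competition; mature trees disperse seeds through
an isotropic Gaussian kernel; germination requires a sufficiently deep
active layer (0.2 m for Dahurian larch, 1.0 m for Scots pine, 2.0 m for
Siberian spruce and pine) and is suppressed exponentially by litter. The
litter layer regrows at 0.5 cm yr⁻¹ with stochastic small-scale
disturbances calibrated to a ~13 cm long-run mean; active-layer depth
relaxes toward a Stefan-type equilibrium (∝ √degree-days) reduced by
litter insulation, so burned ground thaws deeper over the following years.

## Worked example

```python
import numpy as np
import firelarch as fl

# calibrate the annual ignition probability on a synthetic climate
clim = fl.generate_synthetic_climate(500, seed=1)
cal = fl.calibrate(clim, target_mean=0.03)
ratings = fl.annual_ratings(clim, cal=cal)
print(f"calibrated scale: {cal.scale:.6f}")
print(f"mean FPR_ann    : {np.mean([r.fpr_ann for r in ratings]):.6f}")

# a stand-replacing fire scenario: whole-area FI = 1.0 fires every 50 yr
cfg = fl.RunConfig(n_years=500, spinup_years=200, seed=5,
                   fire_mode="fixed", fixed_fri=50, fixed_fi=1.0,
                   snapshot_interval_yr=0)
res = fl.run_simulation(cfg)
sea = fl.superposed_epoch(res.annual["stem_count"].to_numpy(),
                          res.fires["year"].to_numpy(),
                          years=res.annual["year"].to_numpy())
print(f"fires superimposed    : {sea.n_events}")
print(f"pre-fire stem baseline: {sea.baseline():.1f}")
print(f"stems in the fire year: {sea.median[10]:.1f}")
print(f"recovery time         : {fl.recovery_time(sea):.0f} yr")
```

Output:

```
calibrated scale: 0.005486
mean FPR_ann    : 0.030000
fires superimposed    : 10
pre-fire stem baseline: 705.2
stems in the fire year: 11.5
recovery time         : 22 yr
```

On this 99 × 99 m stand, each whole-area stand-replacing fire collapses the
stem count (trees ≥ 130 cm) from ~700 to ~10 — the survivors are larch
resprouts — and the superposed-epoch median regains the pre-fire baseline
22 years after the fire, within the 30-year window the scenario analysis
uses.

A command-line interface wraps the same library:

```
firelarch calibrate-fpr --climate clim.csv --target-mean 0.03 --out fpr.yaml
firelarch run   --config run.yaml  --out outdir
firelarch suite --config base.yaml --out suitedir   # 23 scenario runs
firelarch sea   --annual outdir/annual.csv --fires outdir/fires.csv --out sea.csv
```

## Layout

- `src/firelarch/climate.py` — climate CSV IO, localization, synthetic generator
- `src/firelarch/landscape.py` — ESRI ASCII rasters, fractal DEM / slope / TWI, two-level grid
- `src/firelarch/fire_weather.py` — FPR_mon/FPR_ann, categories, calibration, refit
- `src/firelarch/fire_engine.py` — ignition, placement, TWI-mediated intensity, flame height
- `src/firelarch/forest.py` — demography, seeds, establishment, litter, active layer
- `src/firelarch/fire_impacts.py` — tree mortality, seed and litter consumption
- `src/firelarch/simulation.py` — annual loop, scenario suite, outputs
- `src/firelarch/analysis.py` — superposed epoch analysis, recovery time, structure metrics
- `docs/methods.md` — model description, parameter choices, limitations
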