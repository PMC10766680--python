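# Methods

This note documents the model equations, the parameter choices that
matter, what the synthetic generators emulate, and the known limitations.
All defaults live in dataclasses (`FprModel`, `FprCalibration`,
`FireParams`, `ImpactParams`, `ForestParams`, `LitterParams`,
`ActiveLayerParams`) and in the shipped species table
(`src/firelarch/data/species_traits.csv`).

## Geometry

The simulation area is a square in planar meters (no geodesy). Terrain
(elevation, slope, topographic wetness index TWI, water mask) is stored on
a coarse grid — 90 m at full scale — and looked up per containing cell;
litter height, active-layer depth, ground seed banks, and last fire
intensity live on a 0.2 m fine grid that tiles the coarse grid exactly.
Any coarse resolution with an integer ratio to 0.2 m is accepted: the
desk-scale default is 11 coarse cells at 9 m (99 × 99 m, 495² ≈ 245k fine
cells), which keeps every mechanism of the full 990 × 990 m configuration
while fitting studies of the model into minutes. Coordinates are
continuous (x, y) with origin at the south-west corner and half-open cell
intervals `[i·res, (i+1)·res)`.

## Climate forcing

A climate series is monthly (year, month, T_mon °C, P_mon mm), twelve
contiguous months per year. External series are localized to a reference
monthly climatology by matching means over a fitting window — additively
for temperature, multiplicatively for precipitation (the standard
bias-correction convention; variance is left untouched, since only the
means are specified by the procedure being emulated). Localization is
idempotent.

The synthetic generator emulates the continental climate of western
Central Yakutia: a sinusoidal seasonal temperature cycle with mean
−7.25 °C and amplitude 25.05 °C (January −32.3 °C, July 17.8 °C) plus an
AR(1) monthly anomaly (innovation sd 2 °C, lag-1 autocorrelation 0.3) and
an optional linear trend; monthly precipitation is gamma-distributed
(shape 2) with summer-weighted seasonal means summing to 303 mm yr⁻¹.
With zero noise the series is exactly periodic with period 12. What it
does **not** emulate: millennial-scale transients (glacial–interglacial
trends), interannual persistence beyond one month, and
temperature–precipitation cross-correlation. Passing tests under this
forcing therefore demonstrate the mechanisms under a stationary climate,
not a reconstruction of any particular paleo-trajectory.

The synthetic landscape is a spectral fractal DEM (power spectrum ∝ k⁻³)
scaled to a configurable relief, with slope from central differences, a
single-flow-direction (D8) accumulation, and TWI = ln(specific catchment
area / tan slope). The TWI field is rescaled onto a target range (default
7.1–15.5, typical of thermokarst lowlands). Any monotone TWI serves the
fire module; no specific GIS algorithm is replicated. The lowest-lying
fraction of cells becomes water; water cells never hold trees, seeds, or
litter.

## Fire weather

`FPR_mon = intercept + coef_t·T + coef_p·P` for months above 0 °C (colder
months carry no rating). The published coefficient values of the original
observational fit are not available, so the shipped defaults
(6.46, +0.06 °C⁻¹, −0.01 mm⁻¹) are chosen to keep the published category
thresholds meaningful: a warm, dry month (20 °C, 20 mm) rates at the
extreme threshold. The thresholds are 6.6 (minimum for any fire weather),
7.0 (severe), 7.46 (extreme); boundary values belong to the higher class
(tie-breaking is a package choice). `refit_fpr_model` refits the
coefficients by OLS of log1p(monthly fire counts) on (T, P) — counts are
zero-inflated, and any monotone transform is admissible because only the
rating's quantiles matter downstream — and recomputes the thresholds
(severe = Q3, extreme = distribution maximum, minimum = highest rating of
a zero-fire month).

The annual rating is a clamped weighted category count,
`FPR_ann = clamp(s·(n_mild + 2·n_severe + 4·n_extreme), 0, 1)`. The
functional form of the original aggregation is unpublished; a weighted
count with weights (1, 2, 4) is the simplest form that is monotone under
category promotion, bounded in [0, 1], and tunable to a target mean. The
scale `s` is solved by monotone bisection so that the series mean equals
the target (default 0.03 ± 1e−6); if clamping makes the target
unattainable the achievable maximum is reported and the calibration
errors rather than silently undershooting.

## Fire engine

One fire at most per year. Ignition: uniform draw < FPR_ann. Center:
uniform over the area. Diameter: `width · FPR_ann^e` with e = 1 (the
simplest reading of "extent determined by FPR_ann relative to the area
width"; the exponent is exposed). The disk is clipped at the boundary and
may cover water cells, which simply receive zero intensity — there is no
spread model to route around obstacles.

Per-cell intensity: `FI = FPR_ann · max(0, 1 − (TWI − TWI_min)/(TWI_wet −
TWI_min))`, with the wetness cutoff TWI_wet placed at 80% of the
landscape's land TWI range by default. Cells with FI = 0 inside the
perimeter count as unburned. Fixed-mode scenario fires skip the TWI
mediation and apply the labeled intensity uniformly on land, so a
"FI = 0.5 scenario" means exactly that.

Flame (scorch) height is `h_max · FI^q` with h_max = 15 m. The exponent
only needs to be monotone; the shipped default q = 2 is the value
produced by the impact calibration below. A 2/5-power (Heskestad-style)
configuration is supported and tested for shape, but it cannot satisfy
all three impact anchors simultaneously: with q = 0.4 the flame at
FI = 0.1 reaches 0.398·h_max ≈ 6 m, which fully scorches every tree below
~7 m and contradicts the low-intensity anchor, while lethality at FI = 1
requires the flame to top the tallest crowns.

## Fire impacts

Two independent hazards combine: `p_kill = 1 − (1 − p_stem)(1 − p_canopy)`
with `p_stem = FI · exp(−k_bark · bark)`, bark = bark_coef · height, and
`p_canopy = scorch^γ`, scorch = clip((flame − crown_base)/crown length).
A tree is rated at the mean FI of the fine cells its stem footprint
touches (point stem below 2 m; taller stems sample a height-proportional
disk at its center and four cardinal points). The shipped coefficients
(k_bark = 3 cm⁻¹, γ = 2, q = 2, h_max = 15 m) satisfy three regime
anchors, checked by `scripts/calibrate_fire_impacts.py` and the test
suite:

1. FI 0.1: kill probability < 2% for a 10 m larch — low-intensity fires
   leave no visible stem-count response;
2. FI 0.5: survivable for tall larch (the fire removes the understory);
3. FI 1.0: p_kill ≥ 0.999 for every species at every height —
   stand-replacing.

Killed trees of resprouting species (larches; Dahurian larch 0.15,
other larches 0.10) restart at 10% of pre-fire height at the same
position and age. Ground seeds are erased wherever FI > 0; cone seeds are
destroyed independently with probability FI; litter becomes
`height · max(0, 1 − FI/0.8)`.

## Demography

The demographic core is a deliberately minimal, fully parameter-driven
stand-in for a full individual-based forest model; every constant lives
in the species table so it can be re-tuned without code changes.

* **Growth**: Δh = rate · suitability · size / (1 + CI). Suitability is a
  Gaussian in the growing-season mean temperature (mean over months
  > 0 °C). The size factor is 1 below half the species maximum height and
  declines linearly to 0 at the maximum — so the young-tree increment is
  exactly rate · suitability / (1 + CI), while heights stay bounded below
  the 15 m flame ceiling over millennial runs. The crown base rises
  toward 35% of height at 20% yr⁻¹.
* **Competition** CI: sum over taller-or-equal neighbors within 10 m of
  `(h_neighbor/1000 cm) · (1 − d/10 m)` — increasing in neighbor height,
  decreasing in distance, zero for an isolated tree. Implemented exactly
  (KD-tree radius query); computed once per year and shared by growth and
  mortality, with same-year recruits entering at zero competition.
* **Seeds**: mature trees (height ≥ species maturity) add their annual
  production to cones; half the cone is released each year and placed by
  an isotropic Gaussian kernel (species sd, 4–6 m), truncated to the
  area; water landings are discarded. Ground banks decay at 50% yr⁻¹.
  Wind-driven anisotropic dispersal is out of scope.
* **Establishment**: per seed, germination = 0.02 · exp(−0.177 · litter cm)
  — an order of magnitude lower under 13 cm litter than on bare soil —
  gated by the species' minimum active-layer depth (20 / 25 / 30 cm for
  the larches, 100 cm Scots pine, 200 cm spruce and Siberian pine).
  Recruitment is capped at one seedling (1 cm) per 0.2 m cell per year.
* **Mortality**: independent hazards — background (1.5–1.8% yr⁻¹),
  senescence (zero until 80% of max age, rising quadratically to 1 at max
  age), and competition (1 − exp(−0.03·CI)). A young, uncrowded tree dies
  exactly at the background rate.

With these defaults a 99 × 99 m stand under the stationary synthetic
climate equilibrates near ~600 stems (≥ 130 cm) and ~2,000 individuals,
an open larch woodland; the numbers were chosen for ecological
plausibility and are not fitted to any observed stand.

## Litter and active layer

Litter regrows at 0.5 cm yr⁻¹ (scaled by an optional foliage-supply
factor in [0, 1], 1 by default — the annual loop passes full supply on
land) up to a 40 cm cap; each land cell is independently disturbed with
probability p each year, losing a U(0, 1) fraction. The stationary
balance `m = (m + g)(1 − p/2)` gives `p = 2g/(m + g)`; for the 13 cm
target, p = 2/27 ≈ 0.074 (`calibrate_litter_disturbance`). The cap binds
rarely and biases the mean by under 0.2 cm.

Active-layer depth relaxes toward `stefan_coef · √(thaw index) ·
exp(−k_ins · litter)` with a 5-year e-folding (multi-year thermal
memory). The thaw index is the degree-day sum of positive monthly means ×
30.4. The insulation constants put the bare-ground equilibrium at
~105 cm and the 13 cm-litter equilibrium at ~60 cm under the stationary
synthetic climate (thaw index ≈ 1740 °C·d), so a stand-replacing fire
deepens thaw from ~60 toward ~100 cm over the following decade and
unlocks Scots pine establishment (gate 100 cm) while spruce and Siberian
pine (200 cm) remain excluded under this climate. There is no multilayer
permafrost physics and no soil heat transport; the relaxation is a
contraction with no oscillation.

## Annual loop and experiments

Order within a year: fire-weather rating → fire (ignite/place/impact) →
growth → seed production and dispersal → establishment → mortality →
litter and active-layer update → metrics. Fire precedes demography so
post-fire establishment can respond in the same year. Randomness is split
into named substreams (ignition, placement, demography, disturbance,
litter) spawned from one master seed: toggling fire cannot perturb
demographic draws, runs are bit-identical under the same seed, and a
fire-on run with no ignition equals the fire-off run exactly.

Fire modes: `climate_driven`, `off`, and `fixed` (whole-area fires at a
labeled intensity in years ≡ 0 mod the return interval; spin-up years are
always fire-free). The experiment suite comprises 23 runs: reference with
and without fire, six one-at-a-time ±5% perturbations (T, P, fire
mortality), and the 15 combinations of return interval {10, 50, 100, 200,
300} yr × intensity {0.1, 0.5, 1.0}.

Outputs: annual records (FPR_ann, burned fine cells, stem count ≥ 130 cm
total and per species, seedlings 0–40 cm, mean height of trees > 200 cm,
evergreen/deciduous ratio — missing when no deciduous trees exist — mean
litter, mean active layer), a fire log, and per-coarse-cell snapshots
every 100 years (mean litter, mean active layer, stem-level abundance per
species, so snapshot sums equal the annual stem count).

## Recovery statistics

The superposed epoch analysis cuts a window of 10 years before to 30
years after each fire from an annual series, drops windows truncated by
the series edges (counting them), and reports the per-relative-year
median and quartile band across events. Overlapping windows are all kept.
Recovery time is the first post-fire year at which the median regains the
pre-fire baseline, defined as the mean of the median over relative years
−10…−1 (the underlying procedure says only "pre-fire numbers"); a flat
response recovers at +1, and a median that never recovers within +30 is
reported missing. Scenario file ingestion sorts run names numerically
("run_2" before "run_10").

## Problem sizes and numerical choices

The shipped studies run at desk scale: 99 × 99 m, 500–2,500 simulated
years, ~2,000 individuals — sizes at which a scenario completes in about
a minute on one core while exercising every mechanism; the 990 × 990 m /
multi-millennial configuration is supported but long. Calibration
bisection tolerance is 1e−9 on the mean rating; litter/active-layer
fields are float32; seed banks are integer counts; establishment
positions jitter uniformly within the 0.2 m cell. Degenerate inputs are
errors, not silent defaults: incomplete climate years, mismatched raster
headers, NODATA on land, a zero-precipitation month against a nonzero
reference, an unattainable calibration target.

## Limitations

No active fire spread, no multiple ignitions per year, no overwintering
fires, no running- vs sustained-surface-fire distinction, no fuel-load
dynamics or human suppression. No permafrost physics beyond the
insulation-damped Stefan relaxation, no trait variation or inheritance,
no nutrient pulse after fire, no wind-driven dispersal. The fire-weather
coefficients are configurable stand-ins pending a site refit, and the
demographic constants are documented stand-ins, not a fitted forest
model: results are about mechanism and regime behavior, not about
predicting a particular stand.
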