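# Methods

`sorgsim` simulates the growth of photoperiod-sensitive bioenergy sorghum on
a daily time step, with an optional hourly sub-model for VPD-limited
transpiration traits. This note records the model structure, the parameter
choices that matter, the calibrations the package performs, and what the
synthetic climatology does and does not represent.

## Model structure

Each simulated day proceeds in a fixed order: derive weather quantities
(photoperiod, sunrise/sunset, daily VPD), advance phenology, grow the
potential canopy, compute the radiation-limited biomass rate, resolve water
(daily rule or hourly VPD sub-model), extract soil water, accumulate and
partition biomass, senesce, evaporate from the soil surface, then apply
irrigation and infiltrate rainfall. Seasons run from sowing (April 15 by
default, within the regional April 14 – May 1 window) to a fixed harvest at
200 days after sowing (DAS); nitrogen is assumed non-limiting and grain
development is out of scope, as the crop is harvested for vegetative
biomass.

### Phenology

Thermal time uses the classic eight-point three-hourly interpolation of the
daily temperature range through a triangular response with cardinal
temperatures 11/30/42 °C (base/optimum/maximum — the standard sorghum
values; the model exposes them as configuration). Stages run sowing →
emergence (60 °Cd) → juvenile (120 °Cd) → photoperiod-sensitive phase →
floral initiation → flowering.

Energy sorghum hybrids repress floral initiation while day lengths exceed
12.4 h. This is modeled as a dynamic thermal-time target for the
photoperiod-sensitive phase, re-evaluated daily:

    target = tt_endjuv_to_fi + slope · (min(pp, crit2) − crit1),  pp > crit1

with crit1 = 12.4 h, crit2 = 13.4 h, slope = 1545 °Cd h⁻¹, and photoperiod
computed for a −2.2° twilight sun angle. With these constants the extension
saturates at 1545 °Cd in midsummer — less than a central-Texas season
accumulates — so the gate's timing also depends on the base duration
`tt_endjuv_to_fi`. That base is not published for the energy hybrid; the
crop's thermal-time parameters are conventionally set from observed time to
floral initiation, and this package follows the same procedure:
`tt_endjuv_to_fi` was calibrated once against the noise-free default
climatology so that floral initiation for an April 15 sowing at latitude
30.589 falls at 150 DAS (mid-September, a few days before day length drops
below 12.4 h). The calibrated value, 1500 °Cd, is frozen as the genotype
default; across generator seeds the realized date varies by at most a day
or two because the shrinking photoperiod extension (≈ 45 °Cd d⁻¹ in early
September) dominates day-to-day thermal-time noise.

### Canopy

Total plant leaf area (cm² plant⁻¹) follows a logistic in thermal time
since emergence, `TPLAmax / (1 + exp(−α (tt − β·tt_fi)))`, with α = 0.003
(°Cd)⁻¹, β = 0.725, and `TPLAmax = c · leaf_no_max^γ` with γ = 2.68. The
scaling constant c = 0.110 cm² plant⁻¹ was calibrated once so the default
genotype at 13.2 plants m⁻² peaks near LAI 5 under unlimited water; it is a
named constant (`canopy.TPLA_SCALE`), not hidden. Leaf number appears at
one leaf per 50 °Cd up to 50 leaves; light interception is Beer's law with
k = 0.70; plant height is piecewise linear in stem mass per stem, reaching
4.0 m at 230 g stem⁻¹.

Before 60 DAS leaf-area growth is driven by thermal time only; afterwards
the daily area increment is scaled by the previous day's water-limitation
factor (actual/potential biomass). Senescence has two triggers: a
supply:demand ratio below 0.03 sheds 5 % of green LAI per day (the
threshold is published; the rate is a first-order convention), and
radiation at the canopy base below 0.5 MJ m⁻² for more than 25 consecutive
days sheds the over-shaded lower-canopy area over the same time constant.
Senesced area moves from `lai` to `slai`, conserving produced area.

### Soil water

Six layers (0–150, 150–300, 300–600, 600–900, 900–1200, 1200–1500 mm);
the sixth is a static water table: roots never enter it and water reaching
it is held, so seasonal drainage out of the profile is zero and the budget
closes exactly (the test suite checks < 10⁻⁴ mm per season). Layer
hydraulics are a generic Vertisol-like profile (PAWC ≈ 219 mm over the
rooted 1200 mm; kl = 0.07/0.07/0.05/0.04/0.03 d⁻¹), chosen so a full
profile supports roughly 60–100 DAS of unirrigated growth before stored
water runs out. Infiltration cascades top-down to the drained upper limit;
saturation excess runs off. The profile starts at the drained upper limit
(a "fully saturated profile before sowing" is mapped to the plant-available
ceiling; true saturation is available via configuration). Roots descend at
15 mm d⁻¹ from a 50 mm sowing depth. Irrigation regimes: none, limited
(stops July 7), unlimited; 150 mm applied when the rooted-profile deficit
reaches 50 mm. Soil evaporation is first-stage only, from the surface
layer, shaded by the canopy as exp(−0.7·LAI) with a coefficient of
0.25 mm MJ⁻¹.

### Biomass

Radiation-limited growth is `radn · interception · RUE` with RUE =
2.3 g MJ⁻¹. Water demand converts that gain through the transpiration
efficiency TE = TEc/VPD with TEc = 9 g m⁻² mm⁻¹ kPa (the 0.009 kPa kg kg⁻¹
convention per unit ground area); daily VPD is 0.75 of the
svp(tmax) − svp(tmin) span (Tetens formula). When supply falls short of
demand, growth is uptake · TEc / VPD. Partitioning is 35 % leaf / 65 % stem
before floral initiation and all stem afterwards — fractions chosen so leaf
mass is consistent with peak LAI at a specific leaf area near 200 cm² g⁻¹
and stem mass approaches 230 g stem⁻¹ in irrigated runs.

### Hourly VPD-limited transpiration

The trait {m1, m2, vpd_bp} defines a piecewise-linear transpiration-rate
response to VPD: `Tv = m1·(vpd − 0.25)` below the breakpoint, continuing
from the breakpoint value with slope m2 above it, clamped at zero. The
published formula's intercept contradicts its own stated consequence (zero
transpiration at or below 0.25 kPa); the stated consequence is taken as
authoritative, and the literal printed intercept is available via
`intercept_convention="printed"`.

Hourly temperature follows a continuous piecewise diurnal curve in the
style of sinusoid-based interpolators: a half-sine rise from the pre-dawn
minimum to tmax two hours before sunset, a quarter-cosine decay to a dusk
temperature (tmax minus 0.4 of the span to the next day's tmin), and an
exponential nighttime decay toward the next tmin (rate constant 2.5 over
the night). The cited interpolation method's exact constants are not
published with the crop model, so the peak offset, dusk fraction and night
decay are configurable; the curve is exercised by continuity, bound, and
argmin/argmax tests rather than asserted against specific constants.
Hourly VPD is svp(T(t)) − svp(tmin), i.e. the dewpoint is assumed to sit at
the daily minimum. The day's radiation-limited biomass is distributed over
daylight hours as a half-sinusoid (conserving the daily total exactly).

Units bridging: trait slopes are kept in the source assays' units
(mg H₂O m⁻² leaf s⁻¹ per kPa) and converted to mm h⁻¹ per unit leaf area by
the exact factor 3600 × 10⁻⁶ before entering
`T(t) = min(Tv, Tr, soil term)`, where `Tr = Br(t)·vpd(t)/(TEc·lai)` is the
rate that realizes the hour's radiation-limited biomass share. The daily
soil supply (a stock) is consumed sequentially from sunrise — each hour's
ground-area use `T·lai` is deducted, and the crossing hour is taken
partially. Daily endpoints are `W = lai·Σ T(t)` and
`B = lai·TEc·Σ T(t)/vpd(t)`, with vpd floored at 0.01 kPa in quotients to
avoid dawn blow-ups; the same floor is used in `Tr` so the water-ample
limit recovers the radiation-limited biomass exactly. With the trait
disabled the engine takes the daily pathway, bit-identically to a run with
no trait configured.

`induction_das` models a mid-season induced trait: before the induction
day the genotype follows its no-breakpoint m1 line (under the same hourly
pathway), after it the full breakpoint response — so induced-trait
comparisons isolate the breakpoint itself.

## Synthetic climatology

The generator emulates College Station, TX: mean annual temperature
20.5 °C with a ±9.5 °C seasonal cycle peaking near day 205 and an
11.5 °C diurnal range; solar radiation 16.5 ± 6.2 MJ m⁻² d⁻¹ peaking at the
solstice, reduced 20 % on wet days; rainfall from a first-order two-state
occurrence chain (wet→wet 0.45, dry→wet 0.20) with gamma amounts
(shape 0.65, scale 19 mm) and a mid-summer dip in wet probability (55 %
deep, centered day 225) mirroring the observed decline of rainfall toward
~120 DAS. These defaults give a mean cropping-season (April 15 + 200 d)
rainfall of ≈ 560 mm with a year-to-year SD of ≈ 150 mm, against an
observed 560 ± 180 mm; the generator under-disperses interannually because
it has no year-scale wetness modes (no ENSO-like persistence), so extreme
drought and flood years are rarer than in the real record. It also lacks
temperature–rain correlation beyond wet-day cloudiness, multi-day
temperature persistence, and real station idiosyncrasies. Passing tests on
this climatology therefore demonstrate internal consistency and the
direction and rough magnitude of trait effects, not station-accurate
reproduction of any particular historical year.

## Numerical and design choices

- Hour grid: 24 one-hour steps at half-hour centers; daylight hours are
  those between sunrise and sunset at 0° twilight (photoperiod for
  phenology uses −2.2°). The sampled diurnal curve snaps the peak onto the
  grid so the daily maximum temperature is attained exactly.
- tav/amp: monthly means of (tmax+tmin)/2 pooled by calendar month; tav is
  the mean of the twelve month-of-year means, amp their range.
- Extraction removes water from layers proportionally to each layer's
  kl·(sw − ll) term, with partial-layer weighting at the root front.
- The stage-dependence of TEc is exposed as a parameter but defaults to a
  constant; no published stage schedule exists for the energy hybrid.
- Bootstrap bands resample years with replacement (seeded); the "100 %"
  band is the full range of bootstrap means. The drought classifier uses
  integer DAS window centers, both endpoints inclusive.
- Degenerate inputs: tmax = tmin yields a flat diurnal curve and zero VPD
  (demand 0, growth radiation-limited); zero LAI or zero supply short-
  circuits the hourly integration to zeros; a zero daily VPD with positive
  uptake returns the radiation-limited rate.

## Problem sizes

The test suite runs multi-year directional checks on 14–16 synthetic years
and the landscape dominance check on the reduced 5×5 (m2, vpd_bp) grid with
two m1 values over 3–4 years — sizes chosen to keep the default suite
around a minute and a half while leaving every directional conclusion
unchanged at larger sizes. The drought-classifier/oracle equivalence uses
1,000 random series. Full-resolution landscapes (25×25, three m1 values,
all years) are available through `sorgsim sweep`.

## Known limitations

- Canopy development is somewhat later than field observations: with the
  published logistic coefficients and the calibrated floral-initiation
  thermal time, LAI crosses 4 near DAS 120–130 rather than ~100; the peak
  (≈ 4.7–5) and the water-limitation dynamics match.
- The within-day soil decrement is sequential from sunrise (morning hours
  draw first); a proportional allocation is equally defensible and would
  slightly shift water use toward midday.
- Runoff is saturation-excess only (no curve number); water-table dynamics
  are static; there is no nitrogen, tillering, root-biomass or grain
  module.
- The trait-assay unit bridge (mg m⁻² s⁻¹ → mm h⁻¹) assumes the assay
  rates are per unit leaf area and directly comparable to canopy rates;
  boundary-layer differences between chamber assays and field canopies are
  not represented.
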