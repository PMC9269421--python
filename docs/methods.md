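# Methods

## Model structure

`ecoclimex` implements the classic growth-minus-stress family of
mechanistic species distribution models. A cell's annual suitability is the
product of an annual growth index and a stress survival factor, gated by a
thermal-sum persistence requirement:

```
GI_A = 100 · Σ_w TI_w · MI_w / 52
SI   = (1 − CS/100)(1 − HS/100)(1 − DS/100)
DD   = Σ_w 7 · max(0, tmean_w − DV0)
EI   = GI_A · SI  if DD ≥ PPD, else 0          (clamped to [0, 100])
```

The published material this parameterisation comes from states the
parameter table and the index semantics but not the combination formula or
the stress-accumulation law of the commercial implementation it was run on.
The choices made here, documented as this package's own model, are:

- **Weekly growth composition** `GI_w = TI_w · MI_w`, annual mean ×100.
  The multiplicative form is the standard structure for this model family
  and is the simplest combination with the right boundary behaviour (either
  index at 0 suppresses growth; both at 1 give full growth).
- **Linear stress accumulation** with a ×100 scaling to percent and a hard
  cap at 100. Commercial implementations accumulate stress exponentially;
  linear accumulation preserves the thresholds, the rates, the
  directionality and the one-at-a-time sensitivity semantics, and is
  transparent to test. Consequences: absolute stress magnitudes are not
  comparable to outputs of other implementations, only signs and orderings.
- **Exposure variables**: cold stress reads weekly *minimum* temperature,
  heat stress weekly *maximum*, growth and degree-days the weekly *mean* —
  the conservative choice (stress sees the extremes).
- **Temperature stresses weight by exceedance magnitude** (°C·weeks beyond
  the threshold); **dry stress weights by occupancy** (weeks below SMDS),
  because soil-moisture deficits are bounded in [0, SMDS] ≈ [0, 0.1] and a
  magnitude weighting would make dry stress numerically negligible. Both
  modes are switchable per stress (`mode="magnitude" | "occupancy"`).
- **Degree-day gate**: PPD is a hard persistence threshold (EI = 0 below
  it), the documented role of a per-generation thermal sum.
- **No wet stress, no diapause, no species-interaction or irrigation
  scenarios**: the species table defines no parameters for them; SM3 enters
  only through the moisture trapezoid.
- **Class boundary**: EI exactly 30 is classed "high", so the three classes
  partition [0, 100]. (The source material is ambiguous between "above 30"
  and "30 < EI < 100".)

Trapezoids are exact at their four breakpoints (0, 1, 1, 0) and linear on
the ramps; the engine and the tests treat these as identities, not
approximations.

## Weekly resampling

Stress rates are per week, so monthly normals are resampled to a 52-week,
364-day year: each variable is interpolated linearly between consecutive
month midpoints (months taken as equal twelfths of the year, December
wrapping to January), and weekly precipitation is rescaled per cell so the
52-week total equals the annual monthly total exactly. Linear interpolation
makes the temperature shift of a scenario transform commute with
resampling, which the tests exploit.

## Soil moisture

A single-bucket weekly water balance, spun up to a periodic steady state:

```
E_w  = et_coefficient · max(0, tmean_w) · (1.05 − rh_w)      [mm·week⁻¹]
SM_w = clip(SM_{w−1} + (P_w − E_w)/capacity, 0, ceiling)
```

Defaults: capacity 100 mm, et_coefficient 2 mm·week⁻¹·°C⁻¹ (≈ 25 mm·week⁻¹
of demand at 25 °C and 60% humidity — a mid-range warm-climate
evapotranspiration), initial SM 0.5, at most 50 spin-up years, convergence
when the annual cycle changes by < 10⁻⁶ week-wise (non-convergence warns
and returns the last cycle). The `1.05 − rh` form keeps a small vapour
deficit even at saturation.

The bucket **ceiling defaults to 1.0** (holding capacity; surplus is
runoff). The species' upper moisture limits (SM2 = 8, SM3 = 10) are far
above any physical bucket state, i.e. wet conditions never limit this
species; a saturating bucket that rode up to SM3 would invert that intent
by zeroing the moisture index in the wettest cells. Raising `ceiling`
re-activates the upper trapezoid limbs, which stay implemented and tested.

## Synthetic study conditions

The generator emulates the *structure* of a 1961–1990 gridded climatology,
not its marginals: monthly mean temperature
`T = 27 − 0.55·|lat| + 0.35·|lat|·cos(2π(m − m_peak)/12) + N(0, 0.5²)` °C
with the warmest month in January south of the equator and July north of
it; tmin/tmax at ±5 °C around the mean (noise enters the mean only, so
tmin ≤ tmax holds by construction); precipitation in three latitude bands
(wet tropics 150 mm·month⁻¹ below 15°, dry subtropics 20 mm·month⁻¹ to
35°, moderate temperate 60 mm·month⁻¹ poleward); humidity fixed at
0.75/0.55 for the two observation times. This produces the qualitative
regimes the analysis needs — a moisture-limited subtropical band, a
cold- and degree-day-limited high-latitude zone, and a suitable tropical
core — with seeded, bit-reproducible output.

Occurrence points are sampled over land cells with probability ∝
EI^weighting (default exponent 1), a 5% uniform contamination fraction by
default, and ≤ 5 km within-cell jitter truncated at the cell boundary —
emulating aggregated presence records that concentrate where the species
thrives but include stray records.

What passing tests on this world do **not** show: agreement with real
climatologies' spatial autocorrelation, orography, coastlines, humidity
seasonality, or the true global class shares; published global percentages
are not reproducible from synthetic grids and are not asserted anywhere.
Tests show structural correctness (formulas, invariants, directions,
determinism), and the directional results — e.g. raising the cold-stress
threshold never shrinking the unsuitable area, warming never increasing
accumulated cold stress — mirror the qualitative pattern reported for the
real analysis.

## Sensitivity protocol

One parameter at a time, 15 parameters × {low, high}: temperatures ±1 °C,
moisture/rate parameters ±10% (for the negative rates THCS and HDS, "high"
is the larger magnitude, i.e. more stressful), degree-days ±20 °C·days.
Area shares are cos(latitude)-weighted (equal-angle cells shrink poleward;
raw counts are also available via `weighted=False`), and "change" is
reported in percentage points of class share. The weekly climate and
soil-moisture spin-up are computed once and shared across all 30 runs —
they do not depend on species parameters — so the full analysis on a
36×72 grid takes seconds.

With linear stress accumulation, perturbing a stress threshold only flips a
cell's *class* when stress saturates (CS = 100) or EI crosses a class
boundary; on smooth synthetic worlds the share deltas are therefore often
exactly 0, and the tests assert the direction inequalities plus a
constructed cold-marginal case where the flip provably occurs.

## Scenario projection

A scenario is a uniform transform: `delta_t` added to tmin and tmax,
`precip_scale` on precipitation, humidity unchanged (no humidity delta is
published for the underlying projection). The full-century change is
+2.11 °C and ×0.86 precipitation; the 2050/2080/2100 defaults scale that
change linearly in time from the 1975-centred baseline (fractions 0.60,
0.84, 1.00). The linear time-scaling is this package's stand-in — the
underlying per-year model fields are not published — and is fully
configurable per run.

## Occurrences

Thinning is greedy over records sorted by (lat, lon, species): keep a
record iff its haversine distance (sphere radius 6371 km) to every
previously kept record exceeds the radius (10 km default). Greedy-by-
sorted-order is deterministic and idempotent; the exact algorithm behind
published record counts is unknowable, so counts are compared only against
this package's own oracle. Overlay assigns each point to the nearest cell
centre (longitude treated as periodic at ±180°) and counts it only when
within half the median cell spacing on both axes; farther points are
reported separately as outside the grid.

## Numerical notes

- All randomness flows through `numpy.random.default_rng(seed)`; identical
  spec + seed ⇒ bit-identical grids and point sets.
- The vectorised engine is verified element-wise (rtol = atol = 1e-10)
  against an independent pure-Python per-cell reference on a 500-cell
  seeded grid; the reference shares no code with the engine.
- GeoTIFF export (optional) writes a 3-band float32 raster (EI, class
  code, CS) with EPSG:4326 geokeys and pixel-is-area georeferencing so
  cell centres land exactly on the grid's lat/lon; it requires a complete
  regular grid and errors otherwise.
- RH columns read from CSV with values > 1.5 are auto-interpreted as
  percent and divided by 100.
- Degenerate suitability exponents (EI^weighting overflowing to ∞)
  collapse sampling onto the maximum-EI cells, matching the limit.

## Limitations

- Not bit-compatible with closed-source implementations: stress magnitudes
  and therefore absolute EI values differ; thresholds, bounds, directions
  and class semantics are preserved.
- The soil-moisture model is a single bucket with a linear
  temperature-humidity demand term; no radiation, soil texture or snow.
- Uniform scenario deltas ignore regional and seasonal structure of real
  climate projections.
- Equal-twelfth month midpoints introduce sub-day phase error relative to
  calendar months; immaterial at weekly resolution.
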