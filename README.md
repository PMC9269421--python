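# ecoclimex

Mechanistic ("CLIMEX-style") climate-suitability modelling for invasive
species, parameterised by default for the pasture weed *Urochloa panicoides*
— with a one-at-a-time parameter sensitivity analysis, uniform
climate-change scenario projection, occurrence-record thinning and map
overlay, and a seeded synthetic-climate generator so every stage runs
offline and reproducibly.

## Who this is for

Ecologists and weed-risk analysts who want a transparent, fully tested
implementation of the ecoclimatic-index workflow: the commercial tool
usually used for this kind of analysis is closed source, so published
parameter tables cannot be re-run, probed or extended. `ecoclimex`
re-implements the model structure openly. It is **not** a bit-exact clone of
any commercial implementation (whose internal equations are unpublished);
it is the standard model family stated explicitly and testably.

## The model

A species is described by 15 parameters. Per grid cell, monthly climate
normals (tmin, tmax, precipitation, 09:00/15:00 relative humidity) are
interpolated to a 52-week year, and each week gets:

- a **temperature index** `TI_w`, a trapezoid on (DV0, DV1, DV2, DV3) —
  0 at the limiting temperatures, 1 on the optimal plateau [DV1, DV2];
- a **moisture index** `MI_w`, the same trapezoid shape on
  (SM0, SM1, SM2, SM3), driven by a weekly soil-moisture bucket
  `SM_w = clip(SM_{w−1} + (P_w − E_w)/capacity, 0, ceiling)` spun up to a
  converged annual cycle;
- **stress accumulation**: cold `CS = min(100, 100·Σ_w |THCS|·max(0, TTCS − tmin_w))`,
  heat `HS = min(100, 100·Σ_w THHS·max(0, tmax_w − TTHS))`, and dry
  `DS = min(100, 100·Σ_w |HDS|·1[SM_w < SMDS])`.

Annually these combine into the growth index
`GI_A = 100·Σ_w TI_w·MI_w / 52`, the stress index
`SI = (1 − CS/100)(1 − HS/100)(1 − DS/100)`, and degree-days
`DD = Σ_w 7·max(0, tmean_w − DV0)`. The **Ecoclimatic Index** is

```
EI = GI_A · SI        if DD ≥ PPD   (population can complete a generation)
EI = 0                otherwise
```

mapped to three classes: `EI = 0` unsuitable, `0 < EI < 30` low
suitability, `EI ≥ 30` high suitability.

Default parameters (*U. panicoides*): DV0=4 °C, DV1=25, DV2=35, DV3=45;
SM0=0.1, SM1=0.2, SM2=8, SM3=10; TTCS=4 °C, THCS=−0.002 week⁻¹, TTHS=45 °C,
THHS=0.02 week⁻¹, SMDS=0.1, HDS=−0.01 week⁻¹, PPD=1517 °C·days.

## Worked example

```sh
ecoclimex generate --nlat 24 --nlon 48 --seed 1 --out-dir demo
ecoclimex run --climate demo/climate.csv --occurrences demo/occurrences.csv \
              --seed 1 --out-dir demo
```

The first command writes a synthetic climate grid (`demo/climate.csv`,
24·48·12 = 13 824 cell-month rows) and 730 occurrence points sampled
proportionally to suitability. The second thins the points at 10 km,
computes the map and overlay, and logs:

```
INFO wrote demo/suitability.csv (1152 cells)
INFO thinned occurrences 730 -> 257 at 10.0 km
INFO overlay: high=77.43% low=13.23% unsuitable=9.34%
```

`suitability.csv` holds `lat, lon, EI, class, GI_A, CS, HS, DS, DD` per
cell, headed by `# seed=…` and the full parameter vector. The overlay
shares say where the (synthetic) occurrence records fall on the map — the
usual validation that a model covers the known range: here ~77% of points
sit in high-suitability cells even though that class covers only ~26% of
the land area (`ecoclimex.area_shares`), because the points were sampled
preferentially by EI.

Other subcommands: `sensitivity` (30 perturbed runs: 15 parameters × low/
high, area-share change per class in percentage points), `scenario`
(projections for 2050/2080/2100, defaults scaled from the +2.11 °C / −14 %
precipitation full-century change, or `--delta-t/--precip-scale` for a
custom transform), `thin` and `overlay` standalone. Python API: see
`ecoclimex.run_grid`, `run_sensitivity`, `run_scenarios`.

To probe the documented text-vs-table discrepancy in the published dry
stress threshold, override it: `ecoclimex run … --param SMDS=0.01`.

## Layout

- `src/ecoclimex/params.py` — species parameters, validation, config I/O
- `src/ecoclimex/climate.py` — grid containers, CSV/GeoTIFF I/O, weekly
  interpolation, scenario transforms
- `src/ecoclimex/engine.py` — indices, soil-moisture bucket, stress, EI
- `src/ecoclimex/occurrences.py` — thinning and overlay statistics
- `src/ecoclimex/sensitivity.py` — perturbation protocol, area shares,
  scenario runner
- `src/ecoclimex/synthetic.py` — seeded synthetic climate and occurrences
- `src/ecoclimex/cli.py` — the `ecoclimex` command
- `docs/methods.md` — model assumptions, numerical choices, limitations
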