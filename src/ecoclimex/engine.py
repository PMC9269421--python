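"""The ecoclimatic-index engine.

Given a weekly climate series for each grid cell, the engine computes

* a weekly temperature index ``TI_w`` and moisture index ``MI_w``, each a
  trapezoidal response on (DV0, DV1, DV2, DV3) and (SM0, SM1, SM2, SM3);
* the annual growth index ``GI_A = 100 · mean_w(TI_w · MI_w)``;
* accumulated cold, heat and dry stress (CS, HS, DS), each a weekly
  threshold-exceedance sum scaled by the species rate and capped at 100;
* annual degree-days above DV0 (``DD``), gating persistence against PPD;
* the Ecoclimatic Index ``EI = GI_A · (1 − CS/100)(1 − HS/100)(1 − DS/100)``,
  forced to 0 where ``DD < PPD``, and its three-class label
  (EI = 0 unsuitable, 0 < EI < 30 low, EI ≥ 30 high).

Stress accumulation here is linear in the weekly exceedance: temperature
stresses weight each week by the number of degrees beyond the threshold
(mode ``"magnitude"``), dry stress counts weeks spent below the soil-moisture
threshold (mode ``"occupancy"``, the default, because moisture deficits are
bounded in [0, SMDS]). Both modes are available for every stress.

All operations are vectorised over cells; scalars and 1-D series work too.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .climate import (
    CLASS_NAMES,
    ClimateGrid,
    N_WEEKS,
    DAYS_PER_WEEK,
    WeeklyClimate,
    monthly_to_weekly,
)
from .params import SoilMoistureConfig, SpeciesParameters, ValidationError

EI_HIGH_THRESHOLD = 30.0

__all__ = [
    "EI_HIGH_THRESHOLD",
    "CellAnnualResult",
    "SuitabilityMap",
    "temperature_index",
    "moisture_index",
    "soil_moisture_series",
    "annual_growth_index",
    "cold_stress",
    "heat_stress",
    "dry_stress",
    "degree_days",
    "ecoclimatic_index",
    "classify",
    "prepare_weekly",
    "evaluate",
    "run_grid",
]


def _trapezoid(x: np.ndarray, lo: float, opt_lo: float, opt_hi: float, hi: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    rising = (x > lo) & (x < opt_lo)
    out[rising] = (x[rising] - lo) / (opt_lo - lo)
    out[(x >= opt_lo) & (x <= opt_hi)] = 1.0
    falling = (x > opt_hi) & (x < hi)
    out[falling] = (hi - x[falling]) / (hi - opt_hi)
    return out


def temperature_index(tmean, p: SpeciesParameters) -> np.ndarray:
    """Trapezoidal temperature response on (DV0, DV1, DV2, DV3); 1 on the optimal plateau."""
    return _trapezoid(tmean, p.DV0, p.DV1, p.DV2, p.DV3)


def moisture_index(sm, p: SpeciesParameters) -> np.ndarray:
    """Trapezoidal soil-moisture response on (SM0, SM1, SM2, SM3)."""
    return _trapezoid(sm, p.SM0, p.SM1, p.SM2, p.SM3)


def weekly_evapotranspiration(tmean, rh, cfg: SoilMoistureConfig) -> np.ndarray:
    """Weekly evaporative demand: et_coefficient · max(0, tmean) · (1.05 − rh), mm·week⁻¹."""
    tmean = np.asarray(tmean, dtype=float)
    rh = np.asarray(rh, dtype=float)
    return cfg.et_coefficient * np.maximum(0.0, tmean) * (1.05 - rh)


def soil_moisture_series(
    precip: np.ndarray,
    tmean: np.ndarray,
    rh: np.ndarray,
    cfg: SoilMoistureConfig,
) -> np.ndarray:
    """Converged annual soil-moisture cycle from a weekly bucket model.

    The bucket updates as ``SM_w = clip(SM_{w-1} + (P_w − E_w)/capacity, 0,
    ceiling)`` with evaporative demand ``E_w`` from
    :func:`weekly_evapotranspiration`. The annual cycle is iterated from
    ``initial_sm`` for up to ``spinup_years`` years until the largest weekly
    change between consecutive years falls below 1e-6; a warning is issued on
    non-convergence and the last cycle returned.

    Accepts ``(52,)`` series or ``(n_cells, 52)`` arrays.
    """
    precip = np.asarray(precip, dtype=float)
    squeeze = precip.ndim == 1
    precip = np.atleast_2d(precip)
    tmean = np.atleast_2d(np.asarray(tmean, dtype=float))
    rh = np.atleast_2d(np.asarray(rh, dtype=float))
    if precip.shape[1] != N_WEEKS:
        raise ValidationError(f"expected {N_WEEKS} weekly values, got {precip.shape[1]}")
    net = (precip - weekly_evapotranspiration(tmean, rh, cfg)) / cfg.capacity

    sm_prev = np.full(precip.shape[0], cfg.initial_sm)
    cycle = np.empty_like(precip)
    last_cycle = None
    converged = False
    for _ in range(cfg.spinup_years):
        for w in range(N_WEEKS):
            sm_prev = np.clip(sm_prev + net[:, w], 0.0, cfg.ceiling)
            cycle[:, w] = sm_prev
        if last_cycle is not None and np.max(np.abs(cycle - last_cycle)) < 1e-6:
            converged = True
            break
        last_cycle = cycle.copy()
    if not converged and cfg.spinup_years > 1:
        warnings.warn(
            "soil-moisture spin-up did not converge within "
            f"{cfg.spinup_years} years; returning the last annual cycle",
            RuntimeWarning,
            stacklevel=2,
        )
    return cycle[0] if squeeze else cycle


def annual_growth_index(TI_w: np.ndarray, MI_w: np.ndarray) -> np.ndarray:
    """GI_A = 100 · Σ_w (TI_w · MI_w) / 52, on [0, 100]."""
    TI_w = np.asarray(TI_w, dtype=float)
    MI_w = np.asarray(MI_w, dtype=float)
    if TI_w.shape != MI_w.shape:
        raise ValidationError(f"TI/MI length mismatch: {TI_w.shape} vs {MI_w.shape}")
    return 100.0 * (TI_w * MI_w).sum(axis=-1) / N_WEEKS


def _accumulate(excess: np.ndarray, rate: float, mode: str) -> np.ndarray:
    if mode == "magnitude":
        weekly = abs(rate) * excess
    elif mode == "occupancy":
        weekly = abs(rate) * (excess > 0)
    else:
        raise ValidationError(f"unknown stress mode {mode!r}")
    return np.minimum(100.0, 100.0 * weekly.sum(axis=-1))


def cold_stress(tmin_w, p: SpeciesParameters, mode: str = "magnitude") -> np.ndarray:
    """Accumulated cold stress from weekly minima below TTCS, scaled by |THCS|, capped at 100."""
    deficit = np.maximum(0.0, p.TTCS - np.asarray(tmin_w, dtype=float))
    return _accumulate(deficit, p.THCS, mode)


def heat_stress(tmax_w, p: SpeciesParameters, mode: str = "magnitude") -> np.ndarray:
    """Accumulated heat stress from weekly maxima above TTHS, scaled by THHS, capped at 100."""
    excess = np.maximum(0.0, np.asarray(tmax_w, dtype=float) - p.TTHS)
    return _accumulate(excess, p.THHS, mode)


def dry_stress(sm_w, p: SpeciesParameters, mode: str = "occupancy") -> np.ndarray:
    """Accumulated dry stress from weeks with soil moisture below SMDS, scaled by |HDS|."""
    deficit = np.maximum(0.0, p.SMDS - np.asarray(sm_w, dtype=float))
    return _accumulate(deficit, p.HDS, mode)


def degree_days(tmean_w, p: SpeciesParameters) -> np.ndarray:
    """Annual thermal sum above DV0: DD = Σ_w 7 · max(0, tmean_w − DV0), °C·days."""
    above = np.maximum(0.0, np.asarray(tmean_w, dtype=float) - p.DV0)
    return DAYS_PER_WEEK * above.sum(axis=-1)


def ecoclimatic_index(GI_A, CS, HS, DS, DD, p: SpeciesParameters) -> np.ndarray:
    """Combine growth and stress, gate on degree-day persistence, clamp to [0, 100]."""
    GI_A = np.asarray(GI_A, dtype=float)
    SI = (1.0 - np.asarray(CS) / 100.0) * (1.0 - np.asarray(HS) / 100.0) * (1.0 - np.asarray(DS) / 100.0)
    ei = GI_A * SI
    ei = np.where(np.asarray(DD) >= p.PPD, ei, 0.0)
    return np.clip(ei, 0.0, 100.0)


def classify(EI) -> np.ndarray:
    """Map EI to its suitability class: 0 → unsuitable, (0, 30) → low, ≥ 30 → high."""
    ei = np.asarray(EI, dtype=float)
    if np.any((ei < 0) | (ei > 100)):
        raise ValidationError("EI outside [0, 100]")
    out = np.where(ei == 0.0, CLASS_NAMES[0], np.where(ei < EI_HIGH_THRESHOLD, CLASS_NAMES[1], CLASS_NAMES[2]))
    return out


@dataclass
class CellAnnualResult:
    """Weekly indices and annual summaries for the cells of one run."""

    TI_w: np.ndarray
    MI_w: np.ndarray
    GI_w: np.ndarray
    SM_w: np.ndarray
    GI_A: np.ndarray
    CS: np.ndarray
    HS: np.ndarray
    DS: np.ndarray
    SI: np.ndarray
    DD: np.ndarray
    EI: np.ndarray


@dataclass
class SuitabilityMap:
    """Per-cell EI, component indices and 3-class label on the source grid."""

    lat: np.ndarray
    lon: np.ndarray
    land: np.ndarray
    EI: np.ndarray
    classes: np.ndarray
    GI_A: np.ndarray
    CS: np.ndarray
    HS: np.ndarray
    DS: np.ndarray
    DD: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.lat.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lat": self.lat,
                "lon": self.lon,
                "EI": self.EI,
                "class": self.classes,
                "GI_A": self.GI_A,
                "CS": self.CS,
                "HS": self.HS,
                "DS": self.DS,
                "DD": self.DD,
                "land": self.land,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SuitabilityMap":
        land = df["land"].to_numpy(dtype=bool) if "land" in df.columns else np.ones(len(df), dtype=bool)
        return cls(
            lat=df["lat"].to_numpy(dtype=float),
            lon=df["lon"].to_numpy(dtype=float),
            land=land,
            EI=df["EI"].to_numpy(dtype=float),
            classes=df["class"].to_numpy(dtype=str),
            GI_A=df["GI_A"].to_numpy(dtype=float),
            CS=df["CS"].to_numpy(dtype=float),
            HS=df["HS"].to_numpy(dtype=float),
            DS=df["DS"].to_numpy(dtype=float),
            DD=df["DD"].to_numpy(dtype=float),
        )


@dataclass
class PreparedClimate:
    """Weekly climate plus the converged soil-moisture cycle.

    Soil moisture depends only on climate and the bucket configuration, not
    on the species, so one prepared object serves every parameter
    perturbation of a sensitivity analysis.
    """

    weekly: WeeklyClimate
    SM_w: np.ndarray


def prepare_weekly(grid: ClimateGrid, cfg: SoilMoistureConfig) -> PreparedClimate:
    weekly = monthly_to_weekly(grid)
    sm = soil_moisture_series(weekly.precip, weekly.tmean, weekly.rh, cfg)
    return PreparedClimate(weekly=weekly, SM_w=np.atleast_2d(sm))


def evaluate(prepared: PreparedClimate, p: SpeciesParameters) -> tuple[SuitabilityMap, CellAnnualResult]:
    """Run the species response on prepared weekly climate."""
    wk = prepared.weekly
    TI = temperature_index(wk.tmean, p)
    MI = moisture_index(prepared.SM_w, p)
    GI_w = TI * MI
    GI_A = 100.0 * GI_w.sum(axis=1) / N_WEEKS
    CS = cold_stress(wk.tmin, p)
    HS = heat_stress(wk.tmax, p)
    DS = dry_stress(prepared.SM_w, p)
    DD = degree_days(wk.tmean, p)
    SI = (1 - CS / 100.0) * (1 - HS / 100.0) * (1 - DS / 100.0)
    EI = ecoclimatic_index(GI_A, CS, HS, DS, DD, p)
    result = CellAnnualResult(
        TI_w=TI, MI_w=MI, GI_w=GI_w, SM_w=prepared.SM_w,
        GI_A=GI_A, CS=CS, HS=HS, DS=DS, SI=SI, DD=DD, EI=EI,
    )
    smap = SuitabilityMap(
        lat=wk.lat, lon=wk.lon, land=wk.land,
        EI=EI, classes=classify(EI),
        GI_A=GI_A, CS=CS, HS=HS, DS=DS, DD=DD,
    )
    return smap, result


def run_grid(
    grid: ClimateGrid,
    p: SpeciesParameters | None = None,
    cfg: SoilMoistureConfig | None = None,
) -> SuitabilityMap:
    """Full pipeline: monthly grid → weekly climate → soil moisture → EI map.

    Cells are processed independently; output order matches input order.
    """
    p = p or SpeciesParameters()
    cfg = cfg or SoilMoistureConfig()
    prepared = prepare_weekly(grid, cfg)
    smap, _ = evaluate(prepared, p)
    return smap
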