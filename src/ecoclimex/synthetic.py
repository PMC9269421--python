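"""Seeded synthetic climate grids and occurrence samples.

Real applications of this kind of model run on interpolated 10-arc-minute
global climatologies and curated occurrence downloads. This module builds
structurally similar stand-ins from first principles so the whole pipeline is
exercisable offline: temperature falls linearly with |latitude| and cycles
seasonally with a hemisphere-dependent phase (warmest month January in the
south, July in the north), precipitation follows three latitude bands (wet
tropics, dry subtropics, moderate temperate), and humidity is a fixed
morning/afternoon pair. Occurrences are drawn over grid cells with
probability proportional to a power of the Ecoclimatic Index, optionally
contaminated with uniform background points.

Only the qualitative structure — gradients, seasonality, bands — is meant to
match real climatologies, not their marginal distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climate import ClimateGrid
from .occurrences import OccurrenceSet
from .params import ValidationError

MONTHS = np.arange(1, 13)
_KM_PER_DEG_LAT = 111.32


@dataclass(frozen=True)
class PrecipRegime:
    """Banded monthly precipitation profile (mm·month⁻¹) by |latitude|."""

    wet_tropics: float = 150.0      # |lat| < tropics_edge
    dry_subtropics: float = 20.0    # tropics_edge <= |lat| < subtropics_edge
    moderate_temperate: float = 60.0
    tropics_edge: float = 15.0
    subtropics_edge: float = 35.0

    def __post_init__(self) -> None:
        for name in ("wet_tropics", "dry_subtropics", "moderate_temperate"):
            if getattr(self, name) < 0:
                raise ValidationError(f"precipitation level {name} must be >= 0")

    def monthly(self, abs_lat: np.ndarray) -> np.ndarray:
        return np.where(
            abs_lat < self.tropics_edge,
            self.wet_tropics,
            np.where(abs_lat < self.subtropics_edge, self.dry_subtropics, self.moderate_temperate),
        )


@dataclass(frozen=True)
class SyntheticClimateSpec:
    """Recipe for a rectangular lat/lon grid of monthly climate normals."""

    n_lat: int = 36
    n_lon: int = 72
    lat_range: tuple[float, float] = (-87.5, 87.5)
    equator_mean_temp: float = 27.0
    lapse_per_degree_lat: float = 0.55
    seasonal_amplitude_per_degree_lat: float = 0.35
    diurnal_range: float = 10.0
    precip_regime: PrecipRegime = field(default_factory=PrecipRegime)
    humidity_base: float = 0.65
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lat < 2:
            raise ValidationError(f"n_lat must be >= 2, got {self.n_lat}")
        if self.n_lon < 1:
            raise ValidationError(f"n_lon must be >= 1, got {self.n_lon}")
        lo, hi = self.lat_range
        if not (-90 <= lo < hi <= 90):
            raise ValidationError(f"lat_range must be increasing within [-90, 90], got {self.lat_range}")
        if self.diurnal_range < 0:
            raise ValidationError(f"diurnal_range must be >= 0, got {self.diurnal_range}")
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0 <= self.humidity_base <= 1:
            raise ValidationError(f"humidity_base must be in [0, 1], got {self.humidity_base}")


def generate_climate_grid(spec: SyntheticClimateSpec) -> ClimateGrid:
    """Build the monthly climate grid described by ``spec``.

    The monthly mean temperature of a cell at latitude φ in month m is

        T(φ, m) = equator_mean_temp − lapse·|φ|
                  + amplitude·|φ|·cos(2π (m − m_peak)/12) + ε,

    with m_peak = 7 (July) for φ ≥ 0 and 1 (January) for φ < 0 and
    ε ~ N(0, noise_sd²) seeded by ``spec.seed``. tmin/tmax sit half the
    diurnal range below/above the mean, so tmin ≤ tmax by construction.
    """
    rng = np.random.default_rng(spec.seed)
    lats = np.linspace(spec.lat_range[0], spec.lat_range[1], spec.n_lat)
    lons = np.linspace(-180.0, 180.0, spec.n_lon, endpoint=False)
    lat = np.repeat(lats, spec.n_lon)
    lon = np.tile(lons, spec.n_lat)
    n = lat.size

    abs_lat = np.abs(lat)[:, None]
    peak_month = np.where(lat >= 0, 7.0, 1.0)[:, None]
    phase = np.cos(2.0 * np.pi * (MONTHS[None, :] - peak_month) / 12.0)
    tmean = (
        spec.equator_mean_temp
        - spec.lapse_per_degree_lat * abs_lat
        + spec.seasonal_amplitude_per_degree_lat * abs_lat * phase
    )
    if spec.noise_sd > 0:
        tmean = tmean + rng.normal(0.0, spec.noise_sd, size=(n, 12))

    tmin = tmean - spec.diurnal_range / 2.0
    tmax = tmean + spec.diurnal_range / 2.0
    precip = np.broadcast_to(spec.precip_regime.monthly(np.abs(lat))[:, None], (n, 12)).copy()
    rh09 = np.full((n, 12), min(1.0, spec.humidity_base + 0.10))
    rh15 = np.full((n, 12), max(0.0, spec.humidity_base - 0.10))
    return ClimateGrid(lat=lat, lon=lon, tmin=tmin, tmax=tmax, precip=precip, rh09=rh09, rh15=rh15)


@dataclass(frozen=True)
class OccurrenceSamplingSpec:
    """Recipe for sampling occurrence points from a suitability map."""

    n_points: int = 730
    suitability_weighting: float = 1.0
    contamination_fraction: float = 0.05
    jitter_km: float = 5.0
    seed: int = 0
    species: str = "Urochloa panicoides"

    def __post_init__(self) -> None:
        if self.n_points < 0:
            raise ValidationError(f"n_points must be >= 0, got {self.n_points}")
        if not 0 <= self.contamination_fraction <= 1:
            raise ValidationError(
                f"contamination_fraction must be in [0, 1], got {self.contamination_fraction}"
            )
        if self.jitter_km < 0:
            raise ValidationError(f"jitter_km must be >= 0, got {self.jitter_km}")


class UnsampleableError(ValidationError):
    """Raised when occurrence sampling is requested from an all-zero suitability map."""


def _cell_spacing(values: np.ndarray) -> float:
    uniq = np.unique(values)
    if uniq.size < 2:
        return 1.0
    return float(np.median(np.diff(uniq)))


def sample_occurrences(smap, spec: OccurrenceSamplingSpec) -> OccurrenceSet:
    """Draw occurrence points over land cells, weighted by EI^weighting.

    A ``contamination_fraction`` share of points is instead drawn uniformly
    over land cells, emulating misidentified or casual records. Points are
    jittered uniformly within ``±jitter_km`` of the cell centre, truncated to
    stay inside the cell.
    """
    rng = np.random.default_rng(spec.seed)
    land = np.flatnonzero(smap.land)
    if land.size == 0:
        raise UnsampleableError("no land cells to sample from")
    ei = smap.EI[land]

    n_contam = int(round(spec.n_points * spec.contamination_fraction))
    n_suit = spec.n_points - n_contam
    if n_suit > 0 and not np.any(ei > 0):
        raise UnsampleableError("all-zero EI map: cannot sample suitability-weighted points")

    chosen = []
    if n_suit > 0:
        with np.errstate(over="ignore"):
            w = np.power(ei, spec.suitability_weighting, where=ei > 0, out=np.zeros_like(ei))
        if not np.all(np.isfinite(w)):  # degenerate large exponents: keep only the max-EI cells
            w = (ei == ei.max()).astype(float)
        chosen.append(rng.choice(land, size=n_suit, p=w / w.sum()))
    if n_contam > 0:
        chosen.append(rng.choice(land, size=n_contam))
    idx = np.concatenate(chosen) if chosen else np.empty(0, dtype=int)

    lat = smap.lat[idx]
    lon = smap.lon[idx]
    if idx.size:
        half_lat = _cell_spacing(smap.lat) / 2.0
        half_lon = _cell_spacing(smap.lon) / 2.0
        jlat = np.minimum(spec.jitter_km / _KM_PER_DEG_LAT, half_lat)
        km_per_deg_lon = np.maximum(_KM_PER_DEG_LAT * np.cos(np.radians(lat)), 1e-6)
        jlon = np.minimum(spec.jitter_km / km_per_deg_lon, half_lon)
        lat = lat + rng.uniform(-jlat, jlat, size=idx.size)
        lon = lon + rng.uniform(-jlon, jlon, size=idx.size)
        lat = np.clip(lat, -90.0, 90.0)
        lon = ((lon + 180.0) % 360.0) - 180.0

    df = pd.DataFrame({"species": spec.species, "lat": lat, "lon": lon})
    return OccurrenceSet(df, provenance=f"synthetic seed={spec.seed}")
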