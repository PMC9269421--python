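"""Gridded climate containers, CSV I/O, weekly interpolation and scenario transforms.

The canonical exchange format is a long CSV with one row per cell-month and
columns ``lat, lon, month, tmin, tmax, precip, rh09, rh15`` (an optional
boolean ``land`` column is honoured wherever area shares are computed).
Internally a :class:`ClimateGrid` stores one ``(n_cells, 12)`` array per
variable; :func:`monthly_to_weekly` resamples the monthly normals onto a
364-day, 52-week year so that weekly stress-accumulation rates apply.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .params import ValidationError

N_WEEKS = 52
DAYS_PER_WEEK = 7.0

CLIMATE_COLUMNS = ["lat", "lon", "month", "tmin", "tmax", "precip", "rh09", "rh15"]
_VARIABLES = ["tmin", "tmax", "precip", "rh09", "rh15"]

CLASS_NAMES = ("unsuitable", "low", "high")
CLASS_CODES = {name: code for code, name in enumerate(CLASS_NAMES)}


@dataclass
class ClimateGrid:
    """Per-cell monthly climate normals.

    Arrays are aligned on the cell axis: ``lat``/``lon`` have shape
    ``(n_cells,)`` and each variable has shape ``(n_cells, 12)`` with month 1
    in column 0. ``land`` marks cells that participate in area statistics.
    """

    lat: np.ndarray
    lon: np.ndarray
    tmin: np.ndarray
    tmax: np.ndarray
    precip: np.ndarray
    rh09: np.ndarray
    rh15: np.ndarray
    land: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        n = self.lat.shape[0]
        for name in _VARIABLES:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n, 12):
                raise ValidationError(f"{name} must have shape ({n}, 12), got {arr.shape}")
            setattr(self, name, arr)
        if self.land is None:
            self.land = np.ones(n, dtype=bool)
        else:
            self.land = np.asarray(self.land, dtype=bool)
        self.validate()

    @property
    def n_cells(self) -> int:
        return self.lat.shape[0]

    def validate(self) -> None:
        if self.n_cells == 0:
            raise ValidationError("climate grid has no cells")
        if np.any((self.lat < -90) | (self.lat > 90)):
            raise ValidationError("latitude outside [-90, 90]")
        if np.any((self.lon < -180) | (self.lon >= 180)):
            raise ValidationError("longitude outside [-180, 180)")
        cells = np.column_stack([self.lat, self.lon])
        if np.unique(cells, axis=0).shape[0] != self.n_cells:
            raise ValidationError("duplicate (lat, lon) cells")
        bad = np.argwhere(self.tmin > self.tmax)
        if bad.size:
            i, m = bad[0]
            raise ValidationError(
                f"tmin > tmax at cell (lat={self.lat[i]}, lon={self.lon[i]}), month {m + 1}"
            )
        if np.any(self.precip < 0):
            raise ValidationError("negative precipitation")
        for name in ("rh09", "rh15"):
            arr = getattr(self, name)
            if np.any((arr < 0) | (arr > 1)):
                raise ValidationError(f"{name} outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame in the canonical column order."""
        n = self.n_cells
        months = np.tile(np.arange(1, 13), n)
        df = pd.DataFrame(
            {
                "lat": np.repeat(self.lat, 12),
                "lon": np.repeat(self.lon, 12),
                "month": months,
                "tmin": self.tmin.ravel(),
                "tmax": self.tmax.ravel(),
                "precip": self.precip.ravel(),
                "rh09": self.rh09.ravel(),
                "rh15": self.rh15.ravel(),
            }
        )
        if not self.land.all():
            df["land"] = np.repeat(self.land, 12)
        return df


@dataclass
class WeeklyClimate:
    """52-week climate per cell, interpolated from monthly normals.

    ``precip`` is mm·week⁻¹ and conserves each cell's annual total;
    ``rh`` is the mean of the 09:00 and 15:00 relative humidities.
    """

    lat: np.ndarray
    lon: np.ndarray
    tmin: np.ndarray
    tmax: np.ndarray
    tmean: np.ndarray
    precip: np.ndarray
    rh: np.ndarray
    land: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.lat.shape[0]


@dataclass(frozen=True)
class ScenarioTransform:
    """Uniform climate-change delta: additive on temperature, multiplicative on precipitation."""

    delta_t: float = 0.0
    precip_scale: float = 1.0
    label: str = "scenario"

    def __post_init__(self) -> None:
        if self.precip_scale < 0:
            raise ValidationError(f"precip_scale must be >= 0, got {self.precip_scale}")


# The CSIRO-Mk3.0 / SRES A2 projection summarised as +2.11 °C and -14%
# precipitation by 2100; 2050 and 2080 defaults scale that full change
# linearly in time from the 1975-centred baseline.
CS_A2_FULL_DELTA_T = 2.11
CS_A2_FULL_PRECIP_SCALE = 0.86


def default_scenarios() -> list[ScenarioTransform]:
    out = []
    for label, frac in (("2050", 0.60), ("2080", 0.84), ("2100", 1.00)):
        out.append(
            ScenarioTransform(
                delta_t=round(frac * CS_A2_FULL_DELTA_T, 4),
                precip_scale=round(1.0 - frac * (1.0 - CS_A2_FULL_PRECIP_SCALE), 4),
                label=label,
            )
        )
    return out


def _frame_to_grid(df: pd.DataFrame, source: str = "<frame>") -> ClimateGrid:
    missing = [c for c in CLIMATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{source}: missing column(s) {missing}")
    if df.empty:
        raise ValidationError(f"{source}: no data rows")
    bad = df[CLIMATE_COLUMNS].isna().any(axis=1)
    if bad.any():
        rows = df.loc[bad, ["lat", "lon", "month"]].head(5).to_dict("records")
        raise ValidationError(f"{source}: rows with missing values, e.g. {rows}")
    df = df.copy()
    df["month"] = df["month"].astype(int)
    if not df["month"].between(1, 12).all():
        raise ValidationError(f"{source}: month outside 1..12")

    dup = df.duplicated(subset=["lat", "lon", "month"])
    if dup.any():
        row = df.loc[dup, ["lat", "lon", "month"]].iloc[0].to_dict()
        raise ValidationError(f"{source}: duplicate cell-month {row}")

    # preserve first-appearance cell order
    cell_key = df.groupby(["lat", "lon"], sort=False).ngroup().to_numpy()
    n_cells = cell_key.max() + 1
    counts = np.bincount(cell_key, minlength=n_cells)
    if np.any(counts != 12):
        i = int(np.flatnonzero(counts != 12)[0])
        sel = df[cell_key == i].iloc[0]
        raise ValidationError(
            f"{source}: cell (lat={sel['lat']}, lon={sel['lon']}) has {counts[i]} months, expected 12"
        )

    arrays = {}
    order = np.lexsort((df["month"].to_numpy(), cell_key))
    for name in _VARIABLES:
        arrays[name] = df[name].to_numpy(dtype=float)[order].reshape(n_cells, 12)
    first = order.reshape(n_cells, 12)[:, 0]
    lat = df["lat"].to_numpy(dtype=float)[first]
    lon = df["lon"].to_numpy(dtype=float)[first]

    # RH given in percent is auto-detected and rescaled to a fraction
    for name in ("rh09", "rh15"):
        if np.nanmax(arrays[name]) > 1.5:
            arrays[name] = arrays[name] / 100.0

    land = None
    if "land" in df.columns:
        land = df["land"].astype(bool).to_numpy()[first]
    return ClimateGrid(lat=lat, lon=lon, land=land, **arrays)


def read_climate_csv(path: str | Path) -> ClimateGrid:
    """Read the canonical long-format climate CSV (``#`` lines are metadata)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#")
    return _frame_to_grid(df, source=str(path))


def write_climate_csv(grid: ClimateGrid, path: str | Path, header: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        grid.to_frame().to_csv(fh, index=False)


def _month_midpoints_weeks() -> np.ndarray:
    # equal-length months on the 52-week year: month m spans 52/12 weeks
    return (np.arange(12) + 0.5) * (N_WEEKS / 12.0)


def _interp_circular(monthly: np.ndarray) -> np.ndarray:
    """Piecewise-linear circular interpolation of (n, 12) monthly values onto 52 weeks."""
    xp = _month_midpoints_weeks()
    x = np.arange(N_WEEKS) + 0.5
    # pad one period on each side so Dec->Jan interpolates across the year boundary
    xp_ext = np.concatenate([xp - N_WEEKS, xp, xp + N_WEEKS])
    fp_ext = np.concatenate([monthly, monthly, monthly], axis=1)
    out = np.empty((monthly.shape[0], N_WEEKS))
    for i in range(monthly.shape[0]):
        out[i] = np.interp(x, xp_ext, fp_ext[i])
    return out


def monthly_to_weekly(grid: ClimateGrid) -> WeeklyClimate:
    """Resample monthly normals to 52 weeks.

    Temperatures and humidity are interpolated linearly between consecutive
    month midpoints (circularly, December wrapping to January). Weekly
    precipitation is interpolated the same way and then rescaled per cell so
    the 52-week total equals the annual monthly total.
    """
    tmin = _interp_circular(grid.tmin)
    tmax = _interp_circular(grid.tmax)
    rh = _interp_circular((grid.rh09 + grid.rh15) / 2.0)
    precip = _interp_circular(grid.precip * (12.0 / N_WEEKS))
    annual = grid.precip.sum(axis=1)
    weekly_total = precip.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(weekly_total > 0, annual / weekly_total, 1.0)
    precip = precip * scale[:, None]
    return WeeklyClimate(
        lat=grid.lat.copy(),
        lon=grid.lon.copy(),
        tmin=tmin,
        tmax=tmax,
        tmean=(tmin + tmax) / 2.0,
        precip=precip,
        rh=np.clip(rh, 0.0, 1.0),
        land=grid.land.copy(),
    )


def apply_scenario(grid: ClimateGrid, s: ScenarioTransform) -> ClimateGrid:
    """Shift temperatures by ``delta_t`` and scale precipitation; geometry and humidity unchanged."""
    return ClimateGrid(
        lat=grid.lat.copy(),
        lon=grid.lon.copy(),
        tmin=grid.tmin + s.delta_t,
        tmax=grid.tmax + s.delta_t,
        precip=grid.precip * s.precip_scale,
        rh09=grid.rh09.copy(),
        rh15=grid.rh15.copy(),
        land=grid.land.copy(),
    )


def write_suitability_csv(result_frame: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    """Write a suitability map frame (``lat, lon, EI, class, GI_A, CS, HS, DS, DD``)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        result_frame.to_csv(fh, index=False, float_format="%.6f")


def read_suitability_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _regular_axes(lat: np.ndarray, lon: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lats = np.unique(lat)
    lons = np.unique(lon)
    if lats.size * lons.size != lat.size:
        raise ValidationError("cell set is not a full regular lat/lon grid; GeoTIFF export unsupported")
    for ax in (lats, lons):
        if ax.size > 1:
            steps = np.diff(ax)
            if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
                raise ValidationError("irregular cell spacing; GeoTIFF export unsupported")
    return lats, lons


def write_suitability_geotiff(result_frame: pd.DataFrame, path: str | Path) -> None:
    """Export EI, class code and cold stress as a 3-band float32 GeoTIFF (EPSG:4326).

    Requires a full regular lat/lon grid; cell centres are georeferenced at
    the grid's lat/lon (pixel-is-area convention, north-up).
    """
    import tifffile

    lat = result_frame["lat"].to_numpy(dtype=float)
    lon = result_frame["lon"].to_numpy(dtype=float)
    lats, lons = _regular_axes(lat, lon)
    dlat = float(lats[1] - lats[0]) if lats.size > 1 else 1.0
    dlon = float(lons[1] - lons[0]) if lons.size > 1 else 1.0

    class_code = result_frame["class"].map(CLASS_CODES).to_numpy(dtype=float)
    bands = np.empty((3, lats.size, lons.size), dtype=np.float32)
    # row 0 = northernmost latitude (north-up raster)
    row = np.searchsorted(lats, lat)
    col = np.searchsorted(lons, lon)
    row = lats.size - 1 - row
    for b, values in enumerate([result_frame["EI"].to_numpy(dtype=float), class_code,
                                result_frame["CS"].to_numpy(dtype=float)]):
        grid2d = np.full((lats.size, lons.size), np.nan, dtype=np.float32)
        grid2d[row, col] = values
        bands[b] = grid2d

    west = float(lons[0]) - dlon / 2.0
    north = float(lats[-1]) + dlat / 2.0
    # GeoTIFF tags: pixel scale, tie point anchoring raster origin at the
    # grid's north-west corner, and a minimal EPSG:4326 geokey directory.
    pixel_scale = (dlon, dlat, 0.0)
    tiepoint = (0.0, 0.0, 0.0, west, north, 0.0)
    geokeys = (
        1, 1, 0, 4,
        1024, 0, 1, 2,      # GTModelTypeGeoKey = geographic
        1025, 0, 1, 1,      # GTRasterTypeGeoKey = pixel-is-area; centres land on grid lat/lon
        2048, 0, 1, 4326,   # GeographicTypeGeoKey = WGS 84
        2054, 0, 1, 9102,   # angular unit = degree
    )
    extratags = [
        (33550, "d", 3, pixel_scale, False),
        (33922, "d", 6, tiepoint, False),
        (34735, "H", len(geokeys), geokeys, False),
    ]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, bands, extratags=extratags, photometric="minisblack")
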