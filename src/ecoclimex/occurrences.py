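"""Occurrence records: validation, spatial thinning and suitability overlay.

Thinning removes records closer than a radius to an already-kept record,
the standard remedy for the clustered sampling effort of aggregated
biodiversity databases. Overlay assigns each record to its grid cell and
summarises the share of records per suitability class — the usual sanity
check that a fitted distribution model actually covers the known range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .params import ValidationError

EARTH_RADIUS_KM = 6371.0

OCCURRENCE_COLUMNS = ["species", "lat", "lon"]


@dataclass
class OccurrenceSet:
    """Validated occurrence records with columns ``species, lat, lon``."""

    records: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in OCCURRENCE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"occurrence set missing column(s) {missing}")
        df = df[OCCURRENCE_COLUMNS].reset_index(drop=True)
        bad = df[["lat", "lon"]].isna().any(axis=1)
        bad |= (df["lat"] < -90) | (df["lat"] > 90) | (df["lon"] < -180) | (df["lon"] >= 180)
        if bad.any():
            raise ValidationError(
                f"invalid coordinates in rows {df.index[bad].tolist()[:10]}"
                + ("..." if bad.sum() > 10 else "")
            )
        self.records = df

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_csv(cls, path: str | Path) -> "OccurrenceSet":
        return cls(pd.read_csv(path, comment="#"), provenance=str(path))

    def to_csv(self, path: str | Path, header: str | None = None) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            if header:
                for line in header.splitlines():
                    fh.write(f"# {line}\n")
            self.records.to_csv(fh, index=False)


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    a = np.sin((lat2 - lat1) / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def thin_by_radius(points: OccurrenceSet, radius_km: float) -> OccurrenceSet:
    """Greedy distance thinning.

    Records are visited in (lat, lon, species) order; a record is kept iff
    its haversine distance to every previously kept record exceeds
    ``radius_km``. Deterministic for a given input; idempotent; the kept
    count is non-increasing in the radius.
    """
    if radius_km < 0:
        raise ValidationError(f"radius_km must be >= 0, got {radius_km}")
    df = points.records.sort_values(["lat", "lon", "species"], kind="mergesort").reset_index(drop=True)
    lat = df["lat"].to_numpy()
    lon = df["lon"].to_numpy()
    kept: list[int] = []
    for i in range(len(df)):
        if not kept:
            kept.append(i)
            continue
        klat = lat[kept]
        klon = lon[kept]
        # cheap latitude prefilter: |Δlat| alone already exceeds the radius
        near = np.abs(klat - lat[i]) * 111.0 <= radius_km * 1.01
        if not near.any() or np.all(haversine_km(lat[i], lon[i], klat[near], klon[near]) > radius_km):
            kept.append(i)
    return OccurrenceSet(df.iloc[kept].reset_index(drop=True),
                         provenance=f"{points.provenance} | thinned {radius_km} km")


@dataclass
class OverlayStats:
    """Shares of occurrence points per suitability class."""

    n_points: int
    n_outside_grid: int
    share_unsuitable: float
    share_low: float
    share_high: float
    counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_points": self.n_points,
            "n_outside_grid": self.n_outside_grid,
            "share_unsuitable": self.share_unsuitable,
            "share_low": self.share_low,
            "share_high": self.share_high,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def overlay(points: OccurrenceSet, smap) -> OverlayStats:
    """Assign each point to the nearest cell centre and tally class shares.

    A point counts as inside the grid when the nearest centre is within half
    the median cell spacing along both axes; points farther out are reported
    in ``n_outside_grid`` and excluded from the shares, which sum to 100%
    over the assigned points.
    """
    if smap.n_cells == 0:
        raise ValidationError("empty suitability map")
    lat = points.records["lat"].to_numpy()
    lon = points.records["lon"].to_numpy()

    def spacing(values: np.ndarray) -> float:
        uniq = np.unique(values)
        return float(np.median(np.diff(uniq))) if uniq.size > 1 else np.inf

    slat, slon = spacing(smap.lat), spacing(smap.lon)
    # single-row/column maps: borrow the other axis' spacing for the tolerance
    if not np.isfinite(slat):
        slat = slon if np.isfinite(slon) else 2.0
    if not np.isfinite(slon):
        slon = slat if np.isfinite(slat) else 2.0
    half_lat = slat / 2.0
    half_lon = slon / 2.0
    tree = cKDTree(np.column_stack([smap.lat, smap.lon]))
    # longitude is periodic: query the point and its ±360° images, keep the nearest
    best_d = np.full(lat.shape, np.inf)
    idx = np.zeros(lat.shape, dtype=int)
    for shift in (0.0, -360.0, 360.0):
        d, i = tree.query(np.column_stack([lat, lon + shift]))
        better = d < best_d
        best_d[better] = d[better]
        idx[better] = i[better]
    eps = 1e-9
    dlon = np.abs(smap.lon[idx] - lon)
    dlon = np.minimum(dlon, 360.0 - dlon)
    inside = (np.abs(smap.lat[idx] - lat) <= half_lat + eps) & (dlon <= half_lon + eps)

    n_outside = int((~inside).sum())
    assigned = idx[inside]
    if len(points) > 0 and assigned.size == 0:
        raise ValidationError("all occurrence points fall outside the grid")
    classes = smap.classes[assigned]
    counts = {name: int((classes == name).sum()) for name in ("unsuitable", "low", "high")}
    total = max(assigned.size, 1)
    return OverlayStats(
        n_points=int(len(points)),
        n_outside_grid=n_outside,
        share_unsuitable=100.0 * counts["unsuitable"] / total,
        share_low=100.0 * counts["low"] / total,
        share_high=100.0 * counts["high"] / total,
        counts=counts,
    )
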