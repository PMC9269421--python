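"""Independent scalar reference pipeline, one cell at a time.

A deliberately plain re-statement of the model in pure Python (``math`` and
lists only, no numpy): monthly-to-weekly interpolation, soil-moisture
bucket, trapezoidal indices, stress accumulation, degree-days and the
Ecoclimatic Index. The vectorised engine must agree with this element-wise;
the two share no code.
"""

from __future__ import annotations

import math

N_WEEKS = 52


def interp_circular(monthly: list[float]) -> list[float]:
    """Linear interpolation between month midpoints, wrapping Dec->Jan."""
    mid = [(m + 0.5) * N_WEEKS / 12.0 for m in range(12)]
    out = []
    for w in range(N_WEEKS):
        x = w + 0.5
        # find bracketing midpoints on the circle
        j = 0
        while j < 12 and mid[j] <= x:
            j += 1
        lo = j - 1
        hi = j % 12
        x_lo = mid[lo] if lo >= 0 else mid[11] - N_WEEKS
        x_hi = mid[hi] if j < 12 else mid[0] + N_WEEKS
        y_lo = monthly[lo if lo >= 0 else 11]
        y_hi = monthly[hi]
        t = (x - x_lo) / (x_hi - x_lo)
        out.append(y_lo + t * (y_hi - y_lo))
    return out


def weekly_climate(tmin_m, tmax_m, precip_m, rh09_m, rh15_m):
    tmin = interp_circular(list(tmin_m))
    tmax = interp_circular(list(tmax_m))
    rh = interp_circular([(a + b) / 2.0 for a, b in zip(rh09_m, rh15_m)])
    rh = [min(1.0, max(0.0, v)) for v in rh]
    raw = interp_circular([p * 12.0 / N_WEEKS for p in precip_m])
    annual = sum(precip_m)
    total = sum(raw)
    scale = annual / total if total > 0 else 1.0
    precip = [v * scale for v in raw]
    tmean = [(a + b) / 2.0 for a, b in zip(tmin, tmax)]
    return tmin, tmax, tmean, precip, rh


def soil_moisture(precip, tmean, rh, capacity, et_coefficient, initial_sm, spinup_years, ceiling):
    sm = initial_sm
    last = None
    for _ in range(spinup_years):
        cycle = []
        for w in range(N_WEEKS):
            e = et_coefficient * max(0.0, tmean[w]) * (1.05 - rh[w])
            sm = min(ceiling, max(0.0, sm + (precip[w] - e) / capacity))
            cycle.append(sm)
        if last is not None and max(abs(a - b) for a, b in zip(cycle, last)) < 1e-6:
            return cycle
        last = cycle
    return last


def trapezoid(x, lo, opt_lo, opt_hi, hi):
    if x <= lo or x >= hi:
        return 0.0
    if x < opt_lo:
        return (x - lo) / (opt_lo - lo)
    if x <= opt_hi:
        return 1.0
    return (hi - x) / (hi - opt_hi)


def cell_result(tmin_m, tmax_m, precip_m, rh09_m, rh15_m, p, cfg):
    """Full per-cell pipeline; p and cfg are attribute objects with the usual codes."""
    tmin, tmax, tmean, precip, rh = weekly_climate(tmin_m, tmax_m, precip_m, rh09_m, rh15_m)
    sm = soil_moisture(precip, tmean, rh, cfg.capacity, cfg.et_coefficient,
                       cfg.initial_sm, cfg.spinup_years, cfg.ceiling)
    ti = [trapezoid(t, p.DV0, p.DV1, p.DV2, p.DV3) for t in tmean]
    mi = [trapezoid(s, p.SM0, p.SM1, p.SM2, p.SM3) for s in sm]
    gi_a = 100.0 * sum(a * b for a, b in zip(ti, mi)) / N_WEEKS
    cs = min(100.0, 100.0 * sum(abs(p.THCS) * max(0.0, p.TTCS - t) for t in tmin))
    hs = min(100.0, 100.0 * sum(p.THHS * max(0.0, t - p.TTHS) for t in tmax))
    ds = min(100.0, 100.0 * sum(abs(p.HDS) for s in sm if s < p.SMDS))
    dd = sum(7.0 * max(0.0, t - p.DV0) for t in tmean)
    si = (1 - cs / 100.0) * (1 - hs / 100.0) * (1 - ds / 100.0)
    ei = gi_a * si if dd >= p.PPD else 0.0
    ei = min(100.0, max(0.0, ei))
    if ei == 0.0:
        label = "unsuitable"
    elif ei < 30.0:
        label = "low"
    else:
        label = "high"
    return {"GI_A": gi_a, "CS": cs, "HS": hs, "DS": ds, "DD": dd, "EI": ei, "class": label}


def haversine_km(lat1, lon1, lat2, lon2):
    r = 6371.0
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
    return 2 * r * math.asin(math.sqrt(a))


def greedy_thin(rows, radius_km):
    """Brute-force O(n^2) greedy thinning over (lat, lon, species)-sorted rows."""
    rows = sorted(rows, key=lambda r: (r[1], r[2], r[0]))
    kept = []
    for row in rows:
        if all(haversine_km(row[1], row[2], k[1], k[2]) > radius_km for k in kept):
            kept.append(row)
    return kept
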