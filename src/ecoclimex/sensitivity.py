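"""One-at-a-time parameter sensitivity and climate-scenario projection.

Sensitivity follows the classic protocol for this model family: each of the
15 species parameters is perturbed to a published low and high value while
all others stay at their adjusted values (temperatures ±1 °C, moisture and
rate parameters ±10%, degree-days ±20 °C·days), the suitability map is
recomputed, and the change in the cos(latitude)-weighted area share of each
suitability class is reported in percentage points.

Scenario projection reruns the engine on a uniformly transformed climate
(temperature shift, precipitation scaling) and reports area shares plus
per-cell EI and cold-stress deltas against the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate import CLASS_NAMES, ClimateGrid, ScenarioTransform, apply_scenario
from .engine import SuitabilityMap, evaluate, prepare_weekly
from .params import SoilMoistureConfig, SpeciesParameters, ValidationError

_TEMPERATURE_CODES = ("DV0", "DV1", "DV2", "DV3", "TTCS", "TTHS")
_RELATIVE_CODES = ("SM0", "SM1", "SM2", "SM3", "THCS", "THHS", "SMDS", "HDS")
_DEGREE_DAY_CODES = ("PPD",)


@dataclass(frozen=True)
class PerturbationRule:
    """Low/high perturbation for one parameter code."""

    parameter_code: str
    mode: str  # "absolute" (±1 °C), "relative" (±10%), "absolute_degree_days" (±20 °C·days)
    low_value: float
    high_value: float


def default_rules(p: SpeciesParameters | None = None) -> list[PerturbationRule]:
    """The 15 standard rules: ±1 °C, ±10% or ±20 °C·days around the adjusted values.

    Perturbations of negative rates (THCS, HDS) keep the sign: the "high"
    direction is the larger-magnitude (more stressful) value.
    """
    p = p or SpeciesParameters()
    rules: list[PerturbationRule] = []
    for code in _TEMPERATURE_CODES:
        v = getattr(p, code)
        rules.append(PerturbationRule(code, "absolute", v - 1.0, v + 1.0))
    for code in _RELATIVE_CODES:
        v = getattr(p, code)
        lo, hi = sorted((round(v * 0.9, 10), round(v * 1.1, 10)), key=abs)
        rules.append(PerturbationRule(code, "relative", lo, hi))
    for code in _DEGREE_DAY_CODES:
        v = getattr(p, code)
        rules.append(PerturbationRule(code, "absolute_degree_days", v - 20.0, v + 20.0))
    from .params import PARAMETER_CODES

    rules.sort(key=lambda r: PARAMETER_CODES.index(r.parameter_code))
    return rules


def area_shares(smap: SuitabilityMap, weighted: bool = True) -> dict[str, float]:
    """Percentage of land area per suitability class.

    Cells are weighted by cos(latitude) by default, the area of an
    equal-angle grid cell; ``weighted=False`` counts cells instead. Shares
    sum to 100 over the three classes.
    """
    land = smap.land
    if not np.any(land):
        raise ValidationError("no land cells")
    w = np.cos(np.radians(smap.lat[land])) if weighted else np.ones(int(land.sum()))
    total = w.sum()
    if total <= 0:
        raise ValidationError("zero total land weight")
    classes = smap.classes[land]
    return {name: float(100.0 * w[classes == name].sum() / total) for name in CLASS_NAMES}


@dataclass
class SensitivityReport:
    """Long-format sensitivity table plus the shared baseline."""

    baseline_shares: dict[str, float]
    table: pd.DataFrame  # parameter, direction, value, class, baseline_share, perturbed_share, delta_pp

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def run_sensitivity(
    grid: ClimateGrid,
    p: SpeciesParameters | None = None,
    rules: list[PerturbationRule] | None = None,
    cfg: SoilMoistureConfig | None = None,
    weighted: bool = True,
) -> SensitivityReport:
    """Run the one-at-a-time protocol: one perturbed map per rule and direction.

    The weekly climate and soil-moisture spin-up are shared across runs
    (they do not depend on species parameters), so a full 30-run analysis
    costs one spin-up plus 30 cheap re-evaluations.
    """
    p = p or SpeciesParameters()
    rules = default_rules(p) if rules is None else rules
    cfg = cfg or SoilMoistureConfig()

    prepared = prepare_weekly(grid, cfg)
    base_map, _ = evaluate(prepared, p)
    base = area_shares(base_map, weighted=weighted)

    rows = []
    for rule in rules:
        for direction, value in (("low", rule.low_value), ("high", rule.high_value)):
            perturbed = p.with_overrides(**{rule.parameter_code: value})
            smap, _ = evaluate(prepared, perturbed)
            shares = area_shares(smap, weighted=weighted)
            for cls in CLASS_NAMES:
                rows.append(
                    {
                        "parameter": rule.parameter_code,
                        "direction": direction,
                        "value": value,
                        "class": cls,
                        "baseline_share": base[cls],
                        "perturbed_share": shares[cls],
                        "delta_pp": shares[cls] - base[cls],
                    }
                )
    return SensitivityReport(baseline_shares=base, table=pd.DataFrame(rows))


@dataclass
class ScenarioResult:
    """Baseline and per-scenario maps with area shares and per-cell deltas."""

    baseline: SuitabilityMap
    maps: dict[str, SuitabilityMap]
    shares: pd.DataFrame          # label, class, share
    deltas: pd.DataFrame          # label, lat, lon, dEI, dCS


def run_scenarios(
    grid: ClimateGrid,
    p: SpeciesParameters | None = None,
    transforms: list[ScenarioTransform] | None = None,
    cfg: SoilMoistureConfig | None = None,
    weighted: bool = True,
) -> ScenarioResult:
    """Project the suitability map under each scenario transform."""
    from .climate import default_scenarios

    p = p or SpeciesParameters()
    cfg = cfg or SoilMoistureConfig()
    transforms = default_scenarios() if transforms is None else transforms

    baseline = evaluate(prepare_weekly(grid, cfg), p)[0]
    share_rows = [
        {"label": "baseline", "class": cls, "share": s}
        for cls, s in area_shares(baseline, weighted=weighted).items()
    ]
    maps: dict[str, SuitabilityMap] = {}
    delta_frames = []
    for t in transforms:
        smap = evaluate(prepare_weekly(apply_scenario(grid, t), cfg), p)[0]
        maps[t.label] = smap
        for cls, s in area_shares(smap, weighted=weighted).items():
            share_rows.append({"label": t.label, "class": cls, "share": s})
        delta_frames.append(
            pd.DataFrame(
                {
                    "label": t.label,
                    "lat": grid.lat,
                    "lon": grid.lon,
                    "dEI": smap.EI - baseline.EI,
                    "dCS": smap.CS - baseline.CS,
                }
            )
        )
    deltas = pd.concat(delta_frames, ignore_index=True) if delta_frames else pd.DataFrame(
        columns=["label", "lat", "lon", "dEI", "dCS"]
    )
    return ScenarioResult(baseline=baseline, maps=maps, shares=pd.DataFrame(share_rows), deltas=deltas)
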