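"""Species parameters and soil-moisture configuration.

The species is described by the 15 classic CLIMEX-style parameters: a
temperature trapezoid (DV0..DV3, °C), a soil-moisture trapezoid (SM0..SM3,
expressed as a fraction of the soil bucket's holding capacity), three stress
threshold/rate pairs (cold TTCS/THCS, heat TTHS/THHS, dry SMDS/HDS) and the
degree-day sum per generation (PPD, °C·days above DV0) that gates population
persistence.

Defaults are the adjusted calibration for the invasive pasture grass
*Urochloa panicoides*.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


PARAMETER_CODES = (
    "DV0", "DV1", "DV2", "DV3",
    "SM0", "SM1", "SM2", "SM3",
    "TTCS", "THCS", "TTHS", "THHS",
    "SMDS", "HDS", "PPD",
)


@dataclass(frozen=True)
class SpeciesParameters:
    """The 15-parameter species response.

    Attributes
    ----------
    DV0, DV1, DV2, DV3:
        Limiting low / lower optimal / upper optimal / limiting high
        temperature (°C) of the growth trapezoid.
    SM0, SM1, SM2, SM3:
        The analogous soil-moisture trapezoid (fraction of holding capacity).
    TTCS, THCS:
        Cold stress threshold (°C, on weekly minimum temperature) and weekly
        accumulation rate (week⁻¹, ≤ 0).
    TTHS, THHS:
        Heat stress threshold (°C, on weekly maximum temperature) and weekly
        rate (week⁻¹, ≥ 0).
    SMDS, HDS:
        Dry stress soil-moisture threshold and weekly rate (week⁻¹, ≤ 0).
    PPD:
        Degree-days per generation (°C·days above DV0); cells that cannot
        accumulate PPD in a year cannot sustain a population.
    """

    DV0: float = 4.0
    DV1: float = 25.0
    DV2: float = 35.0
    DV3: float = 45.0
    SM0: float = 0.1
    SM1: float = 0.2
    SM2: float = 8.0
    SM3: float = 10.0
    TTCS: float = 4.0
    THCS: float = -0.002
    TTHS: float = 45.0
    THHS: float = 0.02
    SMDS: float = 0.1
    HDS: float = -0.01
    PPD: float = 1517.0

    def __post_init__(self) -> None:
        if not (self.DV0 < self.DV1 <= self.DV2 < self.DV3):
            raise ValidationError(
                f"temperature limits must satisfy DV0 < DV1 <= DV2 < DV3, got "
                f"{self.DV0}, {self.DV1}, {self.DV2}, {self.DV3}"
            )
        if not (self.SM0 < self.SM1 <= self.SM2 < self.SM3):
            raise ValidationError(
                f"moisture limits must satisfy SM0 < SM1 <= SM2 < SM3, got "
                f"{self.SM0}, {self.SM1}, {self.SM2}, {self.SM3}"
            )
        if self.THCS > 0:
            raise ValidationError(f"THCS must be <= 0, got {self.THCS}")
        if self.HDS > 0:
            raise ValidationError(f"HDS must be <= 0, got {self.HDS}")
        if self.THHS < 0:
            raise ValidationError(f"THHS must be >= 0, got {self.THHS}")
        if self.PPD < 0:
            raise ValidationError(f"PPD must be >= 0, got {self.PPD}")

    def with_overrides(self, **overrides: float) -> "SpeciesParameters":
        """Return a copy with the given parameter codes replaced."""
        unknown = set(overrides) - set(PARAMETER_CODES)
        if unknown:
            raise ValidationError(f"unknown parameter code(s): {sorted(unknown)}")
        return replace(self, **overrides)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_file(cls, path: str | Path) -> "SpeciesParameters":
        """Read a flat ``CODE = value`` config file (``#`` starts a comment)."""
        overrides: dict[str, float] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(f"{path}:{lineno}: expected 'CODE = value', got {raw!r}")
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in PARAMETER_CODES:
                raise ValidationError(f"{path}:{lineno}: unknown parameter code {key!r}")
            try:
                overrides[key] = float(value.strip())
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: non-numeric value {value!r}") from exc
        return cls(**overrides)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{code} = {getattr(self, code)!r}" for code in PARAMETER_CODES]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class SoilMoistureConfig:
    """Weekly soil-moisture bucket settings.

    capacity : mm
        Water the bucket holds at SM = 1.
    et_coefficient : mm·week⁻¹·°C⁻¹
        Scales weekly evapotranspirative demand with temperature and dryness
        of the air.
    initial_sm : fraction of capacity
        Bucket state at the start of spin-up.
    spinup_years : int
        Maximum annual cycles iterated until the cycle converges.
    ceiling : fraction of capacity
        Bucket cap; water above it is lost as runoff/drainage. The default of
        1.0 means the bucket cannot exceed holding capacity, so the upper
        moisture limits (SM2, SM3) only bind if the ceiling is raised.
    """

    capacity: float = 100.0
    et_coefficient: float = 2.0
    initial_sm: float = 0.5
    spinup_years: int = 50
    ceiling: float = 1.0

    def __post_init__(self) -> None:
        if self.capacity <= 0:
            raise ValidationError(f"capacity must be > 0, got {self.capacity}")
        if self.et_coefficient < 0:
            raise ValidationError(f"et_coefficient must be >= 0, got {self.et_coefficient}")
        if self.spinup_years < 1:
            raise ValidationError(f"spinup_years must be >= 1, got {self.spinup_years}")
        if self.ceiling <= 0:
            raise ValidationError(f"ceiling must be > 0, got {self.ceiling}")
        if not 0 <= self.initial_sm <= self.ceiling:
            raise ValidationError(
                f"initial_sm must lie in [0, ceiling={self.ceiling}], got {self.initial_sm}"
            )
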