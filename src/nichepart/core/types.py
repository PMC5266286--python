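"""Domain types for the lake-fish trophic-niche analysis.

The fixed vocabulary (three species, three habitats, three sampling
months, six prey categories) is encoded as enums / ordered tuples so
that every downstream table has a deterministic column order.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

__all__ = [
    "Species",
    "Habitat",
    "Month",
    "Maturity",
    "GearClass",
    "PREY_CATEGORIES",
    "PreyCategory",
    "FishRecord",
    "EffortRecord",
    "IsotopeSample",
    "ValidationError",
    "TableValidationError",
    "FULLNESS_TOL",
]

#: absolute tolerance for "category fullness sums to total fullness"
FULLNESS_TOL = 1e-9


class ValidationError(ValueError):
    """A record violates a domain invariant."""


class TableValidationError(ValueError):
    """One or more rows of a table failed validation.

    Carries every row-addressed message so no malformed row is silently
    dropped.
    """

    def __init__(self, source: str, messages: list[str]):
        self.source = source
        self.messages = list(messages)
        joined = "\n  ".join(self.messages)
        super().__init__(f"{source}: {len(self.messages)} invalid row(s):\n  {joined}")


class _LabelEnum(str, enum.Enum):
    @classmethod
    def parse(cls, value: object) -> "_LabelEnum":
        if isinstance(value, cls):
            return value
        text = str(value).strip()
        for member in cls:
            if member.value.lower() == text.lower():
                return member
        valid = ", ".join(m.value for m in cls)
        raise ValidationError(f"unknown {cls.__name__.lower()} label {value!r} (expected one of: {valid})")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Species(_LabelEnum):
    CHARR = "charr"
    WHITEFISH = "whitefish"
    TROUT = "trout"


class Habitat(_LabelEnum):
    LITTORAL = "littoral"
    PROFUNDAL = "profundal"
    PELAGIC = "pelagic"


class Month(_LabelEnum):
    JUNE = "June"
    AUGUST = "August"
    OCTOBER = "October"


class Maturity(_LabelEnum):
    IMMATURE = "immature"
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class GearClass(_LabelEnum):
    SURVEY = "survey"
    SUPPLEMENTARY = "supplementary"


#: The six prey categories, fixed and ordered. Every diet vector in the
#: package follows this order.
PREY_CATEGORIES: tuple[str, ...] = (
    "copepod_zooplankton",
    "cladoceran_zooplankton",
    "benthic_cladoceran",
    "benthic_invertebrates",
    "pleuston",
    "fish",
)


@dataclass(frozen=True)
class PreyCategory:
    """One of the six prey categories with its member taxa."""

    name: str
    member_taxa: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.name not in PREY_CATEGORIES:
            raise ValidationError(
                f"prey category {self.name!r} is not one of the six fixed categories {PREY_CATEGORIES}"
            )


@dataclass
class FishRecord:
    """One captured fish with habitat/season context and its stomach
    fullness split over the six prey categories.

    ``fullness_by_prey`` holds fullness points per category; their sum
    must equal ``stomach_total_fullness`` (0-100, 0 = empty stomach).
    """

    fish_id: str
    species: Species
    habitat: Habitat
    month: Month
    year: int
    total_length: float
    weight: Optional[float]
    stomach_total_fullness: float
    fullness_by_prey: dict[str, float] = field(default_factory=dict)
    maturity: Maturity = Maturity.UNKNOWN
    gear_class: GearClass = GearClass.SURVEY

    def __post_init__(self) -> None:
        self.species = Species.parse(self.species)
        self.habitat = Habitat.parse(self.habitat)
        self.month = Month.parse(self.month)
        self.maturity = Maturity.parse(self.maturity)
        self.gear_class = GearClass.parse(self.gear_class)
        if not (self.total_length > 0):
            raise ValidationError(f"fish {self.fish_id}: total_length must be > 0, got {self.total_length}")
        if self.weight is not None and not (self.weight > 0):
            raise ValidationError(f"fish {self.fish_id}: weight must be > 0 when present, got {self.weight}")
        tf = self.stomach_total_fullness
        if not (0.0 <= tf <= 100.0):
            raise ValidationError(f"fish {self.fish_id}: total fullness must be in [0, 100], got {tf}")
        for cat, v in self.fullness_by_prey.items():
            if cat not in PREY_CATEGORIES:
                raise ValidationError(f"fish {self.fish_id}: unknown prey category {cat!r}")
            if v < 0 or not math.isfinite(v):
                raise ValidationError(f"fish {self.fish_id}: fullness for {cat!r} must be finite and >= 0, got {v}")
        total = sum(self.fullness_by_prey.values())
        if abs(total - tf) > FULLNESS_TOL:
            raise ValidationError(
                f"fish {self.fish_id}: category fullness sums to {total}, but total fullness is {tf}"
            )

    @property
    def is_empty(self) -> bool:
        return self.stomach_total_fullness == 0.0

    def fullness_vector(self) -> tuple[float, ...]:
        """Per-category fullness points in the fixed category order."""
        return tuple(self.fullness_by_prey.get(cat, 0.0) for cat in PREY_CATEGORIES)


@dataclass
class EffortRecord:
    """Gill-net effort for one habitat/month/year stratum.

    ``net_area`` is in m^2; effort in CPUE units is net_area/100 * nights.
    Supplementary gear never enters the CPUE denominator.
    """

    habitat: Habitat
    month: Month
    year: int
    net_area: float
    nights: int
    gear_class: GearClass = GearClass.SURVEY

    def __post_init__(self) -> None:
        self.habitat = Habitat.parse(self.habitat)
        self.month = Month.parse(self.month)
        self.gear_class = GearClass.parse(self.gear_class)
        if not (self.net_area > 0):
            raise ValidationError(f"effort record: net_area must be > 0, got {self.net_area}")
        if int(self.nights) < 1:
            raise ValidationError(f"effort record: nights must be >= 1, got {self.nights}")
        self.nights = int(self.nights)

    @property
    def effort_units(self) -> float:
        """Effort in 100-m^2 * nights."""
        return self.net_area / 100.0 * self.nights


@dataclass
class IsotopeSample:
    """One delta13C/delta15N measurement with elemental concentrations.

    ``group`` labels either a consumer species or a putative dietary
    source; ``pct_C``/``pct_N`` are percent by weight and feed the
    concentration-dependent mixing model.
    """

    sample_id: str
    group: str
    d13C: float
    d15N: float
    pct_C: float
    pct_N: float
    habitat: Optional[Habitat] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.d13C) or not math.isfinite(self.d15N):
            raise ValidationError(f"sample {self.sample_id}: delta values must be finite")
        for name, v in (("pct_C", self.pct_C), ("pct_N", self.pct_N)):
            if not (0.0 < v <= 100.0):
                raise ValidationError(f"sample {self.sample_id}: {name} must be in (0, 100], got {v}")
        if self.habitat is not None and not isinstance(self.habitat, Habitat):
            self.habitat = Habitat.parse(self.habitat)


def prey_vector_from_mapping(values: Mapping[str, float]) -> tuple[float, ...]:
    """Order an arbitrary category->value mapping along PREY_CATEGORIES."""
    unknown = set(values) - set(PREY_CATEGORIES)
    if unknown:
        raise ValidationError(f"unknown prey categories: {sorted(unknown)}")
    return tuple(float(values.get(cat, 0.0)) for cat in PREY_CATEGORIES)
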