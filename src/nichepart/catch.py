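"""Catch-per-unit-effort, habitat-use proportions and descriptive
size/biomass summaries.

CPUE is the number of fish caught per 100 m^2 of net area per night;
effort for a stratum is the summed net_area/100 * nights of its survey
gear. Supplementary gear never contributes to either numerator or
denominator.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core.types import (
    EffortRecord,
    FishRecord,
    GearClass,
    Habitat,
    Month,
    Species,
    ValidationError,
)

__all__ = [
    "CpueCell",
    "compute_cpue",
    "habitat_use_profile",
    "summarize_sizes",
    "biomass_share",
]


@dataclass(frozen=True)
class CpueCell:
    species: Species
    habitat: Habitat
    month: Month
    cpue: float
    n_fish: int
    effort: float  # 100-m^2 * nights
    year: Optional[int] = None  # None = pooled across years

    def __post_init__(self) -> None:
        if not (self.effort > 0):
            raise ValidationError("CPUE cell requires positive effort")
        if self.n_fish < 0:
            raise ValidationError("negative fish count")
        if abs(self.cpue - self.n_fish / self.effort) > 1e-9:
            raise ValidationError("cpue != n_fish / effort")


def compute_cpue(
    fish: Iterable[FishRecord],
    effort: Iterable[EffortRecord],
    species: Sequence[Species] = tuple(Species),
    pool_years: bool = True,
) -> list[CpueCell]:
    """One cell per species x habitat x month (x year unless pooled).

    Strata with effort but no catch are emitted with cpue = 0 so that
    habitat-use profiles stay well defined. A survey fish caught in a
    stratum with no recorded effort is an error.
    """
    effort_by_stratum: dict[tuple, float] = {}
    for rec in effort:
        if rec.gear_class is not GearClass.SUPPLEMENTARY:
            key = (rec.habitat, rec.month) if pool_years else (rec.habitat, rec.month, rec.year)
            effort_by_stratum[key] = effort_by_stratum.get(key, 0.0) + rec.effort_units

    counts: dict[tuple, int] = {}
    for f in fish:
        if f.gear_class is GearClass.SUPPLEMENTARY:
            continue
        skey = (f.habitat, f.month) if pool_years else (f.habitat, f.month, f.year)
        if skey not in effort_by_stratum:
            raise ValidationError(
                f"fish {f.fish_id} caught in stratum {tuple(str(k) for k in skey)} with no effort record"
            )
        counts[(f.species, *skey)] = counts.get((f.species, *skey), 0) + 1

    cells: list[CpueCell] = []
    for skey, eff in sorted(effort_by_stratum.items(), key=lambda kv: tuple(str(k) for k in kv[0])):
        for sp in species:
            n = counts.get((sp, *skey), 0)
            year = None if pool_years else skey[2]
            cells.append(
                CpueCell(
                    species=sp,
                    habitat=skey[0],
                    month=skey[1],
                    cpue=n / eff,
                    n_fish=n,
                    effort=eff,
                    year=year,
                )
            )
    return cells


def habitat_use_profile(
    cells: Iterable[CpueCell],
    species: Species,
    month: Month,
    habitats: Sequence[Habitat] = tuple(Habitat),
) -> np.ndarray:
    """CPUE-share proportions over habitats for one species/month.

    proportion_h = cpue_h / sum(cpue); raises if the species was caught
    nowhere in that month (the profile is undefined, not zero).
    """
    by_hab = {c.habitat: c.cpue for c in cells if c.species is species and c.month is month}
    vec = np.array([by_hab.get(h, 0.0) for h in habitats], dtype=float)
    total = vec.sum()
    if total <= 0:
        raise ValidationError(
            f"habitat-use profile undefined: all-zero CPUE for {species.value} in {month.value}"
        )
    return vec / total


def summarize_sizes(fish: Iterable[FishRecord]) -> pd.DataFrame:
    """Per-species mean/SD/min/max of total length (cm)."""
    rows = [(f.species.value, f.total_length) for f in fish]
    if not rows:
        raise ValidationError("no fish to summarize")
    df = pd.DataFrame(rows, columns=["species", "total_length"])
    out = df.groupby("species")["total_length"].agg(["count", "mean", "std", "min", "max"]).reset_index()
    return out.rename(columns={"count": "n", "std": "sd"})


def biomass_share(fish: Iterable[FishRecord]) -> dict[str, float]:
    """Each species' fraction of the total catch weight; shares sum to 1."""
    weights: dict[str, float] = {}
    for f in fish:
        if f.weight is not None:
            weights[f.species.value] = weights.get(f.species.value, 0.0) + f.weight
    total = sum(weights.values())
    if total <= 0:
        raise ValidationError("no fish with weights")
    return {sp: w / total for sp, w in sorted(weights.items())}
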