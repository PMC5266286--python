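"""Volumetric diet composition.

The composition of a group of stomachs is the pooled-sum prey abundance:
component i is (sum over fish of fullness in category i) divided by
(sum over fish of total fullness). Empty stomachs add zero to both sums,
so they never shift the profile; they are counted separately.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Hashable, Iterable, Sequence

import numpy as np
import pandas as pd

from .core.types import FishRecord, PREY_CATEGORIES, ValidationError

__all__ = [
    "DietProfile",
    "AllStomachsEmptyError",
    "prey_abundance",
    "empty_stomach_proportion",
    "cell_mean_matrix",
]


class AllStomachsEmptyError(ValidationError):
    """The group has fish, but every stomach is empty — distinct from
    an empty group."""


@dataclass(frozen=True)
class DietProfile:
    """Diet composition of a group as proportions over the six ordered
    prey categories (internally on [0, 1]; reports scale by 100)."""

    group: tuple
    proportions: tuple[float, ...]
    n_fish: int  # non-empty stomachs contributing

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if p.shape != (len(PREY_CATEGORIES),):
            raise ValidationError(f"diet profile must have {len(PREY_CATEGORIES)} components")
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError("diet proportions must be >= 0 and sum to 1")
        if self.n_fish < 1:
            raise ValidationError("a diet profile needs at least one non-empty stomach")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.proportions, dtype=float)

    def as_percent(self) -> np.ndarray:
        return 100.0 * self.as_array()


def prey_abundance(records: Sequence[FishRecord], group: Hashable = ()) -> DietProfile:
    """Pooled-sum diet composition of a group of fish."""
    records = list(records)
    if not records:
        raise ValidationError("no fish in group")
    F = np.array([r.fullness_vector() for r in records], dtype=float)
    totals = np.array([r.stomach_total_fullness for r in records], dtype=float)
    denom = totals.sum()
    if denom <= 0:
        raise AllStomachsEmptyError(f"group {group!r}: all {len(records)} stomachs are empty")
    props = F.sum(axis=0) / denom
    n_nonempty = int((totals > 0).sum())
    key = group if isinstance(group, tuple) else (group,)
    return DietProfile(group=key, proportions=tuple(props), n_fish=n_nonempty)


def empty_stomach_proportion(
    records: Iterable[FishRecord],
    by: Callable[[FishRecord], Hashable] = lambda r: r.species.value,
) -> dict[Hashable, float]:
    """Percent of empty stomachs per group (default grouping: species)."""
    totals: dict[Hashable, int] = {}
    empties: dict[Hashable, int] = {}
    for r in records:
        k = by(r)
        totals[k] = totals.get(k, 0) + 1
        empties[k] = empties.get(k, 0) + (1 if r.is_empty else 0)
    if not totals:
        raise ValidationError("no fish")
    return {k: 100.0 * empties[k] / totals[k] for k in sorted(totals, key=str)}


def cell_mean_matrix(
    records: Iterable[FishRecord],
) -> tuple[list[DietProfile], list[tuple]]:
    """One pooled-sum profile per populated species x habitat x month cell.

    Returns (profiles, omitted) where ``omitted`` lists cells that had
    fish but only empty stomachs; cells with no catch are simply absent.
    """
    cells: dict[tuple, list[FishRecord]] = {}
    for r in records:
        cells.setdefault((r.species.value, r.habitat.value, r.month.value), []).append(r)
    profiles: list[DietProfile] = []
    omitted: list[tuple] = []
    for key in sorted(cells):
        try:
            profiles.append(prey_abundance(cells[key], group=key))
        except AllStomachsEmptyError:
            omitted.append(key)
    return profiles, omitted


def profiles_to_frame(profiles: Sequence[DietProfile], percent: bool = True) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = dict(zip(("species", "habitat", "month")[: len(p.group)], p.group))
        vals = p.as_percent() if percent else p.as_array()
        row.update(dict(zip(PREY_CATEGORIES, vals)))
        row["n_fish"] = p.n_fish
        rows.append(row)
    return pd.DataFrame(rows)
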