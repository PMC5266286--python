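"""Schoener's proportional-similarity overlap for diet and habitat
profiles, pairwise matrices shaped like the published layout, and the
between-year merge check.

alpha(x, y) = 1 - 0.5 * sum_i |P_xi - P_yi|, in [0, 1]; values at or
above the configured threshold (default 0.60) are classed biologically
significant. The internal scale is [0, 1]; matrix reports print whole
percents.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core.types import Habitat, Month, ValidationError

__all__ = [
    "OverlapResult",
    "MergeDecision",
    "schoener_alpha",
    "overlap_matrix",
    "habitat_overlap_matrix",
    "pairwise_table",
    "year_merge_check",
    "DEFAULT_THRESHOLD",
]

DEFAULT_THRESHOLD = 0.60
_NORM_TOL = 1e-6


def schoener_alpha(p_x: Sequence[float], p_y: Sequence[float]) -> float:
    """Overlap of two resource-use distributions (each on the simplex)."""
    x = np.asarray(p_x, dtype=float)
    y = np.asarray(p_y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(f"profile length mismatch: {x.shape} vs {y.shape}")
    for name, v in (("first", x), ("second", y)):
        if (v < 0).any():
            raise ValidationError(f"{name} profile has negative components")
        if abs(v.sum() - 1.0) > _NORM_TOL:
            raise ValidationError(f"{name} profile sums to {v.sum()!r}, not 1")
    alpha = 1.0 - 0.5 * np.abs(x - y).sum()
    # clamp float jitter only
    return float(min(1.0, max(0.0, alpha)))


@dataclass(frozen=True)
class OverlapResult:
    pair: tuple[str, str]
    alpha: float
    significant: bool
    habitat: Optional[str] = None
    month: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValidationError("alpha outside [0, 1]")


#: canonical printing order for species pairs within a habitat block
_PAIR_ORDER = [
    ("charr", "whitefish"),
    ("charr", "trout"),
    ("trout", "whitefish"),
]


def overlap_matrix(
    profiles: Mapping[tuple, Sequence[float]],
    pairs: Optional[Sequence[tuple[str, str]]] = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[OverlapResult]:
    """Pairwise overlap per species-pair x habitat x month.

    ``profiles`` maps (species, habitat, month) string keys to simplex
    vectors. Contexts where either species lacks a profile produce no
    result (reported downstream as "-"): absence is data, not an error.
    """
    if pairs is None:
        pairs = _PAIR_ORDER
    contexts = sorted({(k[1], k[2]) for k in profiles})
    results: list[OverlapResult] = []
    for hab, mo in contexts:
        for a, b in pairs:
            pa = profiles.get((a, hab, mo))
            pb = profiles.get((b, hab, mo))
            if pa is None or pb is None:
                continue
            alpha = schoener_alpha(pa, pb)
            results.append(
                OverlapResult(
                    pair=(a, b),
                    alpha=alpha,
                    significant=alpha >= threshold,
                    habitat=hab,
                    month=mo,
                )
            )
    return results


def pairwise_table(
    results: Sequence[OverlapResult],
    habitats: Sequence[str] = tuple(h.value for h in Habitat),
    months: Sequence[str] = tuple(m.value for m in Month),
    percent: bool = True,
) -> pd.DataFrame:
    """Matrix report: rows = habitat x species-pair, columns = months,
    "-" where a stratum lacks one or both species. Percent cells are
    printed as whole numbers (round(100 * alpha))."""
    lookup = {(r.habitat, r.month, r.pair): r for r in results}
    pairs_seen = [p for p in _PAIR_ORDER] + sorted({r.pair for r in results} - set(_PAIR_ORDER))
    rows = []
    for hab in habitats:
        for pair in pairs_seen:
            row: dict = {"habitat": hab, "pair": f"{pair[0]} vs {pair[1]}"}
            any_value = False
            for mo in months:
                r = lookup.get((hab, mo, pair))
                if r is None:
                    row[mo] = "-"
                else:
                    any_value = True
                    row[mo] = str(int(round(100.0 * r.alpha))) if percent else f"{r.alpha:.4f}"
                row[f"{mo}_significant"] = "" if r is None else str(r.significant)
            if any_value:
                rows.append(row)
    cols = ["habitat", "pair"] + [c for mo in months for c in (mo, f"{mo}_significant")]
    return pd.DataFrame(rows, columns=cols)


def habitat_overlap_matrix(
    cpue_cells: Sequence,
    pairs: Optional[Sequence[tuple[str, str]]] = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[OverlapResult]:
    """Habitat overlap per species pair and month.

    The habitat-use proportions are CPUE shares over the three habitats
    (see :func:`nichepart.catch.habitat_use_profile`); a species with
    all-zero CPUE in a month has no profile, so its pairs are absent for
    that month.
    """
    from .catch import habitat_use_profile
    from .core.types import Species

    if pairs is None:
        pairs = _PAIR_ORDER
    months = sorted({c.month for c in cpue_cells}, key=lambda m: m.value)
    profiles: dict[tuple[str, str], np.ndarray] = {}
    for sp in Species:
        for mo in months:
            try:
                profiles[(sp.value, mo.value)] = habitat_use_profile(cpue_cells, sp, mo)
            except ValidationError:
                continue
    results: list[OverlapResult] = []
    for mo in months:
        for a, b in pairs:
            pa = profiles.get((a, mo.value))
            pb = profiles.get((b, mo.value))
            if pa is None or pb is None:
                continue
            alpha = schoener_alpha(pa, pb)
            results.append(
                OverlapResult(pair=(a, b), alpha=alpha, significant=alpha >= threshold,
                              habitat=None, month=mo.value)
            )
    return results


@dataclass
class MergeDecision:
    """Outcome of the between-year similarity check."""

    merge: bool
    alphas: dict[Hashable, float] = field(default_factory=dict)
    failures: list[Hashable] = field(default_factory=list)
    skipped: list[Hashable] = field(default_factory=list)
    threshold: float = DEFAULT_THRESHOLD


def year_merge_check(
    profiles_by_year: Mapping[int, Mapping[Hashable, Sequence[float]]],
    threshold: float = DEFAULT_THRESHOLD,
) -> MergeDecision:
    """Compare each group's profiles between two sampling years.

    Merging the years is recommended iff every comparable group has
    between-year overlap at or above the threshold. Groups present in
    only one year are skipped with a note.
    """
    years = sorted(profiles_by_year)
    if len(years) != 2:
        raise ValidationError(f"merge check needs exactly two years, got {years}")
    a, b = (profiles_by_year[y] for y in years)
    decision = MergeDecision(merge=True, threshold=threshold)
    for group in sorted(set(a) | set(b), key=str):
        if group not in a or group not in b:
            decision.skipped.append(group)
            continue
        alpha = schoener_alpha(a[group], b[group])
        decision.alphas[group] = alpha
        if alpha < threshold:
            decision.failures.append(group)
            decision.merge = False
    return decision
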