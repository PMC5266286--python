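"""Analysis configuration: prey-taxon mapping, TEFs, source sets, MCMC
and permutation settings, loaded from YAML with sensible defaults."""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import yaml

from .types import PREY_CATEGORIES, ValidationError

__all__ = [
    "DEFAULT_PREY_TAXON_MAP",
    "DEFAULT_SOURCE_SETS",
    "DEFAULT_SOURCE_POOLS",
    "TefConfig",
    "McmcSettings",
    "PermutationSettings",
    "AnalysisConfig",
]

#: Editable taxon -> prey-category mapping, pre-populated with the taxa
#: the six categories are built from. Keys are matched case-insensitively.
DEFAULT_PREY_TAXON_MAP: dict[str, str] = {
    # copepod zooplankton
    "cyclopoida": "copepod_zooplankton",
    "calanoida": "copepod_zooplankton",
    "copepoda": "copepod_zooplankton",
    # cladoceran zooplankton
    "bosmina": "cladoceran_zooplankton",
    "daphnia": "cladoceran_zooplankton",
    "holopedium": "cladoceran_zooplankton",
    "bythotrephes": "cladoceran_zooplankton",
    # benthic cladocerans
    "chydoridae": "benthic_cladoceran",
    "chydorids": "benthic_cladoceran",
    "eurycercus": "benthic_cladoceran",
    # benthic invertebrates
    "ephemeroptera": "benthic_invertebrates",
    "trichoptera": "benthic_invertebrates",
    "plecoptera": "benthic_invertebrates",
    "odonata": "benthic_invertebrates",
    "coleoptera": "benthic_invertebrates",
    "chironomidae": "benthic_invertebrates",
    # pleuston: surface-film insects (emerging pupae + adults)
    "surface_insects": "pleuston",
    "pupae": "pleuston",
    "terrestrial_insects": "pleuston",
    # fish prey
    "fish_prey": "fish",
    "whitefish_prey": "fish",
    "charr_prey": "fish",
}
# a column named exactly like a category maps to itself
DEFAULT_PREY_TAXON_MAP.update({c: c for c in PREY_CATEGORIES})

#: Source groups entering the mixing model per consumer species.
DEFAULT_SOURCE_SETS: dict[str, list[str]] = {
    "trout": ["fish", "benthic_invertebrates", "zooplankton"],
    "charr": ["profundal_invertebrates", "littoral_invertebrates", "zooplankton"],
    "whitefish": ["profundal_invertebrates", "littoral_invertebrates", "zooplankton"],
}

#: Pooled sources: the "fish" source aggregates prey-sized fish samples.
DEFAULT_SOURCE_POOLS: dict[str, list[str]] = {
    "fish": ["whitefish_prey", "charr_prey", "juvenile_trout"],
}


@dataclass
class TefConfig:
    """Trophic-enrichment factors (mean, SD) per isotope, in per mil."""

    d15N_mean: float = 3.23
    d15N_sd: float = 0.79
    d13C_mean: float = 1.03
    d13C_sd: float = 0.29

    def __post_init__(self) -> None:
        if self.d15N_sd < 0 or self.d13C_sd < 0:
            raise ValidationError("TEF SDs must be >= 0")


@dataclass
class McmcSettings:
    chains: int = 4
    iterations: int = 4000
    burn_in: int = 1500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValidationError("MCMC requires at least 2 chains")
        if self.burn_in >= self.iterations:
            raise ValidationError("burn_in must be smaller than iterations")


@dataclass
class PermutationSettings:
    count: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValidationError("permutation count must be >= 1")


@dataclass
class AnalysisConfig:
    """Everything the pipeline stages need besides the data tables."""

    prey_taxon_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_PREY_TAXON_MAP))
    source_sets: dict[str, list[str]] = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_SOURCE_SETS.items()})
    source_pools: dict[str, list[str]] = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_SOURCE_POOLS.items()})
    tef: TefConfig = field(default_factory=TefConfig)
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    permutations: PermutationSettings = field(default_factory=PermutationSettings)
    overlap_threshold: float = 0.60
    report_percent: bool = True
    seed: int = 0
    inputs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap_threshold <= 1.0):
            raise ValidationError("overlap threshold must lie in [0, 1]")
        bad = {t: c for t, c in self.prey_taxon_map.items() if c not in PREY_CATEGORIES}
        if bad:
            raise ValidationError(f"prey_taxon_map targets outside the six categories: {bad}")

    # ------------------------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        kwargs: dict = {}
        if "prey_taxon_map" in raw:
            merged = dict(DEFAULT_PREY_TAXON_MAP)
            merged.update({str(k).lower(): v for k, v in raw["prey_taxon_map"].items()})
            kwargs["prey_taxon_map"] = merged
        for key in ("source_sets", "source_pools", "inputs"):
            if key in raw:
                kwargs[key] = raw[key]
        if "tef" in raw:
            t = raw["tef"]
            kwargs["tef"] = TefConfig(
                d15N_mean=float(t.get("d15N", {}).get("mean", 3.23)),
                d15N_sd=float(t.get("d15N", {}).get("sd", 0.79)),
                d13C_mean=float(t.get("d13C", {}).get("mean", 1.03)),
                d13C_sd=float(t.get("d13C", {}).get("sd", 0.29)),
            )
        if "mcmc" in raw:
            kwargs["mcmc"] = McmcSettings(**raw["mcmc"])
        if "permutations" in raw:
            kwargs["permutations"] = PermutationSettings(**raw["permutations"])
        for key in ("overlap_threshold", "report_percent", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        cfg = cls(**kwargs)
        # one user-visible seed fans out to every stochastic stage unless
        # a stage seed was given explicitly
        if "seed" in raw:
            if "mcmc" not in raw or "seed" not in raw.get("mcmc", {}):
                cfg.mcmc.seed = cfg.seed
            if "permutations" not in raw or "seed" not in raw.get("permutations", {}):
                cfg.permutations.seed = cfg.seed
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def input_path(self, name: str) -> Path:
        try:
            return Path(self.inputs[name])
        except KeyError:
            raise ValidationError(f"config is missing the {name!r} input path") from None
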