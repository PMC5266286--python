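"""Seeded synthetic catch, stomach and isotope datasets.

The generator reproduces the statistical structure the analysis
assumes — Poisson catches against known effort, Dirichlet stomach
compositions with a per-stratum empty probability, and isotope data
drawn from the exact forward model the mixing module inverts
(bivariate-normal sources, TEF-corrected concentration-weighted
mixture for consumers) — so every stage is testable end to end and
true parameters are recorded alongside the data.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core.types import (
    EffortRecord,
    FishRecord,
    GearClass,
    Habitat,
    Month,
    PREY_CATEGORIES,
    Species,
    ValidationError,
)
from .mixing import TEF, SourceDistribution, mixture_moments

__all__ = [
    "SourceSpec",
    "ConsumerSpec",
    "ScenarioConfig",
    "generate_catch",
    "generate_stomachs",
    "generate_isotopes",
    "generate_all",
    "default_scenario",
]

StratumKey = tuple[str, str, str]  # species, habitat, month


@dataclass(frozen=True)
class SourceSpec:
    """Bivariate-normal isotope distribution of one source group."""

    name: str
    mu: tuple[float, float]  # (d13C, d15N)
    sd: tuple[float, float]
    q: tuple[float, float]  # (C, N) fraction by weight
    n: int = 6

    def __post_init__(self) -> None:
        if min(self.sd) < 0 or self.n < 2:
            raise ValidationError(f"source {self.name}: sd >= 0 and n >= 2 required")
        if not all(0 < x <= 1 for x in self.q):
            raise ValidationError(f"source {self.name}: concentrations must lie in (0, 1]")

    def as_distribution(self) -> SourceDistribution:
        return SourceDistribution(name=self.name, mu=self.mu, omega=self.sd, q=self.q, n_samples=self.n)


@dataclass(frozen=True)
class ConsumerSpec:
    """True diet of one consumer species over its source set."""

    sources: tuple[str, ...]
    p_true: tuple[float, ...]
    n: int = 30
    sigma: tuple[float, float] = (0.3, 0.3)  # residual SD per isotope
    pct_C: float = 45.0
    pct_N: float = 12.0

    def __post_init__(self) -> None:
        p = np.asarray(self.p_true, float)
        if len(self.sources) != len(p):
            raise ValidationError("p_true dimension does not match source set")
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError("p_true must lie on the simplex")


@dataclass
class ScenarioConfig:
    """Full specification of a synthetic survey."""

    species: tuple[str, ...] = tuple(s.value for s in Species)
    habitats: tuple[str, ...] = tuple(h.value for h in Habitat)
    months: tuple[str, ...] = tuple(m.value for m in Month)
    years: tuple[int, ...] = (2005, 2006)
    #: expected CPUE (fish per 100 m^2 * night) per species x habitat x month
    cpue_intensity: dict[StratumKey, float] = field(default_factory=dict)
    #: survey net area (m^2) and nights per habitat x month x year
    net_area: float = 450.0
    nights: int = 1
    #: Dirichlet concentration over the six prey categories per stratum
    diet_alpha: dict[StratumKey, tuple[float, ...]] = field(default_factory=dict)
    empty_prob: dict[StratumKey, float] = field(default_factory=dict)
    default_empty_prob: float = 0.3
    #: per-species lognormal length parameters (mean, sd of log length in cm)
    length_logmean: dict[str, float] = field(default_factory=dict)
    length_logsd: dict[str, float] = field(default_factory=dict)
    #: weight = condition * length^3 / 100 with lognormal noise
    weight_lognoise_sd: float = 0.1
    sources: dict[str, SourceSpec] = field(default_factory=dict)
    consumers: dict[str, ConsumerSpec] = field(default_factory=dict)
    tef: TEF = field(default_factory=TEF)
    seed: int = 0

    def validate(self) -> None:
        for key, lam in self.cpue_intensity.items():
            if lam < 0:
                raise ValidationError(f"negative CPUE intensity for {key}")
        for key, alpha in self.diet_alpha.items():
            a = np.asarray(alpha, float)
            if a.shape != (len(PREY_CATEGORIES),) or (a <= 0).any():
                raise ValidationError(f"Dirichlet concentration for {key} must be {len(PREY_CATEGORIES)} positive values")
        for spec in self.consumers.values():
            for s in spec.sources:
                if s not in self.sources:
                    raise ValidationError(f"consumer references unknown source {s!r}")


# ----------------------------------------------------------------------


def generate_catch(
    config: ScenarioConfig, seed: Optional[int] = None
) -> tuple[list[FishRecord], list[EffortRecord]]:
    """Poisson catches per stratum against the configured effort.

    Stomachs are left empty here (total fullness 0); use
    :func:`generate_stomachs` to fill them.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    effort: list[EffortRecord] = []
    for hab in config.habitats:
        for mo in config.months:
            for yr in config.years:
                effort.append(
                    EffortRecord(habitat=hab, month=mo, year=yr, net_area=config.net_area, nights=config.nights)
                )
    effort_units = config.net_area / 100.0 * config.nights  # per year

    fish: list[FishRecord] = []
    counter = 0
    for sp in config.species:
        logm = config.length_logmean.get(sp, np.log(20.0))
        logs = config.length_logsd.get(sp, 0.25)
        for hab in config.habitats:
            for mo in config.months:
                lam = config.cpue_intensity.get((sp, hab, mo), 0.0)
                for yr in config.years:
                    count = rng.poisson(lam * effort_units)
                    for _ in range(count):
                        counter += 1
                        length = float(np.exp(rng.normal(logm, logs)))
                        weight = float(length**3 / 100.0 * np.exp(rng.normal(0.0, config.weight_lognoise_sd)))
                        fish.append(
                            FishRecord(
                                fish_id=f"f{counter:05d}",
                                species=sp,
                                habitat=hab,
                                month=mo,
                                year=yr,
                                total_length=length,
                                weight=weight,
                                stomach_total_fullness=0.0,
                                fullness_by_prey={},
                                gear_class=GearClass.SURVEY,
                            )
                        )
    return fish, effort


def generate_stomachs(
    fish: list[FishRecord], config: ScenarioConfig, seed: Optional[int] = None
) -> list[FishRecord]:
    """Fill stomach compositions in place (and return the list).

    Each fish is empty with its stratum's probability; otherwise total
    fullness ~ Uniform(5, 100) split by the stratum's Dirichlet.
    """
    config.validate()
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    for f in fish:
        key = (f.species.value, f.habitat.value, f.month.value)
        p_empty = config.empty_prob.get(key, config.default_empty_prob)
        if rng.random() < p_empty:
            f.stomach_total_fullness = 0.0
            f.fullness_by_prey = {}
            continue
        total = float(rng.uniform(5.0, 100.0))
        alpha = np.asarray(config.diet_alpha.get(key, np.ones(len(PREY_CATEGORIES))), float)
        split = rng.dirichlet(alpha)
        f.stomach_total_fullness = total
        f.fullness_by_prey = {cat: float(total * w) for cat, w in zip(PREY_CATEGORIES, split)}
        f.__post_init__()  # re-validate invariants
    return fish


def generate_isotopes(
    config: ScenarioConfig, seed: Optional[int] = None
) -> tuple[list, list, dict[str, np.ndarray]]:
    """Source and consumer isotope samples plus the recorded truth.

    Consumers are drawn from the exact forward model of the mixing
    module: mean m_j(p*), variance s_j(p*)^2 + sigma_j^2.
    """
    from .core.types import IsotopeSample

    config.validate()
    rng = np.random.default_rng((config.seed if seed is None else seed) + 2)
    source_samples: list[IsotopeSample] = []
    for name in sorted(config.sources):
        spec = config.sources[name]
        for i in range(spec.n):
            source_samples.append(
                IsotopeSample(
                    sample_id=f"{name}_{i + 1}",
                    group=name,
                    d13C=float(rng.normal(spec.mu[0], spec.sd[0])),
                    d15N=float(rng.normal(spec.mu[1], spec.sd[1])),
                    pct_C=spec.q[0] * 100.0,
                    pct_N=spec.q[1] * 100.0,
                )
            )

    consumer_samples: list[IsotopeSample] = []
    truth: dict[str, np.ndarray] = {}
    for sp in sorted(config.consumers):
        spec = config.consumers[sp]
        dists = [config.sources[s].as_distribution() for s in spec.sources]
        p_true = np.asarray(spec.p_true, float)
        truth[sp] = p_true
        m, s2 = mixture_moments(p_true, dists, config.tef)
        sd = np.sqrt(s2 + np.asarray(spec.sigma, float) ** 2)
        for i in range(spec.n):
            consumer_samples.append(
                IsotopeSample(
                    sample_id=f"{sp}_{i + 1}",
                    group=sp,
                    d13C=float(rng.normal(m[0], sd[0])),
                    d15N=float(rng.normal(m[1], sd[1])),
                    pct_C=spec.pct_C,
                    pct_N=spec.pct_N,
                )
            )
    return source_samples, consumer_samples, truth


def generate_all(config: ScenarioConfig, seed: Optional[int] = None):
    """Catch + stomachs + isotopes in one call."""
    fish, effort = generate_catch(config, seed)
    generate_stomachs(fish, config, seed)
    sources, consumers, truth = generate_isotopes(config, seed)
    return fish, effort, sources, consumers, truth


# ----------------------------------------------------------------------


def default_scenario(seed: int = 0) -> ScenarioConfig:
    """A bundled three-species lake scenario: 3 species x 3 habitats x
    3 months, six prey categories, a piscivorous source set for trout and
    an invertebrate/zooplankton source set for charr and whitefish."""
    sp = [s.value for s in Species]
    hab = [h.value for h in Habitat]
    mo = [m.value for m in Month]

    intensity: dict[StratumKey, float] = {}
    base = {
        ("trout", "littoral"): 9.0,
        ("trout", "profundal"): 2.0,
        ("trout", "pelagic"): 2.0,
        ("charr", "littoral"): 4.0,
        ("charr", "profundal"): 7.0,
        ("charr", "pelagic"): 2.0,
        ("whitefish", "littoral"): 4.0,
        ("whitefish", "profundal"): 2.0,
        ("whitefish", "pelagic"): 6.0,
    }
    for (s, h), lam in base.items():
        for m in mo:
            intensity[(s, h, m)] = lam

    # diet leanings: trout benthivorous/piscivorous, charr and whitefish
    # zooplanktivorous with habitat-dependent benthic components
    alpha: dict[StratumKey, tuple[float, ...]] = {}
    lean = {
        "trout": (0.5, 1.0, 0.5, 8.0, 4.0, 3.0),
        "charr": (3.0, 8.0, 1.5, 3.0, 1.0, 0.2),
        "whitefish": (4.0, 9.0, 1.0, 1.5, 1.0, 0.2),
    }
    for s in sp:
        for h in hab:
            for m in mo:
                alpha[(s, h, m)] = lean[s]

    sources = {
        "zooplankton": SourceSpec("zooplankton", mu=(-32.0, 3.0), sd=(0.8, 0.6), q=(0.45, 0.09), n=6),
        "littoral_invertebrates": SourceSpec("littoral_invertebrates", mu=(-24.0, 1.5), sd=(1.5, 0.8), q=(0.48, 0.10), n=6),
        "profundal_invertebrates": SourceSpec("profundal_invertebrates", mu=(-28.5, 5.0), sd=(0.9, 0.7), q=(0.46, 0.095), n=6),
        "benthic_invertebrates": SourceSpec("benthic_invertebrates", mu=(-25.5, 2.5), sd=(1.2, 0.8), q=(0.47, 0.10), n=12),
        "fish": SourceSpec("fish", mu=(-29.0, 7.5), sd=(0.8, 0.6), q=(0.46, 0.13), n=15),
    }
    consumers = {
        "trout": ConsumerSpec(sources=("fish", "benthic_invertebrates", "zooplankton"), p_true=(0.45, 0.40, 0.15), n=30),
        "charr": ConsumerSpec(sources=("profundal_invertebrates", "littoral_invertebrates", "zooplankton"), p_true=(0.40, 0.10, 0.50), n=25),
        "whitefish": ConsumerSpec(sources=("profundal_invertebrates", "littoral_invertebrates", "zooplankton"), p_true=(0.20, 0.10, 0.70), n=25),
    }
    return ScenarioConfig(
        cpue_intensity=intensity,
        diet_alpha=alpha,
        empty_prob={},
        default_empty_prob=0.3,
        length_logmean={"trout": np.log(21.0), "charr": np.log(20.0), "whitefish": np.log(26.0)},
        length_logsd={"trout": 0.30, "charr": 0.20, "whitefish": 0.28},
        sources=sources,
        consumers=consumers,
        seed=seed,
    )
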