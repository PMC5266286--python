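"""Bayesian linear stable-isotope mixing with trophic-enrichment
correction, source uncertainty and concentration dependence.

For proportions p on the simplex, each consumer observation X_ij
(isotope j in {d13C, d15N}) is modelled as

    X_ij ~ Normal(m_j(p), s_j(p)^2 + sigma_j^2)

    m_j(p)   = sum_k p_k q_jk (mu_jk + lambda_j) / sum_k p_k q_jk
    s_j(p)^2 = sum_k (p_k q_jk)^2 (omega_jk^2 + tau_j^2) / (sum_k p_k q_jk)^2

with a flat Dirichlet(1, ..., 1) prior on p and a half-Normal prior on
each residual SD sigma_j (scale = the consumer-sample SD of that
isotope). Sampling is random-walk Metropolis on softmax-transformed
proportions (K - 1 free coordinates, log-Jacobian included) plus the two
log-sigmas, with an adaptive step during burn-in that is frozen
afterwards. Raw (un-lipid-normalized) delta values are used throughout.

Isotope axis order everywhere in this module: index 0 = d13C, 1 = d15N.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core.types import IsotopeSample, ValidationError

__all__ = [
    "TEF",
    "SourceDistribution",
    "MixingPosterior",
    "mixture_moments",
    "fit_mixing_model",
    "select_sources",
    "summarize_posterior",
]

ISOTOPES = ("d13C", "d15N")


@dataclass(frozen=True)
class TEF:
    """Trophic enrichment factors (per mil): mean and SD per isotope."""

    d13C_mean: float = 1.03
    d13C_sd: float = 0.29
    d15N_mean: float = 3.23
    d15N_sd: float = 0.79

    def __post_init__(self) -> None:
        if self.d13C_sd < 0 or self.d15N_sd < 0:
            raise ValidationError("TEF SDs must be >= 0")

    @property
    def mean(self) -> np.ndarray:
        return np.array([self.d13C_mean, self.d15N_mean])

    @property
    def sd(self) -> np.ndarray:
        return np.array([self.d13C_sd, self.d15N_sd])


@dataclass(frozen=True)
class SourceDistribution:
    """A dietary source: isotope mean/SD and elemental concentrations."""

    name: str
    mu: tuple[float, float]  # (d13C, d15N) per mil
    omega: tuple[float, float]  # SDs, per mil
    q: tuple[float, float]  # (C, N) concentration, fraction of dry weight
    n_samples: int = 0

    def __post_init__(self) -> None:
        if min(self.omega) < 0:
            raise ValidationError(f"source {self.name}: SDs must be >= 0")
        if not all(0.0 < x <= 1.0 for x in self.q):
            raise ValidationError(f"source {self.name}: concentrations must lie in (0, 1]")


def mixture_moments(
    p: np.ndarray, sources: Sequence[SourceDistribution], tef: TEF
) -> tuple[np.ndarray, np.ndarray]:
    """(mean, variance) of the TEF-corrected, concentration-weighted
    mixture per isotope, for one proportion vector."""
    p = np.asarray(p, dtype=float)
    mu = np.array([s.mu for s in sources])  # K x 2
    om = np.array([s.omega for s in sources])
    q = np.array([s.q for s in sources])
    qp = p[:, None] * q  # K x 2
    denom = qp.sum(axis=0)
    m = (qp * (mu + tef.mean)).sum(axis=0) / denom
    s2 = (qp**2 * (om**2 + tef.sd**2)).sum(axis=0) / denom**2
    return m, s2


@dataclass
class MixingPosterior:
    """Pooled post-burn-in draws with convergence diagnostics."""

    source_names: tuple[str, ...]
    draws: np.ndarray  # n_draws x K, rows on the simplex
    sigma_draws: np.ndarray  # n_draws x 2 residual SDs
    n_chains: int
    rhat: np.ndarray = field(default_factory=lambda: np.array([]))
    ess: np.ndarray = field(default_factory=lambda: np.array([]))
    converged: bool = True

    def __post_init__(self) -> None:
        d = np.asarray(self.draws, dtype=float)
        if (d < -1e-12).any() or np.abs(d.sum(axis=1) - 1.0).max(initial=0.0) > 1e-9:
            raise ValidationError("posterior draws must lie on the simplex")

    def mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)


# ----------------------------------------------------------------------
# sampler internals


def _softmax_full(z: np.ndarray) -> np.ndarray:
    zf = np.append(z, 0.0)
    zf -= zf.max()
    e = np.exp(zf)
    return e / e.sum()


class _LogTarget:
    def __init__(
        self,
        stats: tuple[np.ndarray, np.ndarray, int],  # xbar(2,), ss(2,), n
        sources: Sequence[SourceDistribution],
        tef: TEF,
        sigma_scale: np.ndarray,
    ):
        self.xbar, self.ss, self.n = stats
        self.mu = np.array([s.mu for s in sources])
        self.om2 = np.array([s.omega for s in sources]) ** 2
        self.q = np.array([s.q for s in sources])
        self.lam = tef.mean
        self.tau2 = tef.sd**2
        self.h2 = sigma_scale**2
        self.K = len(sources)

    def __call__(self, theta: np.ndarray) -> float:
        z = theta[: self.K - 1]
        u = theta[self.K - 1 :]
        p = _softmax_full(z)
        if (p <= 0).any():
            return -math.inf
        log_jac = float(np.log(p).sum())
        sigma2 = np.exp(2 * u)
        # half-normal prior on sigma plus the log-sigma Jacobian
        log_prior = float(-(sigma2 / (2 * self.h2)).sum() + u.sum())
        qp = p[:, None] * self.q
        denom = qp.sum(axis=0)
        m = (qp * (self.mu + self.lam)).sum(axis=0) / denom
        s2 = (qp**2 * (self.om2 + self.tau2)).sum(axis=0) / denom**2
        v = s2 + sigma2
        loglik = float(
            (-0.5 * self.n * np.log(2 * math.pi * v) - (self.ss + self.n * (self.xbar - m) ** 2) / (2 * v)).sum()
        )
        return log_jac + log_prior + loglik


def _run_chain(
    target: _LogTarget,
    iterations: int,
    burn_in: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    dim = target.K - 1 + 2
    theta = np.concatenate([0.1 * rng.standard_normal(target.K - 1), 0.5 * np.log(target.h2) + 0.1 * rng.standard_normal(2)])
    lp = target(theta)
    scale = 0.5
    sigma_vec = np.ones(dim)  # per-coordinate proposal scales
    accepted = 0
    window = 0
    history = np.empty((burn_in, dim))
    kept_p = np.empty((iterations - burn_in, target.K))
    kept_s = np.empty((iterations - burn_in, 2))
    for it in range(iterations):
        prop = theta + scale * sigma_vec * rng.standard_normal(dim)
        lp_prop = target(prop)
        if math.log(rng.random()) < lp_prop - lp:
            theta, lp = prop, lp_prop
            accepted += 1
        window += 1
        if it < burn_in:
            history[it] = theta
        if it < burn_in and window == 50:
            # global scale targets ~0.3 acceptance; per-coordinate scales
            # track the posterior spread seen so far; both frozen after burn-in
            rate = accepted / window
            scale *= math.exp(rate - 0.3)
            if it >= 200:
                sd = history[max(0, it - 1000): it].std(axis=0)
                sigma_vec = np.maximum(sd, 1e-3)
            accepted = 0
            window = 0
        if it >= burn_in:
            j = it - burn_in
            kept_p[j] = _softmax_full(theta[: target.K - 1])
            kept_s[j] = np.exp(theta[target.K - 1 :])
    return kept_p, kept_s


def _split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction for one scalar quantity.

    ``chains``: n_chains x n_draws."""
    m, L = chains.shape
    half = L // 2
    if half < 2:
        return math.nan
    segs = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    W = segs.var(axis=1, ddof=1).mean()
    B = half * segs.mean(axis=1).var(ddof=1)
    if W <= 0:
        return 1.0
    var_hat = (half - 1) / half * W + B / half
    return float(math.sqrt(var_hat / W))


def _ess(chains: np.ndarray) -> float:
    """Effective sample size via Geyer's initial positive sequence."""
    m, L = chains.shape
    if L < 4:
        return float(m * L)
    rho_sum = 0.0
    for c in chains:
        c = c - c.mean()
        var = c.var()
        if var <= 0:
            continue
        acf = np.correlate(c, c, mode="full")[L - 1 :] / (var * L)
        s = 0.0
        for t in range(1, L - 2, 2):
            pair = acf[t] + acf[t + 1]
            if pair < 0:
                break
            s += pair
        rho_sum += s
    rho = rho_sum / m
    return float(m * L / (1 + 2 * rho))


def fit_mixing_model(
    consumer_d13C: Sequence[float],
    consumer_d15N: Sequence[float],
    sources: Sequence[SourceDistribution],
    tef: TEF = TEF(),
    chains: int = 4,
    iterations: int = 4000,
    burn_in: int = 1500,
    seed: int = 0,
    rhat_threshold: float = 1.1,
) -> MixingPosterior:
    """Sample the posterior of source proportions for one consumer group."""
    x = np.column_stack([np.asarray(consumer_d13C, float), np.asarray(consumer_d15N, float)])
    if x.shape[0] < 1:
        raise ValidationError("need at least one consumer sample")
    if not (2 <= len(sources) <= 5):
        raise ValidationError(f"need 2-5 sources, got {len(sources)}")
    if chains < 2:
        raise ValidationError("need at least 2 chains")
    if burn_in >= iterations:
        raise ValidationError("burn_in must be smaller than iterations")

    n = x.shape[0]
    xbar = x.mean(axis=0)
    ss = ((x - xbar) ** 2).sum(axis=0)
    sd = x.std(axis=0, ddof=1) if n > 1 else np.zeros(2)
    sigma_scale = np.maximum(sd, 0.5)  # weakly-informative floor
    target = _LogTarget((xbar, ss, n), sources, tef, sigma_scale)

    seqs = np.random.SeedSequence(seed).spawn(chains)
    per_chain_p = []
    per_chain_s = []
    for sseq in seqs:
        kp, ks = _run_chain(target, iterations, burn_in, np.random.default_rng(sseq))
        per_chain_p.append(kp)
        per_chain_s.append(ks)

    K = len(sources)
    rhat = np.array([_split_rhat(np.stack([c[:, k] for c in per_chain_p])) for k in range(K)])
    ess = np.array([_ess(np.stack([c[:, k] for c in per_chain_p])) for k in range(K)])
    converged = bool(np.all(np.nan_to_num(rhat, nan=1.0) <= rhat_threshold))

    return MixingPosterior(
        source_names=tuple(s.name for s in sources),
        draws=np.concatenate(per_chain_p, axis=0),
        sigma_draws=np.concatenate(per_chain_s, axis=0),
        n_chains=chains,
        rhat=rhat,
        ess=ess,
        converged=converged,
    )


# ----------------------------------------------------------------------
# source selection


def select_sources(
    species: str,
    samples: Iterable[IsotopeSample],
    source_sets: Mapping[str, Sequence[str]],
    source_pools: Optional[Mapping[str, Sequence[str]]] = None,
) -> list[SourceDistribution]:
    """Build the per-species source set from the isotope table.

    ``source_sets`` maps consumer species to source-group names;
    ``source_pools`` maps a pooled source name (e.g. a "fish" source
    combining prey-sized fish groups) to its member group labels.
    """
    source_pools = source_pools or {}
    try:
        wanted = source_sets[species]
    except KeyError:
        raise ValidationError(f"no source set configured for species {species!r}") from None

    by_group: dict[str, list[IsotopeSample]] = {}
    for s in samples:
        by_group.setdefault(s.group, []).append(s)

    out: list[SourceDistribution] = []
    for name in wanted:
        members = source_pools.get(name, [name])
        pooled = [s for g in members for s in by_group.get(g, [])]
        if not pooled:
            raise ValidationError(
                f"source group {name!r} (members {list(members)}) absent from isotope data"
            )
        if len(pooled) < 2:
            raise ValidationError(f"source group {name!r}: need >= 2 samples to estimate SDs")
        d13 = np.array([s.d13C for s in pooled])
        d15 = np.array([s.d15N for s in pooled])
        out.append(
            SourceDistribution(
                name=name,
                mu=(float(d13.mean()), float(d15.mean())),
                omega=(float(d13.std(ddof=1)), float(d15.std(ddof=1))),
                q=(
                    float(np.mean([s.pct_C for s in pooled]) / 100.0),
                    float(np.mean([s.pct_N for s in pooled]) / 100.0),
                ),
                n_samples=len(pooled),
            )
        )
    return out


# ----------------------------------------------------------------------
# summaries


def _marginal_mode(values: np.ndarray) -> float:
    """Histogram-smoothed marginal mode on [0, 1]."""
    if np.ptp(values) < 1e-12:
        return float(values[0])
    from scipy.stats import gaussian_kde

    grid = np.linspace(max(0.0, values.min()), min(1.0, values.max()), 512)
    dens = gaussian_kde(values)(grid)
    return float(grid[np.argmax(dens)])


def summarize_posterior(posterior: MixingPosterior) -> pd.DataFrame:
    """Mean with 5-95th percentiles (linear interpolation) plus the
    marginal mode with a 2.5-97.5% credibility interval, per source."""
    d = posterior.draws
    if d.size == 0:
        raise ValidationError("empty draw set")
    rows = []
    for k, name in enumerate(posterior.source_names):
        v = d[:, k]
        rows.append(
            {
                "source": name,
                "mean": float(v.mean()),
                "p5": float(np.percentile(v, 5)),
                "p95": float(np.percentile(v, 95)),
                "mode": _marginal_mode(v),
                "lo95": float(np.percentile(v, 2.5)),
                "hi95": float(np.percentile(v, 97.5)),
                "rhat": float(posterior.rhat[k]) if posterior.rhat.size else math.nan,
                "ess": float(posterior.ess[k]) if posterior.ess.size else math.nan,
            }
        )
    return pd.DataFrame(rows)
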