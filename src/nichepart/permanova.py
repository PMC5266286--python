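"""Bray-Curtis dissimilarity and permutational multivariate ANOVA.

The sum-of-squares partition follows the inner-product formulation:
squared dissimilarities are Gower-centered into G = -0.5 * C D^2 C, and
the SS attributable to a model term is tr(H_term G) where H_term is the
increment in hat (projection) matrices when the term's dummy columns
enter the design. Terms are fitted sequentially (Type I) in the order
given, so SS adds up exactly on any design.

Significance uses residual permutation under the reduced model
(Freedman-Lane): for a tested term, rows are regenerated as
fitted-part + permuted residual of the model containing only the
preceding terms. When the number of distinct row permutations (n!) does
not exceed the requested count, every permutation is enumerated and the
p-value is exact; otherwise p = (1 + #exceedances) / (1 + n_perm).
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core.types import ValidationError

__all__ = [
    "DissimilarityMatrix",
    "PermanovaTable",
    "bray_curtis",
    "permanova",
]

_EPS = 1e-12


@dataclass(frozen=True)
class DissimilarityMatrix:
    labels: tuple
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValidationError("dissimilarity matrix shape does not match labels")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValidationError("dissimilarity matrix must be symmetric")
        if np.abs(np.diag(d)).max(initial=0.0) > 1e-12:
            raise ValidationError("dissimilarity matrix must have a zero diagonal")
        if (d < -1e-12).any() or (d > 1 + 1e-12).any():
            raise ValidationError("Bray-Curtis entries must lie in [0, 1]")
        object.__setattr__(self, "d", d)

    def similarity_percent(self) -> np.ndarray:
        return 100.0 * (1.0 - self.d)


def bray_curtis(profiles: np.ndarray, labels: Optional[Sequence] = None) -> DissimilarityMatrix:
    """d(x, y) = sum|x_i - y_i| / sum(x_i + y_i), rows on a common
    (percent or fraction) scale."""
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("need at least two profile rows")
    if (X < 0).any():
        raise ValidationError("profiles must be non-negative")
    row_sums = X.sum(axis=1)
    if (row_sums <= 0).any():
        bad = np.flatnonzero(row_sums <= 0).tolist()
        raise ValidationError(f"all-zero profile rows {bad}: Bray-Curtis undefined")
    diff = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    tot = row_sums[:, None] + row_sums[None, :]
    d = diff / tot
    np.fill_diagonal(d, 0.0)
    if labels is None:
        labels = tuple(range(X.shape[0]))
    return DissimilarityMatrix(labels=tuple(labels), d=d)


@dataclass
class PermanovaTable:
    rows: list[dict] = field(default_factory=list)
    n: int = 0
    total_ss: float = 0.0
    term_order: tuple[str, ...] = ()
    degenerate: bool = False  # total SS ~ 0, all tests undefined

    def to_dataframe(self) -> pd.DataFrame:
        cols = ["term", "df", "SS", "MS", "pseudo_F", "p_perm", "permutations", "exhaustive"]
        return pd.DataFrame(self.rows, columns=cols)

    def __getitem__(self, term: str) -> dict:
        for row in self.rows:
            if row["term"] == term:
                return row
        raise KeyError(term)


# ----------------------------------------------------------------------
# design construction


def _gower_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D**2
    n = A.shape[0]
    C = np.eye(n) - np.full((n, n), 1.0 / n)
    return C @ A @ C


def _term_dummies(factors: pd.DataFrame, term: str) -> np.ndarray:
    """Full one-hot columns for a main effect or ':'-joined interaction."""
    parts = term.split(":")
    for p in parts:
        if p not in factors.columns:
            raise ValidationError(f"unknown factor {p!r} in term {term!r}")
    combo = factors[parts[0]].astype(str)
    for p in parts[1:]:
        combo = combo + "\x1f" + factors[p].astype(str)
    return pd.get_dummies(combo).to_numpy(dtype=float)


def _incremental_bases(factors: pd.DataFrame, terms: Sequence[str]) -> tuple[list[np.ndarray], list[int]]:
    """Orthonormal bases Q_0 (intercept), Q_1, ..., Q_T for nested
    designs, plus the df gained by each term (rank increments)."""
    n = len(factors)
    Q = np.full((n, 1), 1.0 / math.sqrt(n))
    bases = [Q]
    dfs: list[int] = []
    for term in terms:
        cols = _term_dummies(factors, term)
        added = []
        for j in range(cols.shape[1]):
            v = cols[:, j].copy()
            # orthogonalize against current basis (twice, for stability)
            for _ in range(2):
                v -= Q @ (Q.T @ v)
            norm = np.linalg.norm(v)
            if norm > 1e-8 * math.sqrt(n):
                v /= norm
                Q = np.column_stack([Q, v])
                added.append(v)
        dfs.append(len(added))
        bases.append(Q)
    return bases, dfs


def _ss_between(Q_prev: np.ndarray, Q_curr: np.ndarray, G: np.ndarray) -> float:
    """tr((H_curr - H_prev) G) via the basis columns gained."""
    new = Q_curr[:, Q_prev.shape[1]:]
    return float(np.einsum("ij,ji->", new.T @ G, new))


def _residual_ss(Q_full: np.ndarray, G: np.ndarray) -> float:
    return float(np.trace(G) - np.einsum("ij,ji->", Q_full.T @ G, Q_full))


def permanova(
    dmat: DissimilarityMatrix | np.ndarray,
    factors: pd.DataFrame,
    terms: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaTable:
    """Partition a dissimilarity matrix by the given terms and test each
    with a residual-permutation pseudo-F.

    ``factors`` has one row per dissimilarity-matrix row and one column
    per factor; ``terms`` are factor names or 'a:b' interactions, fitted
    in order (sequential SS).
    """
    D = dmat.d if isinstance(dmat, DissimilarityMatrix) else np.asarray(dmat, dtype=float)
    n = D.shape[0]
    if len(factors) != n:
        raise ValidationError("factor table length does not match distance matrix")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if factors.isna().any().any():
        raise ValidationError("factor levels must be fully specified for every row")

    G = _gower_center(D)
    total_ss = float(np.trace(G))
    table = PermanovaTable(n=n, total_ss=total_ss, term_order=tuple(terms))

    bases, dfs = _incremental_bases(factors, terms)
    for term, df in zip(terms, dfs):
        if df == 0:
            raise ValidationError(f"term {term!r} adds zero degrees of freedom (aliased with earlier terms)")
    Q_full = bases[-1]
    df_res = n - Q_full.shape[1]
    if df_res <= 0:
        raise ValidationError(
            "residual degrees of freedom is zero: the requested terms saturate the design "
            "(drop the highest-order interaction)"
        )
    if total_ss <= _EPS:
        # all rows identical: tests are undefined, not p = 0
        table.degenerate = True
        for term, df in zip(terms, dfs):
            table.rows.append(
                {"term": term, "df": df, "SS": 0.0, "MS": 0.0, "pseudo_F": math.nan,
                 "p_perm": math.nan, "permutations": 0, "exhaustive": False}
            )
        table.rows.append(
            {"term": "Residual", "df": df_res, "SS": 0.0, "MS": 0.0, "pseudo_F": math.nan,
             "p_perm": math.nan, "permutations": 0, "exhaustive": False}
        )
        table.rows.append(
            {"term": "Total", "df": n - 1, "SS": 0.0, "MS": math.nan, "pseudo_F": math.nan,
             "p_perm": math.nan, "permutations": 0, "exhaustive": False}
        )
        return table

    ss_res = _residual_ss(Q_full, G)
    ms_res = ss_res / df_res

    rng = np.random.default_rng(seed)
    exhaustive = math.factorial(n) <= n_perm
    I = np.eye(n)

    for t, (term, df) in enumerate(zip(terms, dfs)):
        Q_prev, Q_curr = bases[t], bases[t + 1]
        ss = _ss_between(Q_prev, Q_curr, G)
        ms = ss / df
        f_obs = ms / ms_res

        # Freedman-Lane: reduced model = terms before this one
        R = Q_prev @ Q_prev.T
        IR = I - R

        def f_stat(Gp: np.ndarray) -> float:
            ss_t = _ss_between(Q_prev, Q_curr, Gp)
            ss_r = _residual_ss(Q_full, Gp)
            if ss_r <= _EPS:
                return math.inf if ss_t > _EPS else 0.0
            return (ss_t / df) / (ss_r / df_res)

        if exhaustive:
            count = 0
            total = 0
            for perm in itertools.permutations(range(n)):
                M = R + IR[list(perm), :]
                Gp = M @ G @ M.T
                if f_stat(Gp) >= f_obs - 1e-12:
                    count += 1
                total += 1
            p = count / total
            perms_used = total
        else:
            exceed = 0
            for _ in range(n_perm):
                perm = rng.permutation(n)
                M = R + IR[perm, :]
                Gp = M @ G @ M.T
                if f_stat(Gp) >= f_obs - 1e-12:
                    exceed += 1
            p = (1 + exceed) / (1 + n_perm)
            perms_used = n_perm

        table.rows.append(
            {
                "term": term,
                "df": df,
                "SS": ss,
                "MS": ms,
                "pseudo_F": f_obs,
                "p_perm": p,
                "permutations": perms_used,
                "exhaustive": exhaustive,
            }
        )

    table.rows.append(
        {"term": "Residual", "df": df_res, "SS": ss_res, "MS": ms_res,
         "pseudo_F": math.nan, "p_perm": math.nan, "permutations": 0, "exhaustive": exhaustive}
    )
    table.rows.append(
        {"term": "Total", "df": n - 1, "SS": total_ss, "MS": math.nan,
         "pseudo_F": math.nan, "p_perm": math.nan, "permutations": 0, "exhaustive": exhaustive}
    )
    return table
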