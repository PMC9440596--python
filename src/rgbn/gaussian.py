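"""Gaussian sufficient statistics, Fisher-z tests, and the BIC score.

Every structure learner works from the same moments: sample size, means and
covariance.  Partial correlations come from the inverse of the relevant
covariance submatrix; the Fisher z statistic is sqrt(n - |Z| - 3) *
atanh(rho) with a two-sided normal p-value.  The network score is the
decomposable Gaussian BIC: per node, the linear-Gaussian log-likelihood
given its parents minus ((|Pa| + 2) / 2) * ln(n) — one penalty unit per
coefficient, intercept and residual variance.  Higher is better.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .dag import Dag

logger = logging.getLogger(__name__)

NEG_INF = float("-inf")


@dataclass(frozen=True)
class SufficientStats:
    """Sample size, means, and MLE covariance of a data table."""

    n: int
    names: tuple[str, ...]
    means: np.ndarray
    cov: np.ndarray  # denominator n (MLE), used by the likelihood

    def __post_init__(self) -> None:
        k = len(self.names)
        if self.cov.shape != (k, k):
            raise ValueError("covariance shape does not match variable names")
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")
        if self.n <= k:
            raise ValueError(f"need n > number of variables ({self.n} <= {k})")

    @staticmethod
    def from_table(table: pd.DataFrame) -> "SufficientStats":
        x = table.to_numpy(dtype=float)
        n = x.shape[0]
        means = x.mean(axis=0)
        cov = np.cov(x, rowvar=False, ddof=0)
        cov = np.atleast_2d(cov)
        return SufficientStats(n, tuple(table.columns), means, cov)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def sub_cov(self, names: list[str]) -> np.ndarray:
        idx = [self.index(v) for v in names]
        return self.cov[np.ix_(idx, idx)]


def drop_constant_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Remove zero-variance columns (they carry no structural information)."""
    sds = table.std(ddof=0)
    const = [c for c in table.columns if sds[c] == 0 or not np.isfinite(sds[c])]
    if const:
        logger.warning("dropping constant column(s) before learning: %s", const)
        return table.drop(columns=const)
    return table


def partial_correlation(
    stats: SufficientStats, x: str, y: str, z: list[str] | tuple[str, ...] = ()
) -> float:
    """Partial correlation of x and y given Z, from the covariance inverse."""
    z = list(z)
    if x == y:
        raise ValueError("x and y must differ")
    if x in z or y in z:
        raise ValueError("conditioning set must exclude x and y")
    sub = stats.sub_cov([x, y] + z)
    try:
        prec = np.linalg.inv(sub)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular covariance for ({x}, {y} | {z})"
        ) from exc
    denom = prec[0, 0] * prec[1, 1]
    if denom <= 0:
        raise np.linalg.LinAlgError("non-positive precision diagonal")
    return float(np.clip(-prec[0, 1] / math.sqrt(denom), -1.0, 1.0))


def fisher_z_partial_correlation(
    stats: SufficientStats, x: str, y: str, z: list[str] | tuple[str, ...] = ()
) -> tuple[float, float, float]:
    """(partial correlation, Fisher z statistic, two-sided p-value)."""
    z = list(z)
    dof = stats.n - len(z) - 3
    if dof <= 0:
        raise ValueError(f"need n - |Z| - 3 > 0 (n={stats.n}, |Z|={len(z)})")
    rho = partial_correlation(stats, x, y, z)
    r = np.clip(rho, -1 + 1e-15, 1 - 1e-15)
    zstat = math.sqrt(dof) * math.atanh(r)
    p = 2.0 * special.ndtr(-abs(zstat))
    return rho, float(zstat), float(p)


class FamilyScoreCache:
    """Memoized per-family Gaussian BIC terms for one dataset."""

    def __init__(self, stats: SufficientStats):
        self.stats = stats
        self._cache: dict[tuple[str, frozenset], float] = {}

    def family_score(self, node: str, parents: frozenset[str] | set[str]) -> float:
        key = (node, frozenset(parents))
        if key in self._cache:
            return self._cache[key]
        score = self._compute(node, sorted(key[1]))
        self._cache[key] = score
        return score

    def _compute(self, node: str, parents: list[str]) -> float:
        st = self.stats
        n = st.n
        i = st.index(node)
        var_v = st.cov[i, i]
        if parents:
            s_pp = st.sub_cov(parents)
            idx_p = [st.index(p) for p in parents]
            s_vp = st.cov[i, idx_p]
            try:
                sol = np.linalg.solve(s_pp, s_vp)
            except np.linalg.LinAlgError:
                return NEG_INF
            sigma2 = float(var_v - s_vp @ sol)
        else:
            sigma2 = float(var_v)
        if sigma2 < 1e-12:
            sigma2 = 1e-12  # numerically exact fit; keep the score finite
        loglik = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
        penalty = 0.5 * (len(parents) + 2) * math.log(n)
        return loglik - penalty


def gaussian_bic(dag: Dag, stats: SufficientStats, cache: FamilyScoreCache | None = None) -> float:
    """Decomposable network score: sum of family scores; higher is better."""
    unknown = set(dag.nodes) - set(stats.names)
    if unknown:
        raise ValueError(f"dag nodes missing from stats: {sorted(unknown)}")
    cache = cache or FamilyScoreCache(stats)
    return sum(cache.family_score(v, frozenset(dag.parents(v))) for v in dag.nodes)
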