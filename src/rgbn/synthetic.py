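"""Synthetic cohort generator calibrated to the published summary tables.

The study cohort is not public, so analyses are exercised on simulated data
built in two layers:

1. **Anthropometrics** — age, weight, height, waist and hip circumference
   are drawn from a Gaussian copula whose margins are moment-matched to the
   published per-sex mean/SD/skewness (shifted log-normal when |skewness| >=
   0.1, normal otherwise).  BMI is computed deterministically as
   weight / (height/100)^2, never sampled.
2. **Body composition** — the nine DXA compartments are generated in
   z-score space from the published standardized prediction models treated
   as a linear Gaussian structural equation model (SEM): for each response
   v, ``z_v = beta_v . z_Pa(v) + eps_v``.  The residual variance is set to
   ``Var(beta . z_Pa) * (1 - R2) / R2`` from the realized parent columns, so
   an ordinary least-squares refit of v on its parents recovers both the
   standardized coefficients and the explained variance R2 by construction,
   even with correlated parents.

The published tables carry two internal inconsistencies (a girls trunk-bone
SD incompatible with its own quartiles; boys arm-bone quartiles incompatible
with the mean).  ``validate_marginals`` repairs SDs that disagree with the
IQR-implied robust SD and logs every repair; nothing is silently altered.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import reported
from .catalog import (
    ALL_NAMES,
    COVARIATE_NAMES,
    GROUP_SIZES,
    GROUPS,
    RESPONSE_NAMES,
    GroupSpec,
    VariableCatalog,
)
from .dag import CycleError, Dag
from .preprocess import compute_bmi
from .reported import MarginalRecord

logger = logging.getLogger(__name__)

#: Copula covariates in matrix order (BMI excluded: deterministic).
COPULA_VARS = ("Age", "W", "H", "WC", "HC")

#: Physiologic clipping bounds applied to sampled covariates.
PHYSIOLOGIC_BOUNDS = {
    # the study's age range is enforced per group via age windows, not here
    "Age": (5.0, 25.0),
    "W": (15.0, 150.0),
    "H": (100.0, 210.0),
    "WC": (35.0, 130.0),
    "HC": (45.0, 150.0),
}

#: |SD - IQR/1.349| beyond this many robust-SD units triggers a repair.
_SD_REPAIR_FACTOR = 3.0
_NORMAL_IQR = 1.349  # IQR of the standard normal


# ---------------------------------------------------------------------------
# Marginal specs and repair
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarginalSpec:
    """Per-group marginal summaries (physical units), post-repair."""

    group: str
    records: dict[str, MarginalRecord]

    def __getitem__(self, var: str) -> MarginalRecord:
        return self.records[var]


def validate_marginals(
    records: dict[str, MarginalRecord], context: str = ""
) -> tuple[dict[str, MarginalRecord], list[str]]:
    """Repair SDs inconsistent with their own quartiles; log everything.

    An SD is replaced by IQR/1.349 when it sits more than three robust-SD
    units away from that estimate.  Means outside [q25, q75] are logged as
    suspect but left alone (only the SD enters the generator).
    """
    repaired: dict[str, MarginalRecord] = {}
    log: list[str] = []
    for var, rec in records.items():
        robust_sd = rec.iqr / _NORMAL_IQR
        new = rec
        if robust_sd > 0 and abs(rec.sd - robust_sd) > _SD_REPAIR_FACTOR * robust_sd:
            new = MarginalRecord(
                rec.mean, rec.q25, rec.q50, rec.q75, round(robust_sd, 4), rec.skewness
            )
            msg = (
                f"{context}{var}: SD {rec.sd} inconsistent with IQR {rec.iqr:.2f}"
                f" -> repaired to {new.sd}"
            )
            log.append(msg)
            logger.warning(msg)
        if not (rec.q25 <= rec.mean <= rec.q75):
            msg = f"{context}{var}: mean {rec.mean} outside quartiles [{rec.q25}, {rec.q75}] (left as printed)"
            log.append(msg)
            logger.warning(msg)
        repaired[var] = new
    return repaired, log


# ---------------------------------------------------------------------------
# Covariate dependence
# ---------------------------------------------------------------------------

#: Plausible adolescent anthropometric correlations (not published; the
#: study reports no covariate correlation matrix).  Order = COPULA_VARS.
_DEFAULT_CORR = {
    ("Age", "H"): 0.8,
    ("Age", "W"): 0.7,
    ("W", "H"): 0.7,
    ("W", "WC"): 0.85,
    ("W", "HC"): 0.9,
    ("H", "WC"): 0.4,
    ("H", "HC"): 0.55,
    ("WC", "HC"): 0.85,
    ("Age", "WC"): 0.45,
    ("Age", "HC"): 0.6,
}


def nearest_positive_definite(a: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Nearest correlation-like positive-definite repair (eigenvalue clip)."""
    sym = (a + a.T) / 2
    w, v = np.linalg.eigh(sym)
    if w.min() > eps:
        return sym
    w = np.clip(w, eps, None)
    fixed = v @ np.diag(w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


@dataclass(frozen=True)
class CovariateDependence:
    """Gaussian-copula correlation over the five sampled covariates."""

    group: str
    matrix: np.ndarray  # (5, 5) over COPULA_VARS

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(COPULA_VARS),) * 2:
            raise ValueError(f"correlation matrix must be {len(COPULA_VARS)}x{len(COPULA_VARS)}")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(m).min() <= 0:
            raise ValueError("correlation matrix must be positive definite")
        object.__setattr__(self, "matrix", m)


def default_dependence(group: str) -> CovariateDependence:
    k = len(COPULA_VARS)
    m = np.eye(k)
    for (a, b), r in _DEFAULT_CORR.items():
        i, j = COPULA_VARS.index(a), COPULA_VARS.index(b)
        m[i, j] = m[j, i] = r
    return CovariateDependence(group, nearest_positive_definite(m))


# ---------------------------------------------------------------------------
# Moment-matched margins
# ---------------------------------------------------------------------------

class Margin:
    """Univariate margin matched to (mean, sd, skewness).

    Normal when |skewness| < 0.1; otherwise a shifted log-normal with the
    exact first three moments (mirrored for negative skewness).
    """

    def __init__(self, mean: float, sd: float, skewness: float):
        if sd <= 0:
            raise ValueError("sd must be positive")
        self.mean, self.sd, self.skewness = mean, sd, skewness
        g = abs(skewness)
        if g < 0.1:
            self._dist = stats.norm(loc=mean, scale=sd)
            self._mirror = False
        else:
            # solve (w + 2)^2 (w - 1) = g^2 for w = exp(sigma^2) > 1
            from scipy.optimize import brentq

            w = brentq(lambda w: (w + 2) ** 2 * (w - 1) - g * g, 1 + 1e-12, 1e3)
            sigma = float(np.sqrt(np.log(w)))
            scale = sd / float(np.sqrt(w * (w - 1)))  # = exp(mu)
            self._mirror = skewness < 0
            if not self._mirror:
                loc = mean - scale * float(np.sqrt(w))
                self._dist = stats.lognorm(s=sigma, scale=scale, loc=loc)
            else:
                # X = c - Y with Y ~ lognormal; choose c so E[X] = mean
                c = mean + scale * float(np.sqrt(w))
                self._dist = stats.lognorm(s=sigma, scale=scale, loc=-c)
                # then X = -(Y') where Y' = Y - c, i.e. X = c - lognorm(...)

    def ppf(self, u: np.ndarray) -> np.ndarray:
        if self._mirror:
            return -self._dist.ppf(1.0 - np.asarray(u))
        return self._dist.ppf(u)

    def cdf(self, x: np.ndarray) -> np.ndarray:
        if self._mirror:
            return 1.0 - self._dist.cdf(-np.asarray(x))
        return self._dist.cdf(x)

    def ppf_truncated(self, u: np.ndarray, window: tuple[float, float]) -> np.ndarray:
        lo, hi = window
        a, b = float(self.cdf(np.array(lo))), float(self.cdf(np.array(hi)))
        if not b > a:
            raise ValueError(f"empty truncation window {window}")
        return self.ppf(a + np.asarray(u) * (b - a))


# ---------------------------------------------------------------------------
# Ground-truth SEM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruthSEM:
    """Published standardized prediction models as a generative linear SEM."""

    group: str
    models: dict[str, reported.ModelRow]  # response -> ([(parent, beta)...], R2)

    def __post_init__(self) -> None:
        for resp, (parents, r2) in self.models.items():
            if resp not in RESPONSE_NAMES:
                raise ValueError(f"unknown response {resp}")
            if not 0 < r2 <= 1:
                raise ValueError(f"R^2 for {resp} must be in (0, 1], got {r2}")
            for p, _ in parents:
                if p not in ALL_NAMES:
                    raise ValueError(f"unknown parent {p} of {resp}")
                if p == resp:
                    raise ValueError(f"self-loop {resp}->{resp}")
        self.dag()  # raises CycleError if cyclic

    def parents(self, resp: str) -> list[str]:
        return [p for p, _ in self.models[resp][0]]

    def betas(self, resp: str) -> np.ndarray:
        return np.array([b for _, b in self.models[resp][0]])

    def r2(self, resp: str) -> float:
        return self.models[resp][1]

    @property
    def covariates_used(self) -> tuple[str, ...]:
        used = {
            p
            for parents, _ in self.models.values()
            for p, _ in parents
            if p in COVARIATE_NAMES
        }
        return tuple(v for v in COVARIATE_NAMES if v in used)

    def response_edges(self) -> set[tuple[str, str]]:
        """All generating arcs into responses (truth for recovery tests)."""
        return {
            (p, resp)
            for resp, (parents, _) in self.models.items()
            for p, _ in parents
        }

    def dag(self) -> Dag:
        return Dag(ALL_NAMES, self.response_edges())

    def topological_responses(self) -> list[str]:
        order = self.dag().topological_order()
        return [v for v in order if v in self.models]


def _derived_bmi_record(records: dict[str, MarginalRecord]) -> MarginalRecord:
    """Model-implied BMI moments, used as BMI's z-score anchors.

    BMI is computed from weight and height, never sampled, so its mean and
    SD under the generator differ slightly from the published summary (a
    mean of ratios is not a ratio of means).  Standardizing BMI inside the
    SEM with its own model-implied moments keeps every response calibrated;
    the published BMI row remains a validation reference.  Deterministic:
    fixed internal seed, large n.
    """
    rng = np.random.default_rng(987654321)
    corr_wh = _DEFAULT_CORR[("W", "H")]
    z = rng.standard_normal((200_000, 2))
    z[:, 1] = corr_wh * z[:, 0] + math.sqrt(1 - corr_wh**2) * z[:, 1]
    u = stats.norm.cdf(z)
    w_rec, h_rec = records["W"], records["H"]
    w = Margin(w_rec.mean, w_rec.sd, w_rec.skewness).ppf(np.clip(u[:, 0], 1e-12, 1 - 1e-12))
    h = Margin(h_rec.mean, h_rec.sd, h_rec.skewness).ppf(np.clip(u[:, 1], 1e-12, 1 - 1e-12))
    w = np.clip(w, *PHYSIOLOGIC_BOUNDS["W"])
    h = np.clip(h, *PHYSIOLOGIC_BOUNDS["H"])
    bmi = compute_bmi(w, h)
    q25, q50, q75 = np.percentile(bmi, [25, 50, 75])
    from scipy.stats import skew as _skew

    return MarginalRecord(
        round(float(bmi.mean()), 4),
        round(float(q25), 4),
        round(float(q50), 4),
        round(float(q75), 4),
        round(float(bmi.std(ddof=1)), 4),
        round(float(_skew(bmi)), 4),
    )


# ---------------------------------------------------------------------------
# Default study specs
# ---------------------------------------------------------------------------

def default_study_specs() -> tuple[
    VariableCatalog,
    dict[str, MarginalSpec],
    dict[str, CovariateDependence],
    dict[str, GroundTruthSEM],
]:
    """All four groups' specs transcribed from the published tables.

    Marginals are per sex (the publication reports them by sex only), so
    the two groups of one sex share records; each group keeps its own age
    window.  SDs inconsistent with quartiles are repaired and logged.
    """
    catalog = VariableCatalog()
    marginals: dict[str, MarginalSpec] = {}
    dependence: dict[str, CovariateDependence] = {}
    sems: dict[str, GroundTruthSEM] = {}
    repaired_by_sex = {}
    for sex in ("M", "F"):
        repaired_by_sex[sex], _ = validate_marginals(
            reported.SUMMARY_STATS[sex], context=f"{sex}/"
        )
        repaired_by_sex[sex]["BMI"] = _derived_bmi_record(repaired_by_sex[sex])
    for g in GROUPS:
        marginals[g.label] = MarginalSpec(g.label, repaired_by_sex[g.sex])
        dependence[g.label] = default_dependence(g.label)
        sems[g.label] = GroundTruthSEM(g.label, reported.PREDICTION_MODELS[g.label])
    return catalog, marginals, dependence, sems


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_anthropometrics(
    group: GroupSpec | str,
    n: int,
    marginals: MarginalSpec,
    dep: CovariateDependence,
    seed: int | np.random.Generator,
    age_window: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Draw n rows of covariates from the Gaussian copula.

    ``age_window`` restricts age to [lo, hi) by truncating its margin (the
    copula correlation then induces the matching shift in the size
    variables).  BMI is computed from weight and height, never sampled.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    cols = ["Age", "W", "H", "BMI", "WC", "HC"]
    if n == 0:
        return pd.DataFrame({c: np.array([], dtype=float) for c in cols})
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chol = np.linalg.cholesky(dep.matrix)
    z = rng.standard_normal((n, len(COPULA_VARS))) @ chol.T
    u = stats.norm.cdf(z)
    out = {}
    for j, var in enumerate(COPULA_VARS):
        rec = marginals[var]
        margin = Margin(rec.mean, rec.sd, rec.skewness)
        uj = np.clip(u[:, j], 1e-12, 1 - 1e-12)
        if var == "Age" and age_window is not None:
            x = margin.ppf_truncated(uj, age_window)
        else:
            x = margin.ppf(uj)
        lo, hi = PHYSIOLOGIC_BOUNDS[var]
        x = np.clip(x, lo, hi)
        out[var] = x
    out["BMI"] = compute_bmi(out["W"], out["H"])
    return pd.DataFrame(out)[cols]


def simulate_body_composition(
    anthro: pd.DataFrame,
    sem: GroundTruthSEM,
    marginals: MarginalSpec,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Generate the nine compartments from the SEM, appended in kg.

    Responses are produced in topological order in z-space; residual SD per
    node follows the R2-preserving rule (see module docstring).  z-scores
    are destandardized with the group's marginal mean/SD.
    """
    missing = [c for c in sem.covariates_used if c not in anthro.columns]
    if missing:
        raise ValueError(f"anthropometric table lacks SEM covariates: {missing}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(anthro)
    zcols: dict[str, np.ndarray] = {}
    for var in anthro.columns:
        if var in marginals.records:
            rec = marginals[var]
            zcols[var] = (anthro[var].to_numpy(dtype=float) - rec.mean) / rec.sd
    out = anthro.copy()
    for resp in sem.topological_responses():
        parents = sem.parents(resp)
        betas = sem.betas(resp)
        unknown = [p for p in parents if p not in zcols]
        if unknown:
            raise ValueError(f"SEM references unknown column(s) {unknown} for {resp}")
        if n == 0:
            zcols[resp] = np.array([], dtype=float)
            out[resp] = zcols[resp]
            continue
        eta = np.zeros(n)
        for p, b in zip(parents, betas):
            eta += b * zcols[p]
        r2 = sem.r2(resp)
        var_eta = float(np.var(eta)) if n > 1 else 0.0
        sigma2 = var_eta * (1.0 - r2) / r2
        eps = rng.normal(0.0, np.sqrt(sigma2), n) if sigma2 > 0 else np.zeros(n)
        zv = eta + eps
        zcols[resp] = zv
        rec = marginals[resp]
        out[resp] = rec.mean + rec.sd * zv
    return out


def standardize_with_marginals(
    table: pd.DataFrame, marginals: MarginalSpec
) -> pd.DataFrame:
    """z-score columns using the generator's marginal mean/SD record."""
    z = {}
    for c in table.columns:
        if c in marginals.records:
            rec = marginals[c]
            z[c] = (table[c].to_numpy(dtype=float) - rec.mean) / rec.sd
    return pd.DataFrame(z, index=table.index)


def simulate_group(
    group: GroupSpec,
    n: int,
    seed: int | np.random.Generator,
    specs=None,
) -> pd.DataFrame:
    """Full 15-variable table for one study group."""
    if specs is None:
        specs = default_study_specs()
    _, marginals, dependence, sems = specs
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    anthro = simulate_anthropometrics(
        group, n, marginals[group.label], dependence[group.label], rng,
        age_window=group.age_window,
    )
    table = simulate_body_composition(anthro, sems[group.label], marginals[group.label], rng)
    table.insert(0, "group", group.label)
    table.insert(0, "sex", group.sex)
    return table


def simulate_study_cohort(seed: int) -> pd.DataFrame:
    """The four groups at their published sizes (476 rows total)."""
    specs = default_study_specs()
    ss = np.random.SeedSequence(seed)
    parts = []
    for g, child in zip(GROUPS, ss.spawn(len(GROUPS))):
        rng = np.random.default_rng(child)
        parts.append(simulate_group(g, GROUP_SIZES[g.label], rng, specs))
    cohort = pd.concat(parts, ignore_index=True)
    cohort.insert(0, "id", np.arange(1, len(cohort) + 1))
    return cohort
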