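"""Model-quality criteria and validation metrics.

Four criteria grade a candidate network: summed absolute bias, summed
residual SD, summed standard error of prediction (SEP), and the arc count.
With residuals ``B[i, v] = predicted - observed`` (kg) for observation i
and compartment v:

* ``|Bias| = sum_v | mean_i B[i, v] |`` — per-compartment mean residual,
  absolute, summed over the nine compartments,
* ``SD = sum_v sd_i(B[i, v])`` — sample SD (n - 1),
* ``SEP = sum_v sqrt(bias_v^2 + sd_v^2)``,

so per compartment ``SEP_v^2 = bias_v^2 + sd_v^2`` holds by construction
and SEP dominates both components.  Per-compartment reporting adds MAPE
(mean absolute percentage error) and R^2, the squared Pearson correlation
between predictions and observations.  Candidate selection minimizes
validation SEP, ties broken by fewer covariates, then fewer arcs, then
label order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import RESPONSE_NAMES
from .dag import Dag

logger = logging.getLogger(__name__)

#: Compartment membership of the two aggregate masses.
FAT_COMPARTMENTS = ("TF", "LF", "AF")
FAT_FREE_COMPARTMENTS = ("TL", "TB", "LL", "LB", "AL", "AB")


def residual_matrix(pred: pd.DataFrame, obs: pd.DataFrame) -> pd.DataFrame:
    """Element-wise predicted minus observed, kg."""
    if pred.shape != obs.shape or list(pred.columns) != list(obs.columns):
        raise ValueError("prediction and observation tables must align")
    return pd.DataFrame(
        pred.to_numpy(dtype=float) - obs.to_numpy(dtype=float),
        columns=pred.columns,
        index=pred.index,
    )


def total_bias(residuals: pd.DataFrame) -> float:
    """Sum over compartments of |mean residual|; cancellation is intended."""
    if len(residuals) < 1:
        raise ValueError("need at least one observation")
    return float(np.abs(residuals.mean(axis=0)).sum())


def total_sd(residuals: pd.DataFrame) -> float:
    """Sum over compartments of the residual sample SD (n - 1)."""
    if len(residuals) < 2:
        raise ValueError("need at least two observations")
    return float(residuals.std(axis=0, ddof=1).sum())


def sep_components(residuals: pd.DataFrame) -> pd.Series:
    """Per-compartment SEP_v = sqrt(bias_v^2 + sd_v^2), kg."""
    if len(residuals) < 2:
        raise ValueError("need at least two observations")
    bias = residuals.mean(axis=0)
    sd = residuals.std(axis=0, ddof=1)
    return np.sqrt(bias**2 + sd**2)


def total_sep(residuals: pd.DataFrame) -> float:
    return float(sep_components(residuals).sum())


def mape(pred: np.ndarray | pd.Series, obs: np.ndarray | pd.Series) -> float:
    """Mean absolute percentage error; zero observations are excluded."""
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    keep = o != 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("MAPE: excluded %d zero observations", n_dropped)
    if not keep.any():
        raise ValueError("all observations are zero")
    return float(100.0 * np.mean(np.abs((p[keep] - o[keep]) / o[keep])))


def r_squared(
    pred: np.ndarray | pd.Series, obs: np.ndarray | pd.Series, mode: str = "pearson"
) -> float:
    """Squared Pearson correlation of predictions vs observations.

    ``mode='sse'`` switches to 1 - SSE/SST for sensitivity analyses.
    """
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if mode == "pearson":
        if p.std() == 0 or o.std() == 0:
            return float("nan")
        return float(np.corrcoef(p, o)[0, 1] ** 2)
    if mode == "sse":
        sst = float(((o - o.mean()) ** 2).sum())
        if sst == 0:
            return float("nan")
        return 1.0 - float(((p - o) ** 2).sum()) / sst
    raise ValueError(f"unknown R^2 mode {mode!r}")


@dataclass(frozen=True)
class FitSummary:
    """The four quality criteria plus per-compartment and aggregate metrics."""

    total_bias: float
    total_sd: float
    total_sep: float
    n_arcs: int
    per_compartment: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    aggregates: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v, (m, s, r2) in self.per_compartment.items():
            if m < 0 or s < 0 or r2 > 1 + 1e-9:
                raise ValueError(f"invalid metrics for {v}")


def summarize_fit(pred: pd.DataFrame, obs: pd.DataFrame, n_arcs: int) -> FitSummary:
    """Full quality summary of predictions against observations (kg)."""
    cols = [c for c in RESPONSE_NAMES if c in pred.columns]
    pred, obs = pred[cols], obs[cols]
    resid = residual_matrix(pred, obs)
    sep = sep_components(resid)
    per = {
        v: (mape(pred[v], obs[v]), float(sep[v]), r_squared(pred[v], obs[v]))
        for v in cols
    }
    aggregates = {}
    for name, members in (("fat", FAT_COMPARTMENTS), ("fat_free", FAT_FREE_COMPARTMENTS)):
        mem = [v for v in members if v in cols]
        if not mem:
            continue
        p_tot = pred[mem].sum(axis=1)
        o_tot = obs[mem].sum(axis=1)
        r = p_tot - o_tot
        sep_a = math.sqrt(float(r.mean()) ** 2 + float(r.std(ddof=1)) ** 2)
        aggregates[name] = (mape(p_tot, o_tot), sep_a, r_squared(p_tot, o_tot))
    return FitSummary(
        total_bias(resid), total_sd(resid), total_sep(resid), n_arcs, per, aggregates
    )


@dataclass
class CandidateResult:
    """One covariate subset's fitted network and its train/validation quality."""

    label: str
    covariates: tuple[str, ...]
    train: FitSummary
    validation: FitSummary
    graph: Dag | None = None
    models: dict | None = None

    @property
    def n_arcs(self) -> int:
        return self.validation.n_arcs


def select_best(candidates: list[CandidateResult]) -> CandidateResult:
    """Lowest validation SEP; ties -> fewer covariates, fewer arcs, label."""
    if not candidates:
        raise ValueError("no candidates to select from")
    return min(
        candidates,
        key=lambda c: (
            round(c.validation.total_sep, 10),
            len(c.covariates),
            c.n_arcs,
            c.label,
        ),
    )


def select_best_reported(rows) -> object:
    """Same selection rule applied to published candidate-table rows."""
    if not rows:
        raise ValueError("no candidates to select from")
    return min(
        rows, key=lambda r: (r.test_sep, len(r.covariates), r.n_arcs, r.label)
    )


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def candidate_report(results: dict[str, list[CandidateResult]]) -> pd.DataFrame:
    """Candidates-by-criteria table (one row per group x subset)."""
    rows = []
    for group, cands in results.items():
        for c in cands:
            rows.append(
                {
                    "group": group,
                    "covariates": c.label,
                    "n_arcs": c.n_arcs,
                    "train_bias": c.train.total_bias,
                    "train_sd": c.train.total_sd,
                    "train_sep": c.train.total_sep,
                    "test_bias": c.validation.total_bias,
                    "test_sd": c.validation.total_sd,
                    "test_sep": c.validation.total_sep,
                }
            )
    return pd.DataFrame(rows)


def model_report(models_by_group: dict[str, dict]) -> pd.DataFrame:
    """Extracted standardized equations with explained variance per group."""
    rows = []
    for group, models in models_by_group.items():
        for resp, m in models.items():
            rows.append(
                {
                    "group": group,
                    "response": resp,
                    "equation": m.equation(),
                    "explained_variance": m.r_squared,
                }
            )
    return pd.DataFrame(rows)


def compartment_report(summaries: dict[str, FitSummary]) -> pd.DataFrame:
    """Per-compartment MAPE/SEP/R^2 per group (9 rows per group)."""
    rows = []
    for group, s in summaries.items():
        for v in RESPONSE_NAMES:
            if v in s.per_compartment:
                m, sep, r2 = s.per_compartment[v]
                rows.append(
                    {"group": group, "compartment": v, "mape": m, "sep": sep, "r2": r2}
                )
    return pd.DataFrame(rows)


def aggregate_report(summaries: dict[str, FitSummary]) -> pd.DataFrame:
    """Fat-mass and fat-free-mass aggregate metrics per group."""
    rows = []
    for group, s in summaries.items():
        for agg, (m, sep, r2) in s.aggregates.items():
            rows.append(
                {"group": group, "aggregate": agg, "mape": m, "sep": sep, "r2": r2}
            )
    return pd.DataFrame(rows)
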