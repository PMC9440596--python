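"""Preprocessing: BMI, group assignment, splits, normality, scaling.

The analysis works per study group.  Each group's table is split 80/20 into
training and validation sets; variables that fail a Kolmogorov-Smirnov
normality check are natural-log transformed (the Gaussian network assumes
joint normality); fitting happens on z-scores computed from TRAINING
statistics only, so validation rows are scaled exactly as unseen data
would be.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def compute_bmi(weight_kg, height_cm):
    """Body mass index, kg/m^2: weight / (height in metres)^2."""
    w = np.asarray(weight_kg, dtype=float)
    h = np.asarray(height_cm, dtype=float)
    if np.any(w <= 0) or np.any(h <= 0):
        raise ValueError("weight and height must be positive")
    bmi = w / (h / 100.0) ** 2
    return float(bmi) if bmi.ndim == 0 else bmi


def assign_groups(cohort: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Partition rows into the four sex-by-age groups.

    Girls with age >= 13 are 'older', boys with age >= 14; the boundary age
    belongs to the older group.  Rows missing sex or age are rejected with
    a logged warning.  Expects columns ``sex`` ('M'/'F') and ``Age`` or
    ``age``.
    """
    from .catalog import GROUPS  # local import avoids a cycle

    age_col = "Age" if "Age" in cohort.columns else "age"
    if "sex" not in cohort.columns or age_col not in cohort.columns:
        raise ValueError("cohort must have 'sex' and 'age' columns")
    ok = cohort["sex"].isin(["M", "F"]) & cohort[age_col].notna()
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("assign_groups: rejected %d rows with missing sex/age", n_bad)
    valid = cohort[ok]
    out: dict[str, pd.DataFrame] = {}
    for g in GROUPS:
        mask = [g.contains(s, a) for s, a in zip(valid["sex"], valid[age_col])]
        out[g.label] = valid[np.array(mask, dtype=bool)] if len(valid) else valid.iloc[0:0]
    return out


@dataclass(frozen=True)
class SplitResult:
    """Reproducible train/validation partition of one group's rows."""

    train_ids: tuple
    validation_ids: tuple
    fraction: float
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.validation_ids):
            raise ValueError("train and validation sets overlap")

    def to_json(self) -> str:
        return json.dumps(
            {
                "train_ids": list(self.train_ids),
                "validation_ids": list(self.validation_ids),
                "fraction": self.fraction,
                "seed": self.seed,
            }
        )

    @staticmethod
    def from_json(text: str) -> "SplitResult":
        d = json.loads(text)
        return SplitResult(
            tuple(d["train_ids"]), tuple(d["validation_ids"]), d["fraction"], d["seed"]
        )


def train_validation_split(
    table: pd.DataFrame, fraction: float = 0.8, seed: int = 0
) -> SplitResult:
    """Uniform random split without replacement; |train| = round(f * n).

    ``round`` is Python's banker's rounding (ties to even), fixed here so
    splits are reproducible across platforms.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    n = len(table)
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    n_train = int(round(fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    ids = np.asarray(table.index)
    return SplitResult(
        tuple(ids[perm[:n_train]].tolist()),
        tuple(ids[perm[n_train:]].tolist()),
        fraction,
        seed,
    )


def ks_normality(values) -> tuple[float, float]:
    """One-sample KS test against Normal(sample mean, sample SD).

    Parameters are estimated from the sample itself (not the Lilliefors
    correction), which makes the test anti-conservative; alpha is therefore
    configurable downstream.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 8:
        raise ValueError("KS normality check needs n >= 8")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sample")
    res = stats.kstest(x, "norm", args=(x.mean(), sd))
    return float(res.statistic), float(res.pvalue)


@dataclass
class TransformLog:
    """Per-variable normality-check outcome and whether log was applied."""

    entries: dict[str, dict] = field(default_factory=dict)

    @property
    def transformed(self) -> list[str]:
        return [v for v, e in self.entries.items() if e["transformed"]]

    def to_json(self) -> str:
        return json.dumps(self.entries, sort_keys=True)


def log_transform_skewed(
    table: pd.DataFrame,
    alpha: float = 0.05,
    variables: list[str] | None = None,
) -> tuple[pd.DataFrame, TransformLog]:
    """Natural-log transform every variable whose KS p-value is < alpha."""
    out = table.copy()
    tlog = TransformLog()
    for var in variables if variables is not None else table.columns:
        x = table[var].to_numpy(dtype=float)
        stat, p = ks_normality(x)
        skew = float(stats.skew(x, bias=False))
        flag = p < alpha
        if flag:
            if np.any(x <= 0):
                raise ValueError(
                    f"variable {var!r} flagged for log transform has non-positive values"
                )
            out[var] = np.log(x)
        tlog.entries[var] = {
            "ks_statistic": stat,
            "ks_pvalue": p,
            "skewness": skew,
            "transformed": bool(flag),
        }
    return out, tlog


def inverse_log_transform(table: pd.DataFrame, tlog: TransformLog) -> pd.DataFrame:
    """Back-map log-transformed columns to their original scale."""
    out = table.copy()
    for var in tlog.transformed:
        if var in out.columns:
            out[var] = np.exp(out[var].to_numpy(dtype=float))
    return out


@dataclass(frozen=True)
class Standardizer:
    """Column means/SDs (training set) for z-scoring and back-mapping."""

    means: dict[str, float]
    sds: dict[str, float]

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for c in table.columns:
            if c in self.means:
                out[c] = (table[c].to_numpy(dtype=float) - self.means[c]) / self.sds[c]
        return pd.DataFrame(out, index=table.index)

    def inverse(self, ztable: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for c in ztable.columns:
            if c in self.means:
                out[c] = ztable[c].to_numpy(dtype=float) * self.sds[c] + self.means[c]
        return pd.DataFrame(out, index=ztable.index)


def standardize(
    table: pd.DataFrame, columns: list[str] | None = None
) -> tuple[pd.DataFrame, Standardizer]:
    """z-score columns; returns the mean/SD record for reuse on new data."""
    cols = list(columns) if columns is not None else list(table.columns)
    means, sds = {}, {}
    for c in cols:
        x = table[c].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"column {c!r} has zero or undefined SD")
        means[c], sds[c] = float(x.mean()), float(sd)
    scaler = Standardizer(means, sds)
    return scaler.transform(table[cols]), scaler
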