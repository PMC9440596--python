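"""Published reference values for the Iranian adolescent DXA cohort.

The study data (476 adolescents, 9-18 years, southern Iran) are not public;
what the publication reports are per-sex summary statistics for all 15
variables, the per-group standardized prediction models with their explained
variances, the candidate-model error table used for model selection, and
per-compartment validation metrics.  This module transcribes those values.
They serve three purposes:

* calibration targets for the synthetic-cohort generator,
* ground-truth structural equation models for simulation and recovery tests,
* fixtures for the model-selection and reporting worked examples.

Everything here is a printed constant; no computation happens at import.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .catalog import (
    BOYS_OLDER,
    BOYS_YOUNGER,
    GIRLS_OLDER,
    GIRLS_YOUNGER,
    RESPONSE_NAMES,
)


@dataclass(frozen=True)
class MarginalRecord:
    """Reported marginal summary of one variable: physical units throughout."""

    mean: float
    q25: float
    q50: float
    q75: float
    sd: float
    skewness: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("sd must be positive")
        if not (self.q25 <= self.q50 <= self.q75):
            raise ValueError("quartiles must be non-decreasing")

    @property
    def iqr(self) -> float:
        return self.q75 - self.q25


# Reported summary statistics by sex: mean, q25, q50, q75, SD, skewness.
# Known internal inconsistencies (girls TB SD vs IQR; boys AB quartiles vs
# mean) are transcribed verbatim; `synthetic.validate_marginals` repairs them.
_BOYS = {
    "TF": (1.47, 1.26, 1.42, 1.62, 0.27, 0.77),
    "TL": (15.29, 11.30, 14.81, 19.29, 4.26, 0.29),
    "TB": (0.37, 0.26, 0.34, 0.48, 0.13, 0.53),
    "LF": (1.56, 1.32, 1.53, 1.74, 0.29, 0.44),
    "LL": (11.73, 8.29, 11.13, 15.23, 3.75, 0.19),
    "LB": (0.55, 0.38, 0.52, 0.71, 0.19, 0.40),
    "AF": (0.79, 0.67, 0.77, 0.88, 0.17, 0.83),
    "AL": (3.59, 2.33, 3.34, 4.77, 1.42, 0.39),
    "AB": (0.19, 0.37, 0.44, 0.53, 0.09, 0.21),
    "Age": (14.1, 11.6, 13.9, 15.7, 2.5, -0.07),
    "W": (41.6, 31.0, 40.0, 51.8, 12.0, 0.38),
    "H": (155.2, 142.3, 154.0, 169.8, 15.7, -0.08),
    "BMI": (16.8, 15.1, 16.6, 18.3, 2.3, 0.69),
    "WC": (65.6, 58.0, 65.0, 72.0, 9.1, 0.28),
    "HC": (78.6, 71.8, 78.0, 85.0, 8.6, 0.19),
}

_GIRLS = {
    "TF": (4.41, 2.84, 4.07, 5.79, 1.88, 0.48),
    "TL": (13.65, 11.47, 14.25, 15.79, 2.93, -0.23),
    "TB": (0.36, 0.27, 0.37, 0.44, 0.63, 0.22),
    "LF": (4.96, 3.44, 4.82, 6.39, 1.76, 0.17),
    "LL": (9.32, 7.66, 9.60, 10.70, 2.01, -0.09),
    "LB": (0.48, 0.38, 0.49, 0.57, 0.11, 0.05),
    "AF": (1.19, 0.65, 1.09, 1.62, 0.63, 0.54),
    "AL": (2.72, 2.28, 2.82, 3.22, 0.74, -0.37),
    "AB": (0.16, 0.11, 0.16, 0.20, 0.05, -0.09),
    "Age": (13.8, 11.3, 13.60, 16.1, 2.8, 0.13),
    "W": (40.2, 31.0, 40.0, 48.0, 10.0, 0.10),
    "H": (150.6, 142.0, 153.0, 159.0, 11.0, -0.65),
    "BMI": (17.5, 15.4, 17.4, 19.4, 2.7, 0.48),
    "WC": (68.6, 63.0, 69.0, 75.0, 9.0, 0.08),
    "HC": (82.0, 75.0, 82.0, 89.0, 9.1, 0.00),
}

SUMMARY_STATS: dict[str, dict[str, MarginalRecord]] = {
    "M": {k: MarginalRecord(*v) for k, v in _BOYS.items()},
    "F": {k: MarginalRecord(*v) for k, v in _GIRLS.items()},
}


# ---------------------------------------------------------------------------
# Per-group standardized prediction models and explained variances.
#
# Each response's published model lists its graph parents with standardized
# coefficients.  Every group's AL (arm lean) row as printed contains AL
# itself as a parent — impossible in an acyclic graph — and is remapped to
# AF (arm fat), the only arm variable otherwise absent from those rows.
# ---------------------------------------------------------------------------

# response -> (list of (parent, beta), explained variance R^2)
ModelRow = tuple[list[tuple[str, float]], float]

PREDICTION_MODELS: dict[str, dict[str, ModelRow]] = {
    BOYS_OLDER.label: {
        "TL": ([("W", 0.66), ("H", 0.19), ("HC", 0.18)], 0.88),
        "TF": ([("BMI", 1.29), ("H", 0.47), ("TL", -0.74)], 0.76),
        "TB": ([("TL", 0.88)], 0.77),
        "LL": ([("TL", 0.48), ("W", 0.27), ("H", 0.21)], 0.84),
        "LF": ([("TF", 0.91), ("Age", -0.11)], 0.82),
        "LB": ([("TB", 0.51), ("LL", 0.41)], 0.89),
        "AF": ([("TL", 0.45), ("LL", 0.42), ("Age", 0.11)], 0.84),
        "AL": ([("TF", 0.42), ("AF", 0.28), ("LF", 0.49), ("H", -0.19)], 0.87),
        "AB": ([("AL", 0.76), ("TB", 0.19)], 0.95),
    },
    BOYS_YOUNGER.label: {
        "TL": ([("W", 0.30), ("H", 0.55), ("HC", 0.13)], 0.90),
        "TF": ([("BMI", 0.82), ("H", 0.45), ("TL", -0.37)], 0.75),
        "TB": ([("TL", 0.89)], 0.82),
        "LL": ([("TL", 0.50), ("H", 0.26), ("W", 0.33), ("HC", -0.12)], 0.93),
        "LF": ([("TF", 0.79), ("W", 0.35)], 0.81),
        "LB": ([("LL", 0.63), ("TB", 0.34)], 0.95),
        "AF": ([("LL", 0.81)], 0.84),
        "AL": ([("TF", 0.45), ("LF", 0.44), ("AF", 0.49), ("H", -0.45)], 0.86),
        "AB": ([("AL", 0.76), ("LB", 0.34), ("TB", -0.19)], 0.93),
    },
    GIRLS_OLDER.label: {
        "TL": ([("W", 0.81), ("H", 0.13)], 0.80),
        "TF": ([("BMI", 0.34), ("W", 0.99), ("TL", -0.33)], 0.80),
        "TB": ([("TL", 0.66), ("Age", 0.29)], 0.64),
        "LL": ([("TL", 0.66), ("W", 0.31)], 0.82),
        "LF": ([("TF", 0.80), ("H", -0.15)], 0.81),
        "LB": ([("TB", 0.51), ("LL", 0.22), ("W", 0.14), ("H", 0.19)], 0.69),
        "AF": ([("LL", 0.43), ("W", 0.23)], 0.62),
        "AL": ([("TF", 0.42), ("AF", 0.28), ("LF", 0.49), ("H", -0.19)], 0.91),
        "AB": ([("AL", 0.59), ("TB", 0.30), ("LB", 0.28), ("W", -0.15)], 0.81),
    },
    GIRLS_YOUNGER.label: {
        "TL": ([("W", 0.70), ("H", 0.31)], 0.91),
        "TF": ([("BMI", 0.68), ("WC", 0.21), ("TL", 0.19)], 0.74),
        "TB": ([("TL", 0.89)], 0.80),
        "LL": ([("TL", 0.78), ("W", 0.20)], 0.90),
        "LF": ([("TF", 0.60), ("LL", -0.30), ("W", 0.68)], 0.88),
        "LB": ([("LL", 0.63), ("TB", 0.41), ("H", 0.21)], 0.88),
        "AF": ([("LL", 0.87)], 0.68),
        "AL": ([("LF", 0.61), ("AF", 0.63), ("H", -0.24)], 0.84),
        "AB": ([("AL", 0.74), ("LB", 0.26)], 0.81),
    },
}

#: The covariate subset behind each group's selected model.
SELECTED_COVARIATES: dict[str, tuple[str, ...]] = {
    BOYS_OLDER.label: ("Age", "W", "H", "BMI", "HC"),
    BOYS_YOUNGER.label: ("Age", "W", "H", "BMI", "HC"),
    GIRLS_OLDER.label: ("Age", "W", "H", "BMI"),
    GIRLS_YOUNGER.label: ("Age", "W", "H", "BMI", "WC"),
}


@dataclass(frozen=True)
class CandidateRow:
    """One explored covariate subset with its reported quality criteria."""

    label: str
    covariates: tuple[str, ...]
    n_arcs: int
    train_bias: float
    train_sd: float
    train_sep: float
    test_bias: float
    test_sd: float
    test_sep: float
    selected: bool = False


_AWHBW = ("Age", "W", "H", "BMI", "WC")
_AWHBH = ("Age", "W", "H", "BMI", "HC")
_ABWH = ("Age", "BMI", "WC", "HC")
_AWHB = ("Age", "W", "H", "BMI")

#: Reported candidate-model errors per group (train and validation).
CANDIDATE_METRICS: dict[str, tuple[CandidateRow, ...]] = {
    BOYS_OLDER.label: (
        CandidateRow("Age-W-H-BMI-WC", _AWHBW, 25, 3.41, 4.52, 6.05, 4.00, 4.52, 6.39),
        CandidateRow("Age-W-H-BMI-HC", _AWHBH, 26, 3.35, 4.46, 5.92, 4.09, 4.46, 6.38, True),
        CandidateRow("Age-BMI-WC-HC", _ABWH, 25, 3.93, 5.20, 6.90, 4.86, 5.20, 7.54),
    ),
    BOYS_YOUNGER.label: (
        CandidateRow("Age-W-H-BMI-WC", _AWHBW, 24, 3.23, 4.29, 5.72, 3.35, 4.63, 6.05),
        CandidateRow("Age-W-H-BMI-HC", _AWHBH, 26, 3.24, 4.27, 5.71, 3.29, 4.63, 6.02, True),
        CandidateRow("Age-BMI-WC-HC", _ABWH, 21, 3.83, 5.03, 6.71, 3.86, 5.73, 7.25),
    ),
    GIRLS_OLDER.label: (
        CandidateRow("Age-W-H-BMI-WC", _AWHBW, 27, 3.92, 5.66, 7.29, 4.02, 5.66, 7.35),
        CandidateRow("Age-W-H-BMI-HC", _AWHBH, 27, 3.92, 5.66, 7.29, 4.02, 5.66, 7.35),
        CandidateRow("Age-W-H-BMI", _AWHB, 27, 3.92, 5.66, 7.29, 4.02, 5.66, 7.35, True),
    ),
    GIRLS_YOUNGER.label: (
        CandidateRow("Age-W-H-BMI-WC", _AWHBW, 23, 3.77, 4.86, 6.49, 4.95, 5.14, 7.76, True),
        CandidateRow("Age-W-H-BMI-HC", _AWHBH, 23, 3.73, 4.81, 6.44, 5.03, 5.13, 7.80),
        CandidateRow("Age-W-H-BMI", _AWHB, 22, 3.82, 4.93, 6.56, 4.97, 5.20, 7.84),
    ),
}


# Per-compartment validation quality: compartment -> (MAPE %, SEP kg, R^2).
SEGMENT_METRICS: dict[str, dict[str, tuple[float, float, float]]] = {
    BOYS_OLDER.label: {
        "TF": (18.04, 0.82, 0.82), "TL": (4.88, 1.28, 0.90), "TB": (9.38, 0.06, 0.78),
        "LF": (17.49, 0.77, 0.89), "LL": (5.93, 1.10, 0.84), "LB": (5.84, 0.06, 0.89),
        "AF": (13.93, 0.21, 0.90), "AL": (9.01, 0.47, 0.88), "AB": (6.06, 0.02, 0.94),
    },
    BOYS_YOUNGER.label: {
        "TF": (19.43, 0.73, 0.81), "TL": (5.33, 0.78, 0.93), "TB": (8.69, 0.03, 0.84),
        "LF": (13.97, 0.54, 0.91), "LL": (5.65, 0.67, 0.94), "LB": (7.26, 0.04, 0.90),
        "AF": (17.91, 0.18, 0.88), "AL": (9.48, 0.35, 0.83), "AB": (7.44, 0.01, 0.93),
    },
    GIRLS_OLDER.label: {
        "TF": (14.27, 1.06, 0.81), "TL": (4.97, 0.93, 0.79), "TB": (9.16, 0.05, 0.65),
        "LF": (10.84, 0.87, 0.82), "LL": (5.04, 0.67, 0.83), "LB": (5.03, 0.04, 0.84),
        "AF": (12.37, 0.28, 0.90), "AL": (10.32, 0.37, 0.65), "AB": (8.14, 0.02, 0.82),
    },
    GIRLS_YOUNGER.label: {
        "TF": (17.34, 0.76, 0.74), "TL": (4.97, 0.76, 0.91), "TB": (8.51, 0.03, 0.81),
        "LF": (18.96, 0.43, 0.90), "LL": (4.52, 0.60, 0.91), "LB": (5.87, 0.03, 0.90),
        "AF": (18.97, 0.19, 0.88), "AL": (14.97, 0.38, 0.76), "AB": (11.12, 0.02, 0.78),
    },
}

# Aggregate fat-mass / fat-free-mass validation quality per group:
# (MAPE %, SEP kg, R^2) for each aggregate.
AGGREGATE_METRICS: dict[str, dict[str, tuple[float, float, float]]] = {
    BOYS_OLDER.label: {"fat": (9.98, 1.10, 0.94), "fat_free": (3.39, 1.74, 0.95)},
    BOYS_YOUNGER.label: {"fat": (9.71, 0.64, 0.91), "fat_free": (3.56, 1.14, 0.97)},
    GIRLS_OLDER.label: {"fat": (8.69, 1.27, 0.91), "fat_free": (3.29, 1.24, 0.90)},
    GIRLS_YOUNGER.label: {"fat": (9.00, 0.86, 0.90), "fat_free": (3.29, 0.89, 0.97)},
}


# ---------------------------------------------------------------------------
# Aggregation helpers: group-level averages recomputable from the tables.
# ---------------------------------------------------------------------------

def mean_explained_variance(group_label: str) -> float:
    """Average published explained variance over the nine compartments."""
    rows = PREDICTION_MODELS[group_label]
    return sum(r2 for _, r2 in rows.values()) / len(rows)


def mean_explained_variance_by_sex(sex: str) -> float:
    """Average explained variance over both age groups of one sex."""
    labels = _labels_for_sex(sex)
    vals = [
        r2
        for lab in labels
        for _, r2 in PREDICTION_MODELS[lab].values()
    ]
    return sum(vals) / len(vals)


def mean_validation_r2_by_sex(sex: str) -> float:
    """Average published prediction-vs-DXA R^2 over compartments and age groups."""
    labels = _labels_for_sex(sex)
    vals = [
        SEGMENT_METRICS[lab][v][2]
        for lab in labels
        for v in RESPONSE_NAMES
    ]
    return sum(vals) / len(vals)


def _labels_for_sex(sex: str) -> tuple[str, str]:
    if sex == "M":
        return (BOYS_OLDER.label, BOYS_YOUNGER.label)
    if sex == "F":
        return (GIRLS_OLDER.label, GIRLS_YOUNGER.label)
    raise ValueError(f"sex must be M or F, got {sex!r}")
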