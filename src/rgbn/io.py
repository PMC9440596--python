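"""Cohort CSV schema and graph export.

The on-disk cohort format is one row per participant:

    id, sex (M/F), group, age, weight_kg, height_cm, bmi, wc_cm, hc_cm,
    tf_kg, tl_kg, tb_kg, lf_kg, ll_kg, lb_kg, af_kg, al_kg, ab_kg

In memory the same table uses the short variable codes (Age, W, H, BMI, WC,
HC, TF, ...).  Reading performs unit sanity checks (height 100-210 cm,
weight 15-150 kg) and warns, never rejects, on violations.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .catalog import CSV_COLUMNS
from .dag import Dag, edges_to_tsv, to_dot

logger = logging.getLogger(__name__)

_META = ["id", "sex", "group"]
_TO_CSV = {code: col for code, col in CSV_COLUMNS.items()}
_FROM_CSV = {col: code for code, col in CSV_COLUMNS.items()}

SANITY_RANGES = {"height_cm": (100.0, 210.0), "weight_kg": (15.0, 150.0)}


def write_cohort_csv(table: pd.DataFrame, path: str | Path) -> None:
    out = table.rename(columns=_TO_CSV)
    cols = [c for c in _META if c in out.columns] + list(CSV_COLUMNS.values())
    missing = [c for c in CSV_COLUMNS.values() if c not in out.columns]
    if missing:
        raise ValueError(f"cohort table missing column(s): {missing}")
    out[cols].to_csv(path, index=False, float_format="%.10g")


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS.values() if c not in raw.columns]
    if missing:
        raise ValueError(f"cohort CSV missing column(s): {missing}")
    for col in CSV_COLUMNS.values():
        bad = pd.to_numeric(raw[col], errors="coerce").isna() & raw[col].notna()
        if bad.any():
            raise ValueError(
                f"unparseable number in column {col!r}, first at row {int(bad.idxmax())}"
            )
        raw[col] = pd.to_numeric(raw[col])
    for col, (lo, hi) in SANITY_RANGES.items():
        viol = ((raw[col] < lo) | (raw[col] > hi)).sum()
        if viol:
            logger.warning(
                "%d values of %s outside plausible range [%g, %g]", viol, col, lo, hi
            )
    return raw.rename(columns=_FROM_CSV)


def export_graph(graph: Dag, path: str | Path, fmt: str = "tsv") -> None:
    """Write the graph as a TSV edge list or DOT file, deterministic order."""
    path = Path(path)
    if fmt == "tsv":
        path.write_text(edges_to_tsv(graph))
    elif fmt == "dot":
        path.write_text(to_dot(graph))
    else:
        raise ValueError(f"unknown graph format {fmt!r}")
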