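"""Per-response linear models and hierarchical prediction.

Once the robust network is fixed, each response node's model is the
ordinary least-squares fit of its z-scored values on its z-scored graph
parents, with no intercept (standardized variables are centred).  The
coefficients are therefore standardized regression weights, directly
comparable with the published prediction models.

Prediction runs hierarchically: responses whose parents are all
anthropometric are predicted first, and downstream responses consume the
*predicted* values of their response parents — never observations, which
are unavailable at prediction time.  Because every node is linear with no
intercept, the whole scheme is a composition of linear maps in z-space.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import COVARIATE_NAMES, RESPONSE_NAMES
from .dag import Dag
from .preprocess import Standardizer, TransformLog

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NodeLinearModel:
    """One response's standardized linear model plus its kg-scale anchors."""

    response: str
    parents: tuple[str, ...]
    coefficients: tuple[float, ...]
    residual_sd: float
    r_squared: float
    mean: float  # training-group mean on the (possibly log) fitting scale
    sd: float    # training-group SD, same scale

    def __post_init__(self) -> None:
        if len(self.parents) != len(self.coefficients):
            raise ValueError("one coefficient per parent required")
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValueError(f"R^2 out of range: {self.r_squared}")

    def predict_z(self, parent_z: dict[str, np.ndarray], n: int) -> np.ndarray:
        out = np.zeros(n)
        for p, b in zip(self.parents, self.coefficients):
            out += b * parent_z[p]
        return out

    def equation(self) -> str:
        if not self.parents:
            return f"{self.response} = 0"
        parts = []
        for i, (p, b) in enumerate(zip(self.parents, self.coefficients)):
            sign = "-" if b < 0 else "+"
            mag = f"{abs(b):.2f}{p}"
            parts.append(mag if (i == 0 and sign == "+") else f"{sign} {mag}")
        return f"{self.response} = " + " ".join(parts)


def extract_node_models(
    graph: Dag,
    ztrain: pd.DataFrame,
    scaler: Standardizer,
    responses: tuple[str, ...] = RESPONSE_NAMES,
) -> dict[str, NodeLinearModel]:
    """OLS of each z-scored response on its z-scored graph parents."""
    n = len(ztrain)
    models: dict[str, NodeLinearModel] = {}
    for resp in responses:
        if resp not in ztrain.columns:
            raise ValueError(f"response {resp} missing from training table")
        parents = tuple(p for p in graph.parents(resp) if p in ztrain.columns)
        y = ztrain[resp].to_numpy(dtype=float)
        ss_tot = float(y @ y)
        if not parents:
            models[resp] = NodeLinearModel(
                resp, (), (), float(np.sqrt(ss_tot / max(n - 1, 1))), 0.0,
                scaler.means[resp], scaler.sds[resp],
            )
            continue
        if len(parents) >= n:
            raise ValueError(
                f"{resp}: more parents ({len(parents)}) than observations ({n})"
            )
        x = ztrain[list(parents)].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        ss_res = float(resid @ resid)
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        dof = max(n - len(parents), 1)
        models[resp] = NodeLinearModel(
            resp,
            parents,
            tuple(float(b) for b in beta),
            float(np.sqrt(ss_res / dof)),
            float(r2),
            scaler.means[resp],
            scaler.sds[resp],
        )
    return models


def prediction_order(
    graph: Dag, responses: tuple[str, ...] = RESPONSE_NAMES
) -> list[str]:
    """Topological order of responses over response-to-response arcs.

    Anthropometric parents impose no ordering (covariates are observed);
    ties are broken alphabetically, so a graph with no response-response
    arcs yields plain alphabetical order.
    """
    present = tuple(r for r in responses if r in graph.nodes)
    sub = Dag(
        tuple(sorted(present)),
        {(p, c) for p, c in graph.edges if p in present and c in present},
    )
    return sub.topological_order()


def predict_hierarchical(
    models: dict[str, NodeLinearModel],
    order: list[str],
    covariate_z: pd.DataFrame,
    transform_log: TransformLog | None = None,
    clamp_negative: bool = True,
) -> pd.DataFrame:
    """Predict all responses in kg from covariate z-scores alone.

    Response-parent values are taken from the predictions computed earlier
    in ``order``.  z-space results are destandardized with each model's
    training mean/SD; responses fitted on the log scale are exponentiated
    back; negative masses are clamped to zero with a logged count.
    """
    n = len(covariate_z)
    zvals: dict[str, np.ndarray] = {
        c: covariate_z[c].to_numpy(dtype=float) for c in covariate_z.columns
    }
    out: dict[str, np.ndarray] = {}
    transformed = set(transform_log.transformed) if transform_log else set()
    for resp in order:
        model = models[resp]
        missing = [p for p in model.parents if p not in zvals]
        if missing:
            raise ValueError(f"missing input(s) {missing} for {resp}")
        zpred = model.predict_z(zvals, n)
        zvals[resp] = zpred
        scale_pred = model.mean + model.sd * zpred
        if resp in transformed:
            scale_pred = np.exp(scale_pred)
        neg = scale_pred < 0
        if clamp_negative and np.any(neg):
            logger.warning(
                "clamping %d negative predicted masses for %s to 0", int(neg.sum()), resp
            )
            scale_pred = np.where(neg, 0.0, scale_pred)
        out[resp] = scale_pred
    return pd.DataFrame(out, index=covariate_z.index)[
        [r for r in RESPONSE_NAMES if r in out]
    ]


def composed_linear_weights(
    models: dict[str, NodeLinearModel], order: list[str]
) -> dict[str, dict[str, float]]:
    """Each response's prediction as a direct linear map on covariate z-scores.

    Substituting response parents by their own linear formulas collapses the
    hierarchy into one matrix; used as the closed-form cross-check for
    ``predict_hierarchical`` and exported as the raw-scale equation basis.
    """
    weights: dict[str, dict[str, float]] = {}
    for resp in order:
        model = models[resp]
        w: dict[str, float] = {}
        for p, b in zip(model.parents, model.coefficients):
            if p in weights:  # response parent: substitute its map
                for cov, wc in weights[p].items():
                    w[cov] = w.get(cov, 0.0) + b * wc
            else:
                w[p] = w.get(p, 0.0) + b
        weights[resp] = w
    return weights


def models_to_json(models: dict[str, NodeLinearModel]) -> str:
    payload = {
        resp: {
            "parents": list(m.parents),
            "coefficients": list(m.coefficients),
            "residual_sd": m.residual_sd,
            "r_squared": m.r_squared,
            "mean": m.mean,
            "sd": m.sd,
        }
        for resp, m in models.items()
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def models_from_json(text: str) -> dict[str, NodeLinearModel]:
    data = json.loads(text)
    return {
        resp: NodeLinearModel(
            resp,
            tuple(d["parents"]),
            tuple(d["coefficients"]),
            d["residual_sd"],
            d["r_squared"],
            d["mean"],
            d["sd"],
        )
        for resp, d in data.items()
    }
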