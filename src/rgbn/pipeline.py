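"""End-to-end analysis: learn -> fuse -> extract -> predict -> evaluate.

For each study group and each candidate covariate subset the pipeline

1. splits the group 80/20 into training and validation rows,
2. log-transforms training variables that fail the KS normality check and
   applies the same transforms to validation rows,
3. z-scores everything with TRAINING statistics,
4. learns the twelve-network ensemble under prior-knowledge constraints,
5. fuses it by >= 7-of-12 consensus and the 70% bootstrap stability filter,
6. extracts per-response standardized linear models from the robust graph,
7. predicts all nine compartments hierarchically from anthropometrics alone,
8. scores train and validation predictions (|Bias|, SD, SEP, MAPE, R^2),

and finally selects, per group, the candidate with the lowest validation
SEP.  One top-level seed drives every random stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import reported
from .catalog import COVARIATE_NAMES, GROUPS, RESPONSE_NAMES
from .consensus import arc_significance, bootstrap_edge_stability, consensus_edges
from .dag import ArcConstraints, Dag, default_constraints, edges_to_tsv, to_dot
from .gaussian import SufficientStats, drop_constant_columns
from .learners import AlgorithmConfig, default_algorithm_configs, run_ensemble
from .metrics import (
    CandidateResult,
    aggregate_report,
    candidate_report,
    compartment_report,
    model_report,
    select_best,
    summarize_fit,
)
from .models import (
    extract_node_models,
    models_to_json,
    predict_hierarchical,
    prediction_order,
)
from .preprocess import (
    assign_groups,
    log_transform_skewed,
    standardize,
    train_validation_split,
)

logger = logging.getLogger(__name__)

#: Fast bootstrap mode: one restart-free hill-climbing run per replicate.
FAST_BOOTSTRAP_CONFIGS = (AlgorithmConfig(1, "score", "hill-climbing", restarts=0),)


@dataclass
class RunConfig:
    """All knobs of the end-to-end analysis; defaults match the study design."""

    seed: int = 0
    groups: tuple[str, ...] = tuple(g.label for g in GROUPS)
    candidate_subsets: dict[str, list[tuple[str, ...]]] = field(default_factory=dict)
    min_support: int = 7
    bootstrap_B: int = 500
    bootstrap_m: int = 500
    stability_threshold: float = 0.70
    split_fraction: float = 0.8
    ks_alpha: float = 0.05
    fast_bootstrap: bool = False
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")
        if not 0 <= self.stability_threshold <= 1:
            raise ValueError("stability_threshold must be in [0, 1]")
        if not self.candidate_subsets:
            self.candidate_subsets = {
                label: [tuple(row.covariates) for row in rows]
                for label, rows in reported.CANDIDATE_METRICS.items()
            }
        for label, subsets in self.candidate_subsets.items():
            for s in subsets:
                bad = set(s) - set(COVARIATE_NAMES)
                if bad:
                    raise ValueError(f"unknown covariates {sorted(bad)} for {label}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["candidate_subsets"] = {
            k: [list(s) for s in v] for k, v in self.candidate_subsets.items()
        }
        d["groups"] = list(self.groups)
        return d

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        d = dict(d)
        if "candidate_subsets" in d:
            d["candidate_subsets"] = {
                k: [tuple(s) for s in v] for k, v in d["candidate_subsets"].items()
            }
        if "groups" in d:
            d["groups"] = tuple(d["groups"])
        return RunConfig(**d)


def subset_label(covariates: tuple[str, ...]) -> str:
    return "-".join(covariates)


def apply_transform_plan(table: pd.DataFrame, tlog) -> pd.DataFrame:
    """Apply a training-fitted log-transform plan to new rows."""
    out = table.copy()
    for var in tlog.transformed:
        if var in out.columns:
            x = out[var].to_numpy(dtype=float)
            if np.any(x <= 0):
                raise ValueError(f"variable {var!r} has non-positive values; cannot log")
            out[var] = np.log(x)
    return out


def evaluate_candidate(
    group_table: pd.DataFrame,
    covariates: tuple[str, ...],
    seed: int,
    configs: tuple[AlgorithmConfig, ...] | None = None,
    min_support: int = 7,
    B: int = 500,
    m: int = 500,
    threshold: float = 0.70,
    fraction: float = 0.8,
    ks_alpha: float = 0.05,
    fast_bootstrap: bool = False,
) -> CandidateResult:
    """Run the full pipeline for one group and one covariate subset."""
    bad = set(covariates) - set(COVARIATE_NAMES)
    if bad:
        raise ValueError(f"unknown covariates {sorted(bad)}")
    cols = list(covariates) + list(RESPONSE_NAMES)
    data = group_table[cols].reset_index(drop=True)
    split = train_validation_split(data, fraction, seed)
    train = data.loc[list(split.train_ids)]
    valid = data.loc[list(split.validation_ids)]

    train_t, tlog = log_transform_skewed(train, alpha=ks_alpha)
    valid_t = apply_transform_plan(valid, tlog)
    ztrain, scaler = standardize(train_t)
    zvalid = scaler.transform(valid_t)

    constraints = default_constraints(covariates, RESPONSE_NAMES)
    ensemble = run_ensemble(ztrain, constraints, configs)
    stats = SufficientStats.from_table(drop_constant_columns(ztrain))
    cons_dag, support = consensus_edges(
        [d for _, d in ensemble], min_support, stats, constraints
    )
    boot_configs = FAST_BOOTSTRAP_CONFIGS if fast_bootstrap else configs
    boot_min_support = 1 if fast_bootstrap else min_support
    stable_dag, stability = bootstrap_edge_stability(
        ztrain,
        constraints,
        boot_configs,
        cons_dag,
        B=B,
        m=m,
        threshold=threshold,
        seed=np.random.default_rng(np.random.SeedSequence([seed, 7])),
        min_support=boot_min_support,
    )
    # covariate-to-covariate arcs are ignored downstream: the robust graph
    # keeps only arcs into responses
    final = Dag(
        stable_dag.nodes,
        {(p, c) for p, c in stable_dag.edges if c in RESPONSE_NAMES},
    )
    models = extract_node_models(final, ztrain, scaler)
    order = prediction_order(final)
    pvalues = arc_significance(final, train_t)

    summaries = {}
    for name, zpart, raw in (("train", ztrain, train), ("validation", zvalid, valid)):
        cov_z = zpart[list(covariates)]
        pred = predict_hierarchical(models, order, cov_z, tlog)
        obs = raw[list(RESPONSE_NAMES)].set_index(pred.index)
        summaries[name] = summarize_fit(pred, obs, final.n_edges)

    result = CandidateResult(
        label=subset_label(covariates),
        covariates=tuple(covariates),
        train=summaries["train"],
        validation=summaries["validation"],
        graph=final,
        models=models,
    )
    result.diagnostics = {
        "split": split,
        "transform_log": tlog,
        "support": support,
        "stability": stability,
        "arc_pvalues": pvalues,
        "consensus_dag": cons_dag,
    }
    return result


def run_all(config: RunConfig, cohort: pd.DataFrame | None = None) -> dict:
    """Full study analysis; writes reports under ``config.output_dir``.

    Returns the run summary (also written as JSON): seed, config hash, the
    selected candidate per group and its headline criteria.
    """
    from .synthetic import simulate_study_cohort

    if cohort is None:
        cohort = simulate_study_cohort(config.seed)
    groups = assign_groups(cohort)
    ss = np.random.SeedSequence(config.seed)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    results: dict[str, list[CandidateResult]] = {}
    selected: dict[str, CandidateResult] = {}
    for gi, label in enumerate(config.groups):
        table = groups[label]
        cands = []
        for si, subset in enumerate(config.candidate_subsets[label]):
            sub_seed = int(
                np.random.SeedSequence([config.seed, gi, si]).generate_state(1)[0]
                % (2**31)
            )
            logger.info("group %s subset %s (seed %d)", label, subset, sub_seed)
            cand = evaluate_candidate(
                table,
                subset,
                seed=sub_seed,
                min_support=config.min_support,
                B=config.bootstrap_B,
                m=config.bootstrap_m,
                threshold=config.stability_threshold,
                fraction=config.split_fraction,
                ks_alpha=config.ks_alpha,
                fast_bootstrap=config.fast_bootstrap,
            )
            cands.append(cand)
        results[label] = cands
        best = select_best(cands)
        selected[label] = best
        (outdir / f"graph_{label}.tsv").write_text(edges_to_tsv(best.graph))
        (outdir / f"graph_{label}.dot").write_text(to_dot(best.graph))
        (outdir / f"models_{label}.json").write_text(models_to_json(best.models))

    candidate_report(results).to_csv(outdir / "candidates.csv", index=False)
    model_report({g: c.models for g, c in selected.items()}).to_csv(
        outdir / "models.csv", index=False
    )
    compartment_report({g: c.validation for g, c in selected.items()}).to_csv(
        outdir / "compartments.csv", index=False
    )
    aggregate_report({g: c.validation for g, c in selected.items()}).to_csv(
        outdir / "aggregates.csv", index=False
    )

    hashed = {k: v for k, v in config.to_dict().items() if k != "output_dir"}
    config_json = json.dumps(hashed, sort_keys=True)
    summary = {
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "groups": {
            label: {
                "selected": selected[label].label,
                "n_arcs": selected[label].n_arcs,
                "validation_bias": selected[label].validation.total_bias,
                "validation_sd": selected[label].validation.total_sd,
                "validation_sep": selected[label].validation.total_sep,
            }
            for label in config.groups
        },
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
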