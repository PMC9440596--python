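"""Robust-network fusion: algorithm consensus and bootstrap stability.

The robust Gaussian Bayesian network (RGBN) keeps only dependences that are
(1) found by at least ``min_support`` of the ensemble's runs (default 7 of
12) and (2) re-found in at least a ``threshold`` fraction (default 70%) of
bootstrap replicates.  Both thresholds are closed: exactly 7/12 and exactly
0.70 are retained.  Support and occurrence are counted on the undirected
adjacency — orientation instability should not discard a stable dependence —
and orientation is re-decided by majority vote, BIC-tie-broken; a strict
directed counting mode is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .dag import ArcConstraints, Dag
from .gaussian import FamilyScoreCache, SufficientStats, drop_constant_columns
from .learners import AlgorithmConfig, run_ensemble

logger = logging.getLogger(__name__)

Pair = tuple[str, str]  # sorted undirected pair


def _pair(a: str, b: str) -> Pair:
    return (a, b) if a <= b else (b, a)


@dataclass
class EdgeSupport:
    """Per-edge run counts from the ensemble."""

    ensemble_size: int
    directed: dict[tuple[str, str], int] = field(default_factory=dict)
    adjacency: dict[Pair, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for count in list(self.directed.values()) + list(self.adjacency.values()):
            if count > self.ensemble_size:
                raise ValueError("support count exceeds ensemble size")


def count_support(dags: list[Dag]) -> EdgeSupport:
    support = EdgeSupport(len(dags))
    for dag in dags:
        seen_pairs = set()
        for p, c in dag.edges:
            support.directed[(p, c)] = support.directed.get((p, c), 0) + 1
            pair = _pair(p, c)
            if pair not in seen_pairs:  # guard: a DAG has no 2-cycles anyway
                support.adjacency[pair] = support.adjacency.get(pair, 0) + 1
                seen_pairs.add(pair)
    return support


def consensus_edges(
    ensemble: list[Dag] | list[tuple[AlgorithmConfig, Dag]],
    min_support: int = 7,
    stats: SufficientStats | None = None,
    constraints: ArcConstraints = ArcConstraints(),
) -> tuple[Dag, EdgeSupport]:
    """Keep adjacencies supported by >= min_support runs; orient by majority.

    Orientation ties fall back to whichever direction scores a higher
    Gaussian BIC on the training data (when ``stats`` are supplied), then to
    the lexicographically smaller parent.  If retaining every kept edge
    would close a directed cycle, the lowest-support edge in the cycle is
    removed and logged.
    """
    dags = [d if isinstance(d, Dag) else d[1] for d in ensemble]
    if not dags:
        raise ValueError("ensemble must be non-empty")
    support = count_support(dags)
    nodes = dags[0].nodes
    cache = FamilyScoreCache(stats) if stats is not None else None

    chosen: list[tuple[str, str, int]] = []  # (parent, child, adjacency support)
    for pair, count in sorted(support.adjacency.items()):
        if count < min_support:
            continue
        a, b = pair
        n_ab = support.directed.get((a, b), 0)
        n_ba = support.directed.get((b, a), 0)
        if n_ab != n_ba:
            p, c = (a, b) if n_ab > n_ba else (b, a)
        elif cache is not None:
            gain_ab = cache.family_score(b, frozenset({a})) + cache.family_score(a, frozenset())
            gain_ba = cache.family_score(a, frozenset({b})) + cache.family_score(b, frozenset())
            p, c = (a, b) if gain_ab >= gain_ba else (b, a)
        else:
            p, c = a, b
        if not constraints.allows(p, c):
            p, c = c, p
            if not constraints.allows(p, c):
                logger.warning("edge %s-%s forbidden in both directions; dropped", a, b)
                continue
        chosen.append((p, c, count))

    # acyclicity: repeatedly remove the lowest-support edge of any cycle
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    edge_support = {}
    for p, c, count in chosen:
        g.add_edge(p, c)
        edge_support[(p, c)] = count
    while True:
        try:
            cycle = nx.find_cycle(g, orientation="original")
        except nx.NetworkXNoCycle:
            break
        weakest = min(
            ((u, v) for u, v, _ in cycle), key=lambda e: (edge_support[e], e)
        )
        logger.warning(
            "consensus cycle broken by removing lowest-support edge %s->%s", *weakest
        )
        g.remove_edge(*weakest)
        del edge_support[weakest]
    dag = Dag(nodes, set(g.edges()))
    return dag, support


@dataclass
class StabilityReport:
    """Bootstrap occurrence fractions for the consensus edges."""

    fractions: dict[tuple[str, str], float]
    n_replicates: int
    subset_size: int
    threshold: float
    directed_mode: bool = False
    replicate_edge_sets: list[frozenset] = field(default_factory=list)

    def __post_init__(self) -> None:
        for f in self.fractions.values():
            if not 0.0 <= f <= 1.0:
                raise ValueError("occurrence fractions must lie in [0, 1]")

    def to_tsv(self, arc_pvalues: dict | None = None, support: EdgeSupport | None = None) -> str:
        lines = ["parent\tchild\tsupport_count\toccurrence_fraction\tarc_p_value"]
        for (p, c), f in sorted(self.fractions.items()):
            cnt = support.adjacency.get(_pair(p, c), "") if support else ""
            pv = (arc_pvalues or {}).get((p, c), "")
            pv = f"{pv:.6g}" if isinstance(pv, float) else pv
            lines.append(f"{p}\t{c}\t{cnt}\t{f:.4f}\t{pv}")
        return "\n".join(lines) + "\n"


def bootstrap_edge_stability(
    train: pd.DataFrame,
    constraints: ArcConstraints,
    configs: tuple[AlgorithmConfig, ...] | None,
    consensus: Dag,
    B: int = 500,
    m: int = 500,
    threshold: float = 0.70,
    seed: int | np.random.Generator = 0,
    min_support: int | None = None,
    directed: bool = False,
) -> tuple[Dag, StabilityReport]:
    """Filter consensus edges by bootstrap occurrence.

    Each replicate resamples ``m`` rows with replacement (the published
    subset size, 500, exceeds every group's n, so sampling must be with
    replacement), reruns the ensemble-plus-consensus pipeline, and records
    which consensus edges reappear.  Edges occurring in >= threshold of
    replicates are retained.  Passing a reduced ``configs`` (e.g. a single
    hill-climbing run, with ``min_support=1``) gives a fast approximate mode.
    """
    if B < 1 or m < 1:
        raise ValueError("B and m must be >= 1")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if configs is None:
        from .learners import default_algorithm_configs

        configs = default_algorithm_configs()
    if min_support is None:
        min_support = max(1, (7 * len(configs)) // 12)
    n = len(train)
    counts: dict[tuple[str, str], int] = {e: 0 for e in consensus.edges}
    replicate_sets: list[frozenset] = []
    for _ in range(B):
        idx = rng.integers(0, n, size=m)
        sub = train.iloc[idx].reset_index(drop=True)
        try:
            ens = run_ensemble(sub, constraints, configs)
            sub_tab = drop_constant_columns(sub)
            sub_stats = SufficientStats.from_table(sub_tab)
            cons_b, _ = consensus_edges(
                [d for _, d in ens], min_support, sub_stats, constraints
            )
            edges_b = set(cons_b.edges)
        except Exception as exc:
            logger.warning("bootstrap replicate failed (%s); counted as empty", exc)
            edges_b = set()
        if directed:
            present = edges_b
        else:
            present = {_pair(p, c) for p, c in edges_b}
        replicate_sets.append(frozenset(present))
        for p, c in counts:
            key = (p, c) if directed else _pair(p, c)
            if key in present:
                counts[(p, c)] += 1
    fractions = {e: counts[e] / B for e in counts}
    dag = apply_stability_filter(consensus, fractions, threshold)
    report = StabilityReport(fractions, B, m, threshold, directed, replicate_sets)
    return dag, report


def apply_stability_filter(
    consensus: Dag, fractions: dict[tuple[str, str], float], threshold: float
) -> Dag:
    """Keep consensus edges with occurrence >= threshold (closed bound)."""
    kept = {e for e in consensus.edges if fractions.get(e, 0.0) >= threshold}
    return Dag(consensus.nodes, kept)


def arc_significance(graph: Dag, train: pd.DataFrame) -> dict[tuple[str, str], float]:
    """Coefficient t-test p-value for every arc into a response node.

    Each response is regressed (z-scored, no intercept) on its graph
    parents; the arc's p-value is its coefficient's two-sided t-test.
    Collinear parent sets are flagged unreliable (NaN) and logged.
    """
    import statsmodels.api as sm

    from .catalog import RESPONSE_NAMES
    from .preprocess import standardize

    pvals: dict[tuple[str, str], float] = {}
    cols = [c for c in train.columns if train[c].std(ddof=1) > 0]
    z, _ = standardize(train[cols])
    for node in graph.nodes:
        if node not in RESPONSE_NAMES:
            continue
        parents = [p for p in graph.parents(node) if p in z.columns]
        if not parents or node not in z.columns:
            continue
        x = z[parents].to_numpy()
        if np.linalg.cond(x.T @ x) > 1e10:
            logger.warning("collinear parents of %s; p-values unreliable", node)
            for p in parents:
                pvals[(p, node)] = float("nan")
            continue
        fit = sm.OLS(z[node].to_numpy(), x).fit()
        for p, pv in zip(parents, fit.pvalues):
            pvals[(p, node)] = float(pv)
    return pvals
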