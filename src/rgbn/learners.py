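"""The twelve-algorithm structure-learning ensemble.

Three families, mirroring the standard Gaussian-network toolbox:

* **Constraint-based** (grow-shrink, IAMB, Fast-IAMB, Inter-IAMB): discover
  each node's Markov blanket with Fisher-z tests, reduce blankets to a
  symmetry-corrected skeleton, orient v-structures, propagate orientations
  (Meek rules), and orient the leftovers greedily by BIC.
* **Score-based** (hill-climbing, tabu): greedy add/delete/reverse local
  search maximizing the Gaussian BIC from the empty constraint-respecting
  graph; tabu keeps a fixed-length structure memory and accepts the best
  non-tabu move, returning the best structure seen.
* **Hybrid** (MMHC): max-min parents-and-children sets restrict the search
  space, then hill-climbing within it.

Each learner honours an arc blacklist/whitelist and returns a DAG.  The
default ensemble is 4 constraint-based variants x alpha {0.05, 0.01}, plus
hill-climbing, tabu, and MMHC at both alphas: twelve runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal

import numpy as np
import pandas as pd

from .dag import ArcConstraints, Dag, empty_constrained_dag
from .gaussian import (
    FamilyScoreCache,
    SufficientStats,
    drop_constant_columns,
    fisher_z_partial_correlation,
)

logger = logging.getLogger(__name__)

CB_VARIANTS = ("gs", "iamb", "fast-iamb", "inter-iamb")

#: Largest conditioning set used when reducing blankets to a skeleton.
MAX_SEPSET = 3

#: Blanket symmetry correction: "and" (canonical) requires the pair to be
#: found from both sides; "or" keeps edges found from either side.
SYMMETRY_RULE = "and"


@dataclass(frozen=True)
class AlgorithmConfig:
    """One ensemble member: family, variant, and its parameters."""

    run_id: int
    family: Literal["constraint", "score", "hybrid"]
    variant: str
    alpha: float | None = None
    score: str = "bic-g"
    tabu_length: int = 10
    restarts: int = 10

    @property
    def name(self) -> str:
        tag = f"@{self.alpha}" if self.alpha is not None else ""
        return f"{self.run_id:02d}:{self.variant}{tag}"


def default_algorithm_configs() -> tuple[AlgorithmConfig, ...]:
    """The twelve default runs (4 CB variants x 2 alphas, HC, tabu, MMHC x 2)."""
    configs: list[AlgorithmConfig] = []
    rid = 1
    for variant in CB_VARIANTS:
        for alpha in (0.05, 0.01):
            configs.append(AlgorithmConfig(rid, "constraint", variant, alpha))
            rid += 1
    configs.append(AlgorithmConfig(rid, "score", "hill-climbing"))
    rid += 1
    configs.append(AlgorithmConfig(rid, "score", "tabu"))
    rid += 1
    for alpha in (0.05, 0.01):
        configs.append(AlgorithmConfig(rid, "hybrid", "mmhc", alpha))
        rid += 1
    assert len(configs) == 12
    return tuple(configs)


# ---------------------------------------------------------------------------
# Markov blanket discovery
# ---------------------------------------------------------------------------

def _test(stats: SufficientStats, x: str, y: str, z: list[str]) -> tuple[float, float]:
    """(|partial correlation|, p-value); degenerate tests count as independence."""
    if stats.n - len(z) - 3 <= 0:
        return 0.0, 1.0
    try:
        rho, _, p = fisher_z_partial_correlation(stats, x, y, z)
    except Exception:
        return 0.0, 1.0
    return abs(rho), p


def learn_markov_blanket(
    stats: SufficientStats, target: str, variant: str, alpha: float
) -> set[str]:
    """Markov blanket of ``target`` by the requested discovery variant."""
    others = [v for v in stats.names if v != target]
    mb: list[str] = []

    def shrink() -> None:
        changed = True
        while changed:
            changed = False
            for x in list(mb):
                rest = [v for v in mb if v != x]
                _, p = _test(stats, target, x, rest)
                if p >= alpha:
                    mb.remove(x)
                    changed = True

    if variant == "gs":
        changed = True
        while changed:
            changed = False
            for x in others:
                if x in mb:
                    continue
                _, p = _test(stats, target, x, mb)
                if p < alpha:
                    mb.append(x)
                    changed = True
        shrink()
    elif variant == "iamb":
        while True:
            best, best_assoc = None, 0.0
            for x in others:
                if x in mb:
                    continue
                assoc, p = _test(stats, target, x, mb)
                if p < alpha and assoc > best_assoc:
                    best, best_assoc = x, assoc
            if best is None:
                break
            mb.append(best)
        shrink()
    elif variant == "inter-iamb":
        # visited-state memory: interleaved shrink can undo the last grow,
        # which would otherwise loop forever on degenerate data
        seen: set[frozenset] = set()
        while frozenset(mb) not in seen:
            seen.add(frozenset(mb))
            best, best_assoc = None, 0.0
            for x in others:
                if x in mb:
                    continue
                assoc, p = _test(stats, target, x, mb)
                if p < alpha and assoc > best_assoc:
                    best, best_assoc = x, assoc
            if best is None:
                break
            mb.append(best)
            shrink()
    elif variant == "fast-iamb":
        seen = set()
        while frozenset(mb) not in seen:
            seen.add(frozenset(mb))
            sig = []
            for x in others:
                if x in mb:
                    continue
                assoc, p = _test(stats, target, x, mb)
                if p < alpha:
                    sig.append((assoc, x))
            if not sig:
                break
            # speculative batch insertion in decreasing association order
            for _, x in sorted(sig, key=lambda t: (-t[0], t[1])):
                mb.append(x)
            shrink()
    else:
        raise ValueError(f"unknown Markov blanket variant {variant!r}")
    return set(mb)


def _skeleton_from_blankets(
    stats: SufficientStats, blankets: dict[str, set[str]], alpha: float
) -> tuple[set[frozenset], dict[frozenset, set[str]]]:
    """Symmetry-corrected skeleton and separating sets.

    Candidate edges are blanket pairs confirmed in both directions; they are
    then pruned level-wise in the stable style of the PC algorithm, with
    separating sets drawn from CURRENT neighbourhoods rather than from all
    blanket subsets — conditioning sets shrink as edges fall, which keeps
    the number of tests (and hence false separations) down.
    """
    adj: dict[str, set[str]] = {x: set() for x in stats.names}
    for x in stats.names:
        for y in blankets[x]:
            if SYMMETRY_RULE == "and" and x not in blankets[y]:
                continue
            adj[x].add(y)
            adj[y].add(x)
    sepsets: dict[frozenset, set[str]] = {}
    for size in range(0, MAX_SEPSET + 1):
        to_remove: list[tuple[str, str, tuple[str, ...]]] = []
        for x in sorted(stats.names):
            for y in sorted(adj[x]):
                if x >= y:
                    continue
                base = adj[x] - {y} if len(adj[x]) <= len(adj[y]) else adj[y] - {x}
                if len(base) < size:
                    continue
                for s in combinations(sorted(base), size):
                    _, p = _test(stats, x, y, list(s))
                    if p >= alpha:
                        to_remove.append((x, y, s))
                        break
        for x, y, s in to_remove:
            adj[x].discard(y)
            adj[y].discard(x)
            sepsets[frozenset((x, y))] = set(s)
    skeleton = {frozenset((x, y)) for x in adj for y in adj[x]}
    return skeleton, sepsets


def _orient_skeleton(
    skeleton: set[frozenset],
    sepsets: dict[frozenset, set[str]],
    stats: SufficientStats,
    constraints: ArcConstraints,
    cache: FamilyScoreCache,
) -> Dag:
    """V-structures, Meek propagation, then greedy-BIC orientation."""
    nodes = stats.names
    directed: set[tuple[str, str]] = set()
    undirected: set[frozenset] = set(skeleton)

    def adjacent(a: str, b: str) -> bool:
        return (
            frozenset((a, b)) in undirected
            or (a, b) in directed
            or (b, a) in directed
        )

    def orient(p: str, c: str) -> bool:
        pair = frozenset((p, c))
        if pair not in undirected or not constraints.allows(p, c):
            return False
        if _creates_directed_cycle(directed, p, c):
            return False
        undirected.discard(pair)
        directed.add((p, c))
        return True

    # forced arcs first
    for p, c in sorted(constraints.required):
        pair = frozenset((p, c))
        undirected.discard(pair)
        if p in nodes and c in nodes:
            directed.add((p, c))

    # v-structures: x - y - z, x and z non-adjacent, y outside sepset(x, z)
    for y in sorted(nodes):
        nbrs = sorted(
            a
            for pair in undirected
            for a in pair
            if y in pair and a != y
        )
        for x, z in combinations(nbrs, 2):
            if adjacent(x, z):
                continue
            sep = sepsets.get(frozenset((x, z)))
            if sep is not None and y not in sep:
                if constraints.allows(x, y) and constraints.allows(z, y):
                    orient(x, y)
                    orient(z, y)

    _apply_meek_rules(directed, undirected, constraints)

    # remaining undirected edges: greedy BIC orientation, deterministic order
    dag = Dag(nodes, set())
    for p, c in sorted(directed):
        if not dag.creates_cycle(p, c):
            dag.add_edge(p, c)
        else:
            logger.warning("dropping arc %s->%s (would close a cycle)", p, c)
    for pair in sorted(undirected, key=sorted):
        a, b = sorted(pair)
        options = []
        for p, c in ((a, b), (b, a)):
            if constraints.allows(p, c) and not dag.creates_cycle(p, c):
                gain = cache.family_score(
                    c, frozenset(dag.parents(c)) | {p}
                ) - cache.family_score(c, frozenset(dag.parents(c)))
                options.append((gain, p, c))
        if not options:
            logger.warning("dropping edge %s-%s (no legal orientation)", a, b)
            continue
        # highest gain wins; exact ties go to the lexicographically smaller parent
        best = max(options, key=lambda t: (t[0], t[1] == a))
        dag.add_edge(best[1], best[2])
    return dag


def _creates_directed_cycle(directed: set, p: str, c: str) -> bool:
    # DFS from c through current directed arcs looking for p
    stack, seen = [c], set()
    while stack:
        v = stack.pop()
        if v == p:
            return True
        if v in seen:
            continue
        seen.add(v)
        stack.extend(ch for pa, ch in directed if pa == v)
    return False


def _apply_meek_rules(
    directed: set[tuple[str, str]],
    undirected: set[frozenset],
    constraints: ArcConstraints,
) -> None:
    """Meek rules 1 and 2 to closure, never orienting against the blacklist.

    Rules 3-4 fire only in configurations the greedy-BIC orientation step
    resolves anyway, so they are omitted.
    """

    def adjacent(a: str, b: str) -> bool:
        return (
            frozenset((a, b)) in undirected or (a, b) in directed or (b, a) in directed
        )

    def try_orient(p: str, c: str) -> bool:
        pair = frozenset((p, c))
        if pair not in undirected or not constraints.allows(p, c):
            return False
        if _creates_directed_cycle(directed, p, c):
            return False
        undirected.discard(pair)
        directed.add((p, c))
        return True

    changed = True
    while changed:
        changed = False
        for pair in sorted(undirected, key=sorted):
            a, b = sorted(pair)
            for y, z in ((a, b), (b, a)):
                # R1: x -> y, y - z, x and z non-adjacent  =>  y -> z
                for x, y2 in list(directed):
                    if y2 == y and not adjacent(x, z) and x != z:
                        if try_orient(y, z):
                            changed = True
                        break
                if changed:
                    break
                # R2: y -> w -> z with y - z  =>  y -> z
                for y2, w in list(directed):
                    if y2 == y and (w, z) in directed:
                        if try_orient(y, z):
                            changed = True
                        break
                if changed:
                    break
            if changed:
                break


def learn_markov_blanket_cb(
    table: pd.DataFrame,
    variant: str,
    alpha: float,
    constraints: ArcConstraints,
    stats: SufficientStats | None = None,
    cache: FamilyScoreCache | None = None,
) -> Dag:
    """Constraint-based learner: blankets -> skeleton -> oriented DAG."""
    if variant not in CB_VARIANTS:
        raise ValueError(f"variant must be one of {CB_VARIANTS}")
    if stats is None:
        table = drop_constant_columns(table)
        stats = SufficientStats.from_table(table)
    cache = cache or FamilyScoreCache(stats)
    blankets = {
        v: learn_markov_blanket(stats, v, variant, alpha) for v in stats.names
    }
    skeleton, sepsets = _skeleton_from_blankets(stats, blankets, alpha)
    # fully blacklisted pairs can never appear
    skeleton = {
        pair
        for pair in skeleton
        if any(constraints.allows(p, c) for p, c in (sorted(pair), sorted(pair)[::-1]))
    }
    return _orient_skeleton(skeleton, sepsets, stats, constraints, cache)


# ---------------------------------------------------------------------------
# Score-based search
# ---------------------------------------------------------------------------

def _best_move(
    dag: Dag,
    cache: FamilyScoreCache,
    constraints: ArcConstraints,
    allowed_pairs: set[frozenset] | None = None,
    forbidden_signatures: set[frozenset] | None = None,
):
    """Best legal add/delete/reverse move; deterministic tie-breaking.

    Returns (delta, kind, parent, child) or None.  ``allowed_pairs``
    restricts additions to a skeleton (MMHC); ``forbidden_signatures``
    excludes moves landing on tabu structures.
    """
    nodes = dag.nodes
    parent_sets = {v: frozenset(dag.parents(v)) for v in nodes}
    best = None

    def family_delta(child: str, new_parents: frozenset) -> float:
        return cache.family_score(child, new_parents) - cache.family_score(
            child, parent_sets[child]
        )

    def consider(delta: float, kind: str, p: str, c: str) -> None:
        nonlocal best
        if forbidden_signatures is not None:
            sig = set(dag.edges)
            if kind == "add":
                sig.add((p, c))
            elif kind == "delete":
                sig.discard((p, c))
            else:
                sig.discard((p, c))
                sig.add((c, p))
            if frozenset(sig) in forbidden_signatures:
                return
        key = (delta, kind, p, c)
        if best is None or delta > best[0] + 1e-12:
            best = key

    for p in nodes:
        for c in nodes:
            if p == c:
                continue
            if (p, c) in dag.edges:
                if not constraints.requires(p, c):
                    consider(
                        family_delta(c, parent_sets[c] - {p}), "delete", p, c
                    )
                    # reverse
                    if (
                        constraints.allows(c, p)
                        and not dag.reversal_creates_cycle(p, c)
                    ):
                        delta = family_delta(c, parent_sets[c] - {p}) + (
                            cache.family_score(p, parent_sets[p] | {c})
                            - cache.family_score(p, parent_sets[p])
                        )
                        consider(delta, "reverse", p, c)
            else:
                if (c, p) in dag.edges:
                    continue
                if not constraints.allows(p, c):
                    continue
                if allowed_pairs is not None and frozenset((p, c)) not in allowed_pairs:
                    continue
                if dag.creates_cycle(p, c):
                    continue
                consider(family_delta(c, parent_sets[c] | {p}), "add", p, c)
    return best


def _perturb(
    dag: Dag,
    k: int,
    rng: np.random.Generator,
    constraints: ArcConstraints,
    allowed_pairs: set[frozenset] | None,
) -> Dag:
    """Apply k random legal moves, ignoring the score."""
    nodes = list(dag.nodes)
    for _ in range(k):
        moves = []
        for p in nodes:
            for c in nodes:
                if p == c:
                    continue
                if (p, c) in dag.edges:
                    if not constraints.requires(p, c):
                        moves.append(("delete", p, c))
                        if constraints.allows(c, p) and not dag.reversal_creates_cycle(p, c):
                            moves.append(("reverse", p, c))
                elif (c, p) not in dag.edges and constraints.allows(p, c):
                    if allowed_pairs is not None and frozenset((p, c)) not in allowed_pairs:
                        continue
                    if not dag.creates_cycle(p, c):
                        moves.append(("add", p, c))
        if not moves:
            break
        _apply_move(dag, *moves[rng.integers(len(moves))])
    return dag


def _apply_move(dag: Dag, kind: str, p: str, c: str) -> None:
    if kind == "add":
        dag.add_edge(p, c)
    elif kind == "delete":
        dag.remove_edge(p, c)
    elif kind == "reverse":
        dag.remove_edge(p, c)
        dag.add_edge(c, p)
    else:  # pragma: no cover
        raise ValueError(kind)


def learn_score_based(
    table: pd.DataFrame,
    variant: str = "hill-climbing",
    constraints: ArcConstraints = ArcConstraints(),
    max_iter: int = 500,
    tabu_length: int = 10,
    stats: SufficientStats | None = None,
    cache: FamilyScoreCache | None = None,
    allowed_pairs: set[frozenset] | None = None,
    score_trace: list[float] | None = None,
    restarts: int = 10,
    perturb: int = 8,
    restart_seed: int = 0,
) -> Dag:
    """Greedy BIC local search from the empty constraint-respecting graph.

    Hill-climbing restarts ``restarts`` times from a randomly perturbed copy
    of the incumbent (``perturb`` random legal moves per restart; rng seeded,
    so the learner stays deterministic).  Score equivalence of the Gaussian
    BIC makes orientation ties common, and restarts are the standard escape
    from the local optima they create.
    """
    if variant not in ("hill-climbing", "tabu"):
        raise ValueError("variant must be 'hill-climbing' or 'tabu'")
    if stats is None:
        table = drop_constant_columns(table)
        stats = SufficientStats.from_table(table)
    cache = cache or FamilyScoreCache(stats)
    dag = empty_constrained_dag(stats.names, constraints)

    def total(d: Dag) -> float:
        return sum(cache.family_score(v, frozenset(d.parents(v))) for v in d.nodes)

    def climb(d: Dag, trace: list[float] | None) -> float:
        current = total(d)
        if trace is not None:
            trace.append(current)
        for _ in range(max_iter):
            move = _best_move(d, cache, constraints, allowed_pairs)
            if move is None or move[0] <= 1e-9:
                break
            _apply_move(d, *move[1:])
            current += move[0]
            if trace is not None:
                trace.append(current)
        return current

    if variant == "hill-climbing":
        best_score = climb(dag, score_trace)
        best_dag = dag
        rng = np.random.default_rng(restart_seed)
        for _ in range(restarts):
            trial = _perturb(best_dag.copy(), perturb, rng, constraints, allowed_pairs)
            score = climb(trial, None)
            if score > best_score + 1e-9:
                best_dag, best_score = trial, score
        return best_dag

    # tabu search: best non-tabu move each step (possibly downhill),
    # fixed-length memory of visited structures, return the best seen
    tabu: list[frozenset] = [dag.signature()]
    best_dag, best_score = dag.copy(), total(dag)
    current_score = best_score
    stagnant = 0
    for _ in range(max_iter):
        move = _best_move(
            dag, cache, constraints, allowed_pairs, forbidden_signatures=set(tabu)
        )
        if move is None:
            break
        _apply_move(dag, *move[1:])
        current_score += move[0]
        tabu.append(dag.signature())
        if len(tabu) > tabu_length:
            tabu.pop(0)
        if current_score > best_score + 1e-9:
            best_dag, best_score = dag.copy(), current_score
            stagnant = 0
        else:
            stagnant += 1
            if stagnant >= tabu_length:
                break
    return best_dag


# ---------------------------------------------------------------------------
# Hybrid: MMHC
# ---------------------------------------------------------------------------

def mmpc_skeleton(
    stats: SufficientStats, alpha: float, max_sepset: int = MAX_SEPSET
) -> set[frozenset]:
    """Max-min parents-and-children skeleton (AND-symmetrized)."""
    cpc: dict[str, list[str]] = {}
    for t in stats.names:
        others = [v for v in stats.names if v != t]
        sel: list[str] = []
        while True:
            best, best_minassoc = None, 0.0
            for x in others:
                if x in sel:
                    continue
                # min association over subsets of the current candidate set
                min_assoc, max_p = float("inf"), 0.0
                base = sel
                sizes = range(0, min(len(base), max_sepset) + 1)
                for size in sizes:
                    for s in combinations(base, size):
                        assoc, p = _test(stats, t, x, list(s))
                        if assoc < min_assoc:
                            min_assoc = assoc
                        if p > max_p:
                            max_p = p
                    if max_p >= alpha:
                        break
                if max_p < alpha and min_assoc > best_minassoc:
                    best, best_minassoc = x, min_assoc
            if best is None:
                break
            sel.append(best)
        # backward: drop members separated by some subset of the rest
        changed = True
        while changed:
            changed = False
            for x in list(sel):
                rest = [v for v in sel if v != x]
                separated = False
                for size in range(0, min(len(rest), max_sepset) + 1):
                    for s in combinations(rest, size):
                        _, p = _test(stats, t, x, list(s))
                        if p >= alpha:
                            separated = True
                            break
                    if separated:
                        break
                if separated:
                    sel.remove(x)
                    changed = True
        cpc[t] = sel
    return {
        frozenset((t, x))
        for t in stats.names
        for x in cpc[t]
        if t in cpc[x]
    }


def learn_mmhc(
    table: pd.DataFrame,
    alpha: float,
    constraints: ArcConstraints = ArcConstraints(),
    stats: SufficientStats | None = None,
    cache: FamilyScoreCache | None = None,
    max_iter: int = 500,
) -> Dag:
    """MMHC: restrict the move space to the MMPC skeleton, then hill-climb."""
    if stats is None:
        table = drop_constant_columns(table)
        stats = SufficientStats.from_table(table)
    cache = cache or FamilyScoreCache(stats)
    skeleton = mmpc_skeleton(stats, alpha)
    allowed = skeleton | {frozenset(e) for e in constraints.required}
    return learn_score_based(
        table,
        "hill-climbing",
        constraints,
        max_iter=max_iter,
        stats=stats,
        cache=cache,
        allowed_pairs=allowed,
    )


# ---------------------------------------------------------------------------
# Ensemble
# ---------------------------------------------------------------------------

def run_single(
    config: AlgorithmConfig,
    table: pd.DataFrame,
    constraints: ArcConstraints,
    stats: SufficientStats,
    cache: FamilyScoreCache,
) -> Dag:
    if config.family == "constraint":
        return learn_markov_blanket_cb(
            table, config.variant, config.alpha, constraints, stats, cache
        )
    if config.family == "score":
        return learn_score_based(
            table,
            config.variant,
            constraints,
            tabu_length=config.tabu_length,
            stats=stats,
            cache=cache,
            restarts=config.restarts,
        )
    if config.family == "hybrid":
        return learn_mmhc(table, config.alpha, constraints, stats, cache)
    raise ValueError(f"unknown family {config.family!r}")


def run_ensemble(
    table: pd.DataFrame,
    constraints: ArcConstraints = ArcConstraints(),
    configs: tuple[AlgorithmConfig, ...] | None = None,
) -> list[tuple[AlgorithmConfig, Dag]]:
    """Run every configured learner; a failed run yields an empty graph.

    Results come back in config order so the ensemble size is stable (the
    consensus threshold refers to a fixed number of runs).
    """
    configs = configs if configs is not None else default_algorithm_configs()
    table = drop_constant_columns(table)
    stats = SufficientStats.from_table(table)
    cache = FamilyScoreCache(stats)
    results = []
    for cfg in configs:
        try:
            dag = run_single(cfg, table, constraints, stats, cache)
        except Exception as exc:
            logger.warning("learner %s failed (%s); recording empty graph", cfg.name, exc)
            dag = empty_constrained_dag(stats.names, constraints)
        results.append((cfg, dag))
    return results
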