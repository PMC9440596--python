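"""Independent brute-force oracles used across the test suite."""

from itertools import combinations, product

import numpy as np
import pandas as pd

from rgbn.dag import Dag


def all_dags(nodes):
    """Enumerate every DAG over the given nodes (25 for 3, 543 for 4)."""
    nodes = tuple(nodes)
    pairs = [(a, b) for a in nodes for b in nodes if a != b]
    for mask in product((0, 1), repeat=len(pairs)):
        edges = {p for p, keep in zip(pairs, mask) if keep}
        if any((b, a) in edges for a, b in edges):
            continue
        try:
            yield Dag(nodes, edges)
        except Exception:
            continue


def random_linear_sem(nodes, seed, beta_range=(0.5, 1.2), noise=0.5):
    """A random DAG with strong linear-Gaussian effects, plus a sampler."""
    rng = np.random.default_rng(seed)
    order = list(nodes)
    rng.shuffle(order)
    edges = []
    for i, child in enumerate(order):
        for parent in order[:i]:
            if rng.uniform() < 0.5:
                edges.append((parent, child))
    coeffs = {
        e: rng.uniform(*beta_range) * rng.choice([-1.0, 1.0]) for e in edges
    }

    def sample(n, sample_seed):
        r = np.random.default_rng(sample_seed)
        data = {}
        for i, v in enumerate(order):
            x = r.normal(scale=noise, size=n)
            for p in order[:i]:
                if (p, v) in coeffs:
                    x = x + coeffs[(p, v)] * data[p]
            data[v] = x
        return pd.DataFrame(data)[list(nodes)]

    truth = Dag(tuple(nodes), set(edges))
    return truth, sample


def reachable(dag: Dag, src: str, dst: str) -> bool:
    """Brute-force reachability (all-pairs oracle for topological checks)."""
    frontier, seen = [src], set()
    while frontier:
        v = frontier.pop()
        if v == dst:
            return True
        if v in seen:
            continue
        seen.add(v)
        frontier.extend(dag.children(v))
    return False
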