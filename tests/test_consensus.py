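"""Consensus fusion, bootstrap stability, and arc significance."""

import numpy as np
import pandas as pd
import pytest

from rgbn.consensus import (
    apply_stability_filter,
    arc_significance,
    bootstrap_edge_stability,
    consensus_edges,
    count_support,
)
from rgbn.dag import ArcConstraints, Dag
from rgbn.gaussian import SufficientStats
from rgbn.learners import AlgorithmConfig
from tests.conftest import make_chain

NODES = ("A", "B", "C", "D", "E")


def random_dag(seed: int) -> Dag:
    rng = np.random.default_rng(seed)
    dag = Dag(NODES)
    order = list(NODES)
    rng.shuffle(order)
    for i, c in enumerate(order):
        for p in order[:i]:
            if rng.uniform() < 0.4:
                dag.add_edge(p, c)
    return dag


class TestConsensus:
    def test_identical_ensemble_reproduced_with_full_support(self):
        base = random_dag(0)
        dag, support = consensus_edges([base.copy() for _ in range(12)], 7)
        assert dag.edges == base.edges
        assert all(v == 12 for v in support.adjacency.values())

    def test_seven_of_twelve_kept_six_dropped(self):
        """The >= 7 rule is closed: support 7 passes, support 6 does not."""
        with_edge = Dag(NODES, {("A", "B")})
        without = Dag(NODES)
        for k, expect in [(7, {("A", "B")}), (6, set())]:
            ensemble = [with_edge.copy() for _ in range(k)] + [
                without.copy() for _ in range(12 - k)
            ]
            dag, _ = consensus_edges(ensemble, 7)
            assert dag.edges == expect

    def test_supports_match_bruteforce_recount(self):
        for trial in range(5):
            ensemble = [random_dag(100 * trial + i) for i in range(12)]
            _, support = consensus_edges(ensemble, 7)
            for (a, b), count in support.adjacency.items():
                recount = sum(
                    1 for d in ensemble if (a, b) in d.edges or (b, a) in d.edges
                )
                assert count == recount
            for (p, c), count in support.directed.items():
                assert count == sum(1 for d in ensemble if (p, c) in d.edges)

    def test_monotone_in_min_support(self):
        ensemble = [random_dag(i) for i in range(12)]
        kept = [
            {tuple(sorted(e)) for e in consensus_edges(ensemble, s)[0].edges}
            for s in range(1, 13)
        ]
        for lo, hi in zip(kept, kept[1:]):
            assert hi <= lo

    def test_majority_orientation_wins(self):
        fwd = Dag(NODES, {("A", "B")})
        rev = Dag(NODES, {("B", "A")})
        dag, _ = consensus_edges([fwd.copy() for _ in range(8)] + [rev.copy() for _ in range(4)], 7)
        assert dag.edges == {("A", "B")}

    def test_cycle_broken_at_lowest_support(self, caplog):
        # each run is acyclic, but the majority orientations form the cycle
        # A->B->C->A (every edge in 8 of 12 runs); the tie is broken by
        # removing the lexicographically smallest edge
        pieces = [
            {("A", "B"), ("B", "C")},
            {("B", "C"), ("C", "A")},
            {("C", "A"), ("A", "B")},
        ]
        runs = [Dag(NODES, pieces[i % 3]) for i in range(12)]
        with caplog.at_level("WARNING"):
            dag, _ = consensus_edges(runs, 7)
        assert dag.is_acyclic()
        assert dag.edges == {("B", "C"), ("C", "A")}
        assert "cycle" in caplog.text


class TestBootstrapStability:
    HC = (AlgorithmConfig(1, "score", "hill-climbing"),)

    def test_noise_free_edges_all_retained(self):
        df = make_chain(1000, 0, beta=1.0, noise=0.05)
        cons = Dag(("X", "Y", "Z"), {("X", "Y"), ("Y", "Z")})
        dag, report = bootstrap_edge_stability(
            df, ArcConstraints(), self.HC, cons, B=20, m=500, seed=1, min_support=1
        )
        assert dag.edges == cons.edges
        assert all(f == pytest.approx(1.0) for f in report.fractions.values())

    def test_threshold_boundary_open_below_closed_at(self):
        cons = Dag(NODES, {("A", "B"), ("B", "C")})
        fr = {("A", "B"): 0.70, ("B", "C"): 0.69}
        dag = apply_stability_filter(cons, fr, 0.70)
        assert dag.edges == {("A", "B")}

    def test_fractions_match_replicate_recount(self):
        df = make_chain(400, 2, beta=0.8, noise=0.6)
        cons = Dag(("X", "Y", "Z"), {("X", "Y"), ("Y", "Z")})
        dag, report = bootstrap_edge_stability(
            df, ArcConstraints(), self.HC, cons, B=25, m=200, seed=3, min_support=1
        )
        assert report.n_replicates == 25
        assert len(report.replicate_edge_sets) == 25
        for (p, c), f in report.fractions.items():
            key = tuple(sorted((p, c)))
            recount = sum(1 for s in report.replicate_edge_sets if key in s) / 25
            assert f == pytest.approx(recount)

    def test_deterministic_given_seed(self):
        df = make_chain(300, 4)
        cons = Dag(("X", "Y", "Z"), {("X", "Y"), ("Y", "Z")})
        r1 = bootstrap_edge_stability(df, ArcConstraints(), self.HC, cons, B=10, m=200, seed=9, min_support=1)
        r2 = bootstrap_edge_stability(df, ArcConstraints(), self.HC, cons, B=10, m=200, seed=9, min_support=1)
        assert r1[0].edges == r2[0].edges
        assert r1[1].fractions == r2[1].fractions

    def test_monotone_in_threshold(self):
        df = make_chain(300, 5, noise=0.8)
        cons = Dag(("X", "Y", "Z"), {("X", "Y"), ("Y", "Z")})
        _, report = bootstrap_edge_stability(
            df, ArcConstraints(), self.HC, cons, B=20, m=100, seed=6, min_support=1
        )
        prev = None
        for thr in (0.0, 0.25, 0.5, 0.75, 1.0):
            kept = apply_stability_filter(cons, report.fractions, thr).edges
            if prev is not None:
                assert kept <= prev
            prev = kept


class TestArcSignificance:
    def test_pvalues_match_regression_oracle(self, boys_older_table):
        from rgbn.catalog import RESPONSE_NAMES
        import scipy.stats as sps

        train = boys_older_table[["W", "H", "HC", "TL"]].iloc[:500]
        graph = Dag(("W", "H", "HC", "TL"), {("W", "TL"), ("H", "TL"), ("HC", "TL")})
        pvals = arc_significance(graph, train)
        # normal-equations oracle with homoscedastic t-tests
        z = (train - train.mean()) / train.std(ddof=1)
        x = z[["H", "HC", "W"]].to_numpy()  # parents() is sorted
        y = z["TL"].to_numpy()
        n, k = x.shape
        xtx_inv = np.linalg.inv(x.T @ x)
        beta = xtx_inv @ x.T @ y
        resid = y - x @ beta
        s2 = resid @ resid / (n - k)
        tstats = beta / np.sqrt(np.diag(xtx_inv) * s2)
        for j, p in enumerate(("H", "HC", "W")):
            expected = 2 * sps.t.sf(abs(tstats[j]), n - k)
            assert pvals[(p, "TL")] == pytest.approx(expected, rel=1e-6)

    def test_strong_arcs_near_zero_pvalue(self, boys_older_table):
        graph = Dag(("W", "TL"), {("W", "TL")})
        pvals = arc_significance(graph, boys_older_table[["W", "TL"]])
        assert pvals[("W", "TL")] < 1e-10

    def test_null_arc_uniform_pvalue(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(
                {"W": rng.normal(size=200), "TF": rng.normal(size=200)}
            )
            graph = Dag(("W", "TF"), {("W", "TF")})
            p = arc_significance(graph, df)[("W", "TF")]
            hits += p > 0.05
        assert hits >= 33  # ~95% expected, allow sampling slack
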