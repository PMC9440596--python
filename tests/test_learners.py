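"""Structure learners against enumeration oracles and null simulations."""

import numpy as np
import pandas as pd
import pytest

from rgbn.dag import ArcConstraints, Dag
from rgbn.gaussian import FamilyScoreCache, SufficientStats, gaussian_bic
from rgbn.learners import (
    CB_VARIANTS,
    AlgorithmConfig,
    default_algorithm_configs,
    learn_markov_blanket_cb,
    learn_mmhc,
    learn_score_based,
    mmpc_skeleton,
    run_ensemble,
)
from tests.conftest import make_chain, make_independent
from tests.oracles import all_dags


def blacklist_all(nodes):
    return ArcConstraints.make(
        forbidden=[(a, b) for a in nodes for b in nodes if a != b]
    )


class TestConfigs:
    def test_twelve_defaults_with_family_counts(self):
        cfgs = default_algorithm_configs()
        assert len(cfgs) == 12
        fams = [c.family for c in cfgs]
        assert fams.count("constraint") == 8
        assert fams.count("score") == 2
        assert fams.count("hybrid") == 2
        assert [c.run_id for c in cfgs] == list(range(1, 13))


class TestConstraintBased:
    @pytest.mark.parametrize("variant", CB_VARIANTS)
    def test_chain_adjacency_recovered(self, variant):
        dag = learn_markov_blanket_cb(make_chain(5000, 1), variant, 0.05, ArcConstraints())
        adj = {tuple(sorted(e)) for e in dag.edges}
        assert adj == {("X", "Y"), ("Y", "Z")}

    def test_independent_noise_gives_empty_graph(self):
        # alpha 0.01 (one of the two configured levels) keeps the familywise
        # false-edge rate over the 6 variable pairs near zero
        empties = 0
        for seed in range(20):
            dag = learn_markov_blanket_cb(
                make_independent(2000, seed), "iamb", 0.01, ArcConstraints()
            )
            empties += dag.n_edges == 0
        assert empties >= 18

    def test_full_blacklist_forces_empty_graph(self):
        df = make_chain(2000, 2)
        dag = learn_markov_blanket_cb(df, "gs", 0.05, blacklist_all(df.columns))
        assert dag.n_edges == 0

    def test_directed_chain_with_sink_blacklist_matches_oracle(self):
        """Forbidding arcs into X pins the orientation of the generating chain."""
        df = make_chain(5000, 3)
        cons = ArcConstraints.make(forbidden=[("Y", "X"), ("Z", "X")])
        dag = learn_markov_blanket_cb(df, "inter-iamb", 0.05, cons)
        stats = SufficientStats.from_table(df)
        cache = FamilyScoreCache(stats)
        legal = [
            d for d in all_dags(df.columns)
            if not ({("Y", "X"), ("Z", "X")} & d.edges)
        ]
        best = max(legal, key=lambda d: gaussian_bic(d, stats, cache))
        assert {tuple(sorted(e)) for e in dag.edges} == {
            tuple(sorted(e)) for e in best.edges
        }
        assert ("X", "Y") in dag.edges


class TestScoreBased:
    def test_chain_score_equals_exhaustive_maximum(self):
        df = make_chain(5000, 4)
        stats = SufficientStats.from_table(df)
        cache = FamilyScoreCache(stats)
        hc = learn_score_based(df, "hill-climbing", stats=stats, cache=cache)
        oracle = max(gaussian_bic(d, stats, cache) for d in all_dags(df.columns))
        assert gaussian_bic(hc, stats, cache) == pytest.approx(oracle, rel=1e-12)

    def test_hill_climbing_trace_strictly_increases(self):
        trace: list[float] = []
        learn_score_based(make_chain(2000, 5), "hill-climbing", score_trace=trace)
        assert len(trace) >= 2
        assert all(b > a for a, b in zip(trace, trace[1:]))

    def test_tabu_never_below_hill_climbing(self):
        for seed in range(5):
            df = make_chain(1000, seed, beta=0.7)
            stats = SufficientStats.from_table(df)
            cache = FamilyScoreCache(stats)
            hc = learn_score_based(df, "hill-climbing", stats=stats, cache=cache)
            tb = learn_score_based(df, "tabu", stats=stats, cache=cache)
            assert gaussian_bic(tb, stats, cache) >= gaussian_bic(hc, stats, cache) - 1e-9

    def test_whitelist_arc_kept_blacklist_respected(self):
        df = make_independent(1000, 0, k=3)
        cons = ArcConstraints.make(required=[("V0", "V1")], forbidden=[("V2", "V0")])
        dag = learn_score_based(df, "hill-climbing", cons)
        assert ("V0", "V1") in dag.edges
        assert ("V2", "V0") not in dag.edges


class TestMmhc:
    def test_edges_within_mmpc_skeleton(self, boys_older_table, specs):
        from rgbn.catalog import RESPONSE_NAMES
        from rgbn.synthetic import standardize_with_marginals

        marg = specs[1]["boys_over_14"]
        cols = ["Age", "W", "H", "HC"] + list(RESPONSE_NAMES)
        z = standardize_with_marginals(boys_older_table[cols], marg)
        stats = SufficientStats.from_table(z)
        skeleton = mmpc_skeleton(stats, 0.05)
        dag = learn_mmhc(z, 0.05)
        assert all(frozenset(e) in skeleton for e in dag.edges)

    def test_diamond_adjacency_matches_generating_skeleton(self):
        rng = np.random.default_rng(7)
        n = 5000
        a = rng.normal(size=n)
        b = 0.9 * a + rng.normal(scale=0.4, size=n)
        c = -0.9 * a + rng.normal(scale=0.4, size=n)
        d = 0.7 * b + 0.7 * c + rng.normal(scale=0.4, size=n)
        df = pd.DataFrame({"A": a, "B": b, "C": c, "D": d})
        dag = learn_mmhc(df, 0.05)
        adj = {tuple(sorted(e)) for e in dag.edges}
        assert adj == {("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")}

    def test_alpha_one_reduces_to_plain_hill_climbing(self):
        df = make_chain(2000, 8)
        assert learn_mmhc(df, 1.0).edges == learn_score_based(df, "hill-climbing").edges


class TestEnsemble:
    def test_twelve_results_in_config_order(self, boys_older_table, specs):
        from rgbn.catalog import RESPONSE_NAMES
        from rgbn.dag import default_constraints
        from rgbn.synthetic import standardize_with_marginals

        covs = ("Age", "W", "H", "BMI", "HC")
        cols = list(covs) + list(RESPONSE_NAMES)
        z = standardize_with_marginals(
            boys_older_table[cols], specs[1]["boys_over_14"]
        ).iloc[:400]
        cons = default_constraints(covs, RESPONSE_NAMES)
        results = run_ensemble(z, cons)
        assert [cfg.run_id for cfg, _ in results] == list(range(1, 13))
        for _, dag in results:
            assert dag.is_acyclic()
            for resp in RESPONSE_NAMES:
                for cov in covs:
                    assert (resp, cov) not in dag.edges
            assert all(c != "Age" for _, c in dag.edges)

    def test_failed_learner_yields_empty_graph(self, caplog):
        df = make_chain(200, 9)
        bad = (AlgorithmConfig(1, "constraint", "no-such-variant", 0.05),)
        with caplog.at_level("WARNING"):
            results = run_ensemble(df, ArcConstraints(), bad)
        assert len(results) == 1
        assert results[0][1].n_edges == 0
        assert "failed" in caplog.text

    def test_strong_signal_unanimity(self):
        df = make_chain(5000, 10, beta=1.0, noise=0.2)
        results = run_ensemble(df, ArcConstraints())
        adjs = [{tuple(sorted(e)) for e in d.edges} for _, d in results]
        assert all(a == adjs[0] for a in adjs)
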