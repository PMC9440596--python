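"""Node-model extraction, prediction order, hierarchical prediction."""

import numpy as np
import pandas as pd
import pytest

from rgbn.catalog import RESPONSE_NAMES
from rgbn.dag import Dag
from rgbn.models import (
    NodeLinearModel,
    composed_linear_weights,
    extract_node_models,
    models_from_json,
    models_to_json,
    predict_hierarchical,
    prediction_order,
)
from rgbn.preprocess import Standardizer, standardize
from tests.oracles import reachable


def _scaler(cols):
    return Standardizer({c: 0.0 for c in cols}, {c: 1.0 for c in cols})


@pytest.fixture(scope="module")
def fitted(specs):
    """Models extracted from the generating graph on simulated z-data."""
    from rgbn.catalog import BOYS_OLDER
    from rgbn.synthetic import simulate_group, standardize_with_marginals

    sem = specs[3]["boys_over_14"]
    tab = simulate_group(BOYS_OLDER, 3000, 7, specs)
    cols = ["Age", "W", "H", "BMI", "HC"] + list(RESPONSE_NAMES)
    z = standardize_with_marginals(tab[cols], specs[1]["boys_over_14"])
    scaler = _scaler(cols)
    graph = Dag(tuple(cols), sem.response_edges())
    return extract_node_models(graph, z, scaler), graph, z, sem


class TestExtraction:
    def test_coefficients_match_normal_equations_oracle(self, fitted):
        models, graph, z, _ = fitted
        for resp in RESPONSE_NAMES:
            m = models[resp]
            x = z[list(m.parents)].to_numpy()
            y = z[resp].to_numpy()
            beta = np.linalg.solve(x.T @ x, x.T @ y)
            assert np.allclose(m.coefficients, beta, atol=1e-10)

    def test_generating_coefficients_recovered(self, fitted, specs):
        models, _, _, sem = fitted
        m = models["TL"]
        se = 3 * 0.02  # ~3 standard errors at n = 3000 with high R^2
        assert dict(zip(m.parents, m.coefficients)) == pytest.approx(
            dict(zip(sem.parents("TL"), sem.betas("TL"))), abs=se
        )
        assert m.r_squared == pytest.approx(0.88, abs=0.03)

    def test_parentless_node_predicts_group_mean(self):
        rng = np.random.default_rng(0)
        z = pd.DataFrame({"TF": rng.normal(size=100), "W": rng.normal(size=100)})
        graph = Dag(("W", "TF"))
        scaler = Standardizer({"TF": 4.4, "W": 40.0}, {"TF": 1.9, "W": 10.0})
        models = extract_node_models(graph, z, scaler, responses=("TF",))
        assert models["TF"].parents == ()
        assert models["TF"].r_squared == 0.0
        pred = predict_hierarchical(models, ["TF"], z[["W"]])
        assert np.allclose(pred["TF"], 4.4)

    def test_more_parents_than_rows_rejected(self):
        z = pd.DataFrame({"TF": [0.1, 0.2], "W": [0.3, 0.4], "H": [0.5, 0.6], "BMI": [0.7, 0.8]})
        graph = Dag(("W", "H", "BMI", "TF"), {("W", "TF"), ("H", "TF"), ("BMI", "TF")})
        with pytest.raises(ValueError, match="parents"):
            extract_node_models(graph, z, _scaler(z.columns), responses=("TF",))

    def test_json_roundtrip(self, fitted):
        models, *_ = fitted
        again = models_from_json(models_to_json(models))
        assert again == models


class TestPredictionOrder:
    def test_boys_older_partial_order_constraints(self, fitted):
        _, graph, _, _ = fitted
        order = prediction_order(graph)
        assert set(order) == set(RESPONSE_NAMES)
        idx = {v: i for i, v in enumerate(order)}
        for before, after in [("TL", "TF"), ("TL", "TB"), ("TL", "LL"),
                              ("TF", "LF"), ("TB", "LB"), ("AF", "AL"), ("AL", "AB")]:
            assert idx[before] < idx[after]

    def test_no_response_arcs_gives_alphabetical(self):
        graph = Dag(("W",) + RESPONSE_NAMES, {("W", r) for r in RESPONSE_NAMES})
        assert prediction_order(graph) == sorted(RESPONSE_NAMES)

    def test_order_is_valid_topological_sort_by_reachability(self, fitted):
        _, graph, _, _ = fitted
        order = prediction_order(graph)
        idx = {v: i for i, v in enumerate(order)}
        resp_graph = Dag(
            tuple(RESPONSE_NAMES),
            {(p, c) for p, c in graph.edges if p in RESPONSE_NAMES and c in RESPONSE_NAMES},
        )
        for a in RESPONSE_NAMES:
            for b in RESPONSE_NAMES:
                if a != b and reachable(resp_graph, a, b):
                    assert idx[a] < idx[b]


class TestHierarchicalPrediction:
    def test_zero_covariates_predict_group_means(self, fitted):
        models, graph, _, _ = fitted
        cov_z = pd.DataFrame({c: np.zeros(5) for c in ("Age", "W", "H", "BMI", "HC")})
        pred = predict_hierarchical(models, prediction_order(graph), cov_z,
                                    clamp_negative=False)
        for resp in RESPONSE_NAMES:
            assert np.allclose(pred[resp], models[resp].mean, atol=1e-12)

    def test_equals_composed_linear_map_oracle(self, fitted):
        models, graph, z, _ = fitted
        order = prediction_order(graph)
        covs = ["Age", "W", "H", "BMI", "HC"]
        cov_z = z[covs].iloc[:50]
        pred = predict_hierarchical(models, order, cov_z, clamp_negative=False)
        weights = composed_linear_weights(models, order)
        for resp in RESPONSE_NAMES:
            w = weights[resp]
            direct = sum(w.get(c, 0.0) * cov_z[c].to_numpy() for c in covs)
            m = models[resp]
            assert np.allclose(pred[resp], m.mean + m.sd * direct, atol=1e-10)

    def test_two_level_chain_manual_substitution(self):
        models = {
            "TL": NodeLinearModel("TL", ("W",), (0.8,), 0.1, 0.9, 0.0, 1.0),
            "TB": NodeLinearModel("TB", ("TL",), (0.9,), 0.1, 0.8, 0.0, 1.0),
        }
        w = np.array([0.5, -1.0, 2.0])
        pred = predict_hierarchical(models, ["TL", "TB"], pd.DataFrame({"W": w}),
                                    clamp_negative=False)
        assert np.allclose(pred["TB"], 0.9 * 0.8 * w, atol=1e-12)

    def test_linearity_doubling_covariates_doubles_zscores(self, fitted):
        models, graph, z, _ = fitted
        order = prediction_order(graph)
        covs = ["Age", "W", "H", "BMI", "HC"]
        cov_z = z[covs].iloc[:20]
        p1 = predict_hierarchical(models, order, cov_z, clamp_negative=False)
        p2 = predict_hierarchical(models, order, 2.0 * cov_z, clamp_negative=False)
        for resp in RESPONSE_NAMES:
            m = models[resp]
            z1 = (p1[resp] - m.mean) / m.sd
            z2 = (p2[resp] - m.mean) / m.sd
            assert np.allclose(z2, 2.0 * z1, atol=1e-9)

    def test_negative_mass_clamped_with_warning(self, caplog):
        models = {"TB": NodeLinearModel("TB", ("W",), (1.0,), 0.0, 1.0, 0.3, 0.2)}
        cov_z = pd.DataFrame({"W": [-10.0]})
        with caplog.at_level("WARNING"):
            pred = predict_hierarchical(models, ["TB"], cov_z)
        assert pred["TB"].iloc[0] == 0.0
        assert "clamping" in caplog.text

    def test_missing_covariate_named_in_error(self, fitted):
        models, graph, z, _ = fitted
        cov_z = z[["Age", "W", "H", "BMI"]].iloc[:5]  # HC missing
        with pytest.raises(ValueError, match="HC"):
            predict_hierarchical(models, prediction_order(graph), cov_z)

    def test_validation_predictions_positively_correlated_with_truth(self, specs):
        """Predictions from anthropometrics alone track every compartment."""
        from rgbn.catalog import BOYS_YOUNGER
        from rgbn.synthetic import simulate_group, standardize_with_marginals

        sem = specs[3][BOYS_YOUNGER.label]
        tab = simulate_group(BOYS_YOUNGER, 1000, 11, specs)
        cols = list(sem.covariates_used) + list(RESPONSE_NAMES)
        z = standardize_with_marginals(tab[cols], specs[1][BOYS_YOUNGER.label])
        graph = Dag(tuple(cols), sem.response_edges())
        models = extract_node_models(graph, z, _scaler(cols))
        pred = predict_hierarchical(
            models, prediction_order(graph), z[list(sem.covariates_used)],
            clamp_negative=False,
        )
        for resp in RESPONSE_NAMES:
            r = np.corrcoef(pred[resp], z[resp])[0, 1]
            assert r > 0.3, resp
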