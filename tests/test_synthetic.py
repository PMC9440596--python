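"""Generator calibration, determinism, and SEM recovery-by-construction."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import skew

from rgbn.catalog import (
    BOYS_OLDER,
    GIRLS_OLDER,
    GROUP_SIZES,
    GROUPS,
    RESPONSE_NAMES,
)
from rgbn import reported
from rgbn.dag import CycleError
from rgbn.reported import MarginalRecord
from rgbn.synthetic import (
    GroundTruthSEM,
    Margin,
    default_dependence,
    default_study_specs,
    simulate_anthropometrics,
    simulate_body_composition,
    simulate_study_cohort,
    standardize_with_marginals,
    validate_marginals,
)


class TestDefaultSpecs:
    def test_catalog_has_six_covariates_nine_responses(self, specs):
        catalog = specs[0]
        assert len(catalog.covariates) == 6
        assert len(catalog.responses) == 9

    def test_all_default_sems_are_acyclic(self, specs):
        for sem in specs[3].values():
            assert sem.dag().is_acyclic()
            assert sem.topological_responses()  # topological sort exists

    def test_boys_older_trunk_lean_model_stored_verbatim(self, specs):
        sem = specs[3][BOYS_OLDER.label]
        assert sem.parents("TL") == ["W", "H", "HC"]
        assert tuple(sem.betas("TL")) == (0.66, 0.19, 0.18)
        assert sem.r2("TL") == 0.88

    def test_girls_younger_trunk_fat_parents(self, specs):
        sem = specs[3]["girls_under_13"]
        assert sem.parents("TF") == ["BMI", "WC", "TL"]
        assert tuple(sem.betas("TF")) == (0.68, 0.21, 0.19)

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            GroundTruthSEM("g", {"TF": ([("TF", 0.5)], 0.8)})

    def test_cyclic_sem_rejected(self):
        with pytest.raises(CycleError):
            GroundTruthSEM(
                "g", {"TF": ([("TL", 0.5)], 0.8), "TL": ([("TF", 0.5)], 0.8)}
            )

    def test_girls_trunk_bone_sd_repaired_from_iqr(self, specs):
        rec = specs[1][GIRLS_OLDER.label]["TB"]
        assert rec.sd == pytest.approx(0.17 / 1.349, abs=1e-3)

    def test_repair_pass_logs_inconsistencies(self):
        repaired, log = validate_marginals(reported.SUMMARY_STATS["F"], "F/")
        assert any("TB" in line and "repaired" in line for line in log)
        repaired, log = validate_marginals(reported.SUMMARY_STATS["M"], "M/")
        assert any("AB" in line for line in log)  # mean/quartile clash logged
        assert all(rec.sd == reported.SUMMARY_STATS["M"][v].sd for v, rec in repaired.items())


class TestMargins:
    @pytest.mark.parametrize("mean,sd,g", [(40.2, 10.0, 0.10), (150.6, 11.0, -0.65), (14.1, 2.5, -0.07)])
    def test_moment_matching(self, mean, sd, g):
        m = Margin(mean, sd, g)
        u = np.random.default_rng(0).uniform(1e-6, 1 - 1e-6, 200000)
        x = m.ppf(u)
        assert x.mean() == pytest.approx(mean, rel=0.01)
        assert x.std(ddof=1) == pytest.approx(sd, rel=0.01)
        if abs(g) >= 0.1:
            assert skew(x) == pytest.approx(g, abs=0.05)

    def test_ppf_cdf_roundtrip(self):
        m = Margin(10.0, 2.0, 0.5)
        u = np.linspace(0.01, 0.99, 21)
        assert np.allclose(m.cdf(m.ppf(u)), u, atol=1e-9)

    def test_truncated_ppf_respects_window(self):
        m = Margin(13.8, 2.8, 0.13)
        u = np.random.default_rng(1).uniform(0, 1, 1000)
        x = m.ppf_truncated(u, (13.0, 18.5))
        assert x.min() >= 13.0 and x.max() < 18.5


class TestAnthropometrics:
    def test_zero_rows_gives_empty_table_with_columns(self, specs):
        t = simulate_anthropometrics(GIRLS_OLDER, 0, specs[1][GIRLS_OLDER.label],
                                     specs[2][GIRLS_OLDER.label], 0)
        assert len(t) == 0
        assert list(t.columns) == ["Age", "W", "H", "BMI", "WC", "HC"]

    def test_same_seed_identical_different_seed_not(self, specs):
        args = (GIRLS_OLDER, 50, specs[1][GIRLS_OLDER.label], specs[2][GIRLS_OLDER.label])
        a, b = simulate_anthropometrics(*args, 7), simulate_anthropometrics(*args, 7)
        c = simulate_anthropometrics(*args, 8)
        pd.testing.assert_frame_equal(a, b)
        assert not a.equals(c)

    def test_marginal_calibration_girls(self, specs):
        """Sample mean/SD track the published per-sex summaries within 2%."""
        marg = specs[1][GIRLS_OLDER.label]
        t = simulate_anthropometrics(GIRLS_OLDER, 100_000, marg, specs[2][GIRLS_OLDER.label], 3)
        for var in ("Age", "W", "H", "WC", "HC"):
            rec = marg[var]
            assert t[var].mean() == pytest.approx(rec.mean, rel=0.02)
            assert t[var].std(ddof=1) == pytest.approx(rec.sd, rel=0.02)
            if abs(rec.skewness) >= 0.1:
                assert skew(t[var]) == pytest.approx(rec.skewness, abs=0.15)

    def test_bmi_is_deterministic_in_weight_and_height(self, specs):
        t = simulate_anthropometrics(BOYS_OLDER, 100, specs[1][BOYS_OLDER.label],
                                     specs[2][BOYS_OLDER.label], 0)
        assert np.allclose(t["BMI"], t["W"] / (t["H"] / 100) ** 2)

    def test_bad_correlation_matrix_rejected(self):
        from rgbn.synthetic import CovariateDependence

        bad = np.full((5, 5), 0.99)
        np.fill_diagonal(bad, 1.0)
        bad[0, 1] = bad[1, 0] = -0.99  # makes it indefinite
        with pytest.raises(ValueError):
            CovariateDependence("g", bad)

    def test_default_dependence_is_positive_definite(self):
        dep = default_dependence("g")
        assert np.linalg.eigvalsh(dep.matrix).min() > 0


class TestBodyComposition:
    def test_noise_free_limit_refits_exactly(self, specs):
        """R^2 = 1 forces zero residual SD: a refit reproduces z exactly."""
        marg = specs[1][BOYS_OLDER.label]
        sem0 = GroundTruthSEM(
            BOYS_OLDER.label, {"TL": ([("W", 0.66), ("H", 0.19), ("HC", 0.18)], 1.0)}
        )
        a = simulate_anthropometrics(BOYS_OLDER, 500, marg, specs[2][BOYS_OLDER.label], 0)
        t = simulate_body_composition(a, sem0, marg, 0)
        z = standardize_with_marginals(t, marg)
        pred = 0.66 * z["W"] + 0.19 * z["H"] + 0.18 * z["HC"]
        assert np.allclose(pred, z["TL"], atol=1e-10)

    def test_coefficients_and_r2_recovered_by_construction(self, specs):
        """OLS refit on true parents recovers beta and R^2 (3 seeds, n=5000)."""
        marg, dep, sem = (specs[i][BOYS_OLDER.label] for i in (1, 2, 3))
        betas, r2s = [], []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            a = simulate_anthropometrics(BOYS_OLDER, 5000, marg, dep, rng)
            t = simulate_body_composition(a, sem, marg, rng)
            z = standardize_with_marginals(t, marg)
            x, y = z[["W", "H", "HC"]].to_numpy(), z["TL"].to_numpy()
            b, *_ = np.linalg.lstsq(x, y, rcond=None)
            r = y - x @ b
            betas.append(b)
            r2s.append(1 - (r @ r) / (y @ y))
        assert np.allclose(np.mean(betas, axis=0), [0.66, 0.19, 0.18], atol=4 / np.sqrt(5000))
        assert np.mean(r2s) == pytest.approx(0.88, abs=0.02)

    def test_unknown_covariate_raises(self, specs):
        marg = specs[1][BOYS_OLDER.label]
        sem = GroundTruthSEM(BOYS_OLDER.label, {"TL": ([("WC", 1.0)], 0.9)})
        a = simulate_anthropometrics(BOYS_OLDER, 20, marg, specs[2][BOYS_OLDER.label], 0)
        with pytest.raises(ValueError, match="covariates"):
            simulate_body_composition(a.drop(columns=["WC"]), sem, marg, 0)


class TestStudyCohort:
    def test_published_group_sizes_and_totals(self):
        cohort = simulate_study_cohort(11)
        sizes = cohort.groupby("group").size().to_dict()
        assert sizes == GROUP_SIZES
        assert len(cohort) == 476
        by_sex = cohort.groupby("sex").size().to_dict()
        assert by_sex == {"F": 235, "M": 241}

    def test_age_windows_respected(self):
        cohort = simulate_study_cohort(5)
        for g in GROUPS:
            ages = cohort.loc[cohort["group"] == g.label, "Age"]
            lo, hi = g.age_window
            assert (ages >= lo).all() and (ages < hi).all()

    def test_serialized_determinism(self, tmp_path):
        from rgbn.io import write_cohort_csv

        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_cohort_csv(simulate_study_cohort(3), p1)
        write_cohort_csv(simulate_study_cohort(3), p2)
        assert p1.read_bytes() == p2.read_bytes()
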