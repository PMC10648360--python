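"""Goodness-of-fit metrics, ranking, cross-validation, agreement analyses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sf6dmap import (
    average_rank,
    bland_altman,
    concordance_ccc,
    ecdf_compare,
    information_criteria,
    kfold_cv,
    prediction_metrics,
    spearman_overlap,
)
from sf6dmap.evaluation import correlation_band


class TestPredictionMetrics:
    def test_perfect_prediction_is_all_zero(self):
        y = np.linspace(0.4, 1.0, 10)
        rep = prediction_metrics(y, y)
        assert rep.rmse == rep.mae == rep.me == 0.0
        assert rep.ae_gt_005 == rep.ae_gt_010 == 0.0

    def test_symmetric_errors(self):
        rep = prediction_metrics([0.5, 0.5], [0.4, 0.6])
        assert rep.rmse == pytest.approx(0.1)
        assert rep.mae == pytest.approx(0.1)
        assert rep.me == pytest.approx(0.0)

    def test_exceedance_counts_strict(self):
        obs = np.array([0.0, 0.0, 0.0])
        pred = obs - np.array([0.06, 0.20, 0.01])
        rep = prediction_metrics(obs, pred)
        assert rep.ae_gt_005 == pytest.approx(200 / 3)
        assert rep.ae_gt_010 == pytest.approx(100 / 3)
        # exactly at a threshold does not count as exceeding it
        rep2 = prediction_metrics([0.0, 0.1], [-0.05, 0.1])
        assert rep2.ae_gt_005 == 0.0

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_error_decomposition_and_ordering(self, seed):
        rng = np.random.default_rng(seed)
        o = rng.random(20)
        p = rng.random(20)
        rep = prediction_metrics(o, p)
        assert rep.rmse >= rep.mae >= 0
        e = o - p
        assert rep.rmse**2 == pytest.approx(rep.me**2 + e.var(), abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            prediction_metrics([1.0], [1.0, 2.0])


class TestCCC:
    def test_identity_is_one(self):
        x = np.array([0.3, 0.5, 0.9])
        assert concordance_ccc(x, x) == pytest.approx(1.0)

    def test_location_shift_penalised(self):
        x = np.array([1.0, 2.0, 3.0])
        assert concordance_ccc(x, x + 1) == pytest.approx(4 / 7)

    def test_scale_shift_penalised(self):
        x = np.array([1.0, 2.0, 3.0])
        assert concordance_ccc(x, 2 * x) == pytest.approx(8 / 22)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_ccc_bounded_by_pearson(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random(15)
        y = rng.random(15) + 0.3 * x
        r = stats.pearsonr(x, y).statistic
        assert abs(concordance_ccc(x, y)) <= abs(r) + 1e-12

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            concordance_ccc([1.0, 1.0], [2.0, 2.0])


class TestInformationCriteria:
    def test_formulas(self):
        aic, bic = information_criteria(-100.0, 3, 100)
        assert aic == pytest.approx(206.0)
        assert bic == pytest.approx(200 + 3 * np.log(100))

    def test_penalty_monotone_in_k(self):
        a1, b1 = information_criteria(-50.0, 2, 30)
        a2, b2 = information_criteria(-50.0, 5, 30)
        assert a2 > a1 and b2 > b1


class TestSpearmanOverlap:
    def test_bands(self):
        assert correlation_band(0.797) == "strong"
        assert correlation_band(1.0) == "very strong"
        assert correlation_band(-0.25) == "weak"
        assert correlation_band(0.05) == "very weak"

    def test_perfect_rank_agreement(self):
        a = pd.DataFrame({"x": [1.0, 2.0, 5.0, 9.0]})
        b = pd.DataFrame({"y": [2.0, 4.0, 6.0, 90.0]})
        rho, bands = spearman_overlap(a, b)
        assert rho.loc["y", "x"] == pytest.approx(1.0)
        assert bands.loc["y", "x"] == "very strong"

    def test_matches_rank_then_pearson_oracle(self, rng):
        a = pd.DataFrame({"x": rng.random(12), "z": rng.random(12)})
        b = pd.DataFrame({"y": rng.random(12)})
        rho, _ = spearman_overlap(a, b)
        for col in ("x", "z"):
            rx = stats.rankdata(a[col])
            ry = stats.rankdata(b["y"])
            assert rho.loc["y", col] == pytest.approx(
                stats.pearsonr(rx, ry).statistic, abs=1e-12
            )

    def test_constant_column_flagged(self):
        a = pd.DataFrame({"x": [1.0, 1.0, 1.0]})
        b = pd.DataFrame({"y": [1.0, 2.0, 3.0]})
        rho, bands = spearman_overlap(a, b)
        assert np.isnan(rho.loc["y", "x"])
        assert bands.loc["y", "x"] == "undefined"


class TestAverageRank:
    def test_best_on_everything_ranks_first(self):
        tbl = pd.DataFrame(
            {"rmse": [0.08, 0.09, 0.10], "ccc": [0.9, 0.8, 0.7]},
            index=["a", "b", "c"],
        )
        out = average_rank(tbl)
        assert out.loc["a", "arv"] == 1.0
        assert out.loc["c", "arv"] == 3.0

    def test_ties_share_mean_ranks(self):
        tbl = pd.DataFrame({"rmse": [0.08, 0.08, 0.10]}, index=["a", "b", "c"])
        out = average_rank(tbl)
        assert out.loc["a", "rmse"] == out.loc["b", "rmse"] == 1.5

    def test_ranking_is_within_class(self):
        tbl = pd.DataFrame(
            {"rmse": [0.10, 0.20, 0.01, 0.02]}, index=["a1", "a2", "b1", "b2"]
        )
        out = average_rank(tbl, class_labels={"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert out.loc["a1", "arv"] == 1.0  # best within A despite larger error
        assert out.loc["b2", "arv"] == 2.0

    def test_missing_cell_rejected(self):
        tbl = pd.DataFrame({"rmse": [0.1, np.nan]}, index=["a", "b"])
        with pytest.raises(ValueError, match="missing metric cell"):
            average_rank(tbl)


class TestKFoldCV:
    @staticmethod
    def _mean_recipe(train):
        mu = train["utility"].mean()
        return lambda test: np.full(len(test), mu)

    def test_fold_sizes_and_coverage(self, tariff):
        from sf6dmap import generate_cohort

        cohort625 = generate_cohort(tariff=tariff, n=625, seed=21)
        reps = kfold_cv(cohort625, {"mean": self._mean_recipe}, k=5, seed=0)
        assign = reps["mean"].fold_assignments
        counts = np.bincount(assign)
        assert counts.tolist() == [125] * 5
        assert len(assign) == 625

    def test_same_seed_identical(self, cohort):
        a = kfold_cv(cohort, {"mean": self._mean_recipe}, k=5, seed=3)["mean"]
        b = kfold_cv(cohort, {"mean": self._mean_recipe}, k=5, seed=3)["mean"]
        np.testing.assert_array_equal(a.fold_assignments, b.fold_assignments)
        assert a.averaged.rmse == b.averaged.rmse

    def test_mean_recipe_rmse_is_population_sd(self, cohort):
        rep = kfold_cv(cohort, {"mean": self._mean_recipe}, k=5, seed=1)["mean"]
        assert rep.averaged.rmse == pytest.approx(
            cohort["utility"].std(ddof=0), rel=0.05
        )

    def test_leave_one_out_covers_each_subject_once(self, cohort):
        small = cohort.iloc[:20]
        rep = kfold_cv(small, {"mean": self._mean_recipe}, k=20, seed=0)["mean"]
        assert sorted(rep.fold_assignments.tolist()) == list(range(20))

    def test_failing_fold_recorded(self, cohort):
        calls = {"n": 0}

        def flaky(train):
            calls["n"] += 1
            if calls["n"] == 2:
                raise RuntimeError("boom")
            return self._mean_recipe(train)

        with pytest.warns(UserWarning, match="fold 1 failed"):
            rep = kfold_cv(cohort, {"flaky": flaky}, k=5, seed=0)["flaky"]
        assert rep.failures == [1]
        assert len(rep.fold_metrics) == 4


class TestBlandAltman:
    def test_perfect_agreement(self):
        y = np.linspace(0, 1, 10)
        res = bland_altman(y, y)
        assert res.mean_diff == res.sd_diff == 0.0
        assert res.pct_outside == 0.0

    def test_two_point_limits(self):
        res = bland_altman([0.0, 0.0], [0.1, -0.1])
        assert res.mean_diff == pytest.approx(0.0)
        assert res.sd_diff == pytest.approx(0.1 * np.sqrt(2))
        assert res.upper_limit == pytest.approx(1.96 * 0.1 * np.sqrt(2))

    def test_normal_differences_leave_five_percent_outside(self):
        rng = np.random.default_rng(0)
        diffs = rng.standard_normal(100_000)
        res = bland_altman(diffs, np.zeros_like(diffs))
        assert res.pct_outside == pytest.approx(5.0, abs=0.5)


class TestECDF:
    def test_identical_series_zero_gap(self):
        y = np.array([0.2, 0.5, 0.9])
        frame = ecdf_compare(y, y)
        assert frame.attrs["max_gap"] == 0.0

    def test_disjoint_point_masses_gap_one(self):
        frame = ecdf_compare([0.5] * 4, [0.6] * 4, grid=np.linspace(0.4, 0.7, 301))
        assert frame.attrs["max_gap"] == pytest.approx(1.0)

    def test_matches_sort_and_count_oracle(self, rng):
        o = rng.random(20)
        p = rng.random(20)
        grid = np.linspace(0, 1, 11)
        frame = ecdf_compare(o, p, grid=grid)
        for g, c in zip(frame["grid"], frame["cdf_observed"]):
            assert c == pytest.approx(np.mean(o <= g))
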