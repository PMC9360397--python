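import numpy as np
import pandas as pd
import pytest
from scipy import stats

from serumhb.synthetic import generate_design, generate_samples
from serumhb.univariate import LinearFit, ols_fit, predict_hb
from serumhb.validation import (
    compare_methods,
    ejcr_test,
    equality_line,
    nested_cv,
    paired_t,
    split_calibration,
)


def _table(n_animals=10, seed=42):
    return generate_samples(generate_design(n_animals, seed=seed))


class TestSplitCalibration:
    def test_full_design_split_counts(self, sample_table):
        plan = split_calibration(sample_table, fraction=0.70, seed=1)
        assert len(plan.calibration_ids) == 49
        assert len(plan.validation_ids) == 21

    def test_single_level_seven_three(self):
        frame = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(10)], "fraction": 0.05}
        )
        plan = split_calibration(frame, fraction=0.70, seed=0)
        assert len(plan.calibration_ids) == 7
        assert len(plan.validation_ids) == 3

    def test_deterministic(self, sample_table):
        a = split_calibration(sample_table, seed=5)
        b = split_calibration(sample_table, seed=5)
        assert a == b

    def test_conservation_and_disjointness(self, sample_table):
        plan = split_calibration(sample_table, seed=2)
        cal, val = set(plan.calibration_ids), set(plan.validation_ids)
        assert cal | val == set(sample_table["sample_id"])
        assert not cal & val

    def test_per_level_proportions(self, sample_table):
        plan = split_calibration(sample_table, fraction=0.70, seed=3)
        cal = sample_table[sample_table["sample_id"].isin(plan.calibration_ids)]
        for _, group in cal.groupby("fraction"):
            assert abs(len(group) - 7) <= 1

    def test_rejects_singleton_level(self):
        frame = pd.DataFrame({"sample_id": ["a", "b", "c"], "fraction": [0, 0, 0.1]})
        with pytest.raises(ValueError, match="fewer than 2"):
            split_calibration(frame)

    def test_rejects_bad_fraction(self, sample_table):
        with pytest.raises(ValueError):
            split_calibration(sample_table, fraction=1.0)


class TestNestedCV:
    @staticmethod
    def _identity_fns():
        return (lambda df: None, lambda model, df: df["hb_ref"].to_numpy())

    def test_identity_predictor_rmse_zero(self, sample_table):
        cv = nested_cv(sample_table, *self._identity_fns())
        assert cv.per_fold_rmse == tuple([0.0] * 10)

    def test_animal_folds_of_seven(self, sample_table):
        cv = nested_cv(sample_table, *self._identity_fns())
        folds = pd.Series(cv.fold_assignments)
        assert folds.nunique() == 10
        assert (folds.value_counts() == 7).all()
        # every fold is exactly one animal
        frame = sample_table.set_index("sample_id")
        for fold_idx, ids in folds.groupby(folds).groups.items():
            assert frame.loc[list(ids), "animal_id"].nunique() == 1

    def test_every_sample_predicted_exactly_once(self, sample_table):
        cv = nested_cv(sample_table, *self._identity_fns())
        assert sorted(cv.sample_ids) == sorted(sample_table["sample_id"])
        assert len(cv.predictions) == len(sample_table)

    def test_fallback_to_stratified_folds_warns(self):
        frame = _table(n_animals=3, seed=1)
        with pytest.warns(UserWarning, match="falling back"):
            cv = nested_cv(frame, *self._identity_fns(), k=10)
        assert sorted(cv.sample_ids) == sorted(frame["sample_id"])
        counts = pd.Series(cv.fold_assignments).value_counts()
        assert counts.max() - counts.min() <= 1

    def test_real_model_through_cv(self, sample_table):
        def fit(df):
            return ols_fit(df["hb_ref"].to_numpy(), df["absorbance540"].to_numpy())

        def predict(model, df):
            return predict_hb(model, df["absorbance540"].to_numpy())

        cv = nested_cv(sample_table, fit, predict)
        r = np.corrcoef(cv.predictions, cv.references)[0, 1]
        assert r > 0.98


class TestPairedT:
    def test_published_worked_example(self):
        # engineer differences with exactly the printed mean and SD
        n, mean, sd = 21, 0.0115, 0.455
        z = np.arange(n, dtype=float)
        z = (z - z.mean()) / z.std(ddof=1)
        d = mean + sd * z
        ref = np.linspace(0, 10, n)
        result = paired_t(ref + d, ref)
        assert result.mean_diff == pytest.approx(0.0115, abs=1e-12)
        assert result.sd_diff == pytest.approx(0.455, abs=1e-12)
        assert round(result.t_cal, 3) == 0.116
        assert result.t_cal < result.t_crit

    def test_identical_vectors(self):
        x = np.array([1.0, 2.0, 3.0])
        assert paired_t(x, x).t_cal == 0.0

    def test_symmetric_differences(self):
        result = paired_t(np.array([1.0, -1.0]), np.array([0.0, 0.0]))
        assert result.mean_diff == 0.0
        assert result.t_cal == 0.0

    def test_zero_sd_nonzero_mean_is_infinite(self):
        result = paired_t(np.array([1.0, 2.0]), np.array([0.0, 1.0]))
        assert np.isinf(result.t_cal)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        a, b = rng.normal(size=n), rng.normal(size=n)
        result = paired_t(a, b)
        want = stats.ttest_rel(a, b).statistic
        assert result.t_cal == pytest.approx(want, abs=1e-10)

    def test_rejects_mismatched_lengths(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0], [1.0])


class TestEqualityLine:
    def test_exact_agreement(self):
        x = np.array([0.0, 2.0, 5.0, 9.0])
        fit = equality_line(x, x)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r == pytest.approx(1.0)

    def test_affine_distortion_recovered(self):
        ref = np.array([0.0, 1.0, 4.0, 8.0])
        fit = equality_line(0.9 * ref + 0.5, ref)
        assert fit.slope == pytest.approx(0.9, abs=1e-12)
        assert fit.intercept == pytest.approx(0.5, abs=1e-12)

    def test_simulated_validation_slope_unbiased(self):
        # 200 simulated UV-VIS calibrate/validate cycles: with the reference
        # error-free, the expected equality-line slope is 1 (the printed
        # 0.9688 is a single-draw realisation whose CI includes 1)
        slopes = []
        for seed in range(1, 201):
            samples = generate_samples(generate_design(10, seed=seed))
            plan = split_calibration(samples, seed=seed)
            cal = samples[samples["sample_id"].isin(plan.calibration_ids)]
            val = samples[samples["sample_id"].isin(plan.validation_ids)]
            fit = ols_fit(cal["hb_ref"].to_numpy(), cal["absorbance540"].to_numpy())
            pred = predict_hb(fit, val["absorbance540"].to_numpy())
            slopes.append(equality_line(pred, val["hb_ref"].to_numpy()).slope)
        assert np.mean(slopes) == pytest.approx(1.0, abs=0.01)
        # and the printed single-study value is within the simulated spread
        assert np.quantile(slopes, 0.02) < 0.9688 < np.quantile(slopes, 0.98)


def _fit_with_pair(seed, n=15, slope=1.0, intercept=0.0, noise=0.5):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 10, n)
    y = intercept + slope * x + rng.normal(0, noise, n)
    return ols_fit(x, y), x, y


def ejcr_oracle_sse(x, y, fit, beta0=0.0, beta1=1.0, alpha=0.05):
    """Independent route: the quadratic form equals the extra sum of squares
    of the restricted line, so test SSE(beta) - SSE(b) against 2 s^2 F."""
    sse_full = np.sum((y - fit.intercept - fit.slope * x) ** 2)
    sse_restricted = np.sum((y - beta0 - beta1 * x) ** 2)
    statistic = sse_restricted - sse_full
    critical = 2 * fit.residual_sd**2 * stats.f.ppf(1 - alpha, 2, fit.n - 2)
    return statistic <= critical, statistic


class TestEjcr:
    def test_exact_identity_data(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        result = ejcr_test(ols_fit(x, x))
        assert result.inside
        assert result.statistic == pytest.approx(0.0, abs=1e-18)

    @pytest.mark.parametrize("seed", range(100))
    def test_agrees_with_sse_oracle(self, seed):
        rng = np.random.default_rng(seed)
        slope = rng.uniform(0.5, 1.5)
        intercept = rng.uniform(-1, 1)
        fit, x, y = _fit_with_pair(seed + 1000, n=int(rng.integers(5, 30)),
                                   slope=slope, intercept=intercept,
                                   noise=rng.uniform(0.1, 2.0))
        result = ejcr_test(fit)
        inside_oracle, stat_oracle = ejcr_oracle_sse(x, y, fit)
        assert result.inside == inside_oracle
        assert result.statistic == pytest.approx(stat_oracle, rel=1e-8, abs=1e-10)

    def test_lattice_evaluation_agrees(self):
        # decision for every point of a 400x400 (beta0, beta1) lattice
        fit, x, y = _fit_with_pair(7, n=20, noise=0.8)
        b0 = np.linspace(fit.intercept - 2, fit.intercept + 2, 400)
        b1 = np.linspace(fit.slope - 1, fit.slope + 1, 400)
        B0, B1 = np.meshgrid(b0, b1)
        crit = 2 * fit.residual_sd**2 * stats.f.ppf(0.95, 2, fit.n - 2)
        sse_full = np.sum((y - fit.intercept - fit.slope * x) ** 2)
        resid = y[None, None, :] - B0[..., None] - B1[..., None] * x[None, None, :]
        sse = np.sum(resid**2, axis=-1)
        inside_grid = (sse - sse_full) <= crit
        for i in range(0, 400, 37):
            for j in range(0, 400, 41):
                result = ejcr_test(fit, beta0=B0[i, j], beta1=B1[i, j])
                assert result.inside == inside_grid[i, j]

    def test_nominal_coverage_of_identity(self):
        inside = 0
        n_sim = 500
        for seed in range(n_sim):
            fit, _, _ = _fit_with_pair(seed, n=20, slope=1.0, intercept=0.0,
                                       noise=0.7)
            if ejcr_test(fit).inside:
                inside += 1
        assert inside / n_sim >= 0.93

    def test_needs_at_least_three_points(self):
        with pytest.raises(ValueError):
            LinearFit(0, 1, 0, 0, 0, 0, 1.0, 2, 0.0, np.eye(2))


class TestCompareMethods:
    def test_perfect_method_report(self):
        x = np.linspace(0, 10, 12)
        report = compare_methods("uv", x, x)
        assert report.t_cal == 0.0
        assert report.ejcr_inside
        assert report.equality_fit.slope == pytest.approx(1.0)

    def test_biased_method_detected(self):
        rng = np.random.default_rng(0)
        ref = np.linspace(0, 10, 50)
        pred = 1.3 * ref + 0.8 + rng.normal(0, 0.05, 50)
        report = compare_methods("red", pred, ref)
        assert not report.ejcr_inside
        assert abs(report.t_cal) > report.t_crit
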