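"""Direct counts, robust through-origin regression and published estimators."""

import numpy as np
import pytest
import statsmodels.api as sm

from prenatal_enamel import (
    EstimationError,
    FitError,
    NegativeEstimateWarning,
    PrismSegment,
    ToothRecord,
    compare_polynomial_fit,
    direct_pcft,
    estimate_mahoney,
    estimate_segmentwise_with_intercept,
    fit_edj_regression,
    fit_origin_robust,
    load_published_estimators,
    predict_pcft,
    reliability_stats,
)
from prenatal_enamel.cft_estimators import (
    _MAD_NORMAL,
    OriginRegressionModel,
    polyfit_through_origin,
    tukey_rho,
)
from prenatal_enamel.synthetic_enamel import (
    MeasurementConfig,
    TruthConfig,
    simulate_cohort,
)


def _record(lengths_counts, tooth_id="A"):
    segs = [
        PrismSegment(tooth_id, i + 1, length, list(counts))
        for i, (length, counts) in enumerate(lengths_counts)
    ]
    return ToothRecord(id=tooth_id, arch="upper", nl_present=False, segments=segs)


class TestDirectPcft:
    def test_single_segment(self):
        assert direct_pcft(_record([(200.0, (50.0,))])) == 50.0

    def test_mean_then_sum(self):
        rec = _record([(150.0, (40.0, 41.0)), (180.0, (60.0, 60.0)), (120.0, (30.0, 31.0))])
        assert direct_pcft(rec) == 131.0

    def test_no_segments_raises(self):
        with pytest.raises(EstimationError):
            direct_pcft(ToothRecord(id="X", arch="upper", nl_present=False))

    def test_noiseless_simulation_recovers_true_duration(self):
        records, truths = simulate_cohort(
            10, 0.5, mcfg=MeasurementConfig(observer_noise_sd_days=0.0), seed=5
        )
        for rec, truth in zip(records, truths):
            assert direct_pcft(rec) == pytest.approx(truth.true_pcft_days, abs=1e-9)


class TestReliabilityStats:
    def test_identical_lists(self):
        r, t, df, p = reliability_stats([10, 20, 30, 40], [10, 20, 30, 40])
        assert r == 1.0 and t == 0.0 and df == 3

    def test_constant_shift_moves_t_not_r(self):
        rng = np.random.default_rng(1)
        a = rng.normal(30, 5, 40)
        b = a + rng.normal(0, 1, 40)
        r1, t1, *_ = reliability_stats(a, b)
        r2, t2, *_ = reliability_stats(a, b + 5.0)
        assert r1 == pytest.approx(r2, rel=1e-12)
        assert abs(t2) > abs(t1)

    def test_matches_variance_component_oracle(self):
        rng = np.random.default_rng(2)
        truth = rng.uniform(20, 60, 200)
        a = truth + rng.normal(0, 1.5, 200)
        b = truth + rng.normal(0, 1.5, 200)
        r, *_ = reliability_stats(a, b)
        # independent brute-force variance components
        d = [ai - bi for ai, bi in zip(a, b)]
        m = [(ai + bi) / 2 for ai, bi in zip(a, b)]
        var = lambda v: sum((x - sum(v) / len(v)) ** 2 for x in v) / (len(v) - 1)
        s_w2 = var(d) / 2
        expected = 1 - s_w2 / (var(m) + s_w2)
        assert r == pytest.approx(expected, rel=1e-12)
        # ~ true reliability sigma_b^2/(sigma_b^2 + sigma_w^2)
        assert r == pytest.approx(
            np.var(truth) / (np.var(truth) + 1.5**2), abs=0.05
        )


class TestOriginRobustFit:
    def test_collinear_data_gives_exact_slope(self, collinear_points):
        m = fit_origin_robust(collinear_points)
        assert m.slope == pytest.approx(0.25, abs=1e-12)
        assert m.adj_r2 == pytest.approx(1.0, abs=1e-12)
        assert m.ci_low <= m.slope <= m.ci_high
        assert m.implied_dsr_um_day == pytest.approx(4.0, abs=1e-9)

    def test_gross_outlier_barely_moves_slope(self, collinear_points):
        pts = np.vstack([collinear_points, [100.0, 500.0]])
        m = fit_origin_robust(pts)
        assert m.slope == pytest.approx(0.25, rel=0.01)

    def test_equals_ols_on_clean_collinear_data(self, collinear_points):
        x, y = collinear_points[:, 0], collinear_points[:, 1]
        ols = float(np.dot(x, y) / np.dot(x, x))
        m = fit_origin_robust(collinear_points)
        assert m.slope == pytest.approx(ols, rel=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_grid_search_loss_oracle(self, seed):
        """The IRLS slope minimizes the fixed-scale bisquare loss, verified
        by exhaustive search over a 1e-5 slope grid."""
        rng = np.random.default_rng(seed)
        x = rng.uniform(20, 200, 40)
        y = 0.216 * x + rng.normal(0, 2.0, 40)
        y[:3] += rng.uniform(30, 80, 3)  # gross outliers
        m = fit_origin_robust(np.column_stack([x, y]))
        b0 = np.median(y / x)
        r0 = y - b0 * x
        s = np.median(np.abs(r0 - np.median(r0))) / _MAD_NORMAL
        grid = np.arange(0.15, 0.30, 1e-5)
        losses = [tukey_rho((y - b * x) / s).sum() for b in grid]
        b_grid = grid[int(np.argmin(losses))]
        assert abs(m.slope - b_grid) <= 1e-5

    def test_simulation_recovery_within_two_se(self):
        rng = np.random.default_rng(123)
        x = rng.uniform(20, 200, 1000)
        y = 0.216 * x + rng.normal(0, 1.5, 1000)
        m = fit_origin_robust(np.column_stack([x, y]))
        se = (m.ci_high - m.ci_low) / (2 * 1.96)
        assert abs(m.slope - 0.216) < 2 * se

    def test_agrees_with_statsmodels_rlm(self):
        """Independent implementation check: statsmodels RLM with the same
        bisquare psi lands on essentially the same slope."""
        rng = np.random.default_rng(9)
        x = rng.uniform(20, 200, 300)
        y = 0.216 * x + rng.normal(0, 1.5, 300)
        y[:5] += 40.0
        ours = fit_origin_robust(np.column_stack([x, y]))
        rlm = sm.RLM(y, x[:, None], M=sm.robust.norms.TukeyBiweight()).fit()
        assert ours.slope == pytest.approx(float(rlm.params[0]), rel=5e-3)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(FitError):
            fit_origin_robust([(100.0, 25.0), (120.0, 30.0)])
        with pytest.raises(FitError):
            fit_origin_robust([(0.0, 1.0), (0.0, 2.0), (0.0, 3.0)])


class TestPrediction:
    def test_hand_arithmetic_with_printed_slope(self):
        model = OriginRegressionModel(0.216, 0.2, 0.24, 76, 1.0, "tukey", 0.98)
        rec = _record([(200.0, (40.0,)), (300.0, (60.0,))])  # total 500 um
        est = predict_pcft(model, rec)
        assert est.days == pytest.approx(108.0, abs=1e-12)

    def test_additive_over_partitions(self):
        model = OriginRegressionModel(0.216, 0.2, 0.24, 76, 1.0, "tukey", 0.98)
        fine = _record([(100.0, (20.0,))] * 6)
        coarse = _record([(300.0, (60.0,))] * 2)
        assert predict_pcft(model, fine).days == predict_pcft(model, coarse).days
        per_segment = sum(model.slope * s.length_um for s in fine.segments)
        assert predict_pcft(model, fine).days == pytest.approx(per_segment, abs=1e-12)


class TestSegmentwiseInterceptBias:
    def test_hand_arithmetic(self):
        ests = load_published_estimators()
        bd = ests["birch_dean_incisor"]
        assert bd.intercept == 6.73
        from prenatal_enamel import LinearEstimator

        est = LinearEstimator("bd", 6.73, 0.2, "um")
        rec = _record([(100.0, (20.0,))] * 3)
        out = estimate_segmentwise_with_intercept(est, rec)
        assert out.days == pytest.approx(3 * 6.73 + 60.0, abs=1e-12)  # 80.19

    def test_zero_intercept_reduces_to_origin_prediction(self):
        from prenatal_enamel import LinearEstimator

        est = LinearEstimator("zero", 0.0, 0.216, "um")
        rec = _record([(250.0, (50.0,)), (250.0, (55.0,))])
        out = estimate_segmentwise_with_intercept(est, rec)
        assert out.days == pytest.approx(0.216 * 500.0, abs=1e-12)

    def test_bias_grows_with_segment_count(self):
        from prenatal_enamel import LinearEstimator

        est = LinearEstimator("bd", 6.73, 0.2, "um")
        six = _record([(100.0, (20.0,))] * 6)
        three = _record([(200.0, (40.0,))] * 3)
        d6 = estimate_segmentwise_with_intercept(est, six).days
        d3 = estimate_segmentwise_with_intercept(est, three).days
        assert d6 - d3 == pytest.approx(3 * 6.73, abs=1e-12)


class TestMahoneyEstimators:
    def test_worn_hand_arithmetic(self):
        rec = ToothRecord(id="X", arch="upper", nl_present=False, edj_total_um=10000.0)
        est = estimate_mahoney(rec, "worn")
        assert est.days == pytest.approx(-236.268 + 43.751 * 10.0, abs=1e-9)  # 201.242

    def test_unworn_intercept_at_zero_area(self):
        rec = ToothRecord(id="X", arch="upper", nl_present=False, crown_area_mm2=0.0)
        assert estimate_mahoney(rec, "unworn").days == pytest.approx(122.980, abs=1e-9)

    def test_negative_estimate_warns_not_clips(self):
        rec = ToothRecord(id="X", arch="upper", nl_present=False, edj_total_um=5400.0)
        with pytest.warns(NegativeEstimateWarning):
            est = estimate_mahoney(rec, "worn")
        assert est.days == pytest.approx(-236.268 + 43.751 * 5.4, abs=1e-9)
        assert est.days < 0

    def test_missing_field_names_it(self):
        rec = ToothRecord(id="X", arch="upper", nl_present=False)
        with pytest.raises(EstimationError, match="edj_total_um"):
            estimate_mahoney(rec, "worn")
        with pytest.raises(EstimationError, match="crown_area_mm2"):
            estimate_mahoney(rec, "unworn")


class TestEdjRegression:
    def test_noiseless_slope(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(500, 6000, 50)
        m = fit_edj_regression(np.column_stack([x, 0.02 * x]))
        assert m.slope == pytest.approx(0.02, abs=1e-12)

    def test_predicted_pcft_hand_arithmetic(self):
        assert 0.0214 * 5000 == pytest.approx(107.0, abs=1e-9)

    def test_edj_predictor_is_coarser_than_prism_predictor(self):
        """The EDJ-length regression carries the full nonlinearity of
        extension-rate deceleration, so its per-tooth residuals exceed the
        prism regression's on the same cohort."""
        records, _ = simulate_cohort(
            40, 0.5, TruthConfig(), MeasurementConfig(observer_noise_sd_days=1.0), seed=21
        )
        prism_pts = [(s.length_um, s.count_days) for r in records for s in r.segments]
        edj_pts = [(iv.length_um, iv.days) for r in records for iv in r.edj_intervals]
        pm = fit_origin_robust(prism_pts)
        em = fit_edj_regression(edj_pts)
        prism_mae = np.mean(
            [
                abs(direct_pcft(r) - pm.slope * r.total_prism_length_um)
                for r in records
            ]
        )
        edj_mae = np.mean(
            [
                abs(
                    direct_pcft(r)
                    - em.slope * sum(iv.length_um for iv in r.edj_intervals)
                )
                for r in records
            ]
        )
        assert edj_mae > prism_mae


class TestPolynomialComparison:
    def test_linear_data_gains_nothing_from_cubic(self, collinear_points):
        adj2, rss2 = compare_polynomial_fit(collinear_points, 2)
        adj3, rss3 = compare_polynomial_fit(collinear_points, 3)
        assert rss2 < 1e-16 and rss3 < 1e-16
        assert adj3 == pytest.approx(1.0, abs=1e-12)

    def test_cubic_data_beats_linear(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(1, 10, 50)
        y = 0.5 * x + 0.02 * x**3
        _, rss_linear = compare_polynomial_fit(np.column_stack([x, y]), 2)
        _, rss_cubic = compare_polynomial_fit(np.column_stack([x, y]), 3)
        assert rss_cubic < rss_linear

    def test_coefficients_match_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(1, 10, 30)
        y = rng.normal(0, 1, 30) + x
        pts = np.column_stack([x, y])
        coef = polyfit_through_origin(pts, 3)
        X = np.column_stack([x, x**2, x**3])
        expected = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(coef, expected, atol=1e-8)

    def test_too_few_points_raise(self):
        with pytest.raises(FitError):
            compare_polynomial_fit([(1.0, 1.0), (2.0, 2.0), (3.0, 3.0)], 2)
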