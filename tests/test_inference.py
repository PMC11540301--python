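import numpy as np
import pytest
from scipy import stats

from axonav.inference import (
    RegressionFit,
    ancova_slopes,
    anova_tukey,
    classify_roi_fits,
    detect_significant_runs,
    fit_linear,
    resample_comparison,
    shuffle_baseline,
)
from axonav.trace_qc import normalize_mean


def matrix_ols_oracle(x, y):
    """Independent design-matrix OLS + F test via explicit linear algebra."""
    X = np.column_stack([np.ones_like(x), x])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sse = resid @ resid
    sst = np.sum((y - y.mean()) ** 2)
    n = len(x)
    f = ((sst - sse) / 1.0) / (sse / (n - 2))
    p = stats.f.sf(f, 1, n - 2)
    return beta[1], beta[0], f, p


def ancova_oracle(groups):
    """Nested-model interaction F via statsmodels."""
    import pandas as pd
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    rows = []
    for label, x, y in groups:
        for xi, yi in zip(x, y):
            rows.append({"g": str(label), "x": xi, "y": yi})
    df = pd.DataFrame(rows)
    full = smf.ols("y ~ C(g) + x + C(g):x", data=df).fit()
    reduced = smf.ols("y ~ C(g) + x", data=df).fit()
    tab = anova_lm(reduced, full)
    return float(tab["F"].iloc[1]), float(tab["Pr(>F)"].iloc[1])


class TestFitLinear:
    def test_perfect_line(self):
        fit = fit_linear([0, 1, 2], [0, 1, 2])
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0)
        assert fit.p_value == 0.0

    def test_flat_line(self):
        fit = fit_linear([0, 1, 2], [1, 1, 1])
        assert fit.slope == 0.0
        assert fit.F_stat == 0.0
        assert fit.p_value == 1.0

    def test_matches_matrix_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(0, 2, 50)
            y = 1.5 * x + rng.normal(0, 1, 50)
            fit = fit_linear(x, y)
            s, i, f, p = matrix_ols_oracle(x, y)
            assert fit.slope == pytest.approx(s, rel=1e-10)
            assert fit.intercept == pytest.approx(i, rel=1e-10)
            assert fit.F_stat == pytest.approx(f, rel=1e-10)
            assert fit.p_value == pytest.approx(p, rel=1e-8)

    def test_nan_pairs_dropped(self):
        x = np.array([0, 1, 2, 3, np.nan])
        y = np.array([0, 1, np.nan, 3, 4])
        fit = fit_linear(x, y)
        assert fit.n_points == 3

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="3"):
            fit_linear([0, 1], [0, 1])

    def test_zero_x_variance(self):
        with pytest.raises(ValueError, match="variance"):
            fit_linear([1, 1, 1], [0, 1, 2])


class TestClassify:
    def test_three_way(self):
        fits = [RegressionFit(1, 0, 10, 0.001, 10, 8),
                RegressionFit(-1, 0, 10, 0.001, 10, 8),
                RegressionFit(1, 0, 1, 0.5, 10, 8)]
        counts = classify_roi_fits(fits)
        assert (counts["positive"], counts["negative"], counts["ns"]) == (1, 1, 1)
        assert counts["labels"] == ["positive", "negative", "ns"]

    def test_empty(self):
        counts = classify_roi_fits([])
        assert (counts["positive"], counts["negative"], counts["ns"]) == (0, 0, 0)


class TestResampleComparison:
    def _roi_points(self, rng, n_rois, slope=1.0, noise=1.0):
        out = []
        x = np.linspace(0, 10, 20)
        for _ in range(n_rois):
            out.append((x, slope * x + rng.normal(0, noise, x.shape[0])))
        return out

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        pts = self._roi_points(rng, 20)
        ref = RegressionFit(1.0, 0.0, 10, 0.01, 20, 18)
        a = resample_comparison(pts, 5, ref, n_reps=50, seed=9)
        b = resample_comparison(pts, 5, ref, n_reps=50, seed=9)
        np.testing.assert_array_equal(a.slopes, b.slopes)
        assert a.contained == b.contained

    def test_subsample_too_large(self):
        rng = np.random.default_rng(2)
        pts = self._roi_points(rng, 5)
        with pytest.raises(ValueError, match="subsample"):
            resample_comparison(pts, 5, RegressionFit(1, 0, 1, 0.5, 10, 8))

    def test_containment_calibration_small(self):
        # reference fit uses 2x the subsample ROI count so the check
        # isolates the cloud's coverage (see acceptance suite for the
        # full-scale calibration)
        rng = np.random.default_rng(3)
        same, shifted = 0, 0
        reps = 25
        for i in range(reps):
            pts = self._roi_points(rng, 60)
            ref_pts = self._roi_points(rng, 18)
            x = np.concatenate([p[0] for p in ref_pts])
            y = np.concatenate([p[1] for p in ref_pts])
            ref = fit_linear(x, y)
            cloud = resample_comparison(pts, 9, ref, n_reps=200, seed=100 + i)
            same += cloud.contained
            se = np.std(cloud.slopes)
            ref_far = RegressionFit(ref.slope + 5 * se, ref.intercept,
                                    ref.F_stat, ref.p_value, ref.n_points,
                                    ref.dof_resid)
            shifted += resample_comparison(pts, 9, ref_far, n_reps=200,
                                           seed=500 + i).contained
        assert same >= 0.8 * reps
        assert shifted <= 0.2 * reps


class TestAncova:
    def test_matches_statsmodels_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            groups = []
            for g in range(3):
                x = rng.normal(0, 1, 40)
                y = (1.0 + 0.5 * g) * x + rng.normal(0, 1, 40)
                groups.append((f"g{g}", x, y))
            comp = ancova_slopes(groups)
            f_o, p_o = ancova_oracle(groups)
            assert comp.omnibus_F == pytest.approx(f_o, rel=1e-8)
            assert comp.omnibus_p == pytest.approx(p_o, rel=1e-6, abs=1e-12)

    def test_equal_slopes_type_one(self):
        rng = np.random.default_rng(5)
        rejections = 0
        for _ in range(40):
            groups = []
            for g in range(2):
                x = rng.normal(0, 1, 200)
                groups.append((f"g{g}", x, 2.0 * x + rng.normal(0, 1, 200)))
            if ancova_slopes(groups).omnibus_p < 0.05:
                rejections += 1
        assert rejections <= 8  # ~5% expected

    def test_different_slopes_power(self):
        rng = np.random.default_rng(6)
        detected = 0
        for _ in range(20):
            x0 = rng.normal(0, 1, 200)
            x1 = rng.normal(0, 1, 200)
            groups = [("a", x0, 0.0 * x0 + rng.normal(0, 1, 200)),
                      ("b", x1, 1.0 * x1 + rng.normal(0, 1, 200))]
            if ancova_slopes(groups).omnibus_p < 0.05:
                detected += 1
        assert detected == 20

    def test_pairwise_covers_all_pairs(self):
        rng = np.random.default_rng(7)
        groups = [(f"g{g}", rng.normal(0, 1, 30), rng.normal(0, 1, 30))
                  for g in range(4)]
        comp = ancova_slopes(groups)
        assert len(comp.pairwise) == 6
        assert all(0 <= p <= 1 for *_, p in comp.pairwise)

    def test_degenerate_group_raises(self):
        with pytest.raises(ValueError, match="zero covariate"):
            ancova_slopes([("a", [1, 1, 1], [0, 1, 2]),
                           ("b", [0, 1, 2], [0, 1, 2])])


class TestAnovaTukey:
    def test_textbook_decomposition(self):
        # 3 groups x 4 observations, hand-computed F
        groups = {"a": [1.0, 2.0, 3.0, 4.0],
                  "b": [2.0, 3.0, 4.0, 5.0],
                  "c": [6.0, 7.0, 8.0, 9.0]}
        # grand mean = 4.5; between SS = 4*((2.5-4.5)^2+(3.5-4.5)^2+(7.5-4.5)^2) = 56
        # within SS = 3 * (1.6667*3) = 15; F = (56/2)/(15/9) = 16.8
        comp = anova_tukey(groups)
        assert comp.omnibus_F == pytest.approx(16.8, rel=1e-10)
        f_o, p_o = stats.f_oneway(*groups.values())
        assert comp.omnibus_F == pytest.approx(f_o, rel=1e-10)
        assert comp.omnibus_p == pytest.approx(p_o, rel=1e-8)

    def test_matches_scipy_tukey(self):
        rng = np.random.default_rng(8)
        groups = {f"g{i}": rng.normal(i * 0.5, 1, 12) for i in range(3)}
        comp = anova_tukey(groups)
        res = stats.tukey_hsd(*groups.values())
        labels = list(groups)
        for a, b, est, p in comp.pairwise:
            i, j = labels.index(a), labels.index(b)
            assert p == pytest.approx(res.pvalue[i, j], abs=1e-8)

    def test_identical_groups(self):
        comp = anova_tukey({"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0]})
        assert comp.omnibus_F == 0.0
        assert comp.omnibus_p == 1.0

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(9)
        groups = {"ref": rng.normal(0, 1, 10).tolist(),
                  "shifted": (rng.normal(0, 1, 10) + 10).tolist(),
                  "same": rng.normal(0, 1, 10).tolist()}
        comp = anova_tukey(groups, reference="ref")
        pair = {frozenset((a, b)): p for a, b, _, p in comp.pairwise}
        assert pair[frozenset(("ref", "shifted"))] < 0.01
        assert pair[frozenset(("ref", "same"))] > 0.05
        # reference restricts the pairwise set
        assert len(comp.pairwise) == 2

    def test_small_group_dropped(self):
        comp = anova_tukey({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0], "c": [9.0]})
        assert set(comp.group_stats) == {"a", "b"}


class TestShuffleBaseline:
    def test_mean_near_one_for_normalized_noise(self):
        rng = np.random.default_rng(10)
        traces = np.vstack([
            normalize_mean(1.0 + 0.1 * rng.normal(size=3000)) for _ in range(8)])
        base = shuffle_baseline(traces, 8, 30.0, n_shuffles=100,
                                n_subsample_reps=100, seed=0)
        assert np.mean(base.mean) == pytest.approx(1.0, abs=0.01)
        assert np.all(base.ci_lo <= base.mean + 1e-12)
        assert np.all(base.mean <= base.ci_hi + 1e-12)

    def test_deterministic(self):
        rng = np.random.default_rng(11)
        traces = rng.normal(1, 0.1, (5, 2000))
        a = shuffle_baseline(traces, 5, 30.0, 50, 50, seed=3)
        b = shuffle_baseline(traces, 5, 30.0, 50, 50, seed=3)
        np.testing.assert_array_equal(a.ci_hi, b.ci_hi)

    def test_subsample_too_large_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            shuffle_baseline(np.ones((3, 2000)), 4, 30.0, 50, 50)

    def test_transform_applied(self):
        rng = np.random.default_rng(12)
        traces = rng.normal(1, 0.1, (5, 2000))
        base = shuffle_baseline(traces, 5, 30.0, 50, 50, seed=1,
                                transform=lambda tr: tr[:100])
        assert base.mean.shape[0] == 100


class TestSignificantRuns:
    def _base(self, n):
        from axonav.inference import ShuffleBaseline
        return ShuffleBaseline(np.zeros(n), np.full(n, -1.0), np.full(n, 1.0),
                               100, 100, 5)

    def test_two_point_run(self):
        series = np.zeros(200)
        series[100:102] = 2.0
        runs = detect_significant_runs(series, self._base(200), min_run=2)
        assert runs.segments == [(100, 102)]
        assert runs.durations_s(30.0) == [pytest.approx(2 / 30)]

    def test_isolated_point_rejected(self):
        series = np.zeros(200)
        series[100] = 2.0
        assert detect_significant_runs(series, self._base(200), 2).segments == []

    def test_series_at_mean_no_runs(self):
        assert detect_significant_runs(np.zeros(200), self._base(200), 2).segments == []

    def test_run_to_end(self):
        series = np.zeros(50)
        series[45:] = 2.0
        runs = detect_significant_runs(series, self._base(50), 2)
        assert runs.segments == [(45, 50)]
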