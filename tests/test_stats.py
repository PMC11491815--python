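"""Group-comparison layer: transforms, tests, correlation and smoother."""

import numpy as np
import pytest

from accelflight.metrics import BirdSummary
from accelflight.stats import (
    arcsine_sqrt,
    brood_size_anova,
    compare_pairs,
    compare_sexes,
    loess,
    morphology_effort_correlation,
    time_of_day_trend,
    welch_ttest,
)


def bird(i, sex="female", r=0.13, t=2.3, v=0.76, brood=6, hour=10.0):
    return BirdSummary(
        bird_id=f"b{i}", sex=sex, brood_size=brood, tag_hour=hour,
        recording_duration=7200.0, r_flight=r, t_flight=t, n_flights=400,
        flights_per_hour=200.0, vedba_mean_bird=v,
    )


class TestArcsineSqrt:
    def test_endpoints(self):
        assert arcsine_sqrt(0.0) == 0.0
        assert arcsine_sqrt(1.0) == pytest.approx(np.pi / 2)

    def test_quarter(self):
        assert arcsine_sqrt(0.25) == pytest.approx(np.pi / 6)

    def test_monotone(self):
        p = np.linspace(0, 1, 50)
        assert np.all(np.diff(arcsine_sqrt(p)) > 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            arcsine_sqrt(1.2)


class TestCompareSexes:
    def test_identical_groups_statistic_zero(self):
        birds = [bird(i, "female") for i in range(5)] + [bird(i + 5, "male") for i in range(5)]
        res = compare_sexes(birds, "r_flight")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_fractional_welch_df(self):
        rng = np.random.default_rng(0)
        birds = [bird(i, "female", r=float(x)) for i, x in enumerate(rng.uniform(0.05, 0.2, 13))]
        birds += [bird(i + 13, "male", r=float(x)) for i, x in enumerate(rng.uniform(0.05, 0.4, 13))]
        res = compare_sexes(birds, "r_flight", transform="arcsine")
        assert 2 < res.degrees_of_freedom < 24
        assert res.degrees_of_freedom != round(res.degrees_of_freedom)

    def test_welch_reduces_to_pooled_when_balanced(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = x + 0.5
        w = welch_ttest(x, y)
        p = welch_ttest(x, y, pooled=True)
        assert w.degrees_of_freedom == pytest.approx(p.degrees_of_freedom)
        assert w.statistic == pytest.approx(p.statistic)

    def test_type_I_error_near_alpha(self):
        # two groups from the same distribution; rejection rate ~5%
        rng = np.random.default_rng(1)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            x = rng.normal(0.13, 0.06, 13)
            y = rng.normal(0.13, 0.06, 13)
            if welch_ttest(x, y).p_value < 0.05:
                rejections += 1
        assert rejections / reps == pytest.approx(0.05, abs=0.02)

    def test_power_with_two_sd_shift(self):
        rng = np.random.default_rng(2)
        hits = 0
        reps = 1000
        for _ in range(reps):
            x = rng.normal(0.0, 1.0, 13)
            y = rng.normal(2.0, 1.0, 13)
            if welch_ttest(x, y).p_value < 0.05:
                hits += 1
        assert hits / reps >= 0.9

    def test_small_group_rejected(self):
        birds = [bird(0, "female"), bird(1, "male"), bird(2, "male")]
        with pytest.raises(ValueError):
            compare_sexes(birds, "r_flight")


class TestComparePairs:
    def test_identical_pairs_statistic_zero(self):
        pairs = [(bird(i, "female"), bird(i + 10, "male")) for i in range(6)]
        res = compare_pairs(pairs, "r_flight")
        assert res.statistic == pytest.approx(0.0)

    def test_six_pairs_df_five(self):
        rng = np.random.default_rng(3)
        pairs = [
            (bird(i, "female", r=float(rng.uniform(0.1, 0.2))),
             bird(i + 10, "male", r=float(rng.uniform(0.1, 0.2))))
            for i in range(6)
        ]
        res = compare_pairs(pairs, "r_flight", transform="arcsine")
        assert res.degrees_of_freedom == 5

    def test_constant_difference_flagged(self):
        pairs = [(bird(i, "female", r=0.15), bird(i + 10, "male", r=0.10)) for i in range(4)]
        res = compare_pairs(pairs, "r_flight")
        assert res.extra.get("degenerate") is True

    def test_same_sex_pair_rejected(self):
        pairs = [(bird(0, "female"), bird(1, "female")), (bird(2, "female"), bird(3, "male"))]
        with pytest.raises(ValueError):
            compare_pairs(pairs, "r_flight")


class TestBroodSizeAnova:
    def test_two_levels_F_equals_t_squared(self):
        rng = np.random.default_rng(4)
        birds = [bird(i, brood=5, r=float(rng.normal(0.13, 0.03))) for i in range(10)]
        birds += [bird(i + 10, brood=7, r=float(rng.normal(0.15, 0.03))) for i in range(10)]
        res = brood_size_anova(birds, "r_flight")
        x = np.array([b.r_flight for b in birds[:10]])
        y = np.array([b.r_flight for b in birds[10:]])
        t = welch_ttest(x, y, pooled=True)
        assert res.statistic == pytest.approx(t.statistic**2, rel=1e-10)

    def test_type_I_error_near_alpha(self):
        from scipy.stats import f_oneway
        rng = np.random.default_rng(5)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            groups = [rng.normal(0.13, 0.05, 7) for _ in range(4)]
            if f_oneway(*groups).pvalue < 0.05:
                rejections += 1
        assert rejections / reps == pytest.approx(0.05, abs=0.02)

    def test_single_level_rejected(self):
        birds = [bird(i, brood=6) for i in range(8)]
        with pytest.raises(ValueError):
            brood_size_anova(birds, "r_flight")


class TestMorphologyEffortCorrelation:
    def test_perfect_line_r2_one(self):
        x = np.linspace(0.09, 0.12, 10)
        res = morphology_effort_correlation(x, 2.0 + 3.0 * x)
        assert res.extra["r_squared"] == pytest.approx(1.0)

    def test_slope_coverage(self):
        # true slope inside +/-2 SE in >= 95% of replicates
        rng = np.random.default_rng(6)
        b_true = 8.0
        covered = 0
        reps = 500
        for _ in range(reps):
            x = rng.normal(0.105, 0.008, 19)
            y = 0.2 + b_true * x + rng.normal(0, 0.05, 19)
            res = morphology_effort_correlation(x, y)
            if abs(res.extra["slope"] - b_true) <= 2 * res.extra["slope_stderr"]:
                covered += 1
        assert covered / reps >= 0.93

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 500
        for _ in range(reps):
            x = rng.normal(0.105, 0.008, 19)
            y = rng.normal(0.76, 0.06, 19)
            if morphology_effort_correlation(x, y).p_value < 0.05:
                rejections += 1
        assert rejections / reps == pytest.approx(0.05, abs=0.03)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            morphology_effort_correlation(np.ones(10), np.arange(10.0))


class TestLoess:
    def test_constant_data_flat_curve(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(5, 20, 30)
        grid, fit, se = loess(x, np.full(30, 0.13))
        np.testing.assert_allclose(fit, 0.13, atol=1e-10)

    def test_u_shape_trough_recovered(self):
        # high morning, low early afternoon, rising again: trough ~14 h
        rng = np.random.default_rng(9)
        x = np.sort(rng.uniform(5, 20, 60))
        y = 0.10 + 0.008 * (x - 14.0) ** 2 / 10 + rng.normal(0, 0.005, 60)
        grid, fit, se = loess(x, y, span=0.5)
        assert 12.0 <= grid[np.argmin(fit)] <= 16.0

    def test_band_widens_where_sparse(self):
        rng = np.random.default_rng(10)
        x = np.concatenate([rng.uniform(5, 10, 50), rng.uniform(18, 20, 6)])
        y = 0.13 + rng.normal(0, 0.01, len(x))
        grid, fit, se = loess(x, y, grid=np.array([7.5, 19.0]))
        assert se[1] > se[0]

    def test_identical_x_rejected(self):
        with pytest.raises(ValueError):
            loess(np.full(10, 3.0), np.arange(10.0))

    def test_time_of_day_trend_needs_eight_birds(self):
        birds = [bird(i, hour=float(5 + i)) for i in range(6)]
        with pytest.raises(ValueError):
            time_of_day_trend(birds)

    def test_time_of_day_trend_on_birds(self):
        rng = np.random.default_rng(11)
        birds = [
            bird(i, hour=float(h), r=float(np.clip(0.15 - 0.004 * (h - 5), 0.01, 1)))
            for i, h in enumerate(rng.uniform(5, 20, 20))
        ]
        grid, fit, se = time_of_day_trend(birds)
        assert fit[0] > fit[-1]  # declining pattern recovered
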