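"""Generator contract tests: determinism, time budgets, duration law,
effort convergence, sensor signatures and CSV round-trips."""

import numpy as np
import pytest

import accelflight as af
from accelflight.signal import segment_mean_vedba, vedba
from accelflight.synthetic import (
    DurationLaw,
    GroundTruth,
    SyntheticConfig,
    default_behavior_models,
    generate_population,
    generate_trace,
    read_trace_csv,
    sample_flight_durations,
    write_trace_csv,
)


def short_config(**kw):
    kw.setdefault("sample_rate", 23.0)
    kw.setdefault("session_duration", 120.0)
    return SyntheticConfig(**kw)


class TestGenerateTrace:
    def test_sample_count(self):
        trace, truth = generate_trace(short_config(seed=1))
        assert trace.n_samples == round(23.0 * 120.0)
        assert len(truth.labels) == trace.n_samples

    def test_deterministic_bit_for_bit(self):
        cfg = short_config(seed=7)
        t1, g1 = generate_trace(cfg)
        t2, g2 = generate_trace(cfg)
        np.testing.assert_array_equal(t1.data, t2.data)
        assert list(g1.labels) == list(g2.labels)
        assert g1.flight_intervals == g2.flight_intervals

    def test_different_seeds_differ(self):
        t1, _ = generate_trace(short_config(seed=1))
        t2, _ = generate_trace(short_config(seed=2))
        assert not np.array_equal(t1.data, t2.data)

    def test_zero_flight_weight_excludes_flight(self):
        w = {m.name: 1.0 for m in default_behavior_models()}
        w["flying"] = 0.0
        _, truth = generate_trace(short_config(seed=3, behavior_transition_weights=w))
        assert truth.flight_intervals == ()
        assert "flying" not in set(truth.labels)

    def test_inactive_only_noiseless_is_pure_gravity(self):
        models = tuple(
            af.BehaviorModel(m.name, m.carrier_frequency, m.amplitude, 0.0,
                             m.gravity_axis_bias, m.duration_law, m.axis_mix)
            for m in default_behavior_models()
        )
        w = {m.name: 0.0 for m in models}
        w["inactive"] = 1.0
        cfg = short_config(seed=4, behavior_models=models,
                           behavior_transition_weights=w, apply_quantization=False)
        trace, truth = generate_trace(cfg)
        np.testing.assert_allclose(trace.data, np.tile([0.0, 0.0, 1.0], (trace.n_samples, 1)))
        assert set(truth.labels) == {"inactive"}

    def test_perching_magnitude_near_1g(self):
        trace, truth = generate_trace(short_config(seed=5))
        mags = np.linalg.norm(trace.data, axis=1)
        perch = mags[truth.labels == "inactive"]
        assert abs(perch.mean() - 1.0) < 0.05

    def test_bounding_pauses_drop_below_0p2g(self):
        # a bounding-only configuration must show ballistic samples
        cfg = short_config(seed=6, flight_style_mix=1.0, session_duration=300.0)
        trace, truth = generate_trace(cfg)
        mags = np.linalg.norm(trace.data, axis=1)
        fly = mags[truth.labels == "flying"]
        assert (fly < 0.2).mean() > 0.05

    def test_realized_flight_fraction_tracks_stationary_share(self, field_config, field_trace):
        # brute-force label count over a 2 h session vs the renewal share
        _, truth = field_trace
        counted = np.mean(truth.labels == "flying")
        assert counted == pytest.approx(field_config.expected_flight_fraction(), abs=0.03)

    def test_labels_agree_with_intervals(self):
        trace, truth = generate_trace(short_config(seed=8))
        rate = trace.sample_rate
        from_intervals = np.zeros(trace.n_samples, dtype=bool)
        for s, e in truth.flight_intervals:
            from_intervals[int(round(s * rate)): int(round(e * rate))] = True
        np.testing.assert_array_equal(from_intervals, truth.labels == "flying")

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(session_duration=-5.0)
        with pytest.raises(ValueError):
            SyntheticConfig(sample_rate=0.0)
        with pytest.raises(ValueError):
            SyntheticConfig(flight_style_mix=1.5)


class TestDurationLaw:
    def test_short_flight_fraction_at_least_0p98(self):
        cfg = SyntheticConfig(seed=0)
        durations = sample_flight_durations(cfg, 5000, seed=123)
        assert np.mean(durations < 10.0) >= 0.98

    def test_truncated_mean_matches_monte_carlo(self):
        law = DurationLaw(1.8, 0.7, 60.0)
        rng = np.random.default_rng(0)
        draws = law.sample(rng, 200_000)
        assert law.mean() == pytest.approx(draws.mean(), rel=0.01)

    def test_strictly_positive(self):
        law = DurationLaw(1.8, 0.7, 60.0)
        draws = law.sample(np.random.default_rng(1), 1000)
        assert np.all(draws > 0)


class TestEffortConvergence:
    def test_long_flights_converge_to_target(self):
        cfg_template = SyntheticConfig()
        longs = []
        for seed in range(8):
            cfg = SyntheticConfig(session_duration=7200.0, seed=seed)
            trace, truth = generate_trace(cfg)
            v = vedba(trace, 5)
            for s, e in truth.flight_intervals:
                if e - s >= 10.0:
                    longs.append(segment_mean_vedba(v, s, e - s))
        assert len(longs) >= 5
        assert np.mean(longs) == pytest.approx(cfg_template.target_long_flight_vedba, abs=0.05)

    def test_short_flights_have_larger_spread(self):
        cfg = SyntheticConfig(session_duration=7200.0, seed=0)
        trace, truth = generate_trace(cfg)
        v = vedba(trace, 5)
        shorts = [
            segment_mean_vedba(v, s, e - s)
            for s, e in truth.flight_intervals
            if 0.5 < e - s < 3.0
        ]
        longs = [
            segment_mean_vedba(v, s, e - s)
            for s, e in truth.flight_intervals
            if e - s >= 8.0
        ]
        assert np.std(shorts) > np.std(longs)


class TestGeneratePopulation:
    def test_degenerate_law_returns_means(self):
        law = {
            "male": {"mass_g": (13.0, 0.0), "single_wing_area_mm2": (4356.0, 0.0),
                     "semi_span_mm": (105.5, 0.0)},
            "female": {"mass_g": (13.2, 0.0), "single_wing_area_mm2": (4098.0, 0.0),
                       "semi_span_mm": (101.0, 0.0)},
        }
        df = generate_population(1, sex_ratio=1.0, morphology_law=law, seed=0)
        assert df.loc[0, "sex"] == "male"
        assert df.loc[0, "mass_g"] == 13.0
        assert df.loc[0, "semi_span_mm"] == 105.5

    def test_sample_mean_converges(self):
        df = generate_population(2000, sex_ratio=1.0, seed=1)
        # male semi-span law is 105.5 +/- 3.5 mm (span 211 +/- 7 doubled down)
        assert 2 * df["semi_span_mm"].mean() == pytest.approx(211.0, abs=1.0)

    def test_sex_ratio_one_is_all_male(self):
        df = generate_population(25, sex_ratio=1.0, seed=2)
        assert set(df["sex"]) == {"male"}

    def test_positive_measures_and_reproducible(self):
        a = generate_population(50, seed=3)
        b = generate_population(50, seed=3)
        assert (a[["mass_g", "single_wing_area_mm2", "semi_span_mm"]] > 0).all().all()
        assert a.equals(b)

    def test_invalid_law_rejected(self):
        bad = {"male": {"mass_g": (-1.0, 0.1), "single_wing_area_mm2": (1.0, 0.0),
                        "semi_span_mm": (1.0, 0.0)},
               "female": {"mass_g": (13.0, 0.1), "single_wing_area_mm2": (1.0, 0.0),
                          "semi_span_mm": (1.0, 0.0)}}
        with pytest.raises(ValueError):
            generate_population(5, morphology_law=bad, seed=0)


class TestTraceCsv:
    def test_round_trip_identity(self, tmp_path):
        trace, truth = generate_trace(short_config(seed=9))
        path = tmp_path / "trace.csv"
        write_trace_csv(trace, truth, path)
        back, truth_back = read_trace_csv(path)
        np.testing.assert_array_equal(back.data, trace.data)
        assert list(truth_back.labels) == list(truth.labels)

    def test_non_numeric_field_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_s,ax_g,ay_g,az_g\n0.0,oops,0.0,1.0\n")
        with pytest.raises(ValueError, match="line 2"):
            read_trace_csv(path)

    def test_empty_file_is_parse_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_trace_csv(path)

    def test_header_only_is_error(self, tmp_path):
        path = tmp_path / "hdr.csv"
        path.write_text("time_s,ax_g,ay_g,az_g\n")
        with pytest.raises(ValueError, match="no data"):
            read_trace_csv(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "cols.csv"
        path.write_text("time_s,ax_g,ay_g\n0.0,0.1,0.2\n")
        with pytest.raises(ValueError, match="header"):
            read_trace_csv(path)
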