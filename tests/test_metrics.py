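import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ivtrack.metrics import (
    arrest_coefficient,
    cohort_msd,
    cohort_summary,
    instantaneous_speeds,
    mean_speed,
    metrics_table,
    msd,
    speed_over_time,
    straightness_ratio,
    track_metrics,
)
from ivtrack.model import TrackError
from ivtrack.simulate import RegimeParams, SimConfig, simulate_cohort, simulate_timecourse

from conftest import make_set, make_track, random_track


def brute_force_msd(pos, max_lag):
    """Independent oracle: explicit loop over all (i, i+n) index pairs."""
    out = []
    for n in range(1, max_lag + 1):
        sq = []
        for i in range(len(pos) - n):
            d = pos[i + n] - pos[i]
            sq.append(float(sum(c * c for c in d)))
        out.append((float(np.mean(np.asarray(sq))), len(sq)))
    return out


class TestInstantaneousSpeeds:
    def test_constant_velocity(self):
        tr = make_track([(0, 0, 0), (1, 1, 0), (2, 2, 0)])
        assert np.allclose(instantaneous_speeds(tr).speeds, [1.0, 1.0])

    def test_stationary_all_zero(self, stationary_track):
        assert np.allclose(instantaneous_speeds(stationary_track).speeds, 0.0)

    def test_three_four_five_triangle(self):
        tr = make_track([(0, 0, 0), (1, 3, 4)])
        assert instantaneous_speeds(tr).speeds[0] == pytest.approx(5.0)

    def test_gap_spanning_step_excluded(self):
        tr = make_track([(0, 0, 0), (1, 1, 0), (3, 5, 0), (4, 6, 0)])
        ss = instantaneous_speeds(tr)
        assert np.allclose(ss.speeds, [1.0, 1.0]) and ss.n_total_steps == 3

    def test_too_short(self):
        with pytest.raises(TrackError) as exc:
            instantaneous_speeds(make_track([(0, 0, 0)]))
        assert exc.value.code == "too_short"


class TestArrestCoefficient:
    def test_all_fast_is_zero(self):
        tr = make_track([(t, 6.0 * t, 0) for t in range(5)])
        assert arrest_coefficient(tr) == 0.0

    def test_stationary_is_hundred(self, stationary_track):
        assert arrest_coefficient(stationary_track) == 100.0

    def test_seven_of_ten_slow_steps(self):
        # 7 steps at 1 µm/min then 3 at 6 µm/min: direct count oracle = 70%
        xs = np.concatenate([np.arange(8.0), 7.0 + 6.0 * np.arange(1, 4)])
        tr = make_track([(t, x, 0) for t, x in enumerate(xs)])
        assert arrest_coefficient(tr) == pytest.approx(70.0)

    def test_threshold_is_strict(self):
        tr = make_track([(t, 3.0 * t, 0) for t in range(5)])
        assert arrest_coefficient(tr, threshold=3.0) == 0.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_antitone_in_threshold(self, seed):
        tr = random_track(np.random.default_rng(seed), n_points=20)
        lo = arrest_coefficient(tr, threshold=1.0)
        hi = arrest_coefficient(tr, threshold=4.0)
        assert hi >= lo


class TestStraightness:
    def test_straight_track_is_one(self, straight_track):
        assert straightness_ratio(straight_track) == pytest.approx(1.0)

    def test_closed_loop_is_zero(self):
        tr = make_track([(0, 0, 0), (1, 1, 0), (2, 1, 1), (3, 0, 1), (4, 0, 0)])
        assert straightness_ratio(tr) == pytest.approx(0.0)

    def test_l_shaped_track(self):
        tr = make_track([(0, 0, 0), (1, 1, 0), (2, 1, 1)])
        assert straightness_ratio(tr) == pytest.approx(np.sqrt(2) / 2)

    def test_zero_path_is_nan_not_zero_or_one(self, stationary_track):
        assert np.isnan(straightness_ratio(stationary_track))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_bounded_in_unit_interval(self, seed):
        tr = random_track(np.random.default_rng(seed))
        s = straightness_ratio(tr)
        assert 0.0 <= s <= 1.0 + 1e-12


class TestMeanSpeed:
    def test_constant(self):
        tr = make_track([(t, 2.0 * t, 0) for t in range(5)])
        assert mean_speed(tr) == pytest.approx(2.0)

    def test_stationary(self, stationary_track):
        assert mean_speed(stationary_track) == 0.0

    def test_direct_mean_oracle(self):
        xs = np.cumsum([0.0, 1.0, 1.0, 6.0, 6.0])
        tr = make_track([(t, x, 0) for t, x in enumerate(xs)])
        assert mean_speed(tr) == pytest.approx(3.5)


class TestMSD:
    def test_stationary_identically_zero(self, stationary_track):
        assert np.allclose(msd(stationary_track).values, 0.0)

    def test_ballistic_closed_form(self):
        v, dt = 4.0, 1.0
        tr = make_track([(t, v * t * dt, 0) for t in range(21)])
        curve = msd(tr)
        assert np.allclose(curve.values, (v * curve.lags) ** 2, atol=1e-9)

    def test_five_point_toy_track_matches_brute_force(self):
        tr = make_track([(0, 0, 0), (1, 1.3, -0.2), (2, 0.7, 2.1), (3, -1.1, 1.9), (4, 0.4, 0.3)])
        curve = msd(tr, max_lag_fraction=1.0)
        expected = brute_force_msd(tr.positions, 4)
        assert [(v, n) for v, n in zip(curve.values, curve.n_intervals)] == expected

    def test_random_tracks_match_brute_force_exactly(self):
        rng = np.random.default_rng(77)
        for i in range(20):
            tr = random_track(rng, tid=f"m{i}")
            curve = msd(tr)
            expected = brute_force_msd(tr.positions, int(0.5 * (tr.n_points - 1)))
            assert list(curve.values) == [v for v, _ in expected]
            assert list(curve.n_intervals) == [n for _, n in expected]

    def test_n_intervals_and_lag_truncation(self):
        tr = make_track([(t, t, 0) for t in range(11)])
        curve = msd(tr, max_lag_fraction=0.5)
        assert len(curve.lags) == 5
        assert list(curve.n_intervals) == [11 - n for n in range(1, 6)]


class TestCohortMSD:
    def test_identical_tracks_equal_single_track(self):
        tr = make_track([(t, t * 1.5, 0) for t in range(12)])
        trs = [make_track([(t, t * 1.5, 0) for t in range(12)], tid=f"c{i}") for i in range(4)]
        cohort = cohort_msd(make_set(trs))
        single = msd(tr)
        assert np.allclose(cohort.values, single.values, atol=0)

    def test_two_track_mean(self):
        a = make_track([(t, 1.0 * t, 0) for t in range(11)], tid="a")
        b = make_track([(t, 3.0 * t, 0) for t in range(11)], tid="b")
        cohort = cohort_msd(make_set([a, b]))
        expected = (msd(a).values + msd(b).values) / 2
        assert np.allclose(cohort.values, expected, atol=1e-12)

    def test_diffusive_cohort_recovers_diffusion_coefficient(self):
        # 2D random walk, per-axis step variance sigma^2: MSD(n dt) = 4 D n dt
        rng = np.random.default_rng(2024)
        sigma, dt, n_tracks = 1.5, 1.0, 500
        tracks = [random_track(rng, n_points=31, tid=f"d{i}", step_sigma=sigma) for i in range(n_tracks)]
        curve = cohort_msd(make_set(tracks))
        slope = np.polyfit(curve.lags, curve.values, 1)[0]
        D = sigma**2 / dt  # 4D = 2 * 2 * sigma^2 / dt -> slope = 2 sigma^2
        assert slope == pytest.approx(2 * sigma**2, rel=0.10)
        assert curve.values[0] == pytest.approx(4 * D * dt / 2, rel=0.10)

    def test_min_tracks_truncation(self):
        long = make_track([(t, t, 0) for t in range(21)], tid="long")
        short = make_track([(t, t, 0) for t in range(11)], tid="short")
        curve = cohort_msd(make_set([long, short]), max_lag_fraction=0.5, min_tracks=2)
        assert curve.lags[-1] == 5.0  # truncated where the short track drops out

    def test_empty_cohort_rejected(self):
        with pytest.raises(TrackError) as exc:
            cohort_msd(make_set([]))
        assert exc.value.code == "empty"


class TestSpeedOverTime:
    def test_constant_speed_flat_curve(self):
        tr = make_track([(t, 2.0 * t, 0) for t in range(31)])
        sot = speed_over_time(make_set([tr]), event_time=0.0, bin_width=5.0)
        assert np.allclose(sot.mean, 2.0)
        assert np.all(sot.n > 0)

    def test_regime_switch_drops_post_event_speed(self):
        cfg = SimConfig(n_tracks=100, duration=40.0, seed=9)
        ts = simulate_timecourse("rag2_steady", "ccl25_blockade_post", switch_time=20.0, cfg=cfg)
        sot = speed_over_time(ts, event_time=20.0, bin_width=5.0)
        pre = sot.mean[sot.times < -2.5].mean()
        post = sot.mean[sot.times > 5.0].mean()
        assert post < pre * 0.6

    def test_empty_window_rejected(self):
        with pytest.raises(TrackError) as exc:
            speed_over_time(make_set([]))
        assert exc.value.code == "empty"


class TestMetricsTable:
    def test_single_track_single_record(self, straight_track):
        records = metrics_table(make_set([straight_track]))
        assert len(records) == 1 and records[0].error is None

    def test_short_tracks_flagged_not_dropped(self, straight_track):
        short = make_track([(0, 0, 0)], tid="zz")
        records = metrics_table(make_set([straight_track, short]))
        assert len(records) == 2
        flagged = [r for r in records if r.error]
        assert len(flagged) == 1 and flagged[0].error == "too_short"

    def test_invariants_hold_on_simulated_cohort(self):
        ts = simulate_cohort("ncr1_steady", SimConfig(n_tracks=50, seed=4))
        for r in metrics_table(ts):
            assert r.path_length >= r.net_displacement - 1e-9
            if r.path_length > 0:
                assert r.straightness == pytest.approx(r.net_displacement / r.path_length)

    def test_summary_reports_mean_sem_n(self, straight_track):
        other = make_track([(t, 2.0 * t, 0) for t in range(11)], tid="t2")
        summary = cohort_summary(metrics_table(make_set([straight_track, other])))
        entry = summary[""]
        assert entry["n_tracks"] == 2
        assert entry["mean_speed"]["mean"] == pytest.approx(1.5)
        vals = np.array([1.0, 2.0])
        assert entry["mean_speed"]["sem"] == pytest.approx(vals.std(ddof=1) / np.sqrt(2))


class TestRegimeMSDShapes:
    def test_confined_vs_ballistic_msd_ratio(self):
        """Pure-arrest cohorts plateau (as observed through localization
        noise); pure-run cohorts grow quadratically."""
        cfg = SimConfig(n_tracks=500, duration=30.0, seed=6)
        confined = RegimeParams(name="arrest_only", p_ap=0.0, p_pa=1.0, v_run=0.0,
                                sigma_arrest=0.08, sigma_turn=0.0, drift_amp=0.0)
        curve = cohort_msd(simulate_cohort(confined, cfg))
        i2 = np.where(curve.lags == 2.0)[0][0]
        i10 = np.where(curve.lags == 10.0)[0][0]
        assert curve.values[i10] / curve.values[i2] < 3.0
        cfg = SimConfig(n_tracks=500, duration=30.0, seed=6, localization_sigma=0.0)
        ballistic = RegimeParams(name="run_only", p_ap=1.0, p_pa=0.0, v_run=5.0,
                                 sigma_arrest=0.0, sigma_turn=0.0, sigma_z=0.0,
                                 drift_amp=0.0, confinement=(1e6, 1e6, 1e6))
        curve = cohort_msd(simulate_cohort(ballistic, cfg))
        i2 = np.where(curve.lags == 2.0)[0][0]
        i10 = np.where(curve.lags == 10.0)[0][0]
        assert curve.values[i10] / curve.values[i2] == pytest.approx(25.0, rel=0.05)
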