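"""Spherical geometry, GPS segmentation and parameter fitting."""

import numpy as np
import pytest

from vjump.estimation import (
    EARTH_RADIUS_KM, GPSTrack, LabelledTrack, SegmentationConfig,
    extract_phase_stats, fit_duration_distribution, fit_vonmises_kappa,
    haversine_km, mean_squared_speed, segment_track, split_track,
    window_diameter,
)
from vjump.simulator import persistence_index


class TestHaversine:
    def test_coincident_points(self):
        assert haversine_km((52.0, 4.0), (52.0, 4.0)) == 0.0

    def test_equatorial_antipodes(self):
        assert haversine_km((0.0, 0.0), (0.0, 180.0)) == \
            pytest.approx(np.pi * EARTH_RADIUS_KM, rel=1e-12)

    def test_one_degree_of_longitude(self):
        assert haversine_km((0.0, 0.0), (0.0, 1.0)) == \
            pytest.approx(EARTH_RADIUS_KM * np.pi / 180, rel=1e-10)

    def test_invalid_latitude(self):
        with pytest.raises(ValueError):
            haversine_km((95.0, 0.0), (0.0, 0.0))


class TestWindowDiameter:
    def test_single_point(self):
        assert window_diameter([(10.0, 20.0)]) == 0.0

    def test_two_points(self):
        d = window_diameter([(0.0, 0.0), (0.0, 2.0)])
        assert d == pytest.approx(haversine_km((0.0, 0.0), (0.0, 2.0)))

    def test_collinear_equatorial_points(self):
        pts = [(0.0, 0.0), (0.0, 1.0), (0.0, 2.0)]
        assert window_diameter(pts) == pytest.approx(
            haversine_km((0.0, 0.0), (0.0, 2.0)))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        pts = np.column_stack([rng.uniform(40, 60, 12), rng.uniform(-5, 10, 12)])
        brute = max(haversine_km(tuple(pts[i]), tuple(pts[j]))
                    for i in range(12) for j in range(i + 1, 12))
        assert window_diameter(pts) == pytest.approx(brute, rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            window_diameter([])


def synthetic_track(segments, fix_interval=0.1, lat0=53.0, lon0=5.0,
                    jitter_km=0.0, seed=0):
    """Track built from (state, duration_days, speed_km_per_day) pieces."""
    rng = np.random.default_rng(seed)
    t, lat, lon = [0.0], [lat0], [lon0]
    cur = 0.0
    for state, dur, speed in segments:
        n = int(round(dur / fix_interval))
        for _ in range(n):
            cur += fix_interval
            dlat = (speed * fix_interval / EARTH_RADIUS_KM) * 180 / np.pi \
                if state == "run" else 0.0
            t.append(cur)
            lat.append(lat[-1] + dlat)  # due-north migration
            lon.append(lon[-1])
    lat = np.asarray(lat)
    lon = np.asarray(lon)
    if jitter_km:
        lat = lat + np.degrees(rng.normal(0, jitter_km, lat.size) / EARTH_RADIUS_KM)
        lon = lon + np.degrees(rng.normal(0, jitter_km, lon.size)
                               / (EARTH_RADIUS_KM * np.cos(np.radians(lat))))
    return GPSTrack(np.asarray(t), lat, lon, track_id="s")


class TestSegmentation:
    def test_stationary_track_is_one_rest(self):
        tr = synthetic_track([("rest", 10.0, 0.0)])
        segs = segment_track(tr)
        assert len(segs) == 1
        assert segs[0].state == "rest"
        assert segs[0].start == 0.0 and segs[0].end == pytest.approx(10.0)

    def test_rest_run_rest(self):
        tr = synthetic_track([("rest", 10.0, 0.0), ("run", 3.0, 300.0),
                              ("rest", 10.0, 0.0)])
        segs = segment_track(tr)
        assert [s.state for s in segs] == ["rest", "run", "rest"]
        assert segs[1].start == pytest.approx(10.0, abs=1.0)
        assert segs[1].end == pytest.approx(13.0, abs=1.0)

    def test_short_pause_inside_migration_is_not_a_rest(self):
        tr = synthetic_track([("rest", 6.0, 0.0), ("run", 3.0, 300.0),
                              ("rest", 1.0, 0.0), ("run", 3.0, 300.0),
                              ("rest", 6.0, 0.0)])
        segs = segment_track(tr)
        assert [s.state for s in segs] == ["rest", "run", "rest"]
        assert any(s.merged for s in segs if s.state == "run")

    def test_short_track_rejected(self):
        tr = synthetic_track([("rest", 0.5, 0.0)])
        with pytest.raises(ValueError):
            segment_track(tr)

    def test_jitter_invariance(self):
        pieces = [("rest", 8.0, 0.0), ("run", 4.0, 250.0), ("rest", 8.0, 0.0)]
        clean = segment_track(synthetic_track(pieces))
        noisy = segment_track(synthetic_track(pieces, jitter_km=1.0, seed=3))
        assert [s.state for s in clean] == [s.state for s in noisy]
        for a, b in zip(clean, noisy):
            assert a.start == pytest.approx(b.start, abs=0.5)
            assert a.end == pytest.approx(b.end, abs=0.5)


class TestPhaseStats:
    def make_labelled(self, pieces, dt=0.01):
        t, x, y, state = [0.0], [0.0], [0.0], [pieces[0][0]]
        cur = 0.0
        for st, dur, vx in pieces:
            n = int(round(dur / dt))
            for _ in range(n):
                cur += dt
                t.append(cur)
                x.append(x[-1] + vx * dt)
                y.append(y[-1])
                state.append(st)
        return LabelledTrack(np.asarray(t), np.asarray(x), np.asarray(y),
                             np.asarray(state))

    def test_single_run_track(self):
        tr = self.make_labelled([("run", 2.0, 3.0)])
        st = extract_phase_stats(tr)
        assert st.run_durations.size == 1
        assert st.turn_angles.size == 0
        assert st.initial_state == "run"
        assert st.run_speeds[0] == pytest.approx(3.0, rel=1e-9)

    def test_truncation_flags(self):
        tr = self.make_labelled([("rest", 1.0, 0.0), ("run", 2.0, 1.0),
                                 ("rest", 1.0, 0.0)])
        full = extract_phase_stats(tr)
        assert full.rest_durations.size == 2
        trunc = extract_phase_stats(tr, truncate_first_phase=True,
                                    truncate_last_phase=True)
        assert trunc.rest_durations.size == 0
        assert trunc.run_durations.size == 1
        cens = extract_phase_stats(tr, censor_ends=True)
        assert cens.rest_durations.size == 0
        assert cens.rest_censored.size == 2
        last_only = extract_phase_stats(tr, censor_ends="last")
        assert last_only.rest_durations.size == 1
        assert last_only.rest_censored.size == 1

    def test_turn_angle_between_runs_across_one_rest(self):
        # due-east run, rest, then a 90-degree left turn to due north
        tr = self.make_labelled([("run", 1.0, 1.0), ("rest", 1.0, 0.0)])
        t2 = tr.t[-1] + 0.01 * np.arange(1, 101)
        y2 = 0.01 * np.arange(1, 101)
        tr2 = LabelledTrack(
            np.concatenate([tr.t, t2]),
            np.concatenate([tr.x, np.full(100, tr.x[-1])]),
            np.concatenate([tr.y, y2]),
            np.concatenate([tr.state, np.full(100, "run")]),
        )
        st = extract_phase_stats(tr2)
        assert st.turn_angles.size == 1
        assert st.turn_angles[0] == pytest.approx(np.pi / 2, abs=0.02)


class TestVonMisesFit:
    def test_degenerate_angles_capped(self):
        with pytest.warns(RuntimeWarning):
            kappa, psi = fit_vonmises_kappa(np.zeros(100))
        assert kappa == 1e3

    def test_uniform_angles_give_zero(self):
        rng = np.random.default_rng(1)
        kappa, psi = fit_vonmises_kappa(rng.uniform(0, 2 * np.pi, 100_000))
        assert kappa < 0.02
        assert abs(psi) < 0.01

    def test_recovery(self):
        rng = np.random.default_rng(2)
        angles = rng.vonmises(0.0, 2.0, 100_000)
        kappa, psi = fit_vonmises_kappa(angles)
        assert kappa == pytest.approx(2.0, rel=0.02)
        assert psi == pytest.approx(persistence_index(2.0), rel=0.02)

    @pytest.mark.parametrize("kappa", [0.5, 1.0, 2.0, 5.0])
    def test_psi_estimator_is_nearly_unbiased(self, kappa):
        rng = np.random.default_rng(int(10 * kappa))
        _, psi = fit_vonmises_kappa(rng.vonmises(0.0, kappa, 100_000))
        assert abs(psi - persistence_index(kappa)) < 0.01


class TestDurationFit:
    def test_constant_durations_exponential(self):
        fit = fit_duration_distribution(np.full(10, 4.0), "exponential")
        assert fit.params[0] == pytest.approx(0.25)

    def test_exponential_recovery(self):
        rng = np.random.default_rng(3)
        x = rng.exponential(1 / 11.98, 100_000)
        fit = fit_duration_distribution(x, "exponential")
        assert fit.params[0] == pytest.approx(11.98, rel=0.02)

    def test_inverse_gaussian_recovery(self):
        rng = np.random.default_rng(4)
        x = rng.wald(1.26, 1.22, 100_000)
        fit = fit_duration_distribution(x, "invgauss")
        assert fit.params[0] == pytest.approx(1.26, rel=0.02)
        assert fit.params[1] == pytest.approx(1.22, rel=0.02)

    def test_truncated_inverse_gaussian_recovery(self):
        rng = np.random.default_rng(5)
        x = rng.wald(10.79, 7.42, 60_000)
        fit = fit_duration_distribution(x[x > 2.0], "invgauss", left_truncation=2.0)
        assert fit.params[0] == pytest.approx(10.79, rel=0.03)
        assert fit.params[1] == pytest.approx(7.42, rel=0.05)

    def test_censoring_removes_window_bias(self):
        # durations observed in a window of ~6 means: interior-complete
        # averaging is biased low; adding the censored tail repairs it
        rng = np.random.default_rng(6)
        horizon = 6.0
        complete, censored = [], []
        for _ in range(4000):
            t, durs = 0.0, []
            while t < horizon:
                d = rng.exponential(1.0)
                durs.append(min(d, horizon - t))
                t += d
            complete.extend(durs[:-1])
            censored.append(durs[-1])
        naive = 1.0 / np.mean(complete)
        fit = fit_duration_distribution(np.asarray(complete), "exponential",
                                        censored=np.asarray(censored))
        assert abs(fit.params[0] - 1.0) < abs(naive - 1.0) / 3
        assert fit.params[0] == pytest.approx(1.0, rel=0.02)

    def test_gamma_recovery(self):
        rng = np.random.default_rng(7)
        x = rng.gamma(2.0, 0.5, 100_000)
        fit = fit_duration_distribution(x, "gamma")
        assert fit.params[0] == pytest.approx(2.0, rel=0.03)
        assert fit.params[1] == pytest.approx(0.5, rel=0.03)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            fit_duration_distribution([1.0], "exponential")
        with pytest.raises(ValueError):
            fit_duration_distribution([1.0, -1.0], "exponential")


class TestUtilities:
    def test_mean_squared_speed(self):
        assert mean_squared_speed([1.0]) == 1.0
        assert mean_squared_speed([1.0, 3.0]) == 5.0
        with pytest.raises(ValueError):
            mean_squared_speed([])

    def test_split_track(self):
        t = np.arange(0, 84, 0.1)
        tr = GPSTrack(t, np.full(t.size, 50.0), np.full(t.size, 4.0))
        parts = split_track(tr, 28.0)
        assert len(parts) == 3
        assert all(p.t[-1] - p.t[0] <= 28.0 for p in parts)
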