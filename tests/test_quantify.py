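"""Quantification estimators on analytic phantoms and hand-computed cases."""

import numpy as np
import pandas as pd
import pytest

from discwave.imaging import Movie
from discwave.quantify import (
    LineSegment,
    PointROI,
    RegionMask,
    WaveThresholds,
    detect_events,
    detect_waves,
    difference_mask,
    domain_count,
    front_speed,
    isi_analysis,
    isi_from_spike_times,
    kymograph,
    map_origins,
    oscillation_frequency,
    radial_line,
    spike_times_from_trace,
    trace,
)

BG = 20.0
HI = 220.0


def constant_movie(value=100, shape=(5, 12, 12), interval=5.0, px=1.0):
    frames = np.full(shape, value, dtype=np.uint8)
    return Movie(frames, px, interval)


def step_movie(speed, pixel_size=1.0, interval=1.0, ny=24, nx=120, nt=None):
    """A bright front at x = speed·t sweeping rightward."""
    nt = nt or int(nx * pixel_size / (speed * interval)) - 1
    x = (np.arange(nx) + 0.5) * pixel_size
    frames = np.empty((nt, ny, nx), dtype=np.float32)
    for k in range(nt):
        frames[k] = np.where(x < speed * k * interval, HI, BG)[None, :]
    return Movie(frames, pixel_size, interval)


def radial_wave_movie(
    origins, onsets, speed=15.0, pixel_size=1.0, interval=1.0,
    size=100, duration=600, rmax=45.0, active_for=20.0,
):
    """Phantom with radially expanding fronts of known origin and speed."""
    nt = int(duration / interval)
    yy, xx = np.meshgrid(
        (np.arange(size) + 0.5) * pixel_size,
        (np.arange(size) + 0.5) * pixel_size,
        indexing="ij",
    )
    frames = np.full((nt, size, size), BG, dtype=np.float32)
    for (ox, oy), t0 in zip(origins, onsets):
        r = np.hypot(xx - ox, yy - oy)
        for k in range(nt):
            t = k * interval
            if t < t0:
                continue
            radius = min(speed * (t - t0), rmax)
            # active band: reached by the front, not yet recovered
            active = (r <= radius) & (r >= speed * (t - t0 - active_for))
            frames[k][active] = HI
    return Movie(frames, pixel_size, interval)


def full_mask(movie):
    return np.ones(movie.shape[1:], dtype=bool)


class TestTrace:
    def test_constant_movie_constant_series(self):
        m = constant_movie()
        s = trace(m, PointROI(3.0, 4.0))
        assert len(s) == m.n_frames
        assert (s == 100).all()
        np.testing.assert_allclose(s.index, m.times)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            trace(constant_movie(), PointROI(50.0, 2.0))


class TestKymograph:
    def test_constant_movie_constant_profile(self):
        k = kymograph(constant_movie(), LineSegment(1, 1, 10, 10))
        assert np.all(k == 100)

    def test_orientation_swap_is_transpose(self):
        m = step_movie(10.0)
        line = LineSegment(0.5, 12, 110, 12)
        a = kymograph(m, line, "YT")
        b = kymograph(m, line, "TX")
        assert np.array_equal(a, b.T)

    def test_front_contour_slope_recovers_speed(self):
        """On a translating step the half-max contour is a line of slope v."""
        v = 12.0
        m = step_movie(v)
        k = kymograph(m, LineSegment(0.5, 12, 110.5, 12), "YT")
        level = (HI + BG) / 2
        pos = []
        for col in range(1, k.shape[1]):
            above = np.flatnonzero(k[:, col] >= level)
            pos.append(above.max() if len(above) else 0)
        slope = np.polyfit(np.arange(1, k.shape[1]) * m.frame_interval,
                           np.asarray(pos, float) * m.pixel_size, 1)[0]
        assert slope == pytest.approx(v, rel=0.05)

    def test_zero_length_line_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            kymograph(constant_movie(), LineSegment(2, 2, 2, 2))


class TestDifferenceMask:
    def test_static_movie_gives_all_255(self):
        d = difference_mask(constant_movie(interval=5.0), lag=10.0)
        assert (d.frames == 255).all()
        assert d.n_frames == 3
        assert d.t0 == 10.0

    def test_hand_computed_3x3_values(self):
        """Negative differences clamp to 0; positive invert as 255 − d."""
        f = np.zeros((2, 3, 3), dtype=np.uint8)
        f[0] = [[130, 100, 0], [255, 7, 9], [100, 100, 100]]
        f[1] = [[100, 130, 5], [0, 9, 7], [100, 255, 0]]
        d = difference_mask(Movie(f, 1.0, 5.0), lag=5.0)
        expected = np.array(
            [[255, 225, 250], [255, 253, 255], [255, 100, 255]], dtype=np.uint8
        )
        np.testing.assert_array_equal(d.frames[0], expected)

    def test_time_reversed_rising_movie_is_white(self):
        rising = np.linspace(10, 200, 8)[:, None, None] * np.ones((1, 4, 4))
        m = Movie(rising[::-1].astype(np.uint8), 1.0, 5.0)
        d = difference_mask(m, lag=5.0)
        assert (d.frames == 255).all()

    def test_lag_must_be_frame_multiple(self):
        with pytest.raises(ValueError, match="multiple"):
            difference_mask(constant_movie(interval=5.0), lag=7.0)

    def test_requires_8bit(self):
        m = Movie(np.zeros((3, 4, 4), np.float32), 1.0, 5.0)
        with pytest.raises(ValueError, match="8-bit"):
            difference_mask(m, 5.0)


class TestDetectWaves:
    @pytest.mark.parametrize("k", [0, 1, 2, 5])
    def test_exact_wave_count(self, k):
        """The detector returns exactly K waves for K injected fronts."""
        onsets = [60.0 + 110.0 * i for i in range(k)]
        origins = [(30 + 8 * i, 40 + 5 * i) for i in range(k)]
        m = radial_wave_movie(origins, onsets, duration=60 + 110 * max(k, 1))
        waves = detect_waves(m, full_mask(m))
        assert len(waves) == k

    def test_origins_recovered_within_one_cell_diameter(self):
        origins = [(30.0, 42.0), (70.0, 55.0), (45.0, 25.0)]
        onsets = [50.0, 160.0, 270.0]
        m = radial_wave_movie(origins, onsets, duration=400)
        waves = detect_waves(m, full_mask(m))
        assert len(waves) == 3
        for w, (ox, oy) in zip(waves, origins):
            assert np.hypot(w.origin[0] - ox, w.origin[1] - oy) < 5.0

    def test_quiet_movie_has_no_events(self):
        m = Movie(np.full((60, 40, 40), BG, np.float32), 1.0, 1.0)
        assert detect_waves(m, full_mask(m)) == []

    def test_small_blobs_classified_as_spikes(self):
        frames = np.full((60, 60, 60), BG, dtype=np.float32)
        frames[20:24, 10:13, 10:13] = HI     # 9 px, 0.25% of the region
        frames[40:44, 40:43, 30:33] = HI
        m = Movie(frames, 1.0, 1.0)
        events = detect_events(m, full_mask(m))
        kinds = {e.kind for e in events}
        assert kinds == {"spike"}
        assert len([e for e in events if e.kind == "spike"]) == 2

    def test_global_flash_not_counted_as_wave(self):
        frames = np.full((60, 60, 60), BG, dtype=np.float32)
        frames[30:36] = HI                   # everything at once
        m = Movie(frames, 1.0, 1.0)
        events = detect_events(m, full_mask(m))
        assert [e.kind for e in events] == ["flash"]
        assert oscillation_frequency(events, full_mask(m), 60.0) == 0.0


class TestFrequency:
    def test_zero_events(self):
        m = constant_movie()
        assert oscillation_frequency([], full_mask(m), 3600.0) == 0.0

    def test_five_events_per_hour(self):
        onsets = [100.0 + 150 * i for i in range(5)]
        origins = [(50, 50)] * 5
        m = radial_wave_movie(origins, onsets, duration=900)
        waves = detect_waves(m, full_mask(m))
        assert oscillation_frequency(waves, full_mask(m), 3600.0) == 5.0

    def test_region_entry_requires_footprint_overlap(self):
        m = radial_wave_movie([(20.0, 20.0)], [50.0], duration=200, rmax=25)
        waves = detect_waves(m, full_mask(m))
        assert len(waves) == 1
        far = np.zeros(m.shape[1:], bool)
        far[80:, 80:] = True
        assert oscillation_frequency(waves, far, 3600.0) == 0.0

    def test_duration_must_be_positive(self):
        with pytest.raises(ValueError):
            oscillation_frequency([], np.ones((4, 4), bool), 0.0)


class TestFrontSpeed:
    @pytest.mark.parametrize("px", [0.5, 1.0, 2.0])
    def test_phantom_speed_recovered_within_2pct(self, px):
        """15.4 μm/s radial phantom across pixel sizes."""
        m = radial_wave_movie(
            [(70.0, 70.0)], [30.0], speed=15.4, pixel_size=px,
            size=int(140 / px), duration=90, rmax=65, interval=0.5,
        )
        waves = detect_waves(m, full_mask(m))
        assert len(waves) == 1
        fit = front_speed(m, waves[0], radial_line(waves[0], m))
        assert fit.speed == pytest.approx(15.4, rel=0.02)

    def test_regenerative_front_amplitude_flat(self):
        m = radial_wave_movie(
            [(70.0, 70.0)], [30.0], speed=15.4, size=140, duration=90,
            rmax=65, interval=0.5,
        )
        w = detect_waves(m, full_mask(m))[0]
        fit = front_speed(m, w, radial_line(w, m))
        assert abs(fit.amplitude_decrement()) < 0.10

    def test_static_front_has_zero_speed(self):
        frames = np.full((40, 40, 40), BG, dtype=np.float32)
        frames[10:, :, :20] = HI
        m = Movie(frames, 1.0, 1.0)
        ev = detect_events(m, full_mask(m))
        ev = [e for e in ev if e.kind != "spike"]
        assert len(ev) == 1
        line = LineSegment(*ev[0].origin, 39.0, ev[0].origin[1])
        with pytest.raises(ValueError):
            # a front that never advances has < 3 expansion frames
            front_speed(m, ev[0], line)

    def test_too_few_frames_rejected(self):
        m = radial_wave_movie(
            [(50.0, 50.0)], [30.0], speed=15.0, duration=120, interval=10.0
        )
        waves = detect_waves(m, full_mask(m))
        if waves:
            with pytest.raises(ValueError, match="frames"):
                front_speed(m, waves[0], radial_line(waves[0], m),
                            min_frames=30)


class TestMapOrigins:
    def test_single_event_single_cluster(self):
        m = radial_wave_movie([(40.0, 60.0)], [50.0], duration=200)
        om = map_origins(detect_waves(m, full_mask(m)))
        assert len(om.origins) == 1
        assert om.cluster_sizes == {0: 1}

    def test_recurring_identical_origins_form_one_cluster(self):
        onsets = [60.0 + 110 * i for i in range(5)]
        m = radial_wave_movie([(50.0, 50.0)] * 5, onsets, duration=640)
        om = map_origins(detect_waves(m, full_mask(m)))
        assert len(om.origins) == 5
        assert list(om.cluster_sizes.values()) == [5]
        assert om.dispersion < 5.0

    def test_no_waves_is_an_error(self):
        with pytest.raises(ValueError):
            map_origins([])


class TestISI:
    def test_perfectly_periodic_spikes(self):
        st = {i: np.arange(5) * 600.0 + 37 * i for i in range(5)}
        stats = isi_from_spike_times(st)
        assert np.allclose(stats.tav, 600.0)
        assert np.allclose(stats.sd, 0.0)

    def test_poisson_trains_have_unit_sd_tav_slope(self):
        """Exponential ISIs: SD equals the mean, so the SD-vs-Tav
        regression across points of different rates has slope ≈ 1."""
        rng = np.random.default_rng(42)
        st = {}
        for i, mean_isi in enumerate(np.linspace(100, 600, 20)):
            st[i] = np.cumsum(rng.exponential(mean_isi, 200))
        stats = isi_from_spike_times(st)
        assert 0.8 <= stats.slope <= 1.2
        assert stats.r_squared > 0.6
        assert stats.p_value < 1e-3

    def test_points_with_few_spikes_excluded_with_warning(self):
        st = {0: [0, 600, 1200, 1800], 1: [0, 500, 1100, 1600],
              2: [0, 700, 1300, 2100], 3: [0, 650]}
        with pytest.warns(UserWarning, match="excluded"):
            stats = isi_from_spike_times(st)
        assert len(stats.table) == 3

    def test_fewer_than_three_points_is_an_error(self):
        with pytest.raises(ValueError, match="usable points"):
            isi_from_spike_times({0: [0, 600, 1200], 1: [0, 500, 1000]})

    def test_spike_detection_with_lockout(self):
        t = np.arange(0, 400, 1.0)
        v = np.zeros_like(t)
        for t0 in (50, 60, 200, 350):   # 60 is inside the lockout of 50
            v[(t >= t0) & (t < t0 + 5)] = 100.0
        s = pd.Series(v, index=t)
        times = spike_times_from_trace(s, lockout=30.0)
        np.testing.assert_allclose(times, [50, 200, 350])

    def test_isi_analysis_on_synthetic_movie(self):
        frames = np.full((240, 20, 20), BG, dtype=np.float32)
        for t0 in range(20, 240, 60):   # period 60 frames × 5 s = 300 s
            frames[t0:t0 + 4] = HI
        m = Movie(frames, 1.0, 5.0)
        pts = [PointROI(x + 0.5, x + 0.5) for x in range(5)]
        stats = isi_analysis(m, pts, lockout=30.0)
        assert np.allclose(stats.tav, 300.0)
        assert np.allclose(stats.sd, 0.0)


class TestDomainCount:
    def test_all_white_frame_has_zero_domains(self):
        d = Movie(np.full((2, 30, 30), 255, np.uint8), 1.0, 5.0)
        assert domain_count(d, 0) == 0

    def test_two_blobs(self):
        f = np.full((1, 40, 40), 255, np.uint8)
        f[0, 5:15, 5:15] = 200
        f[0, 25:35, 25:35] = 200
        assert domain_count(Movie(f, 1.0, 5.0), 0) == 2

    def test_small_speckles_removed(self):
        f = np.full((1, 40, 40), 255, np.uint8)
        f[0, 5, 5] = 200
        f[0, 20:30, 20:30] = 200
        assert domain_count(Movie(f, 1.0, 5.0), 0, min_size=4) == 1

    def test_frame_bounds_checked(self):
        d = Movie(np.full((2, 8, 8), 255, np.uint8), 1.0, 5.0)
        with pytest.raises(ValueError):
            domain_count(d, 5)


class TestRegionMaskType:
    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            RegionMask(np.zeros((4, 4), bool))


class TestROIJson:
    def test_round_trip_points_lines_polygons(self, tmp_path):
        import json

        from discwave.quantify import polygon_mask, rois_from_json

        obj = {
            "points": [[3.0, 4.0], [5.5, 1.0]],
            "lines": [[0.0, 0.0, 10.0, 5.0]],
            "polygons": [[[1, 1], [8, 1], [8, 8], [1, 8]]],
        }
        path = tmp_path / "rois.json"
        path.write_text(json.dumps(obj))
        rois = rois_from_json(path)
        assert rois["points"][0] == PointROI(3.0, 4.0)
        assert rois["lines"][0].length == pytest.approx(np.hypot(10, 5))
        mask = polygon_mask(rois["polygons"][0], (12, 12), 1.0)
        assert mask.area_px == 49  # 7×7 pixel centers inside the square
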