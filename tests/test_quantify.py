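"""Event detection, per-event morphometrics and surface summaries."""

import math

import numpy as np
import pytest

from trailforge import (
    DetectionConfig,
    detect_events,
    make_fixture_pit,
    make_flat,
    measure_all,
    measure_event,
    min_area_rectangle,
    quantify_surface,
)


@pytest.fixture
def cfg():
    return DetectionConfig()


def _two_pits(gap):
    """Flat map with two circular pits whose centres are 2*r + gap apart."""
    pristine = make_flat(300, 300)
    final = pristine.copy()
    make_fixture_pit(final, (100, 150), 20, 20, depth=10.0)
    make_fixture_pit(final, (140 + gap, 150), 20, 20, depth=10.0)
    return pristine, final


class TestDetectEvents:
    def test_untouched_surface_has_no_events(self, cfg):
        m = make_flat(100, 100)
        assert detect_events(m, m.copy(), cfg).max() == 0

    def test_disjoint_pits_are_two_events(self, cfg):
        pristine, final = _two_pits(gap=20)
        assert detect_events(pristine, final, cfg).max() == 2

    def test_overlapping_pits_merge_into_one_event(self, cfg):
        pristine, final = _two_pits(gap=-10)
        assert detect_events(pristine, final, cfg).max() == 1

    def test_roughness_alone_creates_no_events(self, cfg, rng):
        # detection runs on excavation, not absolute height
        pristine = make_flat(200, 200)
        pristine.heights += rng.normal(0, 5, size=pristine.heights.shape)
        assert detect_events(pristine, pristine.copy(), cfg).max() == 0

    def test_min_area_filter_drops_speckle(self):
        pristine = make_flat(100, 100)
        final = pristine.copy()
        final.heights[50, 50] -= 5.0  # single-pixel divot, 1 um^2
        cfg = DetectionConfig(min_event_area=20.0)
        assert detect_events(pristine, final, cfg).max() == 0

    def test_shape_mismatch_rejected(self, cfg):
        with pytest.raises(ValueError):
            detect_events(make_flat(10, 10), make_flat(11, 10), cfg)


class TestMeasureEvent:
    def test_ellipse_against_analytic_truth(self, cfg):
        # semi-axes 30 x 5 um, depth 10: area ~ pi*30*5, axes ~ (60, 10)
        pristine = make_flat(200, 200)
        final = pristine.copy()
        _, truth = make_fixture_pit(final, (100, 100), 30, 5, depth=10.0, orientation=0.5)
        labels = detect_events(pristine, final, cfg)
        m = measure_event(labels, 1, pristine, final, cfg)
        assert m.area == pytest.approx(truth.area, rel=0.03)
        # pixel-centre calipers under-read a thin ellipse tip by up to
        # ~1.5 px; the flat-sided width stays within one pixel
        assert m.length == pytest.approx(60.0, abs=1.6)
        assert m.width == pytest.approx(10.0, abs=1.0)
        assert m.max_depth == pytest.approx(10.0)
        assert m.volume == pytest.approx(truth.volume, rel=0.03)

    def test_axis_aligned_square(self, cfg):
        pristine = make_flat(60, 60)
        final = pristine.copy()
        final.heights[20:30, 20:30] = -5.0  # 10 x 10 um square
        labels = detect_events(pristine, final, cfg)
        m = measure_event(labels, 1, pristine, final, cfg)
        # min-area rectangle of a square has equal sides; pixel-centre
        # calipers read the 10 um side to within one pixel
        assert m.length == pytest.approx(m.width)
        assert m.length == pytest.approx(10.0, abs=1.0)
        assert m.area == pytest.approx(100.0)

    def test_depth_quantization_slice_rule(self):
        # 12.3 um deep with 2 um slices -> ceil(12.3/2) = 7 slices -> 14 um
        pristine = make_flat(60, 60)
        final = pristine.copy()
        make_fixture_pit(final, (30, 30), 10, 10, depth=12.3)
        cfg = DetectionConfig(z_step=2.0)
        labels = detect_events(pristine, final, cfg)
        m = measure_event(labels, 1, pristine, final, cfg)
        assert m.quantized_depth == pytest.approx(14.0)

    def test_quantized_depth_brackets_true_depth(self, cfg, rng):
        for _ in range(20):
            depth = float(rng.uniform(1, 40))
            z_step = float(rng.uniform(0.5, 5))
            pristine = make_flat(60, 60)
            final = pristine.copy()
            make_fixture_pit(final, (30, 30), 12, 8, depth=depth)
            c = DetectionConfig(z_step=z_step)
            labels = detect_events(pristine, final, c)
            m = measure_event(labels, 1, pristine, final, c)
            assert m.quantized_depth >= m.max_depth - 1e-9
            assert m.quantized_depth - m.max_depth < z_step

    def test_rotation_changes_axes_by_at_most_two_pixels(self, cfg):
        def measure_rect(theta):
            pristine = make_flat(200, 200)
            final = pristine.copy()
            make_fixture_pit(final, (100, 100), 35, 8, depth=6.0, orientation=theta)
            labels = detect_events(pristine, final, cfg)
            return measure_event(labels, 1, pristine, final, cfg)

        m0 = measure_rect(0.0)
        m37 = measure_rect(math.radians(37))
        assert m37.length == pytest.approx(m0.length, abs=2.0)
        assert m37.width == pytest.approx(m0.width, abs=2.0)

    def test_empty_label_rejected(self, cfg):
        pristine, final = _two_pits(gap=20)
        labels = detect_events(pristine, final, cfg)
        with pytest.raises(ValueError):
            measure_event(labels, 99, pristine, final, cfg)

    def test_edge_touching_flag(self, cfg):
        pristine = make_flat(100, 100)
        final = pristine.copy()
        make_fixture_pit(final, (2, 50), 10, 10, depth=5.0)
        labels = detect_events(pristine, final, cfg)
        m = measure_event(labels, 1, pristine, final, cfg)
        assert m.touches_edge


class TestMinAreaRectangle:
    def test_exact_rectangle(self):
        xs, ys = np.meshgrid(np.arange(0, 30, 0.5), np.arange(0, 8, 0.5))
        pts = np.column_stack([xs.ravel(), ys.ravel()])
        long_side, short_side = min_area_rectangle(pts)
        assert long_side == pytest.approx(29.5)
        assert short_side == pytest.approx(7.5)

    def test_collinear_points_have_zero_width(self):
        pts = np.column_stack([np.arange(10.0), np.arange(10.0)])
        long_side, short_side = min_area_rectangle(pts)
        assert long_side == pytest.approx(9 * math.sqrt(2))
        assert short_side == 0.0

    def test_single_point(self):
        assert min_area_rectangle(np.array([[1.0, 2.0]])) == (0.0, 0.0)


class TestQuantifySurface:
    def test_flat_surface_summary(self, cfg):
        m = make_flat(100, 100)
        measurements, summary = quantify_surface(m, m.copy(), cfg)
        assert measurements == []
        assert summary.resorbed_area_pct == 0.0
        assert summary.events_per_cm2 == 0.0

    def test_single_ellipse_summary(self, cfg):
        # one ~471 um^2 ellipse on 0.01 cm^2: ~0.047% resorbed, 100 events/cm^2
        pristine = make_flat(1000, 1000)
        final = pristine.copy()
        make_fixture_pit(final, (500, 500), 30, 5, depth=10.0)
        _, summary = quantify_surface(pristine, final, cfg)
        assert summary.n_events == 1
        assert summary.events_per_cm2 == pytest.approx(100.0)
        assert summary.resorbed_area_pct == pytest.approx(0.0471, rel=0.05)

    def test_area_conservation_is_exact(self, cfg):
        pristine, final = _two_pits(gap=35)
        labels = detect_events(pristine, final, cfg)
        measurements = measure_all(labels, pristine, final, cfg)
        assert sum(m.area for m in measurements) == pytest.approx(
            np.count_nonzero(labels) * pristine.pixel_size**2
        )

    def test_pooling_two_half_maps_matches_whole(self, cfg):
        pristine = make_flat(400, 400)
        final = pristine.copy()
        make_fixture_pit(final, (100, 100), 20, 10, depth=8.0)
        make_fixture_pit(final, (300, 300), 25, 12, depth=12.0, orientation=0.7)
        whole, _ = quantify_surface(pristine, final, cfg)

        from trailforge import HeightMap

        halves = []
        for sl in (slice(0, 200), slice(200, 400)):
            p_half = HeightMap(pristine.heights[sl].copy(), 1.0)
            f_half = HeightMap(final.heights[sl].copy(), 1.0)
            halves += quantify_surface(p_half, f_half, cfg)[0]
        assert len(halves) == len(whole) == 2
        for a, b in zip(
            sorted(whole, key=lambda m: m.area), sorted(halves, key=lambda m: m.area)
        ):
            assert a.area == pytest.approx(b.area)
            assert a.length == pytest.approx(b.length)
            assert a.width == pytest.approx(b.width)
            assert a.max_depth == pytest.approx(b.max_depth)

    def test_fixture_recovery_over_random_ellipses(self, cfg, rng):
        # 100 random elongated fixtures (pit/trail-like aspect ratios):
        # area within 3% per fixture and exact depth; rectangle axes are
        # unbiased to within one pixel on average, with a worst case of a
        # few pixels because the minimum-area rectangle of a rasterized
        # ellipse may tilt slightly off the true axes
        len_errors, wid_errors = [], []
        for _ in range(100):
            a = float(rng.uniform(14, 40))
            b = float(rng.uniform(5, 0.5 * a))
            depth = float(rng.uniform(2, 30))
            theta = float(rng.uniform(0, math.pi))
            pristine = make_flat(160, 160)
            final = pristine.copy()
            _, truth = make_fixture_pit(final, (80, 80), a, b, depth, orientation=theta)
            measurements, _ = quantify_surface(pristine, final, cfg)
            assert len(measurements) == 1
            m = measurements[0]
            assert m.area == pytest.approx(truth.area, rel=0.03)
            assert m.max_depth == pytest.approx(depth)
            assert m.length == pytest.approx(truth.length, abs=3.0)
            assert m.width == pytest.approx(truth.width, abs=2.0)
            len_errors.append(m.length - truth.length)
            wid_errors.append(m.width - truth.width)
        assert abs(np.mean(len_errors)) <= 1.0
        assert abs(np.mean(wid_errors)) <= 1.0
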