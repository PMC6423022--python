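"""Surface definitions: profiles, gradients, areas, calibration, sampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chisquare, kstest

import nanorsa as nr
from nanorsa.geometry import DEFAULT_RESOLUTION


def gaussian_surface(H, W, d_p, cells=(1, 1)):
    return nr.make_gaussian_surface(nr.GaussianArraySpec(H, W, d_p), cells)


class TestGaussianProfile:
    @pytest.mark.parametrize("H,W", [(200.0, 80.0), (500.0, 60.0), (-550.0, 60.0)])
    def test_peak_height_and_flat_gradient(self, H, W):
        surf = gaussian_surface(H, W, 300.0)
        assert surf.height(150.0, 150.0) == pytest.approx(H, rel=1e-12)
        fx, fy = surf.gradient(150.0, 150.0)
        assert fx == pytest.approx(0.0, abs=1e-12)
        assert fy == pytest.approx(0.0, abs=1e-12)

    def test_half_height_at_half_width(self):
        surf = gaussian_surface(500.0, 60.0, 300.0)
        # lateral distance W/2 = 30 nm from the peak gives exactly H/2
        assert surf.height(180.0, 150.0) == pytest.approx(250.0, rel=1e-12)

    def test_truncation_outside_half_spacing(self):
        surf = gaussian_surface(500.0, 120.0, 140.0)
        # the cell corner is ~98 nm from every peak, beyond d_p/2 = 70 nm
        assert surf.height(139.0, 139.0) == 0.0
        fx, fy = surf.gradient(139.0, 139.0)
        assert fx == 0.0 and fy == 0.0

    def test_variance_derivation(self):
        spec = nr.GaussianArraySpec(100.0, 50.0, 200.0)
        assert spec.variance == pytest.approx((25.0 ** 2) / (2 * np.log(2)), rel=1e-15)

    @pytest.mark.parametrize("bad", [dict(H=10, W=-1, d_p=100), dict(H=10, W=0, d_p=100),
                                     dict(H=10, W=50, d_p=0)])
    def test_invalid_spec_rejected(self, bad):
        with pytest.raises(nr.InvalidSurfaceError):
            nr.GaussianArraySpec(**bad)

    @given(H=st.floats(-600, 600).filter(lambda h: abs(h) > 1.0),
           W=st.floats(10, 120), frac=st.floats(0.05, 0.95))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_profile_invariants(self, H, W, frac):
        d_p = 4.0 * W
        surf = gaussian_surface(H, W, d_p)
        cx = d_p / 2.0
        # half height at W/2 regardless of parameters
        assert surf.height(cx + W / 2.0, cx) == pytest.approx(H / 2.0, rel=1e-9)
        # area weight is never below 1
        x = cx + frac * d_p / 2.0
        assert surf.area_weight(x, cx) >= 1.0
        # periodic: height and gradient agree on opposite edges
        for y in (0.3 * d_p, 0.77 * d_p):
            assert surf.height(0.0, y) == pytest.approx(surf.height(d_p, y), abs=1e-9)
            gx0, gy0 = surf.gradient(0.0, y)
            gx1, gy1 = surf.gradient(d_p, y)
            assert gx0 == pytest.approx(gx1, abs=1e-9)
            assert gy0 == pytest.approx(gy1, abs=1e-9)


class TestHeightField:
    def test_constant_field_is_flat(self):
        hf = nr.HeightField(2.0, 2.0, np.full((8, 8), 5.0))
        surf = nr.make_heightfield_surface(hf)
        assert surf.height(3.3, 7.1) == pytest.approx(5.0)
        assert surf.area_weight(3.3, 7.1) == pytest.approx(1.0)
        assert surf.area().ratio == pytest.approx(1.0, abs=1e-9)

    def test_ramp_weight_matches_plane(self):
        # z = a x: away from the periodic seam the area weight is sqrt(1+a^2)
        a = 0.75
        nx = 64
        x = np.arange(nx) * 1.0
        hf = nr.HeightField(1.0, 1.0, np.tile(a * x, (nx, 1)))
        surf = nr.make_heightfield_surface(hf)
        xs = np.linspace(10, 50, 7)
        w = surf.area_weight(xs, np.full_like(xs, 32.0))
        assert np.allclose(w, np.sqrt(1 + a * a), rtol=1e-12)

    def test_single_spike_ratio_above_one(self):
        z = np.zeros((32, 32))
        z[16, 16] = 30.0
        surf = nr.make_heightfield_surface(nr.HeightField(4.0, 4.0, z))
        assert surf.area().ratio > 1.0

    def test_nonfinite_rejected(self):
        z = np.zeros((8, 8))
        z[2, 3] = np.nan
        with pytest.raises(nr.InvalidSurfaceError):
            nr.HeightField(1.0, 1.0, z)

    def test_too_small_grid_rejected(self):
        with pytest.raises(nr.InvalidSurfaceError):
            nr.HeightField(1.0, 1.0, np.zeros((3, 8)))


class TestSurfaceArea:
    def test_flat_ratio_exactly_one(self, flat_surface):
        area = nr.surface_area(flat_surface)
        assert area.ratio == pytest.approx(1.0, abs=1e-6)
        assert area.A_s == pytest.approx(250000.0)

    def test_refinement_converges(self):
        surf = gaussian_surface(500.0, 60.0, 180.0)
        coarse = nr.surface_area(surf, DEFAULT_RESOLUTION).ratio
        fine = nr.surface_area(surf, DEFAULT_RESOLUTION / 2.0).ratio
        assert abs(fine - coarse) / coarse < 1e-3

    def test_weight_one_only_where_gradient_vanishes(self):
        surf = gaussian_surface(300.0, 60.0, 200.0)
        xs = np.linspace(1.0, 199.0, 41)
        w = surf.area_weight(xs[None, :], xs[:, None])
        fx, fy = surf.gradient(xs[None, :], xs[:, None])
        grad0 = (np.abs(fx) < 1e-12) & (np.abs(fy) < 1e-12)
        assert np.all(w >= 1.0)
        assert np.allclose(w[grad0], 1.0)
        assert np.all(w[~grad0] > 1.0)


class TestCalibrateDp:
    def test_flat_profile_cannot_be_calibrated(self):
        with pytest.raises(nr.CalibrationError):
            nr.calibrate_dp(0.0, 60.0, 2.0)

    def test_round_trip_against_integrator(self):
        d_p = nr.calibrate_dp(500.0, 40.0, 2.8)
        surf = gaussian_surface(500.0, 40.0, d_p)
        assert surf.area().ratio == pytest.approx(2.8, abs=1e-3)

    def test_spacing_decreases_with_target_ratio(self):
        lo = nr.calibrate_dp(500.0, 60.0, 2.8)
        hi = nr.calibrate_dp(500.0, 60.0, 3.6)
        assert hi < lo

    def test_unreachable_target(self):
        with pytest.raises(nr.CalibrationError):
            nr.calibrate_dp(10.0, 60.0, 50.0)


class TestSampling:
    def test_flat_sampling_uniform(self, flat_surface):
        rng = np.random.default_rng(5)
        pts, nrm = nr.sample_surface_point(flat_surface, rng, 100_000)
        counts, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=10,
                                      range=[[0, 500], [0, 500]])
        stat = chisquare(counts.ravel())
        assert stat.pvalue > 0.01
        assert np.allclose(nrm, [0.0, 0.0, 1.0])

    def test_normal_at_peak_is_vertical(self):
        surf = gaussian_surface(500.0, 60.0, 200.0)
        n = surf.normal(100.0, 100.0)
        assert np.allclose(n, [0.0, 0.0, 1.0], atol=1e-12)

    def test_area_weighted_radial_law(self):
        # on a spike cell the lateral radius from the peak must follow
        # the area-element law w(r) 2 pi r dr
        surf = gaussian_surface(500.0, 60.0, 200.0)
        rng = np.random.default_rng(11)
        pts, _ = nr.sample_surface_point(surf, rng, 100_000)
        r = np.hypot(pts[:, 0] - 100.0, pts[:, 1] - 100.0)
        rmax = 100.0
        r = r[r <= rmax]
        rr = np.linspace(0.0, rmax, 2001)
        w = surf.area_weight(100.0 + rr, np.full_like(rr, 100.0))
        pdf = w * 2.0 * np.pi * rr
        cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2.0 * np.diff(rr))])
        cdf /= cdf[-1]
        stat = kstest(r, lambda q: np.interp(q, rr, cdf))
        assert stat.statistic < 0.02

    def test_region_hit_fraction_tracks_area(self):
        # hit fraction of the truncation disk ~ its curved-area share
        surf = gaussian_surface(500.0, 60.0, 200.0)
        rng = np.random.default_rng(17)
        pts, _ = nr.sample_surface_point(surf, rng, 50_000)
        r = np.hypot(pts[:, 0] - 100.0, pts[:, 1] - 100.0)
        inside = np.mean(r <= 100.0)
        area = surf.area()
        rr = np.linspace(0.0, 100.0, 4001)
        w = surf.area_weight(100.0 + rr, np.full_like(rr, 100.0))
        disk = np.trapezoid(w * 2 * np.pi * rr, rr)
        expected = disk / area.A_s
        se = np.sqrt(expected * (1 - expected) / 50_000)
        assert abs(inside - expected) < 4 * se + 1e-3
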