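"""Flow metrics on synthetic tracks and constructed fields."""

import numpy as np
import pandas as pd
import pytest

from streaksim.core import TissueState
from streaksim.metrics import (classify_two_streak_interaction, convert_units,
                               make_track_table, streak_geometry,
                               velocity_field, vorticity_grid,
                               vorticity_profile, vortex_strength)


def synthetic_tracks(position_fn, n_cells=100, steps=(0, 100), rng=None,
                     extent=200.0):
    """Track table from an analytic trajectory x(t) = position_fn(x0, t)."""
    rng = rng or np.random.default_rng(0)
    x0 = rng.uniform(20, extent - 20, size=(n_cells, 2))
    rows = []
    for t in steps:
        for i in range(n_cells):
            x, y = position_fn(x0[i], t)
            rows.append((t, i + 1, 1, x, y, 0.0, 0.0))
    return make_track_table(rows)


class TestVelocityField:
    def test_stationary_cells_zero_field(self):
        tracks = synthetic_tracks(lambda p, t: p, steps=(0, 50))
        vf = velocity_field(tracks, 0, 50, bin_size=20)
        pop = ~np.isnan(vf.vx)
        assert pop.any()
        assert np.allclose(vf.vx[pop], 0) and np.allclose(vf.vy[pop], 0)

    def test_uniform_translation_recovered(self):
        v = np.array([0.03, -0.01])
        tracks = synthetic_tracks(lambda p, t: p + v * t, steps=(0, 200))
        vf = velocity_field(tracks, 0, 200, bin_size=25)
        pop = ~np.isnan(vf.vx)
        assert np.allclose(vf.vx[pop], v[0], atol=1e-12)
        assert np.allclose(vf.vy[pop], v[1], atol=1e-12)

    def test_rigid_rotation_recovered(self):
        """v = omega x r within 2% per populated bin (dense sampling)."""
        omega = 1e-3
        c = np.array([100.0, 100.0])

        def rot(p, t):
            r = p - c
            a = omega * t
            R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
            return c + R @ r

        tracks = synthetic_tracks(rot, n_cells=4000, steps=(0, 10))
        vf = velocity_field(tracks, 0, 10, bin_size=10)
        ny, nx = vf.vx.shape
        checked = 0
        for iy in range(ny):
            for ix in range(nx):
                if np.isnan(vf.vx[iy, ix]):
                    continue
                r = np.array([vf.mx[iy, ix], vf.my[iy, ix]]) - c
                if np.linalg.norm(r) < 20:
                    continue            # tiny velocities, relative err blows up
                expect = omega * np.array([-r[1], r[0]])
                got = np.array([vf.vx[iy, ix], vf.vy[iy, ix]])
                assert np.linalg.norm(got - expect) <= 0.02 * np.linalg.norm(expect)
                checked += 1
        assert checked > 100

    def test_empty_window_raises(self):
        tracks = synthetic_tracks(lambda p, t: p, steps=(0, 50))
        with pytest.raises(ValueError):
            velocity_field(tracks, 0, 0)


class TestVorticity:
    def _rotation_field(self, omega=2e-3, n=5000):
        c = np.array([100.0, 100.0])

        def rot(p, t):
            r = p - c
            a = omega * t
            R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
            return c + R @ r

        tracks = synthetic_tracks(rot, n_cells=n, steps=(0, 5))
        return velocity_field(tracks, 0, 5, bin_size=10)

    def test_rigid_rotation_gives_two_omega(self):
        omega = 2e-3
        vf = self._rotation_field(omega)
        prof = vorticity_profile(vf, y=100.0)
        vals = prof[:, 1]
        good = ~np.isnan(vals)
        # interior bins: curl = 2 * omega
        inner = good & (np.abs(prof[:, 0] - 100) < 60)
        assert inner.sum() >= 5
        assert np.allclose(vals[inner], 2 * omega, rtol=0.1)

    def test_translation_curl_free(self):
        tracks = synthetic_tracks(lambda p, t: p + np.array([0.05, 0.02]) * t,
                                  steps=(0, 100))
        vf = velocity_field(tracks, 0, 100, bin_size=25)
        omega = vorticity_grid(vf)
        assert np.allclose(omega[~np.isnan(omega)], 0, atol=1e-12)

    def test_gradient_flow_curl_free(self):
        """A potential (curl-free) flow v = grad(phi) has zero measured
        vorticity up to discretization error."""
        def potential_flow(p, t):
            # phi = x^2 - y^2 -> v = (2x, -2y) scaled small
            return p + 1e-4 * t * np.array([2 * p[0], -2 * p[1]])

        tracks = synthetic_tracks(potential_flow, n_cells=6000, steps=(0, 10))
        vf = velocity_field(tracks, 0, 10, bin_size=10)
        omega = vorticity_grid(vf)
        vals = np.abs(omega[~np.isnan(omega)])
        assert np.median(vals) < 5e-4

    def test_counter_rotating_pair_odd_profile(self):
        """Two mirror vortices: profile odd about the midline, zero at it."""
        c1 = np.array([60.0, 100.0])
        c2 = np.array([140.0, 100.0])
        w = 2e-3

        def pair(p, t):
            r1, r2 = p - c1, p - c2
            v = (w * np.exp(-np.linalg.norm(r1) / 40) * np.array([-r1[1], r1[0]])
                 - w * np.exp(-np.linalg.norm(r2) / 40) * np.array([-r2[1], r2[0]]))
            return p + v * t

        tracks = synthetic_tracks(pair, n_cells=8000, steps=(0, 10))
        vf = velocity_field(tracks, 0, 10, bin_size=10)
        prof = vorticity_profile(vf, y=100.0)
        xs, vals = prof[:, 0], prof[:, 1]
        mid = np.argmin(np.abs(xs - 100))
        peak = np.nanmax(np.abs(vals))
        assert abs(vals[mid]) < 0.15 * peak
        # odd symmetry: left and right lobes have opposite signs
        left = np.nanmean(vals[(xs > 30) & (xs < 90)])
        right = np.nanmean(vals[(xs > 110) & (xs < 170)])
        assert left * right < 0

    def test_transect_outside_field_raises(self):
        vf = self._rotation_field(n=500)
        with pytest.raises(ValueError):
            vorticity_profile(vf, y=1e6)


class TestStreakGeometry:
    def _state_from_masks(self, s_mask, st_mask=None):
        owner = np.zeros(s_mask.shape, dtype=np.int32)
        owner[s_mask] = 1
        types = [0, 3]
        if st_mask is not None:
            owner[st_mask] = 2
            types.append(4)
        return TissueState(owner, types)

    def test_rectangle_aspect_ten(self):
        m = np.zeros((120, 120), dtype=bool)
        m[10:110, 50:60] = True
        g = streak_geometry(self._state_from_masks(m))
        assert g["aspect_ratio"] == pytest.approx(10.0)
        assert g["aspect_ratio_extent"] == pytest.approx(10.0)

    def test_circle_aspect_one(self):
        yy, xx = np.indices((120, 120))
        m = (yy - 60) ** 2 + (xx - 60) ** 2 <= 35 ** 2
        g = streak_geometry(self._state_from_masks(m))
        assert g["aspect_ratio"] == pytest.approx(1.0, abs=0.02)

    def test_aspect_rotation_invariant(self):
        """A rotated 10:1 rectangle keeps its aspect within 5%."""
        from scipy.ndimage import rotate

        m = np.zeros((160, 160), dtype=bool)
        m[30:130, 75:85] = True
        base = streak_geometry(self._state_from_masks(m))["aspect_ratio"]
        rot = rotate(m.astype(float), 35, reshape=False, order=0) > 0.5
        got = streak_geometry(self._state_from_masks(rot))["aspect_ratio"]
        assert got == pytest.approx(base, rel=0.05)

    def test_tip_attachment_and_split(self):
        s = np.zeros((60, 60), dtype=bool)
        st = np.zeros((60, 60), dtype=bool)
        s[20:30, 20:30] = True
        st[30:34, 22:26] = True          # touching S
        g = streak_geometry(self._state_from_masks(s, st))
        assert g["tip_attached"] and not g["tip_split"]

        st2 = np.zeros((60, 60), dtype=bool)
        st2[40:44, 22:26] = True         # detached by AP gap
        st2[50:54, 40:44] = True         # and split in two
        g2 = streak_geometry(self._state_from_masks(s, st2))
        assert not g2["tip_attached"] and g2["tip_split"]

    def test_no_mesoderm_raises(self):
        owner = np.zeros((20, 20), dtype=np.int32)
        owner[5:10, 5:10] = 1
        with pytest.raises(ValueError):
            streak_geometry(TissueState(owner, [0, 1]))


class TestVortexStrength:
    def _ap_mask(self, shape=(200, 200), r=80):
        yy, xx = np.indices(shape)
        return np.hypot(yy - 100, xx - 100) <= r

    def test_zero_field_grade_none(self):
        tracks = synthetic_tracks(lambda p, t: p, steps=(0, 50))
        vf = velocity_field(tracks, 0, 50, bin_size=20)
        out = vortex_strength(vf, self._ap_mask())
        assert out["fraction"] == 0.0 and out["grade"] == "None"

    def test_whole_ap_rotation_grade_strong(self):
        c = np.array([100.0, 100.0])
        w = 2e-3

        def rot(p, t):
            r = p - c
            a = w * t
            R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
            return c + R @ r

        tracks = synthetic_tracks(rot, n_cells=6000, steps=(0, 10))
        vf = velocity_field(tracks, 0, 10, bin_size=10)
        out = vortex_strength(vf, self._ap_mask())
        assert out["fraction"] > 0.9 and out["grade"] == "Strong"

    def test_half_ap_counter_pair_grade_strong(self):
        """Counter-rotating pair filling about half the AP classifies
        Strong with fraction near 0.5."""
        c1, c2 = np.array([55.0, 100.0]), np.array([145.0, 100.0])
        w = 2e-3

        def pair(p, t):
            v = np.zeros(2)
            for ci, s in ((c1, 1), (c2, -1)):
                r = p - ci
                if np.linalg.norm(r) < 35:
                    v = v + s * w * np.array([-r[1], r[0]])
            return p + v * t

        tracks = synthetic_tracks(pair, n_cells=8000, steps=(0, 10))
        vf = velocity_field(tracks, 0, 10, bin_size=10)
        out = vortex_strength(vf, self._ap_mask())
        assert out["grade"] == "Strong"
        assert 0.25 < out["fraction"] < 0.75


class TestTwoStreakClassifier:
    def _tips(self, fn_a, fn_b, T=40):
        a = np.array([fn_a(t) for t in range(T)], dtype=float)
        b = np.array([fn_b(t) for t in range(T)], dtype=float)
        return a, b

    def test_diverging_headings_repel(self):
        a, b = self._tips(lambda t: (100 - t, 100 - t),
                          lambda t: (100 + t, 100 - t))
        out = classify_two_streak_interaction(a, b, center=(100, 50))
        assert out == "repel"

    def test_converging_merging_attract(self):
        # both curve toward each other much faster than the radial null
        a, b = self._tips(lambda t: (60 + 1.2 * t, 100),
                          lambda t: (140 - 1.2 * t, 100))
        out = classify_two_streak_interaction(a, b, center=(100, 40),
                                              merged=True)
        assert out == "attract/fuse"

    def test_straight_paths_merge_on_contact(self):
        # tips head radially toward the center at their null speed
        center = np.array([100.0, 40.0])
        a0, b0 = np.array([60.0, 100.0]), np.array([140.0, 100.0])

        def toward(p0):
            u = (center - p0) / np.linalg.norm(center - p0)
            return lambda t: tuple(p0 + u * 1.0 * t)

        a, b = self._tips(toward(a0), toward(b0), T=60)
        out = classify_two_streak_interaction(a, b, center=center)
        assert out == "none-until-contact"

    def test_dissolved_tip_unclassifiable(self):
        a, b = self._tips(lambda t: (100, 100 - t), lambda t: (50, 100 - t))
        a[5] = np.nan
        with pytest.raises(ValueError):
            classify_two_streak_interaction(a, b, center=(75, 50))


class TestConvertUnits:
    @pytest.mark.parametrize("kind, value, expected", [
        ("length", 1.0, 10.0),                    # voxel -> um
        ("time", 1.0, 3.0),                       # step -> s
        ("velocity", 1.0, 200.0),                 # voxel/step -> um/min
        ("vorticity", 1.0, 20.0),                 # 1/step -> 1/min
        ("diffusivity", 1.0, 100e-8 / 3.0),       # voxel^2/step -> cm^2/s
        ("velocity", 0.0, 0.0),
    ])
    def test_forward_values(self, kind, value, expected):
        assert convert_units(value, kind) == pytest.approx(expected)

    @pytest.mark.parametrize("kind", ["length", "time", "velocity",
                                      "vorticity", "diffusivity"])
    def test_round_trip_exact(self, kind):
        q = 0.1234
        back = convert_units(convert_units(q, kind), kind, inverse=True)
        assert back == pytest.approx(q, rel=1e-15)

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            convert_units(1.0, "mass")
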