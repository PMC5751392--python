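"""Coarse estimation: NCC, following tracking, level searches, interpolation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ultrastrain.coarse_estimation import (SearchSpec, default_neighborhood,
                                           finalize_lateral, following_track,
                                           interp_grid, level1_search,
                                           level2_search, level3_search, ncc,
                                           reject_outliers)
from ultrastrain.rf_frames import DisplacementGrid, ValidationError

from conftest import envelope_field


def ncc_oracle(A, B, offs_y, offs_x, anchor=(0, 0)):
    """Direct double-loop evaluation of zero-normalized cross-correlation."""
    h, w = A.shape
    out = np.empty((len(offs_y), len(offs_x)))
    for i, dy in enumerate(offs_y):
        for j, dx in enumerate(offs_x):
            P = B[anchor[0] + dy:anchor[0] + dy + h,
                  anchor[1] + dx:anchor[1] + dx + w]
            a = A - A.mean()
            p = P - P.mean()
            out[i, j] = np.sum(a * p) / np.sqrt(np.sum(a * a) * np.sum(p * p))
    return out


class TestNCC:
    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((16, 16))
        B = rng.standard_normal((30, 30))
        offs = np.arange(5)
        surf = ncc(A, B, offs, offs)
        expected = ncc_oracle(A, B, offs, offs)
        assert np.max(np.abs(surf.values - expected)) < 1e-12

    def test_self_match_is_unique_peak_of_one(self):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((8, 8))
        B = np.zeros((16, 16))
        B[:8, :8] = A
        surf = ncc(A, B, np.arange(6), np.arange(6))
        assert surf.values[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert surf.argmax()[:2] == (0, 0)

    def test_detects_embedded_shift(self):
        rng = np.random.default_rng(2)
        A = rng.standard_normal((8, 8))
        B = rng.standard_normal((20, 20)) * 0.01
        B[3:11, 2:10] = A
        surf = ncc(A, B, np.arange(6), np.arange(6))
        dy, dx, peak = surf.argmax()
        assert (dy, dx) == (3, 2)
        assert peak > 0.99

    def test_zero_variance_window_warns_all_nan(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            surf = ncc(np.ones((4, 4)), np.random.default_rng(0).random((8, 8)),
                       np.arange(3), np.arange(3))
        assert np.all(np.isnan(surf.values))

    def test_zero_variance_patch_is_nan_at_that_offset(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((4, 4))
        B = rng.standard_normal((10, 10))
        B[0:4, 0:4] = 5.0                      # constant patch at offset (0,0)
        surf = ncc(A, B, np.arange(3), np.arange(3))
        assert np.isnan(surf.values[0, 0])
        assert np.isfinite(surf.values[1:, 1:]).all()

    def test_offsets_past_region_rejected(self):
        with pytest.raises(ValidationError):
            ncc(np.ones((4, 4)) + np.eye(4), np.zeros((6, 6)),
                np.arange(4), np.arange(1))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_values_bounded_and_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((5, 4))
        B = rng.standard_normal((12, 10))
        surf = ncc(A, B, np.arange(4), np.arange(3))
        finite = surf.values[np.isfinite(surf.values)]
        assert np.all(finite <= 1 + 1e-12) and np.all(finite >= -1 - 1e-12)
        assert np.max(np.abs(surf.values - ncc_oracle(A, B, np.arange(4),
                                                      np.arange(3)))) < 1e-12


def quadratic_eval(peak):
    def f(points):
        return -((points[:, 0] - peak[0]) ** 2.0
                 + (points[:, 1] - peak[1]) ** 2.0)
    return f


class TestFollowingTrack:
    def test_peak_at_init_converges_immediately(self):
        res = following_track(quadratic_eval((0, 0)), (0, 0), (-8, 8, -8, 8))
        assert res.status == "converged"
        assert res.point == (0, 0)
        assert res.steps == 0

    def test_reaches_exhaustive_argmax_on_unimodal_surface(self):
        bounds = (-8, 8, -8, 8)
        res = following_track(quadratic_eval((5, -3)), (0, 0), bounds)
        assert res.point == (5, -3)
        assert res.status == "converged"
        # exhaustive oracle over the same bounds
        pts = np.array([(dy, dx) for dy in range(-8, 9) for dx in range(-8, 9)])
        vals = quadratic_eval((5, -3))(pts)
        assert tuple(pts[np.argmax(vals)]) == res.point

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(-6, 6), st.integers(-6, 6))
    def test_oracle_equivalence_any_peak(self, py, px):
        res = following_track(quadratic_eval((py, px)), (0, 0), (-6, 6, -6, 6))
        assert res.point == (py, px)

    def test_boundary_peak_reports_hit_boundary(self):
        res = following_track(quadratic_eval((12, 0)), (0, 0), (-5, 5, -5, 5))
        assert res.status == "hit_boundary"
        assert res.point == (5, 0)

    def test_init_outside_bounds_rejected(self):
        with pytest.raises(ValidationError):
            following_track(quadratic_eval((0, 0)), (9, 0), (-5, 5, -5, 5))

    def test_max_steps_cap(self):
        res = following_track(quadratic_eval((40, 0)), (-40, 0),
                              (-41, 41, -5, 5), max_steps=3)
        assert res.status == "max_steps"
        assert res.steps == 3


def _shift_field(field, dy, dx):
    return np.roll(field, (dy, dx), axis=(0, 1))


class TestLevelSearches:
    spec1 = SearchSpec(calc_h=12, calc_w=6, search_h=6, search_w=3,
                       depth_growth=0.5)

    def test_level1_no_deformation(self):
        env = envelope_field(160, 40, seed=0)
        g = level1_search(env, env, self.spec1)
        assert np.all(g.axial == 0) and np.all(g.lateral == 0)
        assert g.valid.all()

    def test_level1_global_shift(self):
        env = envelope_field(160, 40, seed=1)
        g = level1_search(env, _shift_field(env, 4, 0), self.spec1)
        assert np.all(g.axial == 4)
        assert np.all(g.lateral == 0)

    def test_level1_frame_too_small(self):
        env = envelope_field(30, 10, seed=2)
        with pytest.raises(ValidationError, match="too small"):
            level1_search(env, env, self.spec1)

    def _grids(self, env, post, spec2=None):
        g1 = level1_search(env, post, self.spec1)
        spec2 = spec2 or SearchSpec(calc_h=8, calc_w=4, search_h=5, search_w=2)
        g2 = level2_search(env, post, g1, spec2, rate=8, rows=5, cols=7)
        return g1, g2

    def test_level2_zero_and_shift(self):
        env = envelope_field(160, 40, seed=3)
        _, g2 = self._grids(env, env)
        assert np.all(g2.axial == 0) and np.all(g2.lateral == 0)
        post = _shift_field(env, 6, 1)
        _, g2s = self._grids(env, post)
        interior = g2s.axial[1:-1, 1:-1]
        assert np.all(interior == 6)
        assert np.all(g2s.lateral[1:-1, 1:-1] == 1)

    def test_level2_requires_enough_valid_windows(self):
        env = envelope_field(160, 40, seed=4)
        g1 = level1_search(env, env, self.spec1)
        g1.valid[:] = False
        g1.valid[0, 0] = True
        with pytest.raises(ValidationError, match="valid"):
            level2_search(env, env, g1, SearchSpec(8, 4, 5, 2), rate=8)

    def test_level3_covers_frame_and_tracks_shift(self):
        env = envelope_field(160, 40, seed=5)
        post = _shift_field(env, 3, 0)
        g1, g2 = self._grids(env, post)
        spec3 = SearchSpec(calc_h=6, calc_w=3, search_h=4, search_w=2)
        g3 = level3_search(env, post, g2, spec3, rate=8, overlap=0.5)
        assert g3.shape[0] >= 2 * g2.shape[0]
        interior = g3.axial[2:-2, 2:-2]
        assert np.all(interior == 3)

    def test_hierarchy_consistency_on_global_shift(self):
        # a shift of 8 finest samples is 1/2/4 samples at rates 8/4/2
        fine = envelope_field(640, 40, seed=6, smooth=6.0)
        post_fine = _shift_field(fine, 8, 0)
        lv = {r: (fine[::r], post_fine[::r]) for r in (8, 4, 2)}
        g1 = level1_search(*lv[8], self.spec1)
        assert np.all(g1.axial == 1)
        g2 = level2_search(*lv[4], g1, SearchSpec(12, 4, 5, 2), rate=4,
                           rows=5, cols=7)
        assert np.all(g2.axial[1:-1, 1:-1] == 2)
        g3 = level3_search(*lv[2], g2, SearchSpec(10, 3, 4, 2), rate=2)
        assert np.all(g3.axial[2:-2, 2:-2] == 4)


class TestFinalizeLateral:
    def _grid(self, lateral):
        r, c = lateral.shape
        return DisplacementGrid(np.zeros((r, c)), lateral, np.arange(r),
                                np.arange(c), np.ones((r, c), bool))

    def test_constant_field_above_threshold_is_kept(self):
        lat = np.full((4, 21), 2.0)
        out = finalize_lateral(self._grid(lat), 7, 2, 0.25)
        assert np.allclose(out, 2.0, atol=1e-10)

    def test_zero_field_stays_zero(self):
        out = finalize_lateral(self._grid(np.zeros((4, 21))), 7, 2, 0.25)
        assert np.all(out == 0.0)

    def test_linear_ramp_preserved(self):
        ramp = np.tile(np.linspace(1, 3, 21), (4, 1))
        out = finalize_lateral(self._grid(ramp), 7, 2, 0.25)
        assert np.allclose(out, ramp, atol=1e-10)

    def test_subthreshold_region_zeroed(self):
        lat = np.full((4, 21), 0.1)
        lat[:, 10:] = 1.0
        out = finalize_lateral(self._grid(lat), 5, 1, 0.25)
        assert np.all(out[:, :6] == 0.0)
        assert np.all(out[:, 14:] != 0.0)

    def test_invalid_filter_params_rejected(self):
        g = self._grid(np.zeros((4, 21)))
        with pytest.raises(ValidationError):
            finalize_lateral(g, 8, 2, 0.25)    # even window
        with pytest.raises(ValidationError):
            finalize_lateral(g, 3, 5, 0.25)    # order >= window


class TestInterpGrid:
    def _grid(self, axial, lateral=None):
        r, c = axial.shape
        return DisplacementGrid(axial, lateral if lateral is not None
                                else np.zeros((r, c)),
                                np.arange(r) * 10.0, np.arange(c) * 5.0,
                                np.ones((r, c), bool))

    def test_identity_at_source_centers(self):
        rng = np.random.default_rng(0)
        g = self._grid(rng.standard_normal((4, 4)))
        out = interp_grid(g, g.centers_axial, g.centers_lateral)
        assert np.allclose(out.axial, g.axial, atol=1e-12)

    def test_constant_grid_everywhere(self):
        g = self._grid(np.full((3, 3), 7.0))
        out = interp_grid(g, [2.0, 17.0], [1.0, 12.0], scale_axial=2.0)
        assert np.allclose(out.axial, 14.0)

    def test_plane_reproduced_exactly_at_midpoints(self):
        rows = np.arange(4) * 10.0
        cols = np.arange(4) * 5.0
        plane = 2.0 * rows[:, None] + 3.0 * cols[None, :]
        g = self._grid(plane)
        mid_r = (rows[:-1] + rows[1:]) / 2
        mid_c = (cols[:-1] + cols[1:]) / 2
        out = interp_grid(g, mid_r, mid_c)
        expected = 2.0 * mid_r[:, None] + 3.0 * mid_c[None, :]
        assert np.allclose(out.axial, expected, atol=1e-10)

    def test_empty_grid_rejected(self):
        g = self._grid(np.zeros((2, 2)))
        g.axial = np.zeros((0, 0))
        with pytest.raises(ValidationError):
            interp_grid(g, [0.0], [0.0])


class TestRejectOutliers:
    def test_isolated_outlier_replaced_by_neighbour_median(self):
        axial = np.full((5, 5), 3.0)
        axial[2, 2] = 50.0
        g = DisplacementGrid(axial, np.zeros((5, 5)), np.arange(5),
                             np.arange(5), np.ones((5, 5), bool))
        out = reject_outliers(g, limit_axial=2.0, limit_lateral=1.0)
        assert out.axial[2, 2] == 3.0
        assert not out.valid[2, 2]
        assert out.valid.sum() == 24
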