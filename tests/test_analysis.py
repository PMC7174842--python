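import numpy as np
import pytest

from dotstripe.analysis import (
    AnalysisError,
    classify_pattern,
    count_transverse_joints,
    dominant_orientation,
    estimate_wavelength,
    find_dot_maxima,
    joint_positions_profile,
    mean_ridge_curvature,
    voronoi_agreement,
)
from dotstripe.geometry import DigitGeometry, GridSpec, build_digit_mask, full_masks

from conftest import gaussian_bump


class TestFindDotMaxima:
    def test_single_gaussian_single_peak(self, square_grid):
        masks = full_masks(square_grid)
        f = gaussian_bump(square_grid.shape, 64, 64, width=4.0)
        pts = find_dot_maxima(f, masks, min_prominence=0.1)
        assert len(pts) == 1
        assert tuple(pts[0]) == (64, 64)

    def test_constant_field_no_peaks(self, square_grid):
        masks = full_masks(square_grid)
        assert len(find_dot_maxima(np.ones(square_grid.shape), masks, 0.1)) == 0

    def test_two_gaussians_found_within_one_bin(self, square_grid):
        masks = full_masks(square_grid)
        f = gaussian_bump(square_grid.shape, 60, 50, 2.0) + gaussian_bump(
            square_grid.shape, 60, 60, 2.0
        )
        pts = find_dot_maxima(f, masks, min_prominence=0.1)
        assert len(pts) == 2
        got = sorted(tuple(p) for p in pts)
        for (gy, gx), (ey, ex) in zip(got, [(60, 50), (60, 60)]):
            assert abs(gy - ey) <= 1 and abs(gx - ex) <= 1

    def test_plateau_collapses_to_centroid(self, square_grid):
        masks = full_masks(square_grid)
        f = np.zeros(square_grid.shape)
        f[50:53, 70:73] = 1.0  # 3x3 flat plateau
        pts = find_dot_maxima(f, masks, min_prominence=0.5)
        assert len(pts) == 1
        assert tuple(pts[0]) == (51, 71)


def paint_square_lattice_edges(shape, origin, spacing, offset):
    """1-bin-wide lines on the Voronoi-edge grid of a square dot lattice."""
    f = np.zeros(shape)
    e = origin + offset + spacing / 2
    for y in range(shape[0]):
        for x in range(shape[1]):
            dx = min((x - e) % spacing, spacing - (x - e) % spacing)
            dy = min((y - e) % spacing, spacing - (y - e) % spacing)
            if min(dx, dy) < 0.5:
                f[y, x] = 1.0
    return f


class TestVoronoiAgreement:
    GRID = GridSpec(64, 64, 1.0)
    PTS = np.array([(y, x) for y in range(7, 64, 10) for x in range(7, 64, 10)], float)

    def test_painting_on_true_edges_scores_near_zero(self):
        masks = full_masks(self.GRID)
        f = paint_square_lattice_edges(self.GRID.shape, 7, 10, 0.0)
        s = voronoi_agreement(self.PTS, f, masks, wavelength=10.0, grid=self.GRID)
        assert s < 0.02

    def test_half_cell_shift_scores_large(self):
        # stripe ridges painted on a half-cell-shifted edge grid run through
        # the dots; frozen value 0.30 from the direct distance computation on
        # this construction (idealized infinite-lattice median is 0.20; the
        # finite 6x6 lattice's outer ridges push it up)
        masks = full_masks(self.GRID)
        f = paint_square_lattice_edges(self.GRID.shape, 7, 10, 5.0)
        s = voronoi_agreement(self.PTS, f, masks, wavelength=10.0, grid=self.GRID)
        assert s == pytest.approx(0.30, abs=0.1)

    def test_collinear_points_rejected(self):
        masks = full_masks(self.GRID)
        pts = np.array([(10.0, 10.0), (10.0, 20.0), (10.0, 30.0)])
        with pytest.raises(AnalysisError, match="collinear"):
            voronoi_agreement(pts, np.ones(self.GRID.shape), masks, 10.0, self.GRID)

    def test_rigid_rotation_invariance(self):
        # rotating points and field together by 90 deg leaves the score
        masks = full_masks(self.GRID)
        f = paint_square_lattice_edges(self.GRID.shape, 7, 10, 0.0)
        s0 = voronoi_agreement(self.PTS, f, masks, 10.0, self.GRID)
        f90 = np.rot90(f)
        n = self.GRID.ny
        pts90 = np.array([(n - 1 - x, y) for y, x in self.PTS], float)
        s90 = voronoi_agreement(pts90, f90, masks, 10.0, self.GRID)
        assert s90 == pytest.approx(s0, abs=0.01)


class TestWavelength:
    def test_cosine_period_recovered(self, square_grid):
        masks = full_masks(square_grid)
        X = np.arange(square_grid.nx)
        f = np.tile(np.cos(2 * np.pi * X / 8.0), (square_grid.ny, 1))
        lam = estimate_wavelength(f, masks, h=1.0)
        assert 7.5 <= lam <= 8.5

    def test_white_noise_has_no_dominant_scale(self, square_grid, rng):
        masks = full_masks(square_grid)
        with pytest.raises(AnalysisError, match="no dominant scale"):
            estimate_wavelength(rng.normal(size=square_grid.shape), masks)

    def test_amplitude_and_offset_invariance(self, square_grid):
        masks = full_masks(square_grid)
        X = np.arange(square_grid.nx)
        f = np.tile(np.cos(2 * np.pi * X / 8.0), (square_grid.ny, 1))
        lam1 = estimate_wavelength(f, masks)
        lam2 = estimate_wavelength(5.0 * f + 3.0, masks)
        assert lam1 == lam2


class TestOrientation:
    def _bands(self, shape, angle_deg, period=8.0):
        ny, nx = shape
        Y, X = np.mgrid[0:ny, 0:nx]
        th = np.radians(angle_deg)
        # ridges run along `angle_deg`; the wave vector is perpendicular
        phase = X * np.sin(th) - Y * np.cos(th)
        return np.cos(2 * np.pi * phase / period)

    @pytest.mark.parametrize("angle, tol", [(90, 2), (0, 2), (45, 3)])
    def test_known_band_angles(self, square_grid, angle, tol):
        masks = full_masks(square_grid)
        f = self._bands(square_grid.shape, angle)
        assert dominant_orientation(f, masks) == pytest.approx(angle, abs=tol)

    def test_isotropic_field_rejected(self, square_grid, rng):
        masks = full_masks(square_grid)
        blob = gaussian_bump(square_grid.shape, 64, 64, width=20.0)
        with pytest.raises(AnalysisError, match="orientation"):
            dominant_orientation(blob, masks)


class TestJointCount:
    GRID = GridSpec(64, 32, 1.0)

    def _digit(self):
        geom = DigitGeometry(L0=40, L=40, W=10, eps=5, anchor=(8.0, 16.0))
        return build_digit_mask(geom, self.GRID, 40.0)

    def _with_bands(self, xs, half=False):
        masks = self._digit()
        f = np.zeros(self.GRID.shape)
        for i, x in enumerate(xs):
            sel = masks.omega.copy()
            if half and i == len(xs) - 1:
                sel[:16] = False  # half-width blob only
                f[sel & (np.abs(np.arange(64) - x)[None, :] < 1.5)] = 1.0
            else:
                f[masks.omega & (np.abs(np.arange(64) - x)[None, :] < 1.5)] = 1.0
        return f, masks

    def test_three_full_bands(self):
        f, masks = self._with_bands([15, 25, 35])
        assert count_transverse_joints(f, masks, self.GRID) == 3

    def test_half_width_blob_not_counted(self):
        f, masks = self._with_bands([15, 25, 40], half=True)
        assert count_transverse_joints(f, masks, self.GRID) == 2

    def test_uniform_field_counts_zero(self):
        masks = self._digit()
        assert count_transverse_joints(np.ones(self.GRID.shape), masks, self.GRID) == 0

    def test_profile_positions_match_band_centres(self):
        f, masks = self._with_bands([15, 25, 35])
        xs = joint_positions_profile(f, masks)
        assert len(xs) == 3
        assert np.allclose(sorted(xs), [15.5, 25.5, 35.5], atol=1.0)


class TestClassifyPattern:
    def test_separated_bumps_are_dots(self, square_grid):
        masks = full_masks(square_grid)
        f = sum(
            gaussian_bump(square_grid.shape, y, x, 3.0)
            for y in range(16, 128, 32)
            for x in range(16, 128, 32)
        )
        assert classify_pattern(f, masks) == "dots"

    def test_negated_bumps_are_holes(self, square_grid):
        masks = full_masks(square_grid)
        f = sum(
            gaussian_bump(square_grid.shape, y, x, 3.0)
            for y in range(16, 128, 32)
            for x in range(16, 128, 32)
        )
        assert classify_pattern(-f, masks) == "holes"

    def test_parallel_bands_are_stripes(self, square_grid):
        masks = full_masks(square_grid)
        X = np.arange(square_grid.nx)
        f = np.tile(np.cos(2 * np.pi * X / 16.0), (square_grid.ny, 1))
        assert classify_pattern(f, masks) == "stripes"

    def test_edge_network_is_lattice(self, square_grid):
        # painted cell-edge network: one connected component enclosing many
        # cells; oracle: Euler characteristic of the construction is
        # 1 - n_cells, i.e. holes = n_cells >= 3
        from skimage.measure import euler_number

        masks = full_masks(square_grid)
        f = paint_square_lattice_edges(square_grid.shape, 0, 16, 0.0)
        wide = np.zeros(square_grid.shape)
        wide[f > 0] = 1.0
        from scipy import ndimage

        wide = ndimage.binary_dilation(wide, iterations=1).astype(float)
        assert 1 - euler_number(wide > 0.5, connectivity=2) >= 3
        assert classify_pattern(wide, masks) == "lattice"

    def test_constant_field_is_none(self, square_grid):
        masks = full_masks(square_grid)
        assert classify_pattern(np.full(square_grid.shape, 2.0), masks) == "none"

    def test_invariance_to_offset_and_scale(self, square_grid):
        masks = full_masks(square_grid)
        f = sum(
            gaussian_bump(square_grid.shape, y, x, 3.0)
            for y in range(16, 128, 32)
            for x in range(16, 128, 32)
        )
        assert classify_pattern(3.0 * f + 7.0, masks) == classify_pattern(f, masks)


class TestRidgeCurvature:
    def test_straight_bands_score_below_rings(self, square_grid):
        masks = full_masks(square_grid)
        X = np.arange(square_grid.nx)
        straight = np.tile(np.cos(2 * np.pi * X / 16.0), (square_grid.ny, 1))
        Y, Xg = np.mgrid[0 : square_grid.ny, 0 : square_grid.nx]
        r = np.hypot(Y - 64, Xg - 64)
        rings = np.cos(2 * np.pi * r / 16.0)
        assert mean_ridge_curvature(straight, masks) < mean_ridge_curvature(rings, masks)
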