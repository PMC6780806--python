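"""Depth from defocus: per-plane measurement, profile intersections,
sharpness judgement, the depth equation, and the iterative estimator."""

import numpy as np
import pytest

from favf.errors import (
    DegenerateGeometryError,
    EstimationError,
    InvalidParameterError,
    NegativeBlurError,
    NoCellError,
)
from favf.imaging_model import CellSpec, OpticsConfig, gaussian_psf, model_blur_diameter
from favf.depth_mdfd import (
    MdfdConfig,
    PGDC,
    contrast,
    depth_from_defocus,
    extract_cell_region,
    extract_pgdc,
    fit_blur_linearity,
    focused_diameter,
    kmeans_segment,
    make_cell_stack_provider,
    mdfd_estimate,
    measure_blur,
    preprocess_roi,
    relative_error,
    run_error_sweep,
    sharpness_judgement,
)


def disc_image(shape=(64, 64), cx=32, cy=32, r=20, hi=180.0, lo=8.0):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    img = np.full(shape, lo)
    img[(xx - cx) ** 2 + (yy - cy) ** 2 <= r**2] = hi
    return img


class TestPreprocess:
    def test_rgb_collapses_to_single_channel(self, rng):
        out = preprocess_roi(rng.uniform(0, 255, size=(20, 30, 3)))
        assert out.shape == (20, 30)

    def test_constant_image_unchanged(self):
        out = preprocess_roi(np.full((15, 15), 37.0), sigma=1.5)
        assert np.allclose(out, 37.0)

    def test_smoothing_reduces_salt_noise(self, rng):
        img = np.zeros((30, 30))
        img[15, 15] = 255.0
        assert preprocess_roi(img, sigma=1.0).max() < 255.0


class TestKmeans:
    def test_three_levels_recovered_exactly(self):
        img = np.zeros((30, 30))
        img[:10] = 0.0
        img[10:20] = 100.0
        img[20:] = 200.0
        res = kmeans_segment(img, 3)
        assert res.k_used == 3 and not res.reduced
        assert np.all(res.labels[:10] == 0)
        assert np.all(res.labels[10:20] == 1)
        assert np.all(res.labels[20:] == 2)

    def test_binary_image_with_k2(self):
        img = disc_image()
        res = kmeans_segment(img, 2)
        assert res.k_used == 2
        assert np.array_equal(res.labels == 1, img > 100)

    def test_fewer_values_than_k_reduces(self):
        res = kmeans_segment(np.full((10, 10), 5.0), 3)
        assert res.reduced and res.k_used == 1


class TestCellRegion:
    def test_disc_hull_is_disc(self):
        res = kmeans_segment(disc_image(), 2)
        mask = extract_cell_region(res)
        want = disc_image() > 100
        assert (mask & ~want).sum() <= mask.sum() * 0.05
        assert (want & ~mask).sum() == 0

    def test_speck_removed(self):
        img = disc_image()
        img[2, 2] = 180.0  # 1-px speck
        mask = extract_cell_region(kmeans_segment(img, 2))
        assert not mask[2, 2]

    def test_empty_foreground_raises(self):
        with pytest.raises(NoCellError):
            extract_cell_region(np.zeros((10, 10), dtype=int))

    def test_hull_closes_concavities(self):
        img = disc_image()
        # carve a wedge out of the disc: the hull must close it
        img[28:36, 32:52] = 8.0
        mask = extract_cell_region(kmeans_segment(img, 2))
        assert mask[32, 40]


class TestMeasureBlur:
    def test_disc_center_and_width(self):
        img = disc_image(cx=30, cy=34, r=20)
        mask = img > 100
        m = measure_blur(mask, img)
        assert m.center[0] == pytest.approx(30, abs=0.5)
        assert m.center[1] == pytest.approx(34, abs=0.5)
        assert m.D_n == pytest.approx(40, abs=1.5)

    def test_translation_equivariance(self):
        a = measure_blur(disc_image(cx=28, cy=28) > 100, disc_image(cx=28, cy=28))
        b = measure_blur(disc_image(cx=34, cy=31) > 100, disc_image(cx=34, cy=31))
        assert b.center[0] - a.center[0] == pytest.approx(6, abs=0.5)
        assert b.center[1] - a.center[1] == pytest.approx(3, abs=0.5)

    def test_measured_width_tracks_blur_model(self, optics):
        """Rendered cell at 12 µm defocus: measured diameter within 10% of
        the analytic blur law."""
        from favf.depth_mdfd import _measure_plane

        provider = make_cell_stack_provider(0.0, optics, noise=False)
        res = _measure_plane(provider(12.0), MdfdConfig())
        cell = CellSpec(id=0, x=0, y=0, z=12.0)
        model = model_blur_diameter(cell, optics)
        assert res[0].D_n == pytest.approx(model / optics.pixel_size, rel=0.10)

    def test_empty_mask_raises(self):
        with pytest.raises(NoCellError):
            measure_blur(np.zeros((10, 10), dtype=bool), np.zeros((10, 10)))


class TestPgdcAndContrast:
    def test_profile_length_is_roi_width(self, rng):
        g = rng.uniform(0, 255, (20, 33))
        assert extract_pgdc(g, (16.0, 10.0)).profile.size == 33

    def test_symmetric_cell_symmetric_profile(self):
        img = disc_image(cx=32, cy=32)
        p = extract_pgdc(img, (32.0, 32.0)).profile
        for k in range(1, 31):  # mirror symmetry about the cell centre
            assert p[32 - k] == p[32 + k]

    def test_center_outside_rejected(self):
        with pytest.raises(InvalidParameterError):
            extract_pgdc(np.zeros((10, 10)), (20.0, 5.0))

    def test_contrast_of_flat_profile_is_zero(self):
        assert contrast(np.full(20, 9.0)) == 0.0

    def test_contrast_is_range(self):
        p = np.linspace(12, 200, 50)
        assert contrast(p) == pytest.approx(188.0)

    def test_focus_has_highest_contrast(self, optics_noise_free):
        from favf.depth_mdfd import _measure_plane

        provider = make_cell_stack_provider(0.0, optics_noise_free, noise=False)
        cfg = MdfdConfig()
        c0 = _measure_plane(provider(0.0), cfg)[0].contrast_c
        c10 = _measure_plane(provider(10.0), cfg)[0].contrast_c
        assert c0 > c10


class TestSharpnessJudgement:
    def test_monotone_rise_means_toward(self):
        res = sharpness_judgement([50.0, 80.0, 120.0])
        assert res.direction == "toward" and not res.screened

    def test_interior_maximum_is_screened(self):
        res = sharpness_judgement([80.0, 120.0, 85.0])
        assert res.screened and res.bracket == (0, 2)

    def test_monotone_fall_means_away(self):
        res = sharpness_judgement([120.0, 80.0, 50.0])
        assert res.direction == "away" and not res.screened

    def test_short_series_rejected(self):
        with pytest.raises(InvalidParameterError):
            sharpness_judgement([1.0, 2.0])

    def test_focus_threshold_sets_focused_at(self):
        res = sharpness_judgement([50.0, 120.0, 80.0], focus_threshold=100.0)
        assert res.focused_at == 1


class TestFocusedDiameter:
    @staticmethod
    def box_profile(width, sigma, n=101):
        """Analytic fixture: centred box of given width spread by a
        unit-sum Gaussian."""
        box = np.zeros(n)
        c = n // 2
        box[c - width // 2 : c + width // 2 + 1] = 100.0
        kernel = gaussian_psf(sigma)[gaussian_psf(sigma).shape[0] // 2]
        kernel = kernel / kernel.sum()
        return np.convolve(box, kernel, mode="same")

    def test_box_profiles_intersect_at_box_width(self):
        w = 31
        p1 = self.box_profile(w, 2.0)
        p2 = self.box_profile(w, 5.0)
        d = focused_diameter([p1, p2], center_x=50.0, min_value=5.0)
        assert d == pytest.approx(w, abs=1.0)

    def test_identical_profiles_raise(self):
        p = self.box_profile(21, 3.0)
        with pytest.raises(EstimationError):
            focused_diameter([p, p.copy()], center_x=50.0)

    def test_three_planes_average(self):
        w = 25
        ps = [self.box_profile(w, s) for s in (1.5, 3.0, 6.0)]
        d = focused_diameter(ps, center_x=50.0, min_value=5.0)
        assert d == pytest.approx(w, abs=1.5)

    def test_simulated_cell_recovers_focused_diameter(self, optics_noise_free):
        from favf.depth_mdfd import _align_profiles, _measure_plane

        provider = make_cell_stack_provider(0.0, optics_noise_free, noise=False)
        cfg = MdfdConfig()
        res = [_measure_plane(provider(z), cfg) for z in (6.0, 12.0, 18.0)]
        aligned, _ = _align_profiles([r[1] for r in res])
        d = focused_diameter(
            aligned,
            center_x=(aligned[0].size - 1) / 2.0,
            min_value=min(r[3] for r in res),
        )
        assert d == pytest.approx(16.0 / optics_noise_free.pixel_size, rel=0.10)


class TestDepthEquation:
    def test_worked_example(self):
        assert depth_from_defocus(10.0, 16.0, 20.0, 6.0) == pytest.approx(9.0)

    def test_in_focus_gives_zero(self):
        assert depth_from_defocus(12.0, 12.0, 15.0, 6.0) == 0.0

    def test_equal_diameters_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            depth_from_defocus(10.0, 16.0, 16.0, 6.0)

    def test_blur_below_focused_rejected(self):
        with pytest.raises(NegativeBlurError):
            depth_from_defocus(16.0, 12.0, 18.0, 6.0)

    def test_inverts_analytic_blur_law_exactly(self, optics):
        """With diameters from the closed-form blur law (no measurement)
        the equation recovers the true depth to machine precision."""
        alpha = optics.blur_slope * optics.pixel_size
        D = 16.0
        for z in (3.0, 7.5, 12.0, 19.0):
            for d in (2.0, 6.0, 11.0):
                d_n = depth_from_defocus(D, D + alpha * z, D + alpha * (z + d), d)
                assert d_n == pytest.approx(z, abs=1e-12)


class TestRelativeError:
    def test_zero_when_exact(self):
        assert relative_error(10.0, 10.0, 12.0) == 0.0

    def test_worked_examples(self):
        assert relative_error(20.0, 18.0, 12.0) == pytest.approx(6.25)
        assert relative_error(12.0, 10.0, 10.0) == pytest.approx(100.0 / 11.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(InvalidParameterError):
            relative_error(0.0, 1.0, 0.0)


class TestIterativeEstimator:
    def test_noise_free_convergence(self, optics_noise_free):
        provider = make_cell_stack_provider(10.0, optics_noise_free, noise=False)
        est = mdfd_estimate(provider, d=6.0)
        assert est.status == "focused"
        assert est.iterations <= 3
        assert relative_error(est.d_n, 10.0, est.D) < 5.0

    def test_in_focus_cell_immediately_focused(self, optics_noise_free):
        provider = make_cell_stack_provider(0.0, optics_noise_free, noise=False)
        est = mdfd_estimate(provider, d=6.0)
        assert est.status == "focused"
        assert abs(est.d_n) <= 1.5

    def test_negative_depth_recovered_with_sign(self, optics):
        provider = make_cell_stack_provider(-9.0, optics, seed=5)
        est = mdfd_estimate(provider, d=6.0)
        assert est.status == "focused"
        assert est.d_n == pytest.approx(-9.0, abs=1.0)

    def test_cell_beyond_range_is_out_of_range(self, optics):
        provider = make_cell_stack_provider(50.0, optics, seed=2)
        est = mdfd_estimate(provider, d=6.0)
        assert est.status == "out_of_range"
        assert abs(est.d_n) > optics.valid_depth_range


class TestErrorSweep:
    def test_oor_when_sweep_exits_range(self, optics):
        errors, oor = run_error_sweep(optics, [36.0], [12.0], n_cells=2, seed=1)
        assert np.isnan(errors.loc[36.0, 12.0])
        assert oor.loc[36.0, 12.0] == 1.0

    def test_empty_grid_rejected(self, optics):
        with pytest.raises(InvalidParameterError):
            run_error_sweep(optics, [], [6.0])


class TestLinearityFit:
    def test_exact_line(self):
        pts = [(x, 2.0 * x + 3.0) for x in (0.0, 1.0, 2.0, 5.0)]
        slope, intercept, r2 = fit_blur_linearity(pts)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(3.0)
        assert r2 == pytest.approx(1.0)

    def test_pure_noise_has_low_r2(self, rng):
        pts = [(float(x), float(rng.uniform(0, 100))) for x in range(30)]
        assert fit_blur_linearity(pts)[2] < 0.3

    def test_degenerate_depths_rejected(self):
        with pytest.raises(InvalidParameterError):
            fit_blur_linearity([(1.0, 2.0), (1.0, 3.0), (1.0, 4.0)])
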