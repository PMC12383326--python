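"""Lorentzian bands, NBI-like rendering, illuminant optimization."""

import numpy as np
import pytest

import specsave as ss
from specsave import fixtures as fx
from specsave.nbi import (
    BandIlluminant,
    LorentzBand,
    default_bounds,
    default_nbi_bands,
    lorentz_profile,
    make_band_illuminant,
    optimize_illuminant,
    render_band_image,
    render_patch_labs,
    render_save_image,
)
from specsave.spectral import Hypercube


class TestLorentzProfile:
    def test_peak_value(self):
        for gamma in (1.0, 7.5, 30.0):
            assert lorentz_profile(500.0, 500.0, gamma) == pytest.approx(
                1.0 / (np.pi * gamma), rel=1e-12
            )

    def test_half_maximum_at_gamma(self):
        x0, gamma = 415.0, 15.0
        half = 0.5 / (np.pi * gamma)
        assert lorentz_profile(x0 + gamma, x0, gamma) == pytest.approx(half, rel=1e-12)
        assert lorentz_profile(x0 - gamma, x0, gamma) == pytest.approx(half, rel=1e-12)

    def test_truncated_integral_closed_form(self):
        # integral over x0 +- 50*gamma equals (2/pi) * arctan(50)
        x0, gamma = 540.0, 10.0
        x = np.linspace(x0 - 50 * gamma, x0 + 50 * gamma, 400001)
        integral = np.trapezoid(lorentz_profile(x, x0, gamma), x)
        assert integral == pytest.approx(2.0 / np.pi * np.arctan(50.0), abs=1e-6)

    def test_nonpositive_gamma_rejected(self):
        with pytest.raises(ValueError):
            lorentz_profile(500.0, 500.0, 0.0)


class TestMakeBandIlluminant:
    def test_single_band_peak_normalized_at_center(self, grid):
        ill = make_band_illuminant([LorentzBand(540.0, 10.0)], grid)
        assert ill.power.max() == pytest.approx(1.0)
        assert grid.wavelengths[np.argmax(ill.power)] == 540.0

    def test_two_far_bands_equal_peaks(self, grid):
        ill = make_band_illuminant(
            [LorentzBand(420.0, 5.0), LorentzBand(740.0, 5.0)], grid
        )
        p420 = ill.power[grid.wavelengths == 420.0][0]
        p740 = ill.power[grid.wavelengths == 740.0][0]
        assert p420 == pytest.approx(p740, abs=1e-6)

    def test_composition_matches_profile_sum(self, grid):
        bands = default_nbi_bands()
        ill = make_band_illuminant(bands, grid)
        w = grid.wavelengths
        oracle = sum(b.weight * lorentz_profile(w, b.center_nm, b.gamma_nm) for b in bands)
        oracle = oracle / oracle.max()
        assert np.max(np.abs(ill.power - oracle)) < 1e-12

    def test_weight_scale_invariance(self, grid):
        bands = default_nbi_bands()
        doubled = [LorentzBand(b.center_nm, b.gamma_nm, 2 * b.weight) for b in bands]
        assert np.max(
            np.abs(
                make_band_illuminant(bands, grid).power
                - make_band_illuminant(doubled, grid).power
            )
        ) < 1e-9

    def test_all_zero_weights_rejected(self, grid):
        with pytest.raises(ValueError):
            make_band_illuminant([LorentzBand(415.0, 15.0, 0.0)], grid)


class TestRenderBandImage:
    def test_perfect_reflector_gives_ones(self, grid):
        cube = Hypercube(grid=grid, values=np.ones((3, 4, len(grid))))
        band = make_band_illuminant([LorentzBand(415.0, 15.0)], grid)
        assert np.allclose(render_band_image(cube, band), 1.0)

    def test_black_cube_gives_zeros(self, grid):
        cube = Hypercube(grid=grid, values=np.zeros((3, 4, len(grid))))
        band = make_band_illuminant([LorentzBand(415.0, 15.0)], grid)
        assert np.allclose(render_band_image(cube, band), 0.0)

    def test_single_pixel_weighted_mean(self, grid, rng):
        refl = rng.random(len(grid))
        cube = Hypercube(grid=grid, values=refl[None, None, :])
        band = make_band_illuminant([LorentzBand(540.0, 10.0)], grid)
        expected = float(band.power @ refl / band.power.sum())
        assert render_band_image(cube, band)[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_grid_mismatch_rejected(self, grid):
        cube = Hypercube(grid=grid, values=np.ones((2, 2, len(grid))))
        other = ss.WavelengthGrid(380, 780, 5)
        band = make_band_illuminant([LorentzBand(540.0, 10.0)], other)
        with pytest.raises(ValueError):
            render_band_image(cube, band)


class TestRenderSaveImage:
    def test_grey_cube_renders_grey(self, grid):
        cube = Hypercube(grid=grid, values=np.full((4, 4, len(grid)), 0.37))
        img = render_save_image(cube, BandIlluminant(grid=grid))
        spread = img.astype(int).max(axis=2) - img.astype(int).min(axis=2)
        assert spread.max() <= 1

    def test_vessel_pixels_darker_in_all_channels(self, grid):
        phantom = fx.generate_vessel_phantom(64, 64, dip_depth=0.5, seed=2, grid=grid)
        img = render_save_image(phantom.cube, BandIlluminant(grid=grid))
        m = phantom.vessel_mask
        for c in range(3):
            assert img[m, c].mean() < img[~m, c].mean()

    def test_channel_map_permutation_equivariance(self, grid, rng):
        cube = Hypercube(grid=grid, values=rng.random((5, 5, len(grid))))
        base = render_save_image(cube, BandIlluminant(grid=grid))
        permuted = render_save_image(
            cube,
            BandIlluminant(grid=grid, channel_map={0: ("R", "G"), 1: ("B",)}),
        )
        # 415 output moves G,B -> R,G and 540 moves R -> B
        assert np.array_equal(permuted[..., 0], base[..., 1])
        assert np.array_equal(permuted[..., 2], base[..., 0])

    def test_channel_map_referencing_absent_band_rejected(self, grid):
        with pytest.raises(ValueError, match="absent band"):
            BandIlluminant(grid=grid, channel_map={5: ("R",)})


class TestOptimizeIlluminant:
    def test_recovers_known_bands(self, color_set, grid, cmf, white):
        spectra, _ = color_set
        target = render_patch_labs(spectra, default_nbi_bands(), grid, cmf, white)
        res = optimize_illuminant(
            spectra, target, grid, cmf, white, seed=7, max_evals=2000
        )
        assert res.objective <= 0.05
        centers = sorted(b.center_nm for b in res.bands)
        assert abs(centers[0] - 415.0) < 2.0
        assert abs(centers[1] - 540.0) < 2.0
        assert res.n_evaluations >= 2000

    def test_collapsed_bounds_return_the_point(self, color_set, grid, cmf, white):
        spectra, _ = color_set
        point = np.array([415.0, 15.0, 1.0, 540.0, 10.0, 1.0])
        bounds = np.stack([point, point], axis=1)
        target = render_patch_labs(spectra, default_nbi_bands(), grid, cmf, white)
        res = optimize_illuminant(spectra, target, grid, cmf, white, bounds=bounds)
        assert np.array_equal(res.best_params, point)
        direct = float(
            np.mean(
                ss.ciede2000(
                    render_patch_labs(spectra, res.bands, grid, cmf, white), target
                )
            )
        )
        assert res.objective == pytest.approx(direct, abs=1e-12)

    def test_reported_objective_matches_reevaluation(self, color_set, grid, cmf, white):
        spectra, _ = color_set
        target = render_patch_labs(
            spectra, [LorentzBand(420.0, 12.0), LorentzBand(535.0, 14.0)], grid, cmf, white
        )
        res = optimize_illuminant(
            spectra, target, grid, cmf, white, seed=3, max_evals=300
        )
        labs = render_patch_labs(spectra, res.bands, grid, cmf, white)
        assert res.objective == pytest.approx(
            float(np.mean(ss.ciede2000(labs, target))), abs=1e-9
        )

    def test_objective_invariant_to_patch_order(self, color_set, grid, cmf, white, rng):
        spectra, _ = color_set
        target = render_patch_labs(spectra, default_nbi_bands(), grid, cmf, white)
        perm = rng.permutation(len(spectra))
        point = default_bounds()[:, 0]
        bounds = np.stack([point, point], axis=1)
        r1 = optimize_illuminant(spectra, target, grid, cmf, white, bounds=bounds)
        r2 = optimize_illuminant(
            spectra[perm], target[perm], grid, cmf, white, bounds=bounds
        )
        assert r1.objective == pytest.approx(r2.objective, abs=1e-12)

    def test_best_so_far_non_increasing_in_evaluations(self, color_set, grid, cmf, white):
        spectra, _ = color_set
        target = render_patch_labs(spectra, default_nbi_bands(), grid, cmf, white)
        objectives = [
            optimize_illuminant(
                spectra, target, grid, cmf, white, seed=11, max_evals=n
            ).objective
            for n in (50, 400, 2000)
        ]
        assert objectives[0] >= objectives[1] >= objectives[2] - 1e-12

    def test_empty_bounds_rejected(self, color_set, grid, cmf, white):
        spectra, _ = color_set
        bad = default_bounds()
        bad[0] = (500.0, 400.0)
        with pytest.raises(ValueError, match="bounds"):
            optimize_illuminant(spectra, np.zeros((len(spectra), 3)), grid, cmf, white,
                                bounds=bad)
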