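"""Color-science primitives: sRGB curve, XYZ integration, Lab, CIEDE2000."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import specsave as ss
from specsave.colorimetry import (
    CMFTable,
    IlluminantSpectrum,
    WavelengthGrid,
    lab_to_xyz,
    srgb_decode,
    srgb_encode,
)

# Published CIEDE2000 reference pair set (Sharma, Wu & Dalal 2005):
# (Lab1, Lab2, expected dE00). Expected values cross-checked against an
# independent oracle implementation.
CIEDE2000_REFERENCE = [
    ((50, 2.6772, -79.7751), (50, 0, -82.7485), 2.0425),
    ((50, 3.1571, -77.2803), (50, 0, -82.7485), 2.8615),
    ((50, 2.8361, -74.0200), (50, 0, -82.7485), 3.4412),
    ((50, -1.3802, -84.2814), (50, 0, -82.7485), 1.0000),
    ((50, -1.1848, -84.8006), (50, 0, -82.7485), 1.0000),
    ((50, -0.9009, -85.5211), (50, 0, -82.7485), 1.0000),
    ((50, 0, 0), (50, -1, 2), 2.3669),
    ((50, -1, 2), (50, 0, 0), 2.3669),
    ((50, 2.4900, -0.0010), (50, -2.4900, 0.0009), 7.1792),
    ((50, 2.4900, -0.0010), (50, -2.4900, 0.0010), 7.1792),
    ((50, 2.4900, -0.0010), (50, -2.4900, 0.0011), 7.2195),
    ((50, 2.4900, -0.0010), (50, -2.4900, 0.0012), 7.2195),
    ((50, -0.0010, 2.4900), (50, 0.0009, -2.4900), 4.8045),
    ((50, -0.0010, 2.4900), (50, 0.0010, -2.4900), 4.8045),
    ((50, -0.0010, 2.4900), (50, 0.0011, -2.4900), 4.7461),
    ((50, 2.5, 0), (50, 0, -2.5), 4.3065),
    ((50, 2.5, 0), (73, 25, -18), 27.1492),
    ((50, 2.5, 0), (61, -5, 29), 22.8977),
    ((50, 2.5, 0), (56, -27, -3), 31.9030),
    ((50, 2.5, 0), (58, 24, 15), 19.4535),
    ((50, 2.5, 0), (50, 3.1736, 0.5854), 1.0000),
    ((50, 2.5, 0), (50, 3.2972, 0), 1.0000),
    ((50, 2.5, 0), (50, 1.8634, 0.5757), 1.0000),
    ((50, 2.5, 0), (50, 3.2592, 0.3350), 1.0000),
    ((60.2574, -34.0099, 36.2677), (60.4626, -34.1751, 39.4387), 1.2644),
    ((63.0109, -31.0961, -5.8663), (62.8187, -29.7946, -4.0864), 1.2630),
    ((61.2901, 3.7196, -5.3901), (61.4292, 2.2480, -4.9620), 1.8731),
    ((35.0831, -44.1164, 3.7933), (35.0232, -40.0716, 1.5901), 1.8645),
    ((22.7233, 20.0904, -46.6940), (23.0331, 14.9730, -42.5619), 2.0373),
    ((36.4612, 47.8580, 18.3852), (36.2715, 50.5065, 21.2231), 1.4146),
    ((90.8027, -2.0831, 1.4410), (91.1528, -1.6435, 0.0447), 1.4441),
    ((90.9257, -0.5406, -0.9208), (88.6381, -0.8985, -0.7239), 1.5381),
    ((6.7747, -0.2908, -2.4247), (5.8714, -0.0985, -2.2286), 0.6377),
    ((2.0776, 0.0795, -1.1350), (0.9033, -0.0636, -0.5514), 0.9082),
]


class TestWavelengthGrid:
    def test_default_grid_has_401_samples(self, grid):
        assert len(grid) == 401
        assert grid.wavelengths[0] == 380 and grid.wavelengths[-1] == 780

    @pytest.mark.parametrize(
        "start,end,step", [(780, 380, 1), (380, 780, -1), (380, 780, 3)]
    )
    def test_invalid_grids_rejected(self, start, end, step):
        with pytest.raises(ValueError):
            WavelengthGrid(start, end, step)

    def test_round_trip_from_wavelengths(self, grid):
        assert WavelengthGrid.from_wavelengths(grid.wavelengths) == grid


class TestSRGB:
    def test_black_and_white_endpoints(self):
        img = np.array([0, 255], dtype=np.uint8)
        assert srgb_decode(img)[0] == 0.0
        assert srgb_decode(img)[1] == 1.0

    def test_mid_value_matches_piecewise_formula(self):
        # independent evaluation of ((v/255 + 0.055)/1.055)^2.4 at v = 55
        expected = ((55 / 255 + 0.055) / 1.055) ** 2.4
        assert srgb_decode(np.uint8(55)) == pytest.approx(expected, abs=1e-12)

    def test_decode_monotone(self):
        v = srgb_decode(np.arange(256, dtype=np.uint8))
        assert np.all(np.diff(v) > 0)

    @given(st.floats(0.0, 1.0))
    def test_encode_decode_identity(self, x):
        assert srgb_decode(np.array(srgb_encode(np.array(x)))) == pytest.approx(
            x, abs=1 / 510
        )


class TestRGBXYZMatrix:
    def test_white_maps_to_d65_white(self):
        xyz = ss.linear_rgb_to_xyz(np.array([1.0, 1.0, 1.0]))
        assert xyz == pytest.approx([0.9505, 1.0000, 1.0890], abs=1e-12)

    def test_primaries_are_matrix_columns(self):
        for i, e in enumerate(np.eye(3)):
            assert np.allclose(ss.linear_rgb_to_xyz(e), ss.colorimetry.SRGB_TO_XYZ[:, i])

    def test_matrix_inverse_round_trip(self, rng):
        rgb = rng.random((50, 3))
        assert np.allclose(ss.xyz_to_linear_rgb(ss.linear_rgb_to_xyz(rgb)), rgb)


class TestSpectrumToXYZ:
    def test_perfect_reflector_is_white_point(self, grid, cmf, d65):
        xyz = ss.spectrum_to_xyz(np.ones(len(grid)), d65, cmf)
        assert xyz[1] == pytest.approx(100.0, abs=1e-9)
        assert np.allclose(xyz, d65.white_point(cmf))

    def test_black_is_zero(self, grid, cmf, d65):
        assert np.allclose(ss.spectrum_to_xyz(np.zeros(len(grid)), d65, cmf), 0.0)

    def test_flat_half_reflectance_under_equal_energy(self, grid, cmf):
        ee = ss.equal_energy_illuminant(grid)
        half = ss.spectrum_to_xyz(np.full(len(grid), 0.5), ee, cmf)
        assert np.allclose(half, 0.5 * ee.white_point(cmf), rtol=1e-12)

    def test_linearity_in_reflectance(self, grid, cmf, d65, rng):
        r1, r2 = rng.random((2, len(grid)))
        a, b = 0.3, 1.7
        lhs = ss.spectrum_to_xyz(a * r1 + b * r2, d65, cmf)
        rhs = a * ss.spectrum_to_xyz(r1, d65, cmf) + b * ss.spectrum_to_xyz(r2, d65, cmf)
        assert np.allclose(lhs, rhs, rtol=1e-12)

    def test_mismatched_grid_rejected(self, cmf):
        small = WavelengthGrid(380, 780, 5)
        ill = IlluminantSpectrum(small, np.ones(len(small)))
        with pytest.raises(ValueError):
            ss.spectrum_to_xyz(np.ones(len(small)), ill, cmf)


class TestLab:
    def test_white_point_maps_to_L100(self, white):
        lab = ss.xyz_to_lab(white, white)
        assert np.allclose(lab, [100.0, 0.0, 0.0], atol=1e-12)

    def test_black_maps_to_origin(self, white):
        assert np.allclose(ss.xyz_to_lab(np.zeros(3), white), 0.0, atol=1e-12)

    def test_eighth_white_lightness(self, white):
        # 116 * (1/8)^(1/3) - 16 = 42, with zero chroma
        lab = ss.xyz_to_lab(white / 8, white)
        assert lab[0] == pytest.approx(116.0 * (1 / 8) ** (1 / 3) - 16.0, abs=1e-9)
        assert abs(lab[1]) < 1e-9 and abs(lab[2]) < 1e-9

    def test_round_trip(self, white, rng):
        xyz = rng.random((100, 3)) * white
        back = lab_to_xyz(ss.xyz_to_lab(xyz, white), white)
        assert np.allclose(back, xyz, rtol=1e-9, atol=1e-12)

    def test_nonpositive_white_rejected(self):
        with pytest.raises(ValueError):
            ss.xyz_to_lab(np.ones(3), np.array([1.0, 0.0, 1.0]))


class TestCIEDE2000:
    def test_reference_pairs(self):
        a = np.array([p[0] for p in CIEDE2000_REFERENCE])
        b = np.array([p[1] for p in CIEDE2000_REFERENCE])
        expected = np.array([p[2] for p in CIEDE2000_REFERENCE])
        got = ss.ciede2000(a, b)
        assert np.max(np.abs(got - expected)) < 1e-4

    def test_bundled_reference_csv_matches_frozen_table(self):
        lab1, lab2, expected = ss.colorimetry.load_ciede2000_reference()
        assert np.array_equal(lab1, np.array([p[0] for p in CIEDE2000_REFERENCE], float))
        assert np.array_equal(lab2, np.array([p[1] for p in CIEDE2000_REFERENCE], float))
        assert np.array_equal(expected, np.array([p[2] for p in CIEDE2000_REFERENCE]))

    def test_identity_and_symmetry(self, rng):
        lab = rng.random((200, 3)) * [100, 120, 120] - [0, 60, 60]
        other = lab + rng.normal(0, 5, lab.shape)
        assert np.allclose(ss.ciede2000(lab, lab), 0.0, atol=1e-12)
        assert np.allclose(ss.ciede2000(lab, other), ss.ciede2000(other, lab))

    def test_matches_independent_oracle_on_random_pairs(self, rng):
        from skimage.color import deltaE_ciede2000

        a = rng.random((500, 3)) * [100, 160, 160] - [0, 80, 80]
        b = rng.random((500, 3)) * [100, 160, 160] - [0, 80, 80]
        assert np.max(np.abs(ss.ciede2000(a, b) - deltaE_ciede2000(a, b))) < 1e-9

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            ss.ciede2000(np.zeros(3), np.zeros(3), kL=0.0)


class TestBundledTables:
    def test_cmf_table_shape_and_positivity(self, cmf, grid):
        assert cmf.values.shape == (len(grid), 3)
        assert np.all(cmf.values >= 0)
        # ybar peaks in the green, near 555 nm
        assert 540 <= grid.wavelengths[np.argmax(cmf.ybar)] <= 570

    def test_d65_is_daylight_shaped(self, d65, grid):
        assert np.all(d65.power > 0)
        # broad daylight curve: more blue than deep red relative to 560 nm
        p = d65.power / d65.power[grid.wavelengths == 560]
        assert p[grid.wavelengths == 450] > p[grid.wavelengths == 700]
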