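"""Colorimetry: sRGB transfer, XYZ integration, Lab and colour difference."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from savehsi.colorimetry import (
    GRID,
    GridError,
    SpectralCurve,
    Tristimulus,
    SRGB_TO_XYZ,
    cie_1931_cmfs,
    decode_srgb,
    delta_e,
    encode_srgb,
    illuminant,
    linear_rgb_to_xyz,
    luminance_scale,
    resample_to_grid,
    spectrum_to_xyz,
    xyz_to_lab,
)


class TestSrgbTransfer:
    @pytest.mark.parametrize(
        "code,expected",
        [
            (0, 0.0),
            (255, 1.0),
            # hand evaluation of ((128/255 + 0.055)/1.055)**2.4
            (128, 0.21586050011389926),
        ],
    )
    def test_decode_8bit_values(self, code, expected):
        assert decode_srgb(code) == pytest.approx(expected, abs=1e-12)

    def test_unit_form_is_explicit(self):
        assert decode_srgb(0.5, bit_depth=None) == pytest.approx(
            decode_srgb(127.5), abs=1e-12
        )

    def test_roundtrip_all_256_codes(self):
        codes = np.arange(256)
        back = encode_srgb(decode_srgb(codes))
        assert np.array_equal(back, codes)

    def test_monotone(self):
        lin = decode_srgb(np.arange(256))
        assert np.all(np.diff(lin) > 0)

    @pytest.mark.parametrize("bad", [-1, 256, 300])
    def test_out_of_range_named_in_error(self, bad):
        with pytest.raises(ValueError, match=str(bad)):
            decode_srgb(bad)

    def test_unit_range_check(self):
        with pytest.raises(ValueError):
            decode_srgb(1.5, bit_depth=None)


class TestLinearRgbToXyz:
    def test_black(self):
        xyz = linear_rgb_to_xyz((0, 0, 0))
        assert (xyz.X, xyz.Y, xyz.Z) == (0, 0, 0)

    def test_white_is_row_sum(self):
        # reference white = 100 x row sums of the published matrix
        xyz = linear_rgb_to_xyz((1, 1, 1))
        expect = 100 * SRGB_TO_XYZ.sum(axis=1)
        assert np.allclose([xyz.X, xyz.Y, xyz.Z], expect, atol=1e-12)

    def test_red_is_first_column(self):
        xyz = linear_rgb_to_xyz((1, 0, 0))
        assert np.allclose([xyz.X, xyz.Y, xyz.Z], 100 * SRGB_TO_XYZ[:, 0])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            linear_rgb_to_xyz((np.nan, 0, 0))


class TestSpectrumToXyz:
    def test_perfect_reflector_has_y_100(self, d65, cmfs):
        r = SpectralCurve(np.ones(GRID.count))
        assert spectrum_to_xyz(r, d65, cmfs).Y == pytest.approx(100.0)

    def test_zero_reflector(self, d65, cmfs):
        r = SpectralCurve(np.zeros(GRID.count))
        xyz = spectrum_to_xyz(r, d65, cmfs)
        assert (xyz.X, xyz.Y, xyz.Z) == (0, 0, 0)

    def test_half_reflector_y_50(self, d65, cmfs):
        r = SpectralCurve(np.full(GRID.count, 0.5))
        assert spectrum_to_xyz(r, d65, cmfs).Y == pytest.approx(50.0)

    @settings(derandomize=True, max_examples=25)
    @given(a=st.floats(0, 0.6), b=st.floats(0, 0.4), seed=st.integers(0, 100))
    def test_linearity_in_reflectance(self, a, b, seed):
        d65, cmfs = illuminant("D65"), cie_1931_cmfs()
        rng = np.random.default_rng(seed)
        r1 = rng.uniform(0, 1, GRID.count)
        r2 = rng.uniform(0, 1, GRID.count)
        lhs = spectrum_to_xyz(SpectralCurve(a * r1 + b * r2), d65, cmfs)
        x1 = spectrum_to_xyz(SpectralCurve(r1), d65, cmfs).as_array()
        x2 = spectrum_to_xyz(SpectralCurve(r2), d65, cmfs).as_array()
        assert np.allclose(lhs.as_array(), a * x1 + b * x2, atol=1e-9)

    def test_k_independent_of_reflectance(self, d65, cmfs):
        # k is a property of illuminant and ybar only
        k = luminance_scale(d65, cmfs)
        assert k == luminance_scale(d65, cmfs)
        flat = illuminant("E")
        assert luminance_scale(flat, cmfs) != pytest.approx(k)

    def test_grid_mismatch_raises(self, d65, cmfs):
        from savehsi.colorimetry import WavelengthGrid

        small = WavelengthGrid(400, 700, 1)
        r = SpectralCurve(np.ones(small.count), small)
        with pytest.raises(GridError):
            spectrum_to_xyz(r, d65, cmfs)

    def test_degenerate_illuminant_raises(self, cmfs):
        dark = SpectralCurve(np.zeros(GRID.count), kind="power")
        r = SpectralCurve(np.ones(GRID.count))
        with pytest.raises(ValueError, match="degenerate"):
            spectrum_to_xyz(r, dark, cmfs)

    def test_ybar_peaks_near_555(self, cmfs):
        peak = GRID.wavelengths[np.argmax(cmfs.ybar)]
        assert 550 <= peak <= 560


class TestLabDeltaE:
    WHITE = Tristimulus(95.047, 100.0, 108.883)

    def test_white_maps_to_l100(self):
        L, a, b = xyz_to_lab(self.WHITE, self.WHITE)
        assert L == pytest.approx(100.0)
        assert a == pytest.approx(0.0, abs=1e-9)
        assert b == pytest.approx(0.0, abs=1e-9)

    def test_nonpositive_white_rejected(self):
        with pytest.raises(ValueError):
            xyz_to_lab(self.WHITE, Tristimulus(-1.0, 100.0, 50.0))

    def test_identity_is_zero_for_both_methods(self):
        p = (53.2, 12.1, -40.7)
        assert delta_e(p, p, "cie1976") == 0.0
        assert delta_e(p, p, "ciede2000") == pytest.approx(0.0, abs=1e-12)

    # published CIEDE2000 verification pairs (Sharma, Wu & Dalal test data)
    @pytest.mark.parametrize(
        "lab1,lab2,expected",
        [
            ((50.0, 2.6772, -79.7751), (50.0, 0.0, -82.7485), 2.0425),
            ((50.0, 3.1571, -77.2803), (50.0, 0.0, -82.7485), 2.8615),
            ((50.0, 2.8361, -74.0200), (50.0, 0.0, -82.7485), 3.4412),
        ],
    )
    def test_ciede2000_reference_pairs(self, lab1, lab2, expected):
        assert delta_e(lab1, lab2) == pytest.approx(expected, abs=1e-4)

    @settings(derandomize=True, max_examples=50)
    @given(
        l1=st.floats(0, 100), a1=st.floats(-60, 60), b1=st.floats(-60, 60),
        l2=st.floats(0, 100), a2=st.floats(-60, 60), b2=st.floats(-60, 60),
        method=st.sampled_from(["cie1976", "ciede2000"]),
    )
    def test_nonnegative_and_symmetric(self, l1, a1, b1, l2, a2, b2, method):
        d12 = delta_e((l1, a1, b1), (l2, a2, b2), method)
        d21 = delta_e((l2, a2, b2), (l1, a1, b1), method)
        assert d12 >= 0
        assert d12 == pytest.approx(d21, rel=1e-9, abs=1e-9)


class TestResample:
    def test_on_grid_unchanged(self):
        vals = np.linspace(0.1, 0.9, GRID.count)
        out = resample_to_grid(GRID.wavelengths, vals)
        assert np.allclose(out.values, vals)

    def test_two_point_ramp(self):
        out = resample_to_grid([380.0, 780.0], [0.0, 1.0])
        assert out.values[200] == pytest.approx(0.5)  # 580 nm

    def test_endpoint_hold(self):
        out = resample_to_grid([400.0, 700.0], [0.3, 0.8])
        assert out.values[0] == pytest.approx(0.3)   # 380 held at 400 nm value
        assert out.values[-1] == pytest.approx(0.8)  # 780 held at 700 nm value

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            resample_to_grid([500.0, 400.0], [0.1, 0.2])
        with pytest.raises(ValueError):
            resample_to_grid([400.0, 400.0], [0.1, 0.2])


class TestIlluminants:
    @pytest.mark.parametrize("name", ["D65", "A", "E"])
    def test_presets_positive_on_grid(self, name):
        s = illuminant(name)
        assert s.grid == GRID
        assert np.all(s.values > 0)

    def test_unknown_name(self):
        with pytest.raises(KeyError):
            illuminant("D50")

    def test_d65_bluer_than_a(self):
        d65, a = illuminant("D65").values, illuminant("A").values
        blue, red = 35, 320  # 415 nm and 700 nm indices
        assert d65[blue] / d65[red] > a[blue] / a[red]
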