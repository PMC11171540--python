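"""PCA basis, transformation matrix and per-pixel spectrum synthesis."""

import numpy as np
import pytest

from conftest import distorted_camera, make_measurements

from savehsi.calibration import ExpansionSpec, UnderdeterminedError, apply_correction
from savehsi.colorimetry import GRID, REFLECTANCE_MAX, Tristimulus
from savehsi.fixtures import synth_patch_spectra
from savehsi.pipeline import calibrate
from savehsi.reconstruction import (
    SpectralCube,
    convert_image,
    fit_basis,
    fit_transformation,
    reconstruct_spectrum,
    spectral_rmse,
)

LINEAR_NOCONST = ExpansionSpec(
    ((1, 0, 0), (0, 1, 0), (0, 0, 1)), include_constant=False
)


class TestFitBasis:
    def test_rank_one_set_needs_single_component(self):
        base = np.linspace(0.2, 0.8, GRID.count)
        spectra = np.stack([0.3 + 0.1 * i * (base - base.mean()) for i in range(5)])
        basis = fit_basis(spectra)
        assert basis.k == 1
        assert basis.explained_variance[0] > 0

    def test_full_rank_reconstructs_training_set(self):
        spectra = synth_patch_spectra(24, 6, seed=1)
        basis = fit_basis(spectra, variance_target=1.0, k_max=24)
        recon = basis.mean_spectrum + (basis.EV @ basis.scores).T
        assert np.abs(recon - spectra).max() < 1e-10

    def test_explained_variance_non_increasing(self):
        basis = fit_basis(synth_patch_spectra(24, 8, seed=2), k=8)
        assert np.all(np.diff(basis.explained_variance) <= 1e-12)

    def test_orthonormal_columns(self):
        basis = fit_basis(synth_patch_spectra(24, 6, seed=3), k=6)
        assert np.allclose(basis.EV.T @ basis.EV, np.eye(6), atol=1e-10)

    def test_mean_spectrum_scores_are_zero(self):
        basis = fit_basis(synth_patch_spectra(24, 6, seed=3), k=6)
        assert np.allclose(basis.scores.mean(axis=1), 0.0, atol=1e-10)

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.5])
    def test_variance_target_validated(self, bad):
        with pytest.raises(ValueError):
            fit_basis(synth_patch_spectra(4, 2, seed=0), variance_target=bad)


class TestFitTransformation:
    def test_exact_when_scores_linear_in_expansion(self, d65):
        ms = make_measurements(d65, camera=distorted_camera())
        model = calibrate(ms, variance_target=1.0)
        scores = model.reconstruction.basis.scores
        from savehsi.calibration import expand

        corrected = apply_correction(model.correction, ms.camera_xyz())
        V = expand(corrected, model.reconstruction.color_spec).T
        resid = scores - model.reconstruction.M @ V
        assert np.abs(resid).max() < 1e-8

    def test_patch_permutation_leaves_m_unchanged(self, d65):
        ms = make_measurements(d65, camera=distorted_camera())
        basis = fit_basis(ms.reference_spectra, k=6)
        xyz = ms.camera_xyz()
        m1 = fit_transformation(basis, xyz)
        perm = np.random.default_rng(0).permutation(ms.n_patches)
        basis_p = fit_basis(ms.reference_spectra[perm], k=6)
        m2 = fit_transformation(basis_p, xyz[perm])
        assert np.allclose(m1.M, m2.M, atol=1e-8)

    def test_underdetermined_raises(self, d65):
        ms = make_measurements(d65, n=6, basis_dim=3)
        basis = fit_basis(ms.reference_spectra, k=3)
        with pytest.raises(UnderdeterminedError):
            fit_transformation(basis, ms.camera_xyz())  # 14 terms > 6 patches


class TestReconstructSpectrum:
    def test_training_patch_recovery_noiseless(self, d65):
        ms = make_measurements(d65, camera=distorted_camera())
        model = calibrate(ms, variance_target=1.0)
        corrected = apply_correction(model.correction, ms.camera_xyz())
        recon = np.stack(
            [reconstruct_spectrum(model.reconstruction, c).values for c in corrected]
        )
        _, avg = spectral_rmse(recon, ms.reference_spectra)
        assert avg < 1e-8

    def test_zero_expansion_returns_mean_spectrum(self, d65):
        ms = make_measurements(d65, n=10, basis_dim=3)
        basis = fit_basis(ms.reference_spectra, k=3)
        model = fit_transformation(basis, ms.camera_xyz(), LINEAR_NOCONST)
        out = reconstruct_spectrum(model, Tristimulus(0, 0, 0))
        assert np.allclose(out.values, np.clip(basis.mean_spectrum, 0, 1.2))

    def test_output_length_and_clip_range(self, d65):
        ms = make_measurements(d65, camera=distorted_camera())
        model = calibrate(ms)
        out = reconstruct_spectrum(
            model.reconstruction, Tristimulus(150.0, 160.0, 170.0)
        )
        assert len(out) == 401
        assert out.values.min() >= 0.0
        assert out.values.max() <= REFLECTANCE_MAX


@pytest.fixture(scope="module")
def model(d65):
    return calibrate(make_measurements(d65, camera=distorted_camera()))


class TestConvertImage:

    def test_uniform_image_matches_single_pixel(self, model):
        img = np.full((4, 5, 3), 137, dtype=np.uint8)
        cube = convert_image(model, img)
        from savehsi.calibration import apply_correction as corr
        from savehsi.colorimetry import decode_srgb, linear_rgb_to_xyz

        xyz = linear_rgb_to_xyz(decode_srgb(np.array([137, 137, 137])))
        single = reconstruct_spectrum(
            model.reconstruction, corr(model.correction, xyz)
        )
        assert np.allclose(cube.values, single.values[None, None, :], atol=1e-6)

    def test_four_known_colors_pixelwise(self, model):
        img = np.array(
            [[[10, 200, 30], [200, 10, 30]], [[128, 128, 128], [250, 250, 10]]],
            dtype=np.uint8,
        )
        cube = convert_image(model, img)
        from savehsi.calibration import apply_correction as corr
        from savehsi.colorimetry import decode_srgb, linear_rgb_to_xyz

        for i in range(2):
            for j in range(2):
                xyz = linear_rgb_to_xyz(decode_srgb(img[i, j]))
                one = reconstruct_spectrum(
                    model.reconstruction, corr(model.correction, xyz)
                )
                assert np.allclose(cube.values[i, j], one.values, atol=1e-6)

    def test_chunk_sizes_bit_identical(self, model):
        rng = np.random.default_rng(7)
        img = rng.integers(0, 256, size=(33, 17, 3), dtype=np.uint8)
        cubes = [convert_image(model, img, chunk_rows=c) for c in (1, 5, 33, 100)]
        for c in cubes[1:]:
            assert np.array_equal(cubes[0].values, c.values)

    def test_non_rgb_rejected(self, model):
        with pytest.raises(ValueError, match="RGB"):
            convert_image(model, np.zeros((4, 4), dtype=np.uint8))

    def test_chunk_rows_validated(self, model):
        with pytest.raises(ValueError):
            convert_image(model, np.zeros((2, 2, 3), dtype=np.uint8), chunk_rows=0)


class TestSpectralRmse:
    def test_identical_lists_zero(self):
        s = synth_patch_spectra(5, 3, seed=0)
        per, avg = spectral_rmse(s, s)
        assert np.all(per == 0) and avg == 0

    def test_constant_offset(self):
        a = np.full((3, GRID.count), 0.4)
        per, avg = spectral_rmse(a, a + 0.05)
        assert np.allclose(per, 0.05) and avg == pytest.approx(0.05)

    def test_hand_built_three_band_case(self):
        a = np.zeros((1, GRID.count))
        b = np.zeros((1, GRID.count))
        b[0, :3] = [0.3, 0.4, 0.0]
        # RMSE = sqrt((0.09 + 0.16) / 401)
        per, avg = spectral_rmse(a, b)
        assert avg == pytest.approx(np.sqrt(0.25 / 401))

    def test_count_mismatch(self):
        with pytest.raises(ValueError):
            spectral_rmse(np.zeros((2, GRID.count)), np.zeros((3, GRID.count)))


def test_cube_clips_to_declared_range():
    vals = np.linspace(-0.5, 2.0, 4 * 4 * GRID.count).reshape(4, 4, GRID.count)
    cube = SpectralCube(vals)
    assert cube.values.min() >= 0.0
    assert cube.values.max() <= REFLECTANCE_MAX
    assert cube.height == cube.width == 4
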