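import numpy as np
import pytest

from savehsi.calibration import PatchMeasurementSet
from savehsi.colorimetry import cie_1931_cmfs, illuminant
from savehsi.fixtures import CameraModel, simulate_camera, synth_patch_spectra

# The simulated endoscope used throughout: mild channel crosstalk, per-channel
# gain error and a compressive cubic response — error sources whose correction
# lies inside the default polynomial expansion span.
CROSSTALK = np.array([
    [0.95, 0.04, 0.01],
    [0.03, 0.94, 0.03],
    [0.02, 0.05, 0.93],
])
GAIN = (1.02, 0.98, 1.04)
NONLINEARITY = (0.9, 2e-5)


@pytest.fixture(scope="session")
def d65():
    return illuminant("D65")


@pytest.fixture(scope="session")
def cmfs():
    return cie_1931_cmfs()


def distorted_camera(noise_sd=0.0, offset=0.0, quantize=False, seed=0):
    return CameraModel(
        gain=GAIN,
        offset=(offset,) * 3,
        crosstalk=CROSSTALK,
        nonlinearity=NONLINEARITY,
        noise_sd=noise_sd,
        quantize=quantize,
        seed=seed,
    )


def make_measurements(illum, n=24, basis_dim=6, seed=42, camera=None):
    """Synthetic patch target captured by the (optionally distorted) camera."""
    spectra = synth_patch_spectra(n, basis_dim, seed=seed)
    cam = camera or distorted_camera()
    rgb = simulate_camera(spectra, illum, cam)
    return PatchMeasurementSet(
        patch_ids=tuple(f"patch_{i:02d}" for i in range(n)),
        camera_rgb=np.asarray(rgb, dtype=float),
        reference_spectra=spectra,
        illuminant=illum,
    )
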