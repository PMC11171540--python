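"""Synthetic data: colour target, camera forward model, tissue phantom.

No public endoscopy dataset or physical colour checker accompanies this
package, so every stage is testable against synthetic stand-ins:

* :func:`synth_patch_spectra` — smooth reflectances from a low-frequency
  raised-cosine basis, emulating the 24-patch Macbeth target the real
  calibration uses;
* :func:`simulate_camera` — a forward camera with controllable distortions
  (channel crosstalk, gain, a cubic response nonlinearity, dark-current
  offset, sensor noise, sRGB encoding, 8-bit quantization);
* :func:`make_phantom` — a vessel-bearing spectral tissue phantom whose
  vessels absorb at the hemoglobin bands (415/540 nm), with ground-truth
  masks, for exercising the narrow-band rendering.

All randomness flows through one explicit seed per call; there is no
global random state.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .colorimetry import (
    GRID,
    ColorMatchingFunctions,
    SpectralCurve,
    WavelengthGrid,
    XYZ_TO_SRGB,
    cie_1931_cmfs,
    srgb_oetf,
)
from .reconstruction import SpectralCube

__all__ = [
    "CameraModel",
    "PhantomSpec",
    "synth_patch_spectra",
    "simulate_camera",
    "make_phantom",
    "write_calibration_manifest",
]


def _raised_cosine_basis(grid: WavelengthGrid, dim: int) -> np.ndarray:
    """(dim, bands) overlapping raised-cosine bumps spanning the grid."""
    lam = grid.wavelengths
    if dim == 1:
        centers = np.array([(grid.start + grid.stop) / 2])
        width = (grid.stop - grid.start)
    else:
        centers = np.linspace(grid.start, grid.stop, dim)
        width = 1.5 * (grid.stop - grid.start) / (dim - 1)
    B = np.zeros((dim, grid.count))
    for j, c in enumerate(centers):
        u = (lam - c) / width
        inside = np.abs(u) <= 1.0
        B[j, inside] = 0.5 * (1.0 + np.cos(np.pi * u[inside]))
    return B


def synth_patch_spectra(
    n: int = 24,
    basis_dim: int = 6,
    seed: int = 0,
    grid: WavelengthGrid = GRID,
    illuminant_name: str = "D65",
) -> np.ndarray:
    """Smooth synthetic patch reflectances, shape ``(n, bands)``.

    Spectra are a constant plus a seeded linear combination of ``basis_dim``
    raised cosines, globally scaled so all values stay within [0.02, 0.95];
    the stacked set therefore has exact rank ≤ basis_dim + 1.

    Colour determines the spectrum. Real reflectance families (colour
    targets, mucosa) are strongly colour–spectrum correlated — which is the
    very property RGB-to-spectrum reconstruction relies on; a set of true
    metamers would be unrecoverable from three channels by construction.
    The generator therefore draws three colour-carrying coordinates freely
    and ties the remaining ``basis_dim - 3`` metameric-black coordinates to
    a fixed seeded polynomial of the patch's tristimulus deviation (single-
    variable powers up to cubic, pairwise and triple products — the same
    monomial family the calibration expands), so the set is exactly
    recoverable from colour while still spanning all ``basis_dim``
    directions with comparable variance.
    """
    if not (1 <= basis_dim <= n):
        raise ValueError("need n >= basis_dim >= 1")
    from .colorimetry import illuminant as _illum

    rng = np.random.default_rng(seed)
    B = _raised_cosine_basis(grid, basis_dim)
    if basis_dim <= 3:
        # three or fewer coordinates: colour alone already determines them
        coeffs = rng.uniform(-1.0, 1.0, size=(n, basis_dim))
    else:
        cmfs = cie_1931_cmfs(grid)
        S = _illum(illuminant_name, grid).values
        bars = np.stack([cmfs.xbar, cmfs.ybar, cmfs.zbar])
        k = 100.0 / float(np.sum(S * cmfs.ybar) * grid.step)
        W = k * grid.step * S * bars                  # (3, bands) XYZ weights
        A = W @ B.T                                   # (3, basis_dim)
        _, _, Vt = np.linalg.svd(A, full_matrices=True)
        Vc, Vn = Vt[:3], Vt[3:]                       # colour / metameric dirs
        pc = rng.uniform(-1.0, 1.0, size=(n, 3))
        coeff_color = pc @ Vc                         # (n, basis_dim)
        xyz_dev = coeff_color @ A.T                   # (n, 3)
        u = xyz_dev / max(float(np.max(np.abs(xyz_dev))), 1e-12)
        u1, u2, u3 = u[:, 0], u[:, 1], u[:, 2]
        monomials = np.stack([
            u1, u2, u3, u1**2, u2**2, u3**2, u1**3, u2**3, u3**3,
            u1 * u2, u1 * u3, u2 * u3, u1 * u2 * u3,
        ], axis=1)                                    # all inside the span
        g = rng.uniform(-1.0, 1.0, size=(13, basis_dim - 3))
        q = monomials @ g
        rms_pc = float(np.sqrt(np.mean(pc**2)))
        rms_q = max(float(np.sqrt(np.mean(q**2))), 1e-12)
        q *= rms_pc / rms_q
        coeffs = coeff_color + q @ Vn
    dev = coeffs @ B
    peak = float(np.max(np.abs(dev)))
    if peak > 0:
        dev *= 0.43 / peak
    return np.clip(0.49 + dev, 0.02, 0.95)


@dataclass(frozen=True)
class CameraModel:
    """Forward model of an imperfect RGB camera.

    The noiseless, distortion-free default is exactly colorimetric: its
    sensitivities are the CIE 1931 colour matching functions, so its raw
    channels equal XYZ and every downstream error is something this model
    deliberately layered on top.

    ``nonlinearity = (a, b)`` gives the sensor a compressive response: the
    recorded channel y solves ``a*y + b*y**3 = x`` for the true channel x.
    Its correction, ``x = a*y + b*y**3``, is a per-channel cubic — inside
    the span of the default polynomial expansion used by the calibration.
    ``offset`` (dark current) and ``noise_sd`` act in 8-bit output counts.
    """

    sensitivities: ColorMatchingFunctions | None = None
    gain: tuple[float, float, float] = (1.0, 1.0, 1.0)
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    crosstalk: np.ndarray | None = None
    nonlinearity: tuple[float, float] | None = None
    noise_sd: float = 0.0
    encode_gamma: bool = True
    quantize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.crosstalk is not None:
            X = np.asarray(self.crosstalk, dtype=float)
            if X.shape != (3, 3):
                raise ValueError("crosstalk must be 3x3")
            object.__setattr__(self, "crosstalk", X)
        if self.nonlinearity is not None:
            a, b = self.nonlinearity
            if a <= 0 or b < 0:
                raise ValueError("nonlinearity needs a > 0, b >= 0")


def _inverse_cubic(x: np.ndarray, a: float, b: float) -> np.ndarray:
    """Solve a*y + b*y^3 = x for y (monotone; single real root, Cardano)."""
    if b == 0:
        return x / a
    p = a / b
    q = -x / b
    disc = np.sqrt(q**2 / 4.0 + p**3 / 27.0)
    return np.cbrt(-q / 2.0 + disc) + np.cbrt(-q / 2.0 - disc)


def simulate_camera(
    spectra,
    illum: SpectralCurve,
    cam: CameraModel = CameraModel(),
    grid: WavelengthGrid = GRID,
) -> np.ndarray:
    """Capture reflectance spectra with the camera model.

    Returns ``(n, 3)`` sRGB values on the 0–255 scale — ``uint8`` when the
    model quantizes, float otherwise (unclipped, for analysis).

    The raw channel is ``k·Σ S(λ)R(λ)c_i(λ)Δλ`` with k normalizing a
    perfect reflector's second channel to 100, then crosstalk, gain, the
    response nonlinearity, sRGB encode (optional), dark-current offset,
    Gaussian noise and quantization are applied in that order.
    """
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    if spectra.shape[1] != grid.count:
        raise ValueError(f"spectra must have {grid.count} bands")
    if illum.grid != grid:
        raise ValueError("illuminant grid mismatch")
    sens = cam.sensitivities or cie_1931_cmfs(grid)
    bars = np.stack([sens.xbar, sens.ybar, sens.zbar], axis=1)
    k = 100.0 / float(np.sum(illum.values * sens.ybar) * grid.step)
    raw = k * grid.step * (spectra * illum.values) @ bars          # (n, 3)
    if cam.crosstalk is not None:
        raw = raw @ np.asarray(cam.crosstalk).T
    raw = raw * np.asarray(cam.gain, dtype=float)
    if cam.nonlinearity is not None:
        a, b = cam.nonlinearity
        raw = _inverse_cubic(raw, a, b)
    lin = raw @ XYZ_TO_SRGB.T / 100.0
    counts = 255.0 * (srgb_oetf(lin) if cam.encode_gamma else lin)
    counts = counts + np.asarray(cam.offset, dtype=float)
    if cam.noise_sd > 0:
        rng = np.random.default_rng(cam.seed)
        counts = counts + rng.normal(0.0, cam.noise_sd, size=counts.shape)
    if cam.quantize:
        counts = np.clip(np.round(counts), 0, 255).astype(np.uint8)
    return counts


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the vessel-bearing spectral tissue phantom.

    The background is a smooth mucosa-like reflectance; vessels attenuate
    it by Gaussian absorption dips at the hemoglobin band centres. Depths
    are the fractional absorption at each centre (0 = no vessel signal).
    """

    height: int = 128
    width: int = 128
    bg_level: float = 0.55
    bg_amplitude: float = 0.12
    absorber_centers: tuple[float, ...] = (415.0, 540.0)
    absorber_depths: tuple[float, ...] = (0.5, 0.25)
    absorber_sigma: float = 15.0
    vessel_count: int = 4
    vessel_width: float = 3.0
    tortuosity: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 8 or self.width < 8:
            raise ValueError("phantom must be at least 8x8 pixels")
        if len(self.absorber_centers) != len(self.absorber_depths):
            raise ValueError("one depth per absorber centre required")
        if any(not (0.0 <= d < 1.0) for d in self.absorber_depths):
            raise ValueError("absorber depths must lie in [0, 1)")


def make_phantom(spec: PhantomSpec) -> tuple[SpectralCube, np.ndarray]:
    """Build the phantom cube and its ground-truth vessel mask.

    Vessels are tortuous horizontal paths spanning the full width; the
    mask marks every pixel within half a vessel width of a path.
    """
    rng = np.random.default_rng(spec.seed)
    grid = GRID
    lam = grid.wavelengths

    # smooth background reflectance (one broad seeded undulation)
    phase = rng.uniform(0, 2 * np.pi)
    bg = spec.bg_level + spec.bg_amplitude * np.cos(
        2 * np.pi * (lam - grid.start) / (grid.stop - grid.start) + phase
    )
    bg = np.clip(bg, 0.05, 0.95)

    # vessel transmission: Gaussian absorption dips at the band centres
    atten = np.ones_like(lam)
    for c, d in zip(spec.absorber_centers, spec.absorber_depths):
        atten = atten - d * np.exp(-((lam - c) ** 2) / (2 * spec.absorber_sigma**2))
    vessel = bg * np.clip(atten, 0.0, None)

    H, W = spec.height, spec.width
    mask = np.zeros((H, W), dtype=bool)
    cols = np.arange(W)
    rows = np.arange(H)[:, None]
    margin = max(2.0, spec.vessel_width)
    for _ in range(spec.vessel_count):
        y0 = rng.uniform(margin, H - margin)
        amp = spec.tortuosity * 0.1 * H
        f1, f2 = rng.uniform(0.5, 2.0, size=2)
        p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
        path = (
            y0
            + amp * np.sin(2 * np.pi * f1 * cols / W + p1)
            + 0.5 * amp * np.sin(2 * np.pi * f2 * cols / W + p2)
        )
        mask |= np.abs(rows - path[None, :]) <= spec.vessel_width / 2.0

    cube = np.where(mask[:, :, None], vessel[None, None, :], bg[None, None, :])
    return SpectralCube(cube.astype(np.float32), grid), mask


def write_calibration_manifest(
    out_dir,
    spectra: np.ndarray,
    camera_rgb: np.ndarray,
    grid: WavelengthGrid = GRID,
) -> Path:
    """Write a calibration manifest consumable by the calibrate step.

    Creates ``manifest.csv`` (columns ``patch_id,r,g,b,spectrum_path``) and
    one two-column reflectance CSV per patch under ``out_dir``; returns the
    manifest path.
    """
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spectra = np.asarray(spectra, dtype=float)
    rgb = np.asarray(camera_rgb, dtype=float)
    rows = []
    for i, (refl, (r, g, b)) in enumerate(zip(spectra, rgb), start=1):
        pid = f"patch_{i:02d}"
        spath = out_dir / f"{pid}.csv"
        pd.DataFrame(
            {"wavelength_nm": grid.wavelengths, "value": refl}
        ).to_csv(spath, index=False)
        rows.append({"patch_id": pid, "r": r, "g": g, "b": b,
                     "spectrum_path": spath.name})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
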