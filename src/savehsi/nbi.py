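"""Virtual narrow-band imaging from a reconstructed spectral cube.

Narrow-band endoscopy restricts illumination to the hemoglobin absorption
bands at 415 nm (superficial capillaries, strong Soret-band absorption) and
540 nm (deeper vessels, secondary absorption peak). Vessels absorb strongly
in these bands, so band images show them dark against the mucosa.

From a reflectance cube the band image is a normalized weighted average of
the bands inside the filter window. The display composite follows the NBI
convention of feeding the 415 nm image to the display's blue *and* green
channels and the 540 nm image to red, which reproduces the characteristic
reddish-brown mucosa with dark vasculature; the mapping is a display
convention of this package, configurable via :class:`NbiMapping`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .colorimetry import (
    ColorMatchingFunctions,
    SpectralCurve,
    cie_1931_cmfs,
    luminance_scale,
    srgb_oetf,
)
from .reconstruction import SpectralCube

__all__ = [
    "BandSpec",
    "NbiMapping",
    "band_image",
    "render_nbi",
    "luminance_image",
    "michelson_contrast",
]

log = logging.getLogger("savehsi")


@dataclass(frozen=True)
class BandSpec:
    """A narrow-band filter: centre wavelength, FWHM, window shape."""

    center: float
    fwhm: float = 30.0
    weighting: str = "gaussian"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.weighting not in ("gaussian", "rectangular"):
            raise ValueError("weighting must be 'gaussian' or 'rectangular'")

    def weights(self, wavelengths: np.ndarray) -> np.ndarray:
        """Filter weights on ``wavelengths``, normalized to sum to 1."""
        lam = np.asarray(wavelengths, dtype=float)
        if self.weighting == "gaussian":
            w = np.exp(-4.0 * np.log(2.0) * ((lam - self.center) / self.fwhm) ** 2)
        else:
            w = (np.abs(lam - self.center) <= self.fwhm / 2).astype(float)
        total = w.sum()
        if total <= 0 or not (
            wavelengths[0] - self.fwhm <= self.center <= wavelengths[-1] + self.fwhm
        ):
            raise ValueError(
                f"band at {self.center} nm lies outside the cube's grid"
            )
        return w / total


NBI_BLUE = BandSpec(415.0)
NBI_GREEN = BandSpec(540.0)


@dataclass(frozen=True)
class NbiMapping:
    """How the two band images drive the displayed RGB channels.

    ``channels`` assigns a band ("blue"=415 or "green"=540) to each display
    channel; percentile normalization resists specular highlights; output
    gamma applies sRGB encoding to the normalized bands.
    """

    channels: tuple[str, str, str] = ("green", "blue", "blue")  # display R, G, B
    percentiles: tuple[float, float] = (1.0, 99.0)
    output_gamma: bool = True
    blue_band: BandSpec = NBI_BLUE
    green_band: BandSpec = NBI_GREEN

    def __post_init__(self) -> None:
        lo, hi = self.percentiles
        if not (0 <= lo < hi <= 100):
            raise ValueError("percentiles must satisfy 0 <= low < high <= 100")
        if any(c not in ("blue", "green") for c in self.channels):
            raise ValueError("channels entries must be 'blue' or 'green'")


def band_image(cube: SpectralCube, band: BandSpec) -> np.ndarray:
    """Per-pixel weighted average of reflectance inside the filter window."""
    w = band.weights(cube.grid.wavelengths)
    return np.tensordot(cube.values.astype(float), w, axes=([2], [0]))


def _normalize(img: np.ndarray, lo_p: float, hi_p: float) -> np.ndarray:
    lo, hi = np.percentile(img, [lo_p, hi_p])
    if hi - lo < 1e-12:
        log.warning("degenerate band normalization (constant band); "
                    "falling back to identity scaling")
        return np.clip(img, 0.0, 1.0)
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def render_nbi(cube: SpectralCube, mapping: NbiMapping = NbiMapping()) -> np.ndarray:
    """Compose the displayed 8-bit NBI image from the two band images."""
    bands = {
        "blue": _normalize(band_image(cube, mapping.blue_band), *mapping.percentiles),
        "green": _normalize(band_image(cube, mapping.green_band), *mapping.percentiles),
    }
    planes = [bands[c] for c in mapping.channels]
    rgb = np.stack(planes, axis=-1)
    if mapping.output_gamma:
        rgb = srgb_oetf(rgb)
    return np.round(np.clip(rgb, 0.0, 1.0) * 255.0).astype(np.uint8)


def luminance_image(
    cube: SpectralCube,
    illum: SpectralCurve,
    cmfs: ColorMatchingFunctions | None = None,
) -> np.ndarray:
    """White-light luminance Y per pixel (0–100) under ``illum``.

    This is the broadband view the narrow-band image is compared against.
    """
    cmfs = cmfs or cie_1931_cmfs(cube.grid)
    if illum.grid != cube.grid or cmfs.grid != cube.grid:
        raise ValueError("cube, illuminant and CMFs must share one grid")
    k = luminance_scale(illum, cmfs)
    weights = illum.values * cmfs.ybar * cube.grid.step
    return k * np.tensordot(cube.values.astype(float), weights, axes=([2], [0]))


def michelson_contrast(image: np.ndarray, mask: np.ndarray) -> float:
    """Michelson contrast (I_bg − I_fg)/(I_bg + I_fg) of masked vs rest.

    ``mask`` marks the foreground (vessels); intensities are region means,
    which keeps the measure robust on noisy scenes. The sign is positive
    when the masked region is darker.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask and image shapes differ")
    if not mask.any() or mask.all():
        raise ValueError("mask must select a proper subset of pixels")
    fg = float(image[mask].mean())
    bg = float(image[~mask].mean())
    denom = bg + fg
    if denom <= 0:
        raise ValueError("non-positive total intensity")
    return (bg - fg) / denom
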