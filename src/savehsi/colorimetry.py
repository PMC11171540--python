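"""CIE 1931 colorimetry on a fixed 380–780 nm, 1 nm wavelength grid.

This module is the numeric foundation of the package: sRGB decoding to
linear RGB, linear RGB → XYZ, reflectance-spectrum → XYZ integration with
illuminant luminance normalization, CIELAB / colour difference, and
resampling of arbitrary spectrometer exports onto the working grid.

Conventions
-----------
* Tristimulus values use the 0–100 luminance scale: a perfect reflector
  under the chosen illuminant has Y = 100 exactly.
* Spectral integration is a rectangle rule at Δλ = 1 nm (the grid is dense
  and uniform, so higher-order quadrature buys nothing).
* The colour matching functions are the CIE 1931 2° standard observer,
  generated from the multi-lobe piecewise-Gaussian analytic fit of
  Wyman, Sloan & Shirley (2013), clipped to be non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WavelengthGrid",
    "SpectralCurve",
    "ColorMatchingFunctions",
    "Tristimulus",
    "GRID",
    "cie_1931_cmfs",
    "illuminant",
    "decode_srgb",
    "encode_srgb",
    "srgb_eotf",
    "srgb_oetf",
    "linear_rgb_to_xyz",
    "xyz_to_linear_rgb",
    "spectrum_to_xyz",
    "luminance_scale",
    "xyz_to_lab",
    "delta_e",
    "resample_to_grid",
    "read_spectrum_csv",
    "write_spectrum_csv",
]

REFLECTANCE_MAX = 1.2  # regression overshoot ceiling; see docs/methods.md


class GridError(ValueError):
    """Raised when spectral operands do not share one wavelength grid."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid in nm. The package default is 380–780 at 1 nm."""

    start: float = 380.0
    stop: float = 780.0
    step: float = 1.0

    def __post_init__(self) -> None:
        if self.stop <= self.start or self.step <= 0:
            raise ValueError("grid must be strictly increasing")
        n = (self.stop - self.start) / self.step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("step must divide the span exactly")

    @property
    def count(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.count)


#: The working grid shared by every spectral object in the package.
GRID = WavelengthGrid()


@dataclass(frozen=True)
class SpectralCurve:
    """A sampled spectrum on a :class:`WavelengthGrid`.

    ``kind`` is ``"reflectance"`` (unitless, clipped to [0, 1.2]) or
    ``"power"`` (illuminant SPD, arbitrary non-negative units).
    """

    values: np.ndarray
    grid: WavelengthGrid = GRID
    kind: str = "reflectance"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.grid.count,):
            raise GridError(
                f"expected {self.grid.count} samples, got {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("spectrum contains non-finite values")
        if self.kind == "reflectance":
            v = np.clip(v, 0.0, REFLECTANCE_MAX)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.grid.count


@dataclass(frozen=True)
class ColorMatchingFunctions:
    """x̄, ȳ, z̄ of a standard observer sampled on a grid."""

    xbar: np.ndarray
    ybar: np.ndarray
    zbar: np.ndarray
    grid: WavelengthGrid = GRID

    def __post_init__(self) -> None:
        for name in ("xbar", "ybar", "zbar"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (self.grid.count,):
                raise GridError(f"{name}: expected {self.grid.count} samples")
            if np.any(v < 0):
                raise ValueError(f"{name} must be non-negative")
            object.__setattr__(self, name, v)


@dataclass(frozen=True)
class Tristimulus:
    """CIE 1931 X, Y, Z on the 0–100 luminance scale."""

    X: float
    Y: float
    Z: float

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.X, self.Y, self.Z])):
            raise ValueError("non-finite tristimulus")

    def as_array(self) -> np.ndarray:
        return np.array([self.X, self.Y, self.Z], dtype=float)


# ---------------------------------------------------------------------------
# CIE 1931 2° observer (analytic multi-lobe Gaussian fit) and illuminants
# ---------------------------------------------------------------------------

def _lobe(lam: np.ndarray, mu: float, s_lo: float, s_hi: float) -> np.ndarray:
    s = np.where(lam < mu, s_lo, s_hi)
    return np.exp(-0.5 * ((lam - mu) / s) ** 2)


def cie_1931_cmfs(grid: WavelengthGrid = GRID) -> ColorMatchingFunctions:
    """CIE 1931 2° colour matching functions on ``grid``.

    Evaluates the piecewise-Gaussian analytic fit (accurate to about 1% of
    each curve's peak over the visible range); small negative excursions of
    the fit are clipped to zero.
    """
    lam = grid.wavelengths
    xbar = (
        1.056 * _lobe(lam, 599.8, 37.9, 31.0)
        + 0.362 * _lobe(lam, 442.0, 16.0, 26.7)
        - 0.065 * _lobe(lam, 501.1, 20.4, 26.2)
    )
    ybar = 0.821 * _lobe(lam, 568.8, 46.9, 40.5) + 0.286 * _lobe(
        lam, 530.9, 16.3, 31.1
    )
    zbar = 1.217 * _lobe(lam, 437.0, 11.8, 36.0) + 0.681 * _lobe(
        lam, 459.0, 26.0, 13.8
    )
    return ColorMatchingFunctions(
        np.clip(xbar, 0.0, None), ybar, zbar, grid=grid
    )


# CIE standard illuminant D65, relative SPD at 10 nm (published constants),
# linearly interpolated onto the working grid.
_D65_NM = np.arange(380.0, 781.0, 10.0)
_D65_SPD = np.array([
    49.9755, 54.6482, 82.7549, 91.486, 93.4318, 86.6823, 104.865, 117.008,
    117.812, 114.861, 115.923, 108.811, 109.354, 107.802, 104.790, 107.689,
    104.405, 104.046, 100.0, 96.3342, 95.788, 88.6856, 90.0062, 89.5991,
    87.6987, 83.2886, 83.6992, 80.0268, 80.2146, 82.2778, 78.2842, 69.7213,
    71.6091, 74.349, 61.604, 69.8856, 75.087, 63.5927, 46.4182, 66.8054,
    63.3828,
])


def illuminant(name: str = "D65", grid: WavelengthGrid = GRID) -> SpectralCurve:
    """Named illuminant SPD on ``grid``.

    Presets: ``"D65"`` (daylight, interpolated 10 nm table), ``"A"``
    (incandescent; Planckian radiator at 2856 K per its definition, scaled
    to 100 at 560 nm) and ``"E"`` (equal energy).
    """
    lam = grid.wavelengths
    key = name.upper()
    if key == "D65":
        return resample_to_grid(_D65_NM, _D65_SPD, grid, kind="power")
    if key == "E":
        return SpectralCurve(np.full(grid.count, 100.0), grid, kind="power")
    if key == "A":
        def planck(l_nm: np.ndarray) -> np.ndarray:
            l_m = np.asarray(l_nm) * 1e-9
            c2 = 1.4388e-2  # m·K, per the illuminant-A definition
            return l_m ** -5.0 / np.expm1(c2 / (l_m * 2856.0))

        spd = 100.0 * planck(lam) / planck(np.array([560.0]))[0]
        return SpectralCurve(spd, grid, kind="power")
    raise KeyError(f"unknown illuminant {name!r}; presets: D65, A, E")


# ---------------------------------------------------------------------------
# sRGB transfer functions and the RGB↔XYZ matrices
# ---------------------------------------------------------------------------

def srgb_eotf(u: np.ndarray) -> np.ndarray:
    """Vectorized sRGB electro-optical transfer (encoded [0,1] → linear).

    Extended sign-symmetrically outside [0,1] so that synthetic out-of-gamut
    encodings round-trip; the validating scalar API is :func:`decode_srgb`.
    """
    u = np.asarray(u, dtype=float)
    a = np.abs(u)
    lin = np.where(a <= 0.04045, a / 12.92, ((a + 0.055) / 1.055) ** 2.4)
    return np.sign(u) * lin


def srgb_oetf(v: np.ndarray) -> np.ndarray:
    """Vectorized sRGB opto-electronic transfer (linear → encoded), extended."""
    v = np.asarray(v, dtype=float)
    a = np.abs(v)
    enc = np.where(a <= 0.0031308, a * 12.92, 1.055 * a ** (1 / 2.4) - 0.055)
    return np.sign(v) * enc


def decode_srgb(encoded, *, bit_depth: int | None = 8) -> np.ndarray | float:
    """Decode sRGB-encoded channel values to linear light in [0, 1].

    Parameters
    ----------
    encoded:
        Channel value(s). With ``bit_depth=8`` the expected range is
        [0, 255]; with ``bit_depth=None`` the input is already unit-scaled
        in [0, 1]. The form is explicit, never guessed.
    """
    e = np.asarray(encoded, dtype=float)
    hi = 255.0 if bit_depth == 8 else 1.0
    if bit_depth not in (8, None):
        raise ValueError("bit_depth must be 8 or None (unit-scaled)")
    if np.any(e < 0) or np.any(e > hi):
        bad = e[(e < 0) | (e > hi)].ravel()[0]
        raise ValueError(f"encoded value {bad} outside [0, {hi:g}]")
    out = srgb_eotf(e / hi)
    return float(out) if np.isscalar(encoded) else out


def encode_srgb(linear, *, bit_depth: int | None = 8) -> np.ndarray | float:
    """Inverse of :func:`decode_srgb`; rounds to integers when ``bit_depth=8``."""
    v = np.asarray(linear, dtype=float)
    if np.any(v < 0) or np.any(v > 1):
        bad = v[(v < 0) | (v > 1)].ravel()[0]
        raise ValueError(f"linear value {bad} outside [0, 1]")
    enc = srgb_oetf(v)
    if bit_depth == 8:
        enc = np.round(enc * 255.0)
    out = enc
    return float(out) if np.isscalar(linear) else out


#: sRGB (D65) linear RGB → XYZ, Y normalized to 1 for reference white.
SRGB_TO_XYZ = np.array([
    [0.4124, 0.3576, 0.1805],
    [0.2126, 0.7152, 0.0722],
    [0.0193, 0.1192, 0.9505],
])
XYZ_TO_SRGB = np.linalg.inv(SRGB_TO_XYZ)


def linear_rgb_to_xyz(rgb) -> Tristimulus:
    """Map a linear-RGB triple in [0, 1] to XYZ on the 0–100 scale."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape != (3,):
        raise ValueError("expected an RGB triple")
    if not np.all(np.isfinite(rgb)):
        raise ValueError("non-finite RGB")
    X, Y, Z = 100.0 * (SRGB_TO_XYZ @ rgb)
    return Tristimulus(X, Y, Z)


def linear_rgb_image_to_xyz(rgb: np.ndarray) -> np.ndarray:
    """Vectorized form of :func:`linear_rgb_to_xyz` for ``(..., 3)`` arrays."""
    return 100.0 * np.asarray(rgb, dtype=float) @ SRGB_TO_XYZ.T


def xyz_to_linear_rgb(xyz: np.ndarray) -> np.ndarray:
    """Inverse of :func:`linear_rgb_image_to_xyz` (``(..., 3)`` arrays)."""
    return np.asarray(xyz, dtype=float) @ XYZ_TO_SRGB.T / 100.0


# ---------------------------------------------------------------------------
# Spectrum → XYZ
# ---------------------------------------------------------------------------

def luminance_scale(
    illum: SpectralCurve, cmfs: ColorMatchingFunctions
) -> float:
    """Luminance normalizer k = 100 / Σ S(λ)·ȳ(λ)·Δλ.

    k depends only on the illuminant and ȳ; it makes a perfect reflector's
    Y equal 100 under that illuminant.
    """
    if illum.grid != cmfs.grid:
        raise GridError("illuminant and CMFs are on different grids")
    denom = float(np.sum(illum.values * cmfs.ybar) * illum.grid.step)
    if denom <= 0:
        raise ValueError("degenerate illuminant: Σ S·ȳ is not positive")
    return 100.0 / denom


def spectrum_to_xyz(
    reflectance: SpectralCurve,
    illum: SpectralCurve,
    cmfs: ColorMatchingFunctions,
) -> Tristimulus:
    """Integrate a reflectance spectrum against illuminant and observer.

    X = k·Σ S(λ)R(λ)x̄(λ)·Δλ (likewise Y, Z) with
    k = 100 / Σ S(λ)ȳ(λ)·Δλ, rectangle rule at the grid step.
    """
    if reflectance.grid != illum.grid or reflectance.grid != cmfs.grid:
        raise GridError("reflectance, illuminant and CMFs must share a grid")
    k = luminance_scale(illum, cmfs)
    sr = illum.values * reflectance.values * reflectance.grid.step
    return Tristimulus(
        k * float(np.sum(sr * cmfs.xbar)),
        k * float(np.sum(sr * cmfs.ybar)),
        k * float(np.sum(sr * cmfs.zbar)),
    )


def spectra_to_xyz(
    reflectances: np.ndarray,
    illum: SpectralCurve,
    cmfs: ColorMatchingFunctions,
) -> np.ndarray:
    """Batch spectrum→XYZ: ``(n, bands)`` reflectances → ``(n, 3)`` XYZ."""
    if cmfs.grid != illum.grid:
        raise GridError("illuminant and CMFs are on different grids")
    refl = np.asarray(reflectances, dtype=float)
    if refl.shape[-1] != illum.grid.count:
        raise GridError("reflectance band count does not match the grid")
    k = luminance_scale(illum, cmfs)
    bars = np.stack([cmfs.xbar, cmfs.ybar, cmfs.zbar], axis=1)  # (bands, 3)
    return k * illum.grid.step * (refl * illum.values) @ bars


# ---------------------------------------------------------------------------
# CIELAB and colour difference
# ---------------------------------------------------------------------------

def xyz_to_lab(xyz: Tristimulus, white: Tristimulus) -> tuple[float, float, float]:
    """CIE 1976 L*a*b* relative to ``white`` (which must have Y = 100)."""
    w = white.as_array()
    if np.any(w <= 0):
        raise ValueError("reference white must be strictly positive")
    if abs(white.Y - 100.0) > 1e-6:
        raise ValueError("reference white must have Y = 100")
    t = xyz.as_array() / w
    d = 6.0 / 29.0
    f = np.where(t > d**3, np.cbrt(t), t / (3 * d * d) + 4.0 / 29.0)
    L = 116.0 * f[1] - 16.0
    a = 500.0 * (f[0] - f[1])
    b = 200.0 * (f[1] - f[2])
    return float(L), float(a), float(b)


def _delta_e_2000(lab1, lab2) -> float:
    # CIEDE2000 per the published formula (kL = kC = kH = 1).
    L1, a1, b1 = lab1
    L2, a2, b2 = lab2
    C1 = np.hypot(a1, b1)
    C2 = np.hypot(a2, b2)
    Cbar = 0.5 * (C1 + C2)
    G = 0.5 * (1 - np.sqrt(Cbar**7 / (Cbar**7 + 25.0**7)))
    a1p, a2p = (1 + G) * a1, (1 + G) * a2
    C1p = np.hypot(a1p, b1)
    C2p = np.hypot(a2p, b2)
    h1p = np.degrees(np.arctan2(b1, a1p)) % 360 if (a1p or b1) else 0.0
    h2p = np.degrees(np.arctan2(b2, a2p)) % 360 if (a2p or b2) else 0.0

    dLp = L2 - L1
    dCp = C2p - C1p
    if C1p * C2p == 0:
        dhp = 0.0
    else:
        dh = h2p - h1p
        if abs(dh) <= 180:
            dhp = dh
        elif dh > 180:
            dhp = dh - 360
        else:
            dhp = dh + 360
    dHp = 2 * np.sqrt(C1p * C2p) * np.sin(np.radians(dhp) / 2)

    Lbp = 0.5 * (L1 + L2)
    Cbp = 0.5 * (C1p + C2p)
    if C1p * C2p == 0:
        hbp = h1p + h2p
    else:
        hsum = h1p + h2p
        if abs(h1p - h2p) <= 180:
            hbp = hsum / 2
        elif hsum < 360:
            hbp = (hsum + 360) / 2
        else:
            hbp = (hsum - 360) / 2
    T = (
        1
        - 0.17 * np.cos(np.radians(hbp - 30))
        + 0.24 * np.cos(np.radians(2 * hbp))
        + 0.32 * np.cos(np.radians(3 * hbp + 6))
        - 0.20 * np.cos(np.radians(4 * hbp - 63))
    )
    d_theta = 30 * np.exp(-(((hbp - 275) / 25) ** 2))
    RC = 2 * np.sqrt(Cbp**7 / (Cbp**7 + 25.0**7))
    SL = 1 + 0.015 * (Lbp - 50) ** 2 / np.sqrt(20 + (Lbp - 50) ** 2)
    SC = 1 + 0.045 * Cbp
    SH = 1 + 0.015 * Cbp * T
    RT = -np.sin(np.radians(2 * d_theta)) * RC
    return float(
        np.sqrt(
            (dLp / SL) ** 2
            + (dCp / SC) ** 2
            + (dHp / SH) ** 2
            + RT * (dCp / SC) * (dHp / SH)
        )
    )


def delta_e(lab1, lab2, method: str = "ciede2000") -> float:
    """Colour difference between two Lab triples.

    ``method`` is ``"ciede2000"`` (default, the current perceptual standard)
    or ``"cie1976"`` (plain Euclidean distance in Lab).
    """
    if method == "cie1976":
        return float(np.linalg.norm(np.subtract(lab1, lab2)))
    if method == "ciede2000":
        return _delta_e_2000(tuple(map(float, lab1)), tuple(map(float, lab2)))
    raise ValueError(f"unknown delta-E method {method!r}")


# ---------------------------------------------------------------------------
# Resampling and CSV I/O
# ---------------------------------------------------------------------------

def resample_to_grid(
    wavelengths,
    values,
    grid: WavelengthGrid = GRID,
    kind: str = "reflectance",
) -> SpectralCurve:
    """Linearly interpolate measured samples onto ``grid``.

    Outside the measured range the endpoint values are held constant
    (spectrometer exports rarely cover the full 380–780 nm span).
    """
    w = np.asarray(wavelengths, dtype=float)
    v = np.asarray(values, dtype=float)
    if w.ndim != 1 or w.size < 2 or w.shape != v.shape:
        raise ValueError("need >=2 paired (wavelength, value) samples")
    if np.any(np.diff(w) <= 0):
        raise ValueError("wavelengths must be strictly increasing")
    out = np.interp(grid.wavelengths, w, v)  # np.interp holds endpoints
    return SpectralCurve(out, grid, kind=kind)


def read_spectrum_csv(path, grid: WavelengthGrid = GRID,
                      kind: str = "reflectance") -> SpectralCurve:
    """Read a two-column ``wavelength_nm,value`` CSV (header required)."""
    import pandas as pd

    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    if "wavelength_nm" not in cols or "value" not in cols:
        raise ValueError(f"{path}: expected columns wavelength_nm,value")
    df.columns = cols
    df = df.sort_values("wavelength_nm")
    return resample_to_grid(
        df["wavelength_nm"].to_numpy(), df["value"].to_numpy(), grid, kind
    )


def write_spectrum_csv(path, curve: SpectralCurve) -> None:
    import pandas as pd

    pd.DataFrame(
        {"wavelength_nm": curve.grid.wavelengths, "value": curve.values}
    ).to_csv(path, index=False)
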