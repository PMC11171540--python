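"""Spectral reconstruction: from corrected XYZ to a 401-band reflectance.

The reference patch reflectances are decomposed by mean-centred PCA into an
orthonormal basis EV (401 × k) with per-patch scores. A transformation
matrix M maps a polynomial expansion of the corrected tristimulus values
(the "colour" variable matrix, V_color) to those scores:

    M = Score · pinv(V_color)

so that an unseen pixel's analog spectrum is

    S = mean + EV · M · V_color(XYZ_correct),

clipped to the declared reflectance range [0, 1.2]. Whole images are
converted in row chunks with bounded working memory; per-pixel arithmetic
is accumulated term by term in a fixed order, so the result is bit-identical
for every chunk size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .calibration import (
    PINV_RTOL,
    CorrectionModel,
    ExpansionSpec,
    UnderdeterminedError,
    default_expansion,
    expand,
)
from .colorimetry import (
    GRID,
    REFLECTANCE_MAX,
    SpectralCurve,
    Tristimulus,
    WavelengthGrid,
    srgb_eotf,
    SRGB_TO_XYZ,
)

__all__ = [
    "PCABasis",
    "ReconstructionModel",
    "CalibrationModel",
    "SpectralCube",
    "fit_basis",
    "fit_transformation",
    "reconstruct_spectrum",
    "convert_image",
    "spectral_rmse",
]

log = logging.getLogger("savehsi")


@dataclass(frozen=True)
class PCABasis:
    """Mean-centred PCA of the reference reflectance set."""

    EV: np.ndarray                 # (bands, k), orthonormal columns
    mean_spectrum: np.ndarray      # (bands,)
    scores: np.ndarray             # (k, n_patches)
    explained_variance: np.ndarray  # (k,), non-increasing
    grid: WavelengthGrid = GRID

    def __post_init__(self) -> None:
        EV = np.asarray(self.EV, dtype=float)
        k = EV.shape[1]
        gram = EV.T @ EV
        if not np.allclose(gram, np.eye(k), atol=1e-10):
            raise ValueError("EV columns are not orthonormal")
        ev_var = np.asarray(self.explained_variance, dtype=float)
        if np.any(np.diff(ev_var) > 1e-12):
            raise ValueError("explained variance must be non-increasing")
        object.__setattr__(self, "EV", EV)

    @property
    def k(self) -> int:
        return self.EV.shape[1]


@dataclass(frozen=True)
class ReconstructionModel:
    """Transformation matrix M with its expansion spec and PCA basis."""

    M: np.ndarray                  # (k, n_terms)
    color_spec: ExpansionSpec
    basis: PCABasis

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=float)
        if M.shape != (self.basis.k, self.color_spec.n_terms):
            raise ValueError("M shape inconsistent with basis / spec")
        if not np.all(np.isfinite(M)):
            raise ValueError("M contains non-finite entries")
        object.__setattr__(self, "M", M)


@dataclass(frozen=True)
class CalibrationModel:
    """The serializable product of the full calibration procedure."""

    correction: CorrectionModel
    reconstruction: ReconstructionModel
    illuminant: SpectralCurve
    grid: WavelengthGrid = GRID
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.illuminant.grid != self.grid:
            raise ValueError("illuminant grid differs from the model grid")
        if self.reconstruction.basis.grid != self.grid:
            raise ValueError("basis grid differs from the model grid")


@dataclass
class SpectralCube:
    """H×W×bands reflectance block on a wavelength grid (float32 storage)."""

    values: np.ndarray
    grid: WavelengthGrid = GRID

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3 or v.shape[2] != self.grid.count:
            raise ValueError(
                f"cube must be (H, W, {self.grid.count}), got {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("cube contains non-finite values")
        self.values = np.clip(v, 0.0, REFLECTANCE_MAX).astype(
            np.float32, copy=False
        )

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _stack_spectra(spectra, grid: WavelengthGrid) -> np.ndarray:
    if isinstance(spectra, np.ndarray):
        arr = np.asarray(spectra, dtype=float)
    else:
        rows = []
        for s in spectra:
            if isinstance(s, SpectralCurve):
                if s.grid != grid:
                    raise ValueError("spectra are on different grids")
                rows.append(s.values)
            else:
                rows.append(np.asarray(s, dtype=float))
        arr = np.stack(rows)
    if arr.ndim != 2 or arr.shape[1] != grid.count:
        raise ValueError(f"expected (n, {grid.count}) spectra")
    return arr


def fit_basis(
    reference_spectra,
    variance_target: float = 0.999,
    k_max: int = 12,
    k: int | None = None,
    grid: WavelengthGrid = GRID,
) -> PCABasis:
    """Mean-centred PCA of the reference reflectances.

    ``k`` is the smallest component count whose cumulative explained
    variance reaches ``variance_target``, capped at ``k_max``; pass ``k``
    explicitly to override. Component signs are fixed so the largest-
    magnitude loading of each component is positive, making the basis
    invariant to patch ordering.
    """
    R = _stack_spectra(reference_spectra, grid)
    n = R.shape[0]
    if n < 2:
        raise ValueError("need at least two reference spectra")
    if not (0.0 < variance_target <= 1.0):
        raise ValueError("variance_target must lie in (0, 1]")
    mean = R.mean(axis=0)
    centered = R - mean
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    var = s**2
    total = float(var.sum())
    if k is None:
        if total <= 1e-300:
            k = 1
        else:
            frac = np.cumsum(var) / total
            k = int(np.searchsorted(frac, variance_target - 1e-12) + 1)
        k = min(k, k_max, len(s))
    else:
        if not (1 <= k <= len(s)):
            raise ValueError(f"k must be in [1, {len(s)}]")
    EV = Vt[:k].T                                   # (bands, k)
    sign = np.sign(EV[np.argmax(np.abs(EV), axis=0), np.arange(k)])
    sign[sign == 0] = 1.0
    EV = EV * sign
    scores = EV.T @ centered.T                      # (k, n)
    return PCABasis(
        EV=EV,
        mean_spectrum=mean,
        scores=scores,
        explained_variance=var[:k] / max(n - 1, 1),
        grid=grid,
    )


def fit_transformation(
    basis: PCABasis,
    corrected_xyz: np.ndarray,
    color_spec: ExpansionSpec | None = None,
) -> ReconstructionModel:
    """Fit M = Score · pinv(V_color) over the stacked patch columns."""
    color_spec = color_spec or default_expansion()
    xyz = np.asarray(corrected_xyz, dtype=float).reshape(-1, 3)
    n = xyz.shape[0]
    if n != basis.scores.shape[1]:
        raise ValueError("one corrected XYZ per training spectrum required")
    if n < color_spec.n_terms:
        raise UnderdeterminedError(
            f"{n} patches cannot determine {color_spec.n_terms} colour terms"
        )
    V = expand(xyz, color_spec).T                   # (n_terms, n)
    M = basis.scores @ np.linalg.pinv(V, rcond=PINV_RTOL)
    return ReconstructionModel(M=M, color_spec=color_spec, basis=basis)


# ---------------------------------------------------------------------------
# Synthesis
# ---------------------------------------------------------------------------

def _acc_matmul(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """``A @ B.T`` accumulated over the shared axis in fixed term order.

    A is (m, t), B is (r, t) with small t; the per-element summation order
    never depends on m, which makes chunked image conversion bit-identical
    to the unchunked run.
    """
    out = np.zeros((A.shape[0], B.shape[0]))
    for t in range(A.shape[1]):
        out += A[:, t, None] * B[None, :, t]
    return out


def _reconstruct_block(model: ReconstructionModel, xyz: np.ndarray) -> np.ndarray:
    """(m, 3) corrected XYZ → (m, bands) clipped reflectance, with overshoot log."""
    V = expand(xyz, model.color_spec)               # (m, n_terms)
    scores = _acc_matmul(V, model.M)                # (m, k)
    spectra = model.basis.mean_spectrum + _acc_matmul(scores, model.basis.EV)
    n_over = int(np.count_nonzero(spectra > REFLECTANCE_MAX))
    n_under = int(np.count_nonzero(spectra < 0.0))
    if n_over or n_under:
        log.debug(
            "reconstruction overshoot: %d samples above %.2f, %d below 0",
            n_over, REFLECTANCE_MAX, n_under,
        )
    return np.clip(spectra, 0.0, REFLECTANCE_MAX)


def reconstruct_spectrum(
    model: ReconstructionModel, corrected_xyz
) -> SpectralCurve:
    """Analog spectrum S = mean + EV·M·V_color(XYZ_correct) for one pixel."""
    if isinstance(corrected_xyz, Tristimulus):
        corrected_xyz = corrected_xyz.as_array()
    xyz = np.asarray(corrected_xyz, dtype=float).reshape(1, 3)
    return SpectralCurve(_reconstruct_block(model, xyz)[0], model.basis.grid)


def convert_image(
    calib: CalibrationModel,
    image: np.ndarray,
    chunk_rows: int = 64,
) -> SpectralCube:
    """Convert an 8-bit sRGB image to a reflectance cube, pixel by pixel.

    Per pixel: sRGB decode → linear-RGB→XYZ → polynomial correction →
    spectral reconstruction. Rows are processed in chunks of ``chunk_rows``
    to bound working memory; the result is identical for any chunk size.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H×W×3 RGB image, got shape {img.shape}")
    if chunk_rows < 1:
        raise ValueError("chunk_rows must be >= 1")
    H, W, _ = img.shape
    bands = calib.grid.count
    out = np.empty((H, W, bands), dtype=np.float32)
    Ccorr = calib.correction.C
    for r0 in range(0, H, chunk_rows):
        r1 = min(r0 + chunk_rows, H)
        block = img[r0:r1].reshape(-1, 3).astype(float)
        lin = srgb_eotf(block / 255.0)
        xyz = 100.0 * _acc_matmul(lin, SRGB_TO_XYZ)
        corrected = _acc_matmul(expand(xyz, calib.correction.spec), Ccorr)
        spectra = _reconstruct_block(calib.reconstruction, corrected)
        out[r0:r1] = spectra.reshape(r1 - r0, W, bands).astype(np.float32)
    return SpectralCube(out, calib.grid)


def spectral_rmse(reconstructed, reference, grid: WavelengthGrid = GRID):
    """Per-spectrum RMSE over the grid's bands and their mean.

    Returns ``(per_item, average)`` where ``per_item`` is an array with one
    RMSE (reflectance units) per spectrum pair.
    """
    a = _stack_spectra(reconstructed, grid)
    b = _stack_spectra(reference, grid)
    if a.shape != b.shape:
        raise ValueError(f"count mismatch: {a.shape[0]} vs {b.shape[0]}")
    per = np.sqrt(np.mean((a - b) ** 2, axis=1))
    return per, float(per.mean())
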