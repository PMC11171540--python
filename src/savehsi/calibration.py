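"""Camera-error correction against a 24-patch colour target.

A consumer endoscope camera does not report colorimetric XYZ: its output is
perturbed by a nonlinear response, dark current, colour-filter separation
and colour shift. The correction step models the *reference* tristimulus
values (obtained from spectrometer-measured patch reflectances) as a fixed
polynomial of the *camera-derived* tristimulus values:

    XYZ_correct = C · V(XYZ_camera)

where V expands XYZ into a configurable family of monomials (constant,
linear, cross and power terms) and C is the 3 × n_terms least-squares
solution C = XYZ_ref · pinv(V) over the stacked patch columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colorimetry import (
    GRID,
    ColorMatchingFunctions,
    SpectralCurve,
    Tristimulus,
    WavelengthGrid,
    cie_1931_cmfs,
    linear_rgb_image_to_xyz,
    spectra_to_xyz,
    srgb_eotf,
)

__all__ = [
    "ExpansionSpec",
    "PatchMeasurementSet",
    "CorrectionModel",
    "default_expansion",
    "expand",
    "fit_correction",
    "apply_correction",
    "xyz_rmse",
    "UnderdeterminedError",
]

PINV_RTOL = 1e-10  # documented rank-revealing tolerance for all pinv calls


class UnderdeterminedError(ValueError):
    """Fewer training patches than expansion terms (no silent regularization)."""


@dataclass(frozen=True)
class ExpansionSpec:
    """Ordered monomial family defining the variable matrix V.

    Each term is a triple of non-negative exponents ``(a, b, c)`` mapping
    XYZ to ``X^a · Y^b · Z^c``; ``include_constant`` prepends a 1 term.
    The three linear terms must always be present — without them the model
    could not even represent an already-correct camera.
    """

    terms: tuple[tuple[int, int, int], ...]
    include_constant: bool = True

    def __post_init__(self) -> None:
        terms = tuple(tuple(int(e) for e in t) for t in self.terms)
        if not terms:
            raise ValueError("expansion needs at least one term")
        if len(set(terms)) != len(terms):
            raise ValueError("duplicate expansion terms")
        if any(len(t) != 3 or min(t) < 0 for t in terms):
            raise ValueError("terms are exponent triples of non-negative ints")
        for lin in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
            if lin not in terms:
                raise ValueError("the three linear terms X, Y, Z are required")
        object.__setattr__(self, "terms", terms)

    @property
    def n_terms(self) -> int:
        return len(self.terms) + (1 if self.include_constant else 0)

    def labels(self) -> list[str]:
        out = ["1"] if self.include_constant else []
        for a, b, c in self.terms:
            lbl = "".join(
                s * e for s, e in zip("XYZ", (a, b, c))
            )
            out.append(lbl or "1")
        return out


def default_expansion() -> ExpansionSpec:
    """The 14-term default: 1, X, Y, Z, all degree-2 monomials, XYZ, cubes.

    The constant term absorbs dark-current offset, the cross terms
    colour-filter separation and colour shift, and the square/cube terms the
    nonlinear channel response.
    """
    terms = [
        (1, 0, 0), (0, 1, 0), (0, 0, 1),                    # linear
        (2, 0, 0), (0, 2, 0), (0, 0, 2),                    # squares
        (1, 1, 0), (1, 0, 1), (0, 1, 1),                    # cross terms
        (1, 1, 1),                                          # XYZ
        (3, 0, 0), (0, 3, 0), (0, 0, 3),                    # cubes
    ]
    return ExpansionSpec(tuple(terms), include_constant=True)


def expand(xyz, spec: ExpansionSpec) -> np.ndarray:
    """Evaluate the monomial family on XYZ values.

    ``xyz`` is a :class:`Tristimulus`, a triple, or an ``(..., 3)`` array;
    the result has shape ``(..., n_terms)`` in the spec's deterministic
    term order (constant first when enabled).
    """
    if isinstance(xyz, Tristimulus):
        xyz = xyz.as_array()
    arr = np.asarray(xyz, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("xyz must have a trailing axis of size 3")
    cols = []
    if spec.include_constant:
        cols.append(np.ones(arr.shape[:-1]))
    X, Y, Z = arr[..., 0], arr[..., 1], arr[..., 2]
    for a, b, c in spec.terms:
        cols.append(X**a * Y**b * Z**c)
    return np.stack(cols, axis=-1)


@dataclass(frozen=True)
class PatchMeasurementSet:
    """Paired camera readings and reference spectra for a colour target.

    ``camera_rgb`` holds 8-bit sRGB triples (floats allowed, e.g. averaged
    over a patch region); ``reference_spectra`` the spectrometer reflectance
    of each patch; both indexed by ``patch_ids``.
    """

    patch_ids: tuple[str, ...]
    camera_rgb: np.ndarray           # (n, 3), 0-255 sRGB-encoded
    reference_spectra: np.ndarray    # (n, bands) reflectance
    illuminant: SpectralCurve
    grid: WavelengthGrid = GRID

    def __post_init__(self) -> None:
        ids = tuple(str(i) for i in self.patch_ids)
        if len(set(ids)) != len(ids):
            raise ValueError("patch ids must be unique")
        rgb = np.asarray(self.camera_rgb, dtype=float)
        refl = np.asarray(self.reference_spectra, dtype=float)
        n = len(ids)
        if rgb.shape != (n, 3):
            raise ValueError(f"camera_rgb must be ({n}, 3)")
        if refl.shape != (n, self.grid.count):
            raise ValueError(f"reference_spectra must be ({n}, {self.grid.count})")
        if self.illuminant.grid != self.grid:
            raise ValueError("illuminant grid mismatch")
        object.__setattr__(self, "patch_ids", ids)
        object.__setattr__(self, "camera_rgb", rgb)
        object.__setattr__(self, "reference_spectra", refl)

    @property
    def n_patches(self) -> int:
        return len(self.patch_ids)

    def camera_xyz(self) -> np.ndarray:
        """Camera-derived XYZ: sRGB decode then the standard matrix, (n, 3).

        Uses the extended (non-validating) transfer so that patch readings
        averaged or simulated slightly outside [0, 255] still decode.
        """
        return linear_rgb_image_to_xyz(srgb_eotf(self.camera_rgb / 255.0))

    def reference_xyz(self, cmfs: ColorMatchingFunctions) -> np.ndarray:
        """Spectrometer-derived XYZ via spectrum integration, (n, 3)."""
        return spectra_to_xyz(self.reference_spectra, self.illuminant, cmfs)


@dataclass(frozen=True)
class CorrectionModel:
    """Fitted correction C with its expansion spec and training diagnostics."""

    C: np.ndarray                    # (3, n_terms)
    spec: ExpansionSpec
    residuals: np.ndarray            # (n_patches, 3) corrected - reference
    rmse: float                      # pooled over 3 components x n patches

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if C.shape != (3, self.spec.n_terms):
            raise ValueError("C shape inconsistent with expansion spec")
        if not np.all(np.isfinite(C)):
            raise ValueError("C contains non-finite entries")
        object.__setattr__(self, "C", C)


def fit_correction(
    measurements: PatchMeasurementSet,
    spec: ExpansionSpec | None = None,
    cmfs: ColorMatchingFunctions | None = None,
) -> CorrectionModel:
    """Fit C = XYZ_ref · pinv(V) over the stacked patch columns.

    Reference XYZ is computed internally from each patch's reflectance via
    spectrum integration under the set's illuminant. Raises
    :class:`UnderdeterminedError` when patches < n_terms, and a rank error
    when the expanded design matrix is rank-deficient.
    """
    spec = spec or default_expansion()
    cmfs = cmfs or cie_1931_cmfs(measurements.grid)
    n = measurements.n_patches
    if n < spec.n_terms:
        raise UnderdeterminedError(
            f"{n} patches cannot determine {spec.n_terms} expansion terms"
        )
    cam_xyz = measurements.camera_xyz()
    ref_xyz = measurements.reference_xyz(cmfs)
    V = expand(cam_xyz, spec).T                     # (n_terms, n)
    rank = np.linalg.matrix_rank(V, tol=PINV_RTOL * np.linalg.norm(V, 2))
    if rank < spec.n_terms:
        raise np.linalg.LinAlgError(
            f"expanded design matrix is rank deficient ({rank} < {spec.n_terms})"
        )
    C = ref_xyz.T @ np.linalg.pinv(V, rcond=PINV_RTOL)   # (3, n_terms)
    corrected = (C @ V).T
    resid = corrected - ref_xyz
    rmse = float(np.sqrt(np.mean(resid**2)))
    return CorrectionModel(C=C, spec=spec, residuals=resid, rmse=rmse)


def apply_correction(model: CorrectionModel, xyz):
    """Apply XYZ_correct = C · V(xyz).

    Accepts a single :class:`Tristimulus` (returned as such) or an
    ``(..., 3)`` array for whole image planes.
    """
    single = isinstance(xyz, Tristimulus)
    V = expand(xyz, model.spec)
    out = V @ model.C.T
    if single:
        return Tristimulus(*out)
    return out


def xyz_rmse(set_a, set_b) -> float:
    """Pooled RMSE between two equally long lists of tristimulus values.

    The mean square runs over all 3 components of all patches (a single
    pooled mean), then one square root.
    """
    a = _stack_xyz(set_a)
    b = _stack_xyz(set_b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def _stack_xyz(values) -> np.ndarray:
    if isinstance(values, np.ndarray):
        return values.reshape(-1, 3).astype(float)
    rows = [
        v.as_array() if isinstance(v, Tristimulus) else np.asarray(v, float)
        for v in values
    ]
    return np.stack(rows)
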