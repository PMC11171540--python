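"""End-to-end calibration: from paired patch measurements to a model.

``calibrate`` chains the three fitting stages — polynomial XYZ correction,
PCA basis of the reference reflectances, and the score-regression
transformation matrix — into one :class:`CalibrationModel` ready for
image conversion.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np

from . import __version__
from .calibration import (
    ExpansionSpec,
    PatchMeasurementSet,
    apply_correction,
    default_expansion,
    fit_correction,
)
from .colorimetry import (
    GRID,
    ColorMatchingFunctions,
    SpectralCurve,
    WavelengthGrid,
    cie_1931_cmfs,
    illuminant as named_illuminant,
    read_spectrum_csv,
)
from .reconstruction import (
    CalibrationModel,
    fit_basis,
    fit_transformation,
)

__all__ = ["calibrate", "read_calibration_manifest"]


def calibrate(
    measurements: PatchMeasurementSet,
    correction_spec: ExpansionSpec | None = None,
    color_spec: ExpansionSpec | None = None,
    variance_target: float = 0.999,
    k_max: int = 12,
    k: int | None = None,
    cmfs: ColorMatchingFunctions | None = None,
    provenance: dict | None = None,
) -> CalibrationModel:
    """Run the full calibration procedure on a patch measurement set.

    Stages: fit the correction C on camera vs spectrometer XYZ; correct
    the camera readings; fit the PCA basis of the reference reflectances;
    regress the PCA scores on the expanded corrected XYZ to obtain M.
    """
    correction_spec = correction_spec or default_expansion()
    color_spec = color_spec or default_expansion()
    cmfs = cmfs or cie_1931_cmfs(measurements.grid)
    correction = fit_correction(measurements, correction_spec, cmfs)
    corrected = apply_correction(correction, measurements.camera_xyz())
    basis = fit_basis(
        measurements.reference_spectra,
        variance_target=variance_target,
        k_max=k_max,
        k=k,
        grid=measurements.grid,
    )
    recon = fit_transformation(basis, corrected, color_spec)
    prov = {
        "created": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "package_version": __version__,
        "n_patches": measurements.n_patches,
        "k": basis.k,
    }
    prov.update(provenance or {})
    return CalibrationModel(
        correction=correction,
        reconstruction=recon,
        illuminant=measurements.illuminant,
        grid=measurements.grid,
        provenance=prov,
    )


def read_calibration_manifest(
    manifest_path,
    illuminant: str | SpectralCurve = "D65",
    grid: WavelengthGrid = GRID,
) -> PatchMeasurementSet:
    """Load a CSV manifest of patch ids, camera RGB and reflectance CSVs.

    The manifest has columns ``patch_id,r,g,b,spectrum_path`` with spectrum
    paths relative to the manifest's directory; each spectrum CSV is
    resampled onto the working grid on read.
    """
    import pandas as pd

    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    required = {"patch_id", "r", "g", "b", "spectrum_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{manifest_path}: missing columns {sorted(missing)}")
    spectra = []
    for rel in df["spectrum_path"]:
        p = Path(rel)
        if not p.is_absolute():
            p = manifest_path.parent / p
        spectra.append(read_spectrum_csv(p, grid).values)
    illum = (
        named_illuminant(illuminant, grid)
        if isinstance(illuminant, str)
        else illuminant
    )
    return PatchMeasurementSet(
        patch_ids=tuple(df["patch_id"].astype(str)),
        camera_rgb=df[["r", "g", "b"]].to_numpy(dtype=float),
        reference_spectra=np.stack(spectra),
        illuminant=illum,
        grid=grid,
    )
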