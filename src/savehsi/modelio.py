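"""Serialization of the fitted CalibrationModel.

The archive is a single zip file holding a plain-text ``header.json``
(expansion specs, PCA dimension, grid, provenance, format version) and one
``.npy`` payload per matrix. Loading reconstructs the exact matrices, so a
saved model converts images bit-identically to the model that produced it.
"""

from __future__ import annotations

import io
import json
import zipfile
from pathlib import Path

import numpy as np

from .calibration import CorrectionModel, ExpansionSpec
from .colorimetry import SpectralCurve, WavelengthGrid
from .reconstruction import CalibrationModel, PCABasis, ReconstructionModel

__all__ = ["save_model", "load_model"]

FORMAT_VERSION = 1

_ARRAYS = (
    "C", "residuals", "EV", "mean_spectrum", "scores",
    "explained_variance", "M", "illuminant",
)


def _spec_dict(spec: ExpansionSpec) -> dict:
    return {"terms": [list(t) for t in spec.terms],
            "include_constant": spec.include_constant}


def _spec_from(d: dict) -> ExpansionSpec:
    return ExpansionSpec(tuple(tuple(t) for t in d["terms"]),
                         include_constant=d["include_constant"])


def save_model(path, model: CalibrationModel) -> Path:
    path = Path(path)
    g = model.grid
    header = {
        "format": "savehsi-calibration",
        "version": FORMAT_VERSION,
        "grid": {"start": g.start, "stop": g.stop, "step": g.step},
        "correction_spec": _spec_dict(model.correction.spec),
        "correction_rmse": model.correction.rmse,
        "color_spec": _spec_dict(model.reconstruction.color_spec),
        "k": model.reconstruction.basis.k,
        "provenance": model.provenance,
    }
    arrays = {
        "C": model.correction.C,
        "residuals": model.correction.residuals,
        "EV": model.reconstruction.basis.EV,
        "mean_spectrum": model.reconstruction.basis.mean_spectrum,
        "scores": model.reconstruction.basis.scores,
        "explained_variance": model.reconstruction.basis.explained_variance,
        "M": model.reconstruction.M,
        "illuminant": model.illuminant.values,
    }
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("header.json", json.dumps(header, indent=2))
        for name, arr in arrays.items():
            buf = io.BytesIO()
            np.save(buf, np.asarray(arr))
            zf.writestr(f"{name}.npy", buf.getvalue())
    return path


def load_model(path) -> CalibrationModel:
    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        header = json.loads(zf.read("header.json"))
        if header.get("format") != "savehsi-calibration":
            raise ValueError(f"{path} is not a savehsi calibration archive")
        if header["version"] > FORMAT_VERSION:
            raise ValueError(f"archive version {header['version']} is newer "
                             f"than supported ({FORMAT_VERSION})")
        arrays = {
            name: np.load(io.BytesIO(zf.read(f"{name}.npy")))
            for name in _ARRAYS
        }
    g = header["grid"]
    grid = WavelengthGrid(g["start"], g["stop"], g["step"])
    correction = CorrectionModel(
        C=arrays["C"],
        spec=_spec_from(header["correction_spec"]),
        residuals=arrays["residuals"],
        rmse=float(header["correction_rmse"]),
    )
    basis = PCABasis(
        EV=arrays["EV"],
        mean_spectrum=arrays["mean_spectrum"],
        scores=arrays["scores"],
        explained_variance=arrays["explained_variance"],
        grid=grid,
    )
    recon = ReconstructionModel(
        M=arrays["M"], color_spec=_spec_from(header["color_spec"]), basis=basis
    )
    illum = SpectralCurve(arrays["illuminant"], grid, kind="power")
    return CalibrationModel(
        correction=correction,
        reconstruction=recon,
        illuminant=illum,
        grid=grid,
        provenance=header.get("provenance", {}),
    )
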