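"""ENVI-style spectral cube I/O: text header + band-sequential binary.

Two modes:

* lossless — float32 payload (ENVI data type 4), bit-exact round trip of
  the cube's native storage;
* 16-bit  — uint16 payload (data type 12) with the reflectance range
  [0, 1.2] mapped onto [0, 65535]; about 2× smaller, quantized.

Only the small subset of the ENVI dialect this package writes is parsed
back (BSQ interleave, little-endian, types 4 and 12).
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .colorimetry import REFLECTANCE_MAX, WavelengthGrid
from .reconstruction import SpectralCube

__all__ = ["write_envi", "read_envi"]

_DTYPE = {4: np.float32, 12: np.uint16}


def _header_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".hdr") if path.suffix != ".hdr" else path


def write_envi(path, cube: SpectralCube, mode: str = "lossless") -> Path:
    """Write ``cube`` as ``<path>`` (binary) plus ``<path>.hdr`` (text).

    ``mode`` is ``"lossless"`` (float32) or ``"uint16"`` (lossy 16-bit).
    Returns the binary path.
    """
    path = Path(path)
    if mode == "lossless":
        dtype_code = 4
        payload = cube.values.astype(np.float32, copy=False)
    elif mode == "uint16":
        dtype_code = 12
        scaled = np.clip(cube.values / REFLECTANCE_MAX, 0.0, 1.0)
        payload = np.round(scaled * 65535.0).astype(np.uint16)
    else:
        raise ValueError("mode must be 'lossless' or 'uint16'")
    H, W = cube.height, cube.width
    g = cube.grid
    # BSQ: band-major on disk
    bsq = np.ascontiguousarray(np.moveaxis(payload, 2, 0))
    wl = ", ".join(f"{w:g}" for w in g.wavelengths)
    header = (
        "ENVI\n"
        "description = { savehsi reflectance cube }\n"
        f"samples = {W}\n"
        f"lines = {H}\n"
        f"bands = {g.count}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {dtype_code}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"reflectance scale factor = {REFLECTANCE_MAX if mode == 'uint16' else 1}\n"
        f"wavelength = {{ {wl} }}\n"
    )
    _header_path(path).write_text(header)
    bsq.tofile(path)
    return path


def _parse_header(text: str) -> dict:
    # collapse { ... } blocks onto one line before splitting on '='
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields = {}
    for line in text.splitlines():
        if "=" in line:
            key, _, val = line.partition("=")
            fields[key.strip().lower()] = val.strip()
    return fields


def read_envi(path) -> SpectralCube:
    """Read a cube written by :func:`write_envi`."""
    path = Path(path)
    hdr = _parse_header(_header_path(path).read_text())
    W = int(hdr["samples"])
    H = int(hdr["lines"])
    bands = int(hdr["bands"])
    dtype_code = int(hdr["data type"])
    if hdr.get("interleave", "bsq").lower() != "bsq":
        raise ValueError("only BSQ interleave is supported")
    if int(hdr.get("byte order", "0")) != 0:
        raise ValueError("only little-endian cubes are supported")
    if dtype_code not in _DTYPE:
        raise ValueError(f"unsupported ENVI data type {dtype_code}")
    wl_match = re.search(r"wavelength\s*=\s*\{([^}]*)\}", _header_path(path).read_text())
    if wl_match:
        wl = np.array([float(x) for x in wl_match.group(1).split(",")])
        grid = WavelengthGrid(wl[0], wl[-1], float(wl[1] - wl[0]))
    else:
        grid = WavelengthGrid()
    raw = np.fromfile(path, dtype=_DTYPE[dtype_code])
    if raw.size != H * W * bands:
        raise ValueError(f"{path}: payload size does not match header")
    cube = np.moveaxis(raw.reshape(bands, H, W), 0, 2)
    if dtype_code == 12:
        scale = float(hdr.get("reflectance scale factor", REFLECTANCE_MAX))
        cube = cube.astype(np.float32) * np.float32(scale / 65535.0)
    return SpectralCube(cube, grid)
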