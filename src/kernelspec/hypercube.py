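"""Hyperspectral cube container, plain-ENVI storage, and reflectance calibration.

A cube is a (rows, cols, bands) array with a strictly increasing wavelength
axis in nm.  Raw cubes hold camera counts; calibration against a dark-current
frame B and a white-reference frame W converts counts I0 to relative
reflectance  I = (I0 - B) / (W - B)  per pixel per band.  Pixels where
W - B <= 0 cannot be calibrated and are carried in an explicit validity mask
rather than propagated as inf/nan.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Hypercube",
    "ReferenceFrames",
    "EnviFormatError",
    "read_cube",
    "write_cube",
    "calibrate",
]

# ENVI "data type" codes for the dtypes this package round-trips.
ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in ENVI_DTYPES.items()}


class EnviFormatError(ValueError):
    """Malformed, incomplete, or contradictory ENVI header/raster pair."""


@dataclass
class Hypercube:
    """A (rows, cols, bands) image stack with band centers in nm.

    Parameters
    ----------
    data
        3-D array, band axis last.
    wavelengths
        Band centers in nm; strictly increasing, one per band.
    calibrated
        True once :func:`calibrate` has been applied.
    valid
        Optional boolean mask, broadcastable to ``data.shape``; False marks
        pixels whose reflectance is undefined (e.g. W - B <= 0).
    """

    data: np.ndarray
    wavelengths: np.ndarray
    calibrated: bool = False
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"cube must be 3-D (rows, cols, bands), got ndim={self.data.ndim}")
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise ValueError("wavelengths must be 1-D with one entry per band")
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.valid is not None:
            self.valid = np.broadcast_to(np.asarray(self.valid, bool), self.data.shape)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band_index(self, wavelength_nm: float) -> int:
        """Index of the band whose center is nearest ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))

    def band_image(self, index: int) -> np.ndarray:
        return self.data[:, :, index]

    def validity(self) -> np.ndarray:
        """Full boolean validity mask (all-True when no mask was set)."""
        if self.valid is None:
            return np.ones(self.data.shape, dtype=bool)
        return self.valid


@dataclass
class ReferenceFrames:
    """Dark-current (B) and white-panel (W) reference frames.

    Either full-frame per-band arrays (rows, cols, bands), per-line references
    (cols, bands) as produced by a line-scan camera, or per-band vectors
    (bands,); both must share one shape, broadcastable to the cube.
    """

    dark: np.ndarray
    white: np.ndarray

    def __post_init__(self) -> None:
        self.dark = np.asarray(self.dark, dtype=float)
        self.white = np.asarray(self.white, dtype=float)
        if self.dark.shape != self.white.shape:
            raise ValueError("dark and white frames must share a shape")
        if self.dark.ndim not in (1, 2, 3):
            raise ValueError("reference frames must be (bands,), (cols, bands) or (rows, cols, bands)")


# ---------------------------------------------------------------------------
# ENVI header + flat binary storage
# ---------------------------------------------------------------------------

def _parse_header(text: str) -> dict:
    if not text.lstrip().upper().startswith("ENVI"):
        raise EnviFormatError("header does not start with 'ENVI'")
    fields: dict[str, str] = {}
    # join {...} blocks onto one line
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, val = line.split("=", 1)
        fields[key.strip().lower()] = val.strip()
    return fields


def _require(fields: dict, key: str) -> str:
    if key not in fields:
        raise EnviFormatError(f"header missing required field '{key}'")
    return fields[key]


def read_cube(path: str | Path, header: str | Path | None = None) -> Hypercube:
    """Read a plain-ENVI cube (header + flat binary, BIL or BSQ).

    Parameters
    ----------
    path
        Raw binary raster file.
    header
        ENVI ``.hdr`` text header; defaults to ``path`` + ``.hdr``.
    """
    path = Path(path)
    header = Path(header) if header is not None else path.with_suffix(path.suffix + ".hdr")
    fields = _parse_header(header.read_text())

    lines = int(_require(fields, "lines"))
    samples = int(_require(fields, "samples"))
    bands = int(_require(fields, "bands"))
    interleave = _require(fields, "interleave").lower()
    dtype_code = int(_require(fields, "data type"))
    if dtype_code not in ENVI_DTYPES:
        raise EnviFormatError(f"unsupported ENVI data type code {dtype_code}")
    dtype = np.dtype(ENVI_DTYPES[dtype_code])
    byte_order = int(fields.get("byte order", "0"))
    dtype = dtype.newbyteorder("<" if byte_order == 0 else ">")

    wl_text = _require(fields, "wavelength")
    wl = np.array([float(x) for x in wl_text.strip("{} \n").split(",") if x.strip()])
    if len(wl) != bands:
        raise EnviFormatError(f"header declares {bands} bands but {len(wl)} wavelengths")

    raw = np.fromfile(path, dtype=dtype)
    expected = lines * samples * bands
    if raw.size != expected:
        raise EnviFormatError(
            f"raster has {raw.size} values, header implies {expected} "
            f"({lines}x{samples}x{bands})"
        )
    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:
        raise EnviFormatError(f"unsupported interleave '{interleave}' (need bil or bsq)")
    calibrated = fields.get("kernelspec calibrated", "0").strip() == "1"
    return Hypercube(np.ascontiguousarray(data), wl, calibrated=calibrated)


def write_cube(cube: Hypercube, path: str | Path, header: str | Path | None = None,
               interleave: str = "bsq") -> None:
    """Write ``cube`` as flat binary plus an ENVI header (default BSQ)."""
    path = Path(path)
    header = Path(header) if header is not None else path.with_suffix(path.suffix + ".hdr")
    dtype = np.dtype(cube.data.dtype).newbyteorder("=")
    if dtype not in _DTYPE_CODES:
        raise EnviFormatError(f"dtype {dtype} has no ENVI data-type code; cast first")
    rows, cols, bands = cube.shape
    interleave = interleave.lower()
    if interleave == "bsq":
        out = cube.data.transpose(2, 0, 1)
    elif interleave == "bil":
        out = cube.data.transpose(0, 2, 1)
    else:
        raise EnviFormatError(f"unsupported interleave '{interleave}'")
    np.ascontiguousarray(out).astype(dtype.newbyteorder("<")).tofile(path)
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    header.write_text(
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"kernelspec calibrated = {1 if cube.calibrated else 0}\n"
        f"wavelength = {{ {wl} }}\n"
    )


# ---------------------------------------------------------------------------
# Reflectance calibration
# ---------------------------------------------------------------------------

def calibrate(raw: Hypercube, refs: ReferenceFrames) -> Hypercube:
    """Dark/white reflectance calibration: I = (I0 - B) / (W - B).

    Pixels where W - B <= 0 are flagged invalid in the output's ``valid``
    mask (value set to 0 there) rather than silently yielding inf/nan.

    Raises
    ------
    ValueError
        If ``raw`` is already calibrated or shapes do not conform.
    """
    if raw.calibrated:
        raise ValueError("cube is already calibrated")
    dark, white = refs.dark, refs.white
    try:
        np.broadcast_shapes(raw.data.shape, dark.shape)
    except ValueError as exc:
        raise ValueError(
            f"reference frame shape {dark.shape} does not broadcast to cube {raw.data.shape}"
        ) from exc
    denom = white - dark
    valid = denom > 0
    safe = np.where(valid, denom, 1.0)
    out = (raw.data.astype(float) - dark) / safe
    valid_full = np.broadcast_to(valid, out.shape)
    if not valid_full.all():
        out = np.where(valid_full, out, 0.0)
        warnings.warn(
            f"{int((~valid_full).sum())} pixel-band samples have W - B <= 0; flagged invalid",
            stacklevel=2,
        )
        mask = valid_full
    else:
        mask = None
    return Hypercube(out, raw.wavelengths.copy(), calibrated=True, valid=mask)
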