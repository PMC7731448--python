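"""Reading and writing hyperspectral cubes (ENVI dialect) and spectra tables (CSV).

The on-disk cube format is the plain ENVI convention: a flat binary raster
plus a small text header (``.hdr``) declaring dimensions, interleave
(BIL/BIP/BSQ), data type and the per-band wavelength list in nm.  Spectra
tables are comma-separated text with one label column, an optional seed-id
column, and one numeric column per band named by its wavelength.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "HyperCube",
    "ReferenceFrame",
    "SpectraTable",
    "SeedspecError",
    "FormatError",
    "CorruptionError",
    "MetadataError",
    "ParseError",
    "read_envi_cube",
    "write_envi_cube",
    "read_spectra_csv",
    "write_spectra_csv",
]


class SeedspecError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(SeedspecError):
    """A file is missing or is not in the expected format."""


class CorruptionError(FormatError):
    """Header metadata and binary payload disagree (e.g. size mismatch)."""


class MetadataError(FormatError):
    """Required metadata (wavelengths, column names) absent or inconsistent."""


class ParseError(FormatError):
    """A cell of a text table could not be parsed; reports row and column."""


# ENVI numeric data-type codes actually supported by this dialect.
_ENVI_DTYPES = {4: np.float32, 5: np.float64, 12: np.uint16}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass
class HyperCube:
    """A hyperspectral raster: rows x cols x bands with a wavelength axis.

    Parameters
    ----------
    data
        3-D array indexed ``[row, col, band]``; raw detector counts (DN) or
        relative reflectance, depending on ``kind``.
    wavelengths
        Band-center wavelengths in nm, strictly increasing, one per band.
    kind
        ``"raw"`` (detector counts) or ``"reflectance"`` (calibrated).
    """

    data: np.ndarray
    wavelengths: np.ndarray
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D, got {self.data.ndim}-D")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise ValueError(
                f"wavelength count {len(self.wavelengths)} does not match "
                f"band dimension {self.data.shape[2]}"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.data.astype(float, copy=False))):
            raise ValueError("cube contains non-finite values")
        if self.kind not in ("raw", "reflectance"):
            raise ValueError(f"kind must be 'raw' or 'reflectance', got {self.kind!r}")

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def band_nearest(self, wavelength_nm: float) -> int:
        """0-based index of the band closest to ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))


@dataclass
class ReferenceFrame:
    """A white or dark calibration frame, broadcastable to a cube.

    ``data`` may be a full cube (rows x cols x bands), a single spatial
    frame, or a per-band vector; ``role`` is ``"white"`` or ``"dark"``.
    """

    data: np.ndarray
    role: str = "white"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.role not in ("white", "dark"):
            raise ValueError(f"role must be 'white' or 'dark', got {self.role!r}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("reference frame contains non-finite values")


@dataclass
class SpectraTable:
    """Per-seed (or per-pixel) reflectance spectra with variety labels.

    ``spectra`` is an n x B matrix; ``labels`` holds the variety identifier
    of each row; ``seed_ids`` records provenance (source cube, component
    index).  This is the sample set the classifiers train on.
    """

    spectra: np.ndarray
    labels: np.ndarray
    wavelengths: np.ndarray
    seed_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.labels = np.asarray(self.labels)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.spectra.ndim != 2 or self.spectra.shape[0] < 1:
            raise ValueError("spectra must be a 2-D matrix with at least one row")
        if len(self.labels) != self.spectra.shape[0]:
            raise ValueError("one label per spectrum required")
        if len(self.wavelengths) != self.spectra.shape[1]:
            raise ValueError("one wavelength per band column required")
        if not np.all(np.isfinite(self.spectra)):
            raise ValueError("spectra contain missing or non-finite values")
        if not self.seed_ids:
            self.seed_ids = [f"s{i}" for i in range(self.spectra.shape[0])]
        if len(self.seed_ids) != self.spectra.shape[0]:
            raise ValueError("one seed_id per spectrum required")

    @property
    def n_samples(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[1]

    @property
    def label_set(self) -> list:
        """Distinct labels in first-appearance order."""
        seen: dict = {}
        for lab in self.labels.tolist():
            seen.setdefault(lab, None)
        return list(seen)


# ---------------------------------------------------------------------------
# ENVI cubes
# ---------------------------------------------------------------------------

def _header_path(data_path: Path) -> Path:
    """Locate the .hdr companion: <stem>.hdr beside the data file, or
    <name>.hdr appended to the full filename."""
    cand = data_path.with_suffix(".hdr")
    if cand.exists():
        return cand
    cand2 = Path(str(data_path) + ".hdr")
    if cand2.exists():
        return cand2
    return cand  # default target for writing / error reporting


def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().upper().startswith("ENVI"):
        raise FormatError("not an ENVI header: missing 'ENVI' magic line")
    fields: dict[str, str] = {}
    # join brace-delimited multi-line values first
    body = text.split("\n", 1)[1] if "\n" in text else ""
    # normalize: collapse { ... } blocks onto one line
    def _collapse(match: re.Match) -> str:
        return match.group(0).replace("\n", " ")

    body = re.sub(r"\{[^}]*\}", _collapse, body)
    for line in body.splitlines():
        if "=" not in line:
            continue
        key, val = line.split("=", 1)
        fields[key.strip().lower()] = val.strip()
    return fields


def read_envi_cube(path: str | Path) -> HyperCube:
    """Read an ENVI raster (binary data + ``.hdr`` text header) into a cube.

    Raises
    ------
    FormatError
        If the header file is missing or malformed.
    CorruptionError
        If the binary payload size disagrees with the header dimensions.
    MetadataError
        If the header carries no wavelength list.
    """
    data_path = Path(path)
    hdr_path = _header_path(data_path)
    if not hdr_path.exists():
        raise FormatError(f"ENVI header not found: {hdr_path}")
    if not data_path.exists():
        raise FormatError(f"ENVI data file not found: {data_path}")
    fields = _parse_envi_header(hdr_path.read_text())

    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise MetadataError(f"ENVI header missing required field: {exc}") from exc
    if interleave not in ("bil", "bip", "bsq"):
        raise FormatError(f"unsupported interleave {interleave!r}")
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type code {dtype_code}")
    if "wavelength" not in fields:
        raise MetadataError("ENVI header has no wavelength list")
    wl_text = fields["wavelength"].strip()
    if not (wl_text.startswith("{") and wl_text.endswith("}")):
        raise MetadataError("malformed wavelength list (expected braces)")
    wavelengths = np.array(
        [float(w) for w in wl_text[1:-1].split(",") if w.strip()], dtype=float
    )
    if len(wavelengths) != bands:
        raise MetadataError(
            f"header declares {bands} bands but lists {len(wavelengths)} wavelengths"
        )

    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    byte_order = int(fields.get("byte order", "0"))
    if byte_order == 1:
        dtype = dtype.newbyteorder(">")
    offset = int(fields.get("header offset", "0"))
    raw = data_path.read_bytes()[offset:]
    expected = lines * samples * bands * dtype.itemsize
    if len(raw) != expected:
        raise CorruptionError(
            f"binary size {len(raw)} bytes does not match header "
            f"({lines}x{samples}x{bands} {dtype.name} = {expected} bytes)"
        )
    flat = np.frombuffer(raw, dtype=dtype)
    if interleave == "bip":
        data = flat.reshape(lines, samples, bands)
    elif interleave == "bil":
        data = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bsq
        data = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    kind = fields.get("data kind", "raw")
    if kind not in ("raw", "reflectance"):
        kind = "raw"
    return HyperCube(np.ascontiguousarray(data), wavelengths, kind=kind)


def write_envi_cube(
    cube: HyperCube, path: str | Path, interleave: str = "bil"
) -> None:
    """Write ``cube`` as an ENVI raster at ``path`` plus a ``.hdr`` header.

    The header records dimensions, interleave, data type, the wavelength
    list and the cube ``kind`` so that :func:`read_envi_cube` reproduces the
    cube exactly.
    """
    interleave = interleave.lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise ValueError(f"unsupported interleave {interleave!r}")
    dt = np.dtype(cube.data.dtype)
    if dt not in _DTYPE_CODES:
        raise ValueError(
            f"unsupported cube dtype {dt}; use uint16, float32 or float64"
        )
    data_path = Path(path)
    hdr_path = data_path.with_suffix(".hdr")
    lines, samples, bands = cube.shape
    if interleave == "bip":
        arr = cube.data
    elif interleave == "bil":
        arr = cube.data.transpose(0, 2, 1)
    else:
        arr = cube.data.transpose(2, 0, 1)
    try:
        data_path.write_bytes(np.ascontiguousarray(arr).tobytes())
    except OSError as exc:
        raise SeedspecError(f"cannot write ENVI data to {data_path}: {exc}") from exc
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        "description = {seedspec hyperspectral cube}\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[dt]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"data kind = {cube.kind}\n"
        "wavelength units = nm\n"
        f"wavelength = {{{wl}}}\n"
    )
    hdr_path.write_text(header)


# ---------------------------------------------------------------------------
# Spectra tables
# ---------------------------------------------------------------------------

_LABEL_COL = "label"
_SEED_COL = "seed_id"


def write_spectra_csv(table: SpectraTable, path: str | Path) -> None:
    """Write a spectra table as CSV: label, seed_id, then one column per
    band named by wavelength (nm, 4 decimals).  Values are written at full
    float precision so a round trip is lossless."""
    cols = [f"{w:.4f}" for w in table.wavelengths]
    df = pd.DataFrame(table.spectra, columns=cols)
    df.insert(0, _SEED_COL, table.seed_ids)
    df.insert(0, _LABEL_COL, [str(l) for l in table.labels])
    # %.17g keeps every float64 bit, so a round trip is lossless
    df.to_csv(path, index=False, float_format="%.17g")


def read_spectra_csv(path: str | Path) -> SpectraTable:
    """Read a spectra table written by :func:`write_spectra_csv` (or any CSV
    with a ``label`` column and wavelength-named numeric band columns).

    Raises
    ------
    MetadataError
        On a missing label column, duplicated wavelength columns, or band
        columns not parseable as wavelengths.
    ParseError
        On a non-numeric band cell, reporting its row and column.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        header = next(csv.reader(fh), None)
    if header is None:
        raise FormatError(f"empty CSV file: {path}")
    if _LABEL_COL not in header:
        raise MetadataError(f"CSV has no '{_LABEL_COL}' column: {path}")
    band_cols = [c for c in header if c not in (_LABEL_COL, _SEED_COL)]
    if len(set(band_cols)) != len(band_cols):
        dupes = sorted({c for c in band_cols if band_cols.count(c) > 1})
        raise MetadataError(f"duplicated wavelength columns: {dupes}")
    try:
        wavelengths = np.array([float(c) for c in band_cols], dtype=float)
    except ValueError as exc:
        raise MetadataError(f"band column name is not a wavelength: {exc}") from exc

    df = pd.read_csv(
        path, dtype={_LABEL_COL: str, _SEED_COL: str}, float_precision="round_trip"
    )
    for col in band_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {df[col].iloc[row]!r} at row {row + 2}, "
                f"column {col!r}"
            )
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise ParseError(f"missing value at row {row + 2}, column {col!r}")
        df[col] = numeric
    seed_ids = (
        df[_SEED_COL].tolist() if _SEED_COL in df.columns else []
    )
    return SpectraTable(
        spectra=df[band_cols].to_numpy(dtype=float),
        labels=df[_LABEL_COL].to_numpy(),
        wavelengths=wavelengths,
        seed_ids=seed_ids,
    )
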