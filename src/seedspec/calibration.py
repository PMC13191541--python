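"""Hyperspectral cube IO, reflectance calibration, and ROI spectrum extraction.

A push-broom VNIR camera records raw digital numbers (DN).  Converting DN to
relative reflectance requires a dark-current reference frame and a white
(Spectralon) reference frame::

    R = (DN - dark) / (white - dark)

One seed contributes a single spectrum: the per-band arithmetic mean over a
fixed square pixel block (region of interest, ROI) placed inside the seed.

Cubes are read and written in the ENVI convention (ASCII ``.hdr`` sidecar plus
a flat binary file, interleave ``bil``/``bip``/``bsq``), and seed-level spectra
tables as wide CSV (``seed_id``, ``accession``, one column per wavelength).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# ENVI numeric data-type codes used here (little-endian only).
_ENVI_DTYPES = {4: np.dtype("<f4"), 12: np.dtype("<u2")}
_ENVI_CODES = {np.dtype("<f4"): 4, np.dtype("float32"): 4,
               np.dtype("<u2"): 12, np.dtype("uint16"): 12}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength axis in nanometres, inclusive of both endpoints."""

    start_nm: float
    end_nm: float
    n_bands: int
    values: np.ndarray = field(repr=False)

    @property
    def spacing_nm(self) -> float:
        return (self.end_nm - self.start_nm) / (self.n_bands - 1)

    def __len__(self) -> int:
        return self.n_bands


def build_wavelength_grid(start_nm: float, end_nm: float, n_bands: int) -> WavelengthGrid:
    """Build a uniform grid of ``n_bands`` wavelengths from start to end inclusive.

    Raises
    ------
    ValueError
        If the span is non-positive or fewer than two bands are requested.
    """
    if n_bands < 2:
        raise ValueError(f"n_bands must be >= 2, got {n_bands}")
    if not end_nm > start_nm:
        raise ValueError(f"end_nm ({end_nm}) must exceed start_nm ({start_nm})")
    values = np.linspace(start_nm, end_nm, n_bands)
    return WavelengthGrid(float(start_nm), float(end_nm), int(n_bands), values)


@dataclass(frozen=True)
class ROISpec:
    """A square pixel block inside a cube; 0-based, half-open row/col ranges."""

    seed_id: str
    top_row: int
    left_col: int
    height: int = 10
    width: int = 10


@dataclass
class HyperCube:
    """Raw digital-number cube (lines x samples x bands) with reference frames.

    ``dark`` and ``white`` are per-band reference vectors (already averaged
    over their acquisition lines).
    """

    dn: np.ndarray
    dark: np.ndarray
    white: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self) -> None:
        if self.dn.ndim != 3:
            raise ValueError(f"cube must be 3-D (lines, samples, bands), got {self.dn.shape}")
        b = self.dn.shape[2]
        if b != self.grid.n_bands:
            raise ValueError(f"cube has {b} bands but grid has {self.grid.n_bands}")
        if self.dark.shape != (b,) or self.white.shape != (b,):
            raise ValueError("dark/white references must be per-band vectors matching the cube")


@dataclass
class SpectralDataset:
    """N x P reflectance matrix with wavelength grid, labels, and seed ids.

    The central object of the pipeline: one row per seed, one column per band.
    """

    X: np.ndarray
    grid: WavelengthGrid
    labels: np.ndarray
    seed_ids: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        self.seed_ids = np.asarray(self.seed_ids)
        n, p = self.X.shape
        if p != self.grid.n_bands:
            raise ValueError(f"X has {p} columns but grid has {self.grid.n_bands} bands")
        if len(self.labels) != n or len(self.seed_ids) != n:
            raise ValueError("labels/seed_ids length must equal the number of rows")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> np.ndarray:
        """Sorted unique accession labels."""
        return np.unique(self.labels)


# ---------------------------------------------------------------------------
# Reflectance calibration and ROI extraction
# ---------------------------------------------------------------------------

def to_reflectance(cube: HyperCube) -> np.ndarray:
    """Convert raw DN to relative reflectance, R = (DN - dark)/(white - dark).

    The output is *not* clipped: clipping to [0, 1] is a preprocessing
    decision.  Bands where white equals dark (dead bands) are set to 0 and a
    warning is logged so a single dead band cannot abort a session.
    """
    denom = cube.white.astype(float) - cube.dark.astype(float)
    dead = denom == 0
    if dead.any():
        logger.warning("%d dead band(s) (white == dark) set to reflectance 0: indices %s",
                       dead.sum(), np.flatnonzero(dead).tolist())
    safe = np.where(dead, 1.0, denom)
    refl = (cube.dn.astype(float) - cube.dark) / safe
    refl[:, :, dead] = 0.0
    return refl


def extract_roi_spectrum(reflectance: np.ndarray, roi: ROISpec) -> np.ndarray:
    """Per-band mean reflectance over the ROI pixel block (one spectrum per seed)."""
    lines, samples, _ = reflectance.shape
    r0, r1 = roi.top_row, roi.top_row + roi.height
    c0, c1 = roi.left_col, roi.left_col + roi.width
    if r0 < 0 or c0 < 0 or r1 > lines or c1 > samples:
        raise ValueError(
            f"ROI {roi.seed_id!r} [{r0}:{r1}, {c0}:{c1}] is outside the "
            f"{lines}x{samples} cube extent")
    return reflectance[r0:r1, c0:c1, :].mean(axis=(0, 1))


# ---------------------------------------------------------------------------
# ENVI cube IO
# ---------------------------------------------------------------------------

def write_envi_cube(cube: HyperCube, path: str | Path, interleave: str = "bil") -> None:
    """Write a cube as ENVI: ASCII header at ``<path>.hdr`` plus raw binary.

    Little-endian; data types uint16 (code 12) and float32 (code 4).  The
    dark and white reference vectors ride along in the header so that a
    write -> read round trip reproduces the full :class:`HyperCube`.
    """
    path = Path(path)
    interleave = interleave.lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise ValueError(f"unsupported interleave {interleave!r}; expected bil, bip or bsq")
    dn = np.ascontiguousarray(cube.dn)
    code = _ENVI_CODES.get(dn.dtype)
    if code is None:
        raise ValueError(f"unsupported data type {dn.dtype}; expected uint16 or float32")
    lines, samples, bands = dn.shape

    if interleave == "bip":
        ordered = dn  # (lines, samples, bands)
    elif interleave == "bil":
        ordered = dn.transpose(0, 2, 1)  # (lines, bands, samples)
    else:  # bsq
        ordered = dn.transpose(2, 0, 1)  # (bands, lines, samples)

    def _vec(v: np.ndarray) -> str:
        return " , ".join(repr(float(x)) for x in v)

    hdr = "\n".join([
        "ENVI",
        "description = { seedspec hyperspectral cube }",
        f"samples = {samples}",
        f"lines = {lines}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {code}",
        f"interleave = {interleave}",
        "byte order = 0",
        "wavelength units = Nanometers",
        "wavelength = { " + _vec(cube.grid.values) + " }",
        "dark reference = { " + _vec(cube.dark) + " }",
        "white reference = { " + _vec(cube.white) + " }",
        "",
    ])
    path.with_suffix(path.suffix + ".hdr").write_text(hdr)
    ordered.astype(_ENVI_DTYPES[code]).tofile(path)
    logger.info("wrote ENVI cube %s: %dx%dx%d %s %s", path, lines, samples, bands,
                interleave, dn.dtype)


def _parse_envi_header(text: str) -> dict:
    """Parse ENVI's ``key = value`` header lines, including {...} blocks."""
    fields: dict[str, str] = {}
    # collapse multi-line { ... } groups first
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def read_envi_cube(path: str | Path) -> HyperCube:
    """Read an ENVI cube written by :func:`write_envi_cube`.

    Raises an explicit error for unsupported interleaves or data types, and
    when the header's wavelength count does not match the band count.
    """
    path = Path(path)
    hdr_path = path.with_suffix(path.suffix + ".hdr")
    if not hdr_path.exists():
        raise FileNotFoundError(f"ENVI header not found: {hdr_path}")
    fields = _parse_envi_header(hdr_path.read_text())

    for required in ("samples", "lines", "bands", "interleave", "data type", "wavelength"):
        if required not in fields:
            raise ValueError(f"ENVI header {hdr_path} is missing required field {required!r}")

    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    interleave = fields["interleave"].lower()
    code = int(fields["data type"])
    if interleave not in ("bil", "bip", "bsq"):
        raise ValueError(f"unsupported interleave {interleave!r}")
    if code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type code {code}; supported: 4 (float32), 12 (uint16)")
    if int(fields.get("byte order", "0")) != 0:
        raise ValueError("only little-endian (byte order = 0) ENVI files are supported")

    def _vec(key: str) -> np.ndarray:
        raw = fields[key].strip()
        if not (raw.startswith("{") and raw.endswith("}")):
            raise ValueError(f"malformed {key!r} field in {hdr_path}")
        return np.array([float(tok) for tok in raw[1:-1].split(",") if tok.strip()])

    wavelengths = _vec("wavelength")
    if len(wavelengths) != bands:
        raise ValueError(f"wavelength list has {len(wavelengths)} entries but bands = {bands}")

    raw = np.fromfile(path, dtype=_ENVI_DTYPES[code])
    expected = lines * samples * bands
    if raw.size != expected:
        raise ValueError(f"binary size mismatch in {path}: {raw.size} values, expected {expected}")
    if interleave == "bip":
        dn = raw.reshape(lines, samples, bands)
    elif interleave == "bil":
        dn = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bsq
        dn = raw.reshape(bands, lines, samples).transpose(1, 2, 0)

    grid = build_wavelength_grid(float(wavelengths[0]), float(wavelengths[-1]), bands)
    dark = _vec("dark reference") if "dark reference" in fields else np.zeros(bands)
    white = _vec("white reference") if "white reference" in fields else np.ones(bands)
    logger.info("read ENVI cube %s: %dx%dx%d %s, grid %.2f-%.2f nm", path, lines,
                samples, bands, interleave, grid.start_nm, grid.end_nm)
    return HyperCube(dn=np.ascontiguousarray(dn), dark=dark, white=white, grid=grid)


# ---------------------------------------------------------------------------
# Spectra-table CSV IO
# ---------------------------------------------------------------------------

def write_dataset_csv(dataset: SpectralDataset, path: str | Path) -> None:
    """Write a wide CSV: seed_id, accession, then one column per wavelength (%.2f nm)."""
    cols = [f"{w:.2f}" for w in dataset.grid.values]
    df = pd.DataFrame(dataset.X, columns=cols)
    df.insert(0, "accession", dataset.labels)
    df.insert(0, "seed_id", dataset.seed_ids)
    df.to_csv(path, index=False)
    logger.info("wrote dataset CSV %s: N=%d, P=%d", path, dataset.n, dataset.p)


def read_dataset_csv(path: str | Path) -> SpectralDataset:
    """Read a wide spectra CSV back into a :class:`SpectralDataset`.

    Wavelength column headers are parsed as nanometres (a trailing ``nm``
    suffix is tolerated) and must form a uniform grid to within the printed
    precision; labels stay paired with their rows regardless of row order.
    """
    df = pd.read_csv(path)
    if "seed_id" not in df.columns or "accession" not in df.columns:
        raise ValueError(f"{path}: expected 'seed_id' and 'accession' columns")
    wl_cols = [c for c in df.columns if c not in ("seed_id", "accession")]
    wavelengths = np.array([float(re.sub(r"\s*nm\s*$", "", c)) for c in wl_cols])
    if len(wavelengths) < 2 or np.any(np.diff(wavelengths) <= 0):
        raise ValueError(f"{path}: wavelength columns are not strictly increasing")
    grid = build_wavelength_grid(wavelengths[0], wavelengths[-1], len(wavelengths))
    # headers carry 2 printed decimals, so allow rounding slack of half a unit
    if np.max(np.abs(grid.values - wavelengths)) > 0.006:
        raise ValueError(f"{path}: wavelength columns are not uniformly spaced")
    dataset = SpectralDataset(
        X=df[wl_cols].to_numpy(dtype=float),
        grid=grid,
        labels=df["accession"].to_numpy(),
        seed_ids=df["seed_id"].to_numpy(),
    )
    logger.info("read dataset CSV %s: N=%d, P=%d, grid %.2f-%.2f nm", path,
                dataset.n, dataset.p, grid.start_nm, grid.end_nm)
    return dataset
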