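"""Spectral dataset container and on-disk formats (CSV, ENVI).

The canonical in-memory unit is :class:`SpectralDataset`: an [N, D]
reflectance array, one integer class label per row, the D band-center
wavelengths in nm, and class names. CSV is the canonical interchange
format (one row per pixel, one column per band plus a ``label`` column);
ENVI header + raw binary pairs (BSQ/BIL/BIP interleaves) are supported
because imaging spectrometers emit them, with a label raster whose
sentinel value marks unlabeled pixels.

Band order is always ascending wavelength; the network's "sequential"
scan direction is low-to-high wavelength and "reverse" is high-to-low.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SpectralDataset", "read_csv_dataset", "write_csv_dataset",
           "read_envi_cube", "write_envi_cube", "UNLABELED"]

UNLABELED = -1  # sentinel in label rasters

_WL_COL = re.compile(r"^wl_([0-9.+-eE]+)$")


@dataclass
class SpectralDataset:
    """N labeled reflectance vectors plus band metadata."""

    spectra: np.ndarray              # [N, D] float
    labels: np.ndarray               # [N] int in [0, C)
    wavelengths: np.ndarray          # [D] nm, strictly increasing
    class_names: list[str] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self):
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.spectra.ndim != 2:
            raise ValueError("spectra must be a 2-D [N, D] array")
        n, d = self.spectra.shape
        if self.labels.shape != (n,):
            raise ValueError("labels must align with spectra rows")
        if self.wavelengths.shape != (d,):
            raise ValueError("wavelengths must align with spectra columns")
        if d > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.spectra)):
            raise ValueError("spectra contain non-finite values")
        if n and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if not self.class_names:
            c = int(self.labels.max()) + 1 if n else 0
            self.class_names = [f"class {i}" for i in range(c)]
        if n and self.labels.max() >= len(self.class_names):
            raise ValueError("label outside [0, number of classes)")

    @property
    def n_samples(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.spectra).tobytes())
        h.update(np.ascontiguousarray(self.labels).tobytes())
        h.update(np.ascontiguousarray(self.wavelengths).tobytes())
        return h.hexdigest()

    def subset(self, idx) -> "SpectralDataset":
        return SpectralDataset(self.spectra[idx], self.labels[idx],
                               self.wavelengths, list(self.class_names),
                               provenance=self.provenance)


# --------------------------------------------------------------------------
# CSV
# --------------------------------------------------------------------------

def write_csv_dataset(ds: SpectralDataset, path) -> Path:
    path = Path(path)
    cols = [f"wl_{w:.5f}" for w in ds.wavelengths]
    df = pd.DataFrame(ds.spectra, columns=cols)
    df["label"] = ds.labels
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_csv_dataset(path, wavelength_range: tuple[float, float] = (400.0, 1000.0),
                     class_names: list[str] | None = None) -> SpectralDataset:
    """Read an [N, D] spectra table with a ``label`` column.

    Wavelengths are parsed from ``wl_<nm>`` headers when present, else
    inferred linearly over ``wavelength_range``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError(f"{path}: missing required 'label' column "
                         f"(columns found: {list(df.columns)[:5]}...)")
    feat_cols = [c for c in df.columns if c != "label"]
    if not feat_cols:
        raise ValueError(f"{path}: no reflectance columns found")

    feats = df[feat_cols].apply(pd.to_numeric, errors="coerce")
    bad = feats.isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        col = feats.columns[feats.iloc[row].isna().to_numpy()][0]
        raise ValueError(f"{path}: non-numeric reflectance at data line "
                         f"{row + 2}, column '{col}'")
    labels = pd.to_numeric(df["label"], errors="coerce")
    if labels.isna().any():
        row = int(np.flatnonzero(labels.isna().to_numpy())[0])
        raise ValueError(f"{path}: non-numeric label at data line {row + 2}")
    labels = labels.to_numpy()
    if not np.allclose(labels, np.round(labels)):
        raise ValueError(f"{path}: labels must be integers")

    wl = []
    for c in feat_cols:
        m = _WL_COL.match(c)
        if not m:
            wl = None
            break
        wl.append(float(m.group(1)))
    if wl is None:
        lo, hi = wavelength_range
        wl = np.linspace(lo, hi, len(feat_cols))
    return SpectralDataset(feats.to_numpy(float), labels.astype(np.int64),
                           np.asarray(wl, dtype=float),
                           class_names=list(class_names) if class_names else [],
                           provenance=str(path))


# --------------------------------------------------------------------------
# ENVI header + raw binary
# --------------------------------------------------------------------------

_DTYPE = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
          5: np.float64, 12: np.uint16}
_DTYPE_CODE = {np.dtype(v): k for k, v in _DTYPE.items()}


def _parse_envi_header(hdr_path: Path) -> dict:
    text = hdr_path.read_text()
    if not text.lstrip().lower().startswith("envi"):
        raise ValueError(f"{hdr_path}: not an ENVI header")
    fields: dict[str, str] = {}
    # join brace-delimited multi-line values, then split on top-level lines
    body = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in body.splitlines()[1:]:
        if "=" not in line:
            continue
        key, val = line.split("=", 1)
        fields[key.strip().lower()] = val.strip()
    return fields


def write_envi_cube(cube: np.ndarray, base_path, wavelengths=None,
                    interleave: str = "bsq", description: str = "") -> tuple[Path, Path]:
    """Write an [H, W, D] cube (or [H, W] raster) as an ENVI .img/.hdr pair."""
    base_path = Path(base_path)
    cube = np.asarray(cube)
    if cube.ndim == 2:
        cube = cube[:, :, None]
    h, w, d = cube.shape
    interleave = interleave.lower()
    if interleave == "bsq":
        raw = np.transpose(cube, (2, 0, 1))
    elif interleave == "bil":
        raw = np.transpose(cube, (0, 2, 1))
    elif interleave == "bip":
        raw = cube
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    dtype = cube.dtype if cube.dtype in _DTYPE_CODE else np.dtype(np.float32)
    img = base_path.with_suffix(".img")
    hdr = base_path.with_suffix(".hdr")
    np.ascontiguousarray(raw.astype(dtype)).tofile(img)
    lines = ["ENVI",
             f"description = {{{description}}}",
             f"samples = {w}", f"lines = {h}", f"bands = {d}",
             "header offset = 0", "file type = ENVI Standard",
             f"data type = {_DTYPE_CODE[np.dtype(dtype)]}",
             f"interleave = {interleave}", "byte order = 0"]
    if wavelengths is not None:
        wl = ", ".join(f"{v:.5f}" for v in np.asarray(wavelengths))
        lines.append(f"wavelength = {{ {wl} }}")
    hdr.write_text("\n".join(lines) + "\n")
    return hdr, img


def _read_envi_pair(hdr_path: Path) -> tuple[np.ndarray, dict]:
    fields = _parse_envi_header(hdr_path)
    h = int(fields["lines"])
    w = int(fields["samples"])
    d = int(fields["bands"])
    dtype = _DTYPE[int(fields["data type"])]
    interleave = fields.get("interleave", "bsq").lower()
    img_path = hdr_path.with_suffix(".img")
    raw = np.fromfile(img_path, dtype=dtype)
    if raw.size != h * w * d:
        raise ValueError(f"{img_path}: expected {h * w * d} values, found {raw.size}")
    if interleave == "bsq":
        cube = np.transpose(raw.reshape(d, h, w), (1, 2, 0))
    elif interleave == "bil":
        cube = np.transpose(raw.reshape(h, d, w), (0, 2, 1))
    elif interleave == "bip":
        cube = raw.reshape(h, w, d)
    else:
        raise ValueError(f"{hdr_path}: unknown interleave {interleave!r}")
    return cube, fields


def read_envi_cube(hdr_path, label_hdr_path,
                   wavelength_range: tuple[float, float] = (400.0, 1000.0),
                   class_names: list[str] | None = None) -> SpectralDataset:
    """Flatten the labeled pixels of an ENVI cube + label raster into a
    dataset; pixels whose label equals the UNLABELED sentinel are dropped."""
    hdr_path, label_hdr_path = Path(hdr_path), Path(label_hdr_path)
    cube, fields = _read_envi_pair(hdr_path)
    labels, _ = _read_envi_pair(label_hdr_path)
    labels = labels[:, :, 0] if labels.ndim == 3 else labels
    if labels.shape != cube.shape[:2]:
        raise ValueError(f"label raster shape {labels.shape} does not match "
                         f"cube spatial dims {cube.shape[:2]}")
    if "wavelength" in fields:
        wl = np.array([float(v) for v in
                       fields["wavelength"].strip("{} ").split(",") if v.strip()])
    else:
        wl = np.linspace(*wavelength_range, cube.shape[2])
    mask = labels.astype(np.int64) != UNLABELED
    return SpectralDataset(cube[mask].astype(float),
                           labels[mask].astype(np.int64), wl,
                           class_names=list(class_names) if class_names else [],
                           provenance=str(hdr_path))


def dataset_to_cube(ds: SpectralDataset, n_cols: int | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Arrange flat pixels into an [H, W, D] cube and [H, W] label raster,
    padding the last row with UNLABELED zero-spectra pixels."""
    n = ds.n_samples
    if n_cols is None:
        n_cols = int(np.ceil(np.sqrt(n)))
    n_rows = int(np.ceil(n / n_cols))
    cube = np.zeros((n_rows * n_cols, ds.n_bands), dtype=np.float32)
    labels = np.full(n_rows * n_cols, UNLABELED, dtype=np.int16)
    cube[:n] = ds.spectra
    labels[:n] = ds.labels
    return (cube.reshape(n_rows, n_cols, ds.n_bands),
            labels.reshape(n_rows, n_cols))
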