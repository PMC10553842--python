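"""File I/O: dense matrices, labels, centroids.

Two matrix formats are supported:

* delimited text (comma or tab), square numeric, optional single header row
  of region IDs;
* a dense binary format with an 8-byte shape header (two little-endian
  uint32: rows, cols) followed by row-major float64 data — round-trips
  bit-exactly.

Label files are two-column delimited text (region_id, label); centroid files
are four columns (region_id, x, y, z).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MatrixReport",
    "load_matrix",
    "save_matrix",
    "load_labels",
    "save_labels",
    "load_centroids",
    "save_centroids",
]

_MAGIC_LEN = 8


@dataclass
class MatrixReport:
    """What load_matrix found: shape, symmetry, NaN locations."""

    shape: tuple[int, int]
    symmetric: bool
    nan_indices: np.ndarray  # (k, 2)

    @property
    def has_nan(self) -> bool:
        return self.nan_indices.shape[0] > 0


def save_matrix(matrix: np.ndarray, path: str | Path, fmt: str = "delimited") -> None:
    m = np.asarray(matrix, dtype=float)
    path = Path(path)
    if fmt == "delimited":
        np.savetxt(path, m, delimiter=",", fmt="%.17g")
    elif fmt == "dense-binary":
        with open(path, "wb") as fh:
            fh.write(struct.pack("<II", m.shape[0], m.shape[1]))
            fh.write(np.ascontiguousarray(m, dtype="<f8").tobytes())
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")


def load_matrix(
    path: str | Path,
    fmt: str = "delimited",
    expected_size: int | None = None,
) -> tuple[np.ndarray, MatrixReport]:
    """Load a square matrix; validate shape, report (not enforce) symmetry.

    Returns the matrix and a :class:`MatrixReport`. A non-square file raises
    ``ValueError``; NaN entries are reported with indices in the report.
    """
    path = Path(path)
    if fmt == "dense-binary":
        raw = path.read_bytes()
        rows, cols = struct.unpack("<II", raw[:_MAGIC_LEN])
        m = np.frombuffer(raw[_MAGIC_LEN:], dtype="<f8").reshape(rows, cols).copy()
    elif fmt == "delimited":
        # sniff a header row of region IDs: first line not fully numeric
        with open(path) as fh:
            first = fh.readline()
        sep = "\t" if "\t" in first else ","
        tokens = [t.strip() for t in first.strip().split(sep)]
        header = 0
        try:
            [float(t) for t in tokens if t != ""]
        except ValueError:
            header = 1
        m = pd.read_csv(path, sep=sep, header=None, skiprows=header).to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")

    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{path}: expected a square matrix, got shape {m.shape}")
    if expected_size is not None and m.shape[0] != expected_size:
        raise ValueError(f"{path}: expected size {expected_size}, got {m.shape[0]}")
    nan_idx = np.argwhere(np.isnan(m))
    finite = np.nan_to_num(m)
    symmetric = bool(np.allclose(finite, finite.T, atol=1e-12, rtol=0.0))
    return m, MatrixReport(shape=m.shape, symmetric=symmetric, nan_indices=nan_idx)


def save_labels(region_ids, labels, path: str | Path) -> None:
    pd.DataFrame({"region_id": list(region_ids), "label": list(labels)}).to_csv(
        path, index=False
    )


def load_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: label files have exactly two columns")
    df.columns = ["region_id", "label"]
    return df


def save_centroids(region_ids, xyz: np.ndarray, path: str | Path) -> None:
    xyz = np.asarray(xyz, dtype=float)
    df = pd.DataFrame(
        {"region_id": list(region_ids), "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2]}
    )
    df.to_csv(path, index=False)


def load_centroids(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.shape[1] != 4:
        raise ValueError(f"{path}: centroid files have exactly four columns")
    df.columns = ["region_id", "x", "y", "z"]
    return df
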