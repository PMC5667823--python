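"""TIFF stack and table I/O.

Volumes are numpy arrays with axis order (z, y, x) on disk and in memory;
tables are CSV files with a header row.  Object tables use 0-based voxel
coordinates with ``x`` the fastest-varying image axis.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = ["read_stack", "write_stack", "read_table", "write_table"]


def read_stack(path) -> np.ndarray:
    """Read a 3D grayscale TIFF stack as a (z, y, x) array.

    2D images are promoted to single-slice 3D stacks with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image stack: {path}")
    arr = tifffile.imread(str(path))
    arr = np.asarray(arr)
    if arr.ndim == 2:
        warnings.warn(f"{path.name}: 2D image promoted to single-slice 3D stack")
        arr = arr[np.newaxis, ...]
    if arr.ndim != 3:
        raise ValueError(f"{path.name}: expected a 2D/3D grayscale stack, got shape {arr.shape}")
    return arr


def write_stack(volume: np.ndarray, path) -> None:
    """Write a 3D volume as TIFF; dtype is preserved (8/16-bit int, float32)."""
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {volume.shape}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), volume, photometric="minisblack")


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such table: {path}")
    return pd.read_csv(path)


def write_table(table: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
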