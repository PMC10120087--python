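"""Image and configuration I/O.

Images travel as single-plane TIFFs, written as 32-bit float, row-major,
with the shear axis along the second (column) index.  Ground-truth maps
follow the ``_tau`` / ``_amp`` suffix convention next to their images.
"""

from __future__ import annotations

import os

import numpy as np
import tifffile

from .config import load_config, save_config  # re-exported  # noqa: F401

__all__ = ["read_image", "write_image", "load_config", "save_config"]


def read_image(path) -> np.ndarray:
    """Read a single-plane grayscale TIFF as a float array.

    Accepts 8/16-bit unsigned integer and 32/64-bit float planes;
    integer data is converted to float without rescaling.  Multi-plane
    stacks and RGB images are rejected.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such image: {path}")
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError(
            f"unsupported TIFF layout {arr.shape} in {path}: expected a "
            "single grayscale plane")
    if arr.dtype.kind not in "uif":
        raise ValueError(f"unsupported TIFF sample type {arr.dtype}")
    return np.asarray(arr, dtype=np.float32 if arr.dtype.itemsize <= 4
                      else np.float64).astype(float)


def write_image(grid, path) -> None:
    """Write a 2-D array as a 32-bit float single-plane TIFF."""
    arr = np.asarray(getattr(grid, "s", getattr(grid, "q", getattr(
        grid, "tau", getattr(grid, "a", grid)))), dtype=np.float32)
    if arr.ndim != 2:
        raise ValueError("images must be 2-D")
    tifffile.imwrite(path, arr)
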