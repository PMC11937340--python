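"""Flat-index pixel-set algebra shared by the quantification modules.

A nucleus region is a set of (row, col) pixels. Internally regions are kept
as sorted 1-D arrays of flat raster indices (row * width + col), which makes
intersection / union / difference O(n log n) via the sorted-array routines in
numpy while remaining exactly equivalent to explicit set algebra.
"""

from __future__ import annotations

import numpy as np


def coords_to_flat(coords: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """(N, 2) array of (row, col) -> sorted unique flat indices."""
    coords = np.asarray(coords, dtype=np.int64)
    if coords.size == 0:
        return np.empty(0, dtype=np.int64)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be an (N, 2) array of (row, col) pairs")
    flat = coords[:, 0] * shape[1] + coords[:, 1]
    return np.unique(flat)


def flat_to_coords(flat: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    rows, cols = np.divmod(np.asarray(flat, dtype=np.int64), shape[1])
    return np.column_stack([rows, cols])


def as_flat(pixels, shape: tuple[int, int]) -> np.ndarray:
    """Canonicalize a pixel collection to sorted flat indices.

    Accepts a set/sequence of (row, col) pairs, an (N, 2) coordinate array,
    or an already-flat 1-D index array.
    """
    if isinstance(pixels, (set, frozenset)):
        pixels = np.array(sorted(pixels), dtype=np.int64).reshape(-1, 2)
    arr = np.asarray(pixels, dtype=np.int64)
    if arr.ndim == 1:
        return np.unique(arr)
    return coords_to_flat(arr, shape)


def intersect(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.intersect1d(a, b, assume_unique=True)


def setdiff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.setdiff1d(a, b, assume_unique=True)


def union_size(a: np.ndarray, b: np.ndarray, n_overlap: int | None = None) -> int:
    if n_overlap is None:
        n_overlap = intersect(a, b).size
    return int(a.size + b.size - n_overlap)


def is_subset(a: np.ndarray, b: np.ndarray) -> bool:
    """True iff pixel set a ⊆ b (flat-index form, both sorted unique)."""
    if a.size > b.size:
        return False
    return intersect(a, b).size == a.size
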