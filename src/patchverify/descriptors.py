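"""Patch descriptors: LBP code maps, histograms, the joint
intensity+texture descriptor, min-max normalization and the chi-square
histogram distance.

The texture channel is the basic 8-neighbor local binary pattern: each
pixel with a full 3x3 neighborhood receives an 8-bit code, one bit per
neighbor, set when neighbor >= center. Bits are ordered clockwise starting
at the top-left neighbor, most-significant first, so a constant image
codes to 255 everywhere. Codes are computed once on the whole face and
histogrammed per patch, which avoids artificial edges at patch borders
(per-patch code computation is available for sensitivity checks).

The joint descriptor concatenates a 256-bin intensity histogram and the
256-bin LBP histogram of a patch; each block is L1-normalized before
concatenation so the descriptor is invariant to patch pixel count, then
per-dimension min-max over the training set maps values into [0, 1].
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .faceio import NormalizedFace, Patch, PatchGrid

__all__ = [
    "CHI2_EPS",
    "MinMaxModel",
    "lbp_code_map",
    "lbp_histogram",
    "intensity_histogram",
    "ite",
    "face_descriptors",
    "face_lbp_histograms",
    "minmax_fit",
    "minmax_apply",
    "chi2_distance",
]

#: Guard against zero denominators in the chi-square distance.
CHI2_EPS = 1e-10

#: Clockwise 3x3 neighbor offsets starting at top-left; MSB first.
_NEIGHBOR_OFFSETS = [
    (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1),
]

NO_CODE = -1  # sentinel for border pixels, which carry no LBP code


def lbp_code_map(pixels: np.ndarray) -> np.ndarray:
    """8-bit LBP codes for every pixel with a full 3x3 neighborhood.

    Returns an int16 raster of the input shape; border pixels hold the
    sentinel ``NO_CODE``.
    """
    pixels = np.asarray(pixels)
    if pixels.ndim != 2:
        raise ValueError("LBP requires a 2-D grayscale raster")
    h, w = pixels.shape
    if h < 3 or w < 3:
        raise ValueError("LBP requires a raster of at least 3x3")
    center = pixels[1:-1, 1:-1].astype(np.int16)
    codes = np.zeros((h - 2, w - 2), dtype=np.int16)
    for bit, (dr, dc) in enumerate(_NEIGHBOR_OFFSETS):
        neighbor = pixels[1 + dr : h - 1 + dr, 1 + dc : w - 1 + dc].astype(np.int16)
        codes |= (neighbor >= center).astype(np.int16) << (7 - bit)
    out = np.full((h, w), NO_CODE, dtype=np.int16)
    out[1:-1, 1:-1] = codes
    return out


def lbp_histogram(codes: np.ndarray, bounds: tuple[slice, slice] | None = None) -> np.ndarray:
    """256-bin count histogram of the codes inside the given pixel bounds.

    ``bounds`` is a (row slice, col slice) pair in full-face coordinates;
    omitted means the whole raster. Border pixels (sentinel codes) are not
    counted, so edge patches have smaller totals than interior ones.
    """
    codes = np.asarray(codes)
    region = codes if bounds is None else codes[bounds[0], bounds[1]]
    valid = region[region >= 0]
    if valid.size == 0:
        warnings.warn("patch contains no LBP codes; returning all-zero histogram")
        return np.zeros(256)
    return np.bincount(valid.ravel(), minlength=256).astype(float)


def intensity_histogram(patch: Patch | np.ndarray) -> np.ndarray:
    """256-bin count histogram of 8-bit pixel values."""
    pixels = patch.pixels if isinstance(patch, Patch) else np.asarray(patch)
    return np.bincount(pixels.ravel().astype(np.intp), minlength=256).astype(float)[:256]


def _l1(hist: np.ndarray) -> np.ndarray:
    total = hist.sum()
    return hist / total if total > 0 else hist


def ite(patch: Patch, codes: np.ndarray, grid: PatchGrid) -> np.ndarray:
    """Joint intensity+texture descriptor for one patch (length 512).

    Indices 0-255 hold the L1-normalized intensity histogram, 256-511 the
    L1-normalized LBP histogram taken from the full-face code map.
    """
    bounds = grid.bounds(patch.row_index, patch.col_index)
    return np.concatenate([
        _l1(intensity_histogram(patch)),
        _l1(lbp_histogram(codes, bounds)),
    ])


def face_descriptors(
    face: NormalizedFace,
    grid: PatchGrid,
    *,
    per_patch_codes: bool = False,
) -> np.ndarray:
    """Descriptors for all patches of a face, row-major: (m*n, 512) array.

    With ``per_patch_codes`` the LBP codes are recomputed inside each patch
    instead of on the whole face (sensitivity-check mode).
    """
    from .faceio import tessellate

    patches = tessellate(face, grid)
    if per_patch_codes:
        rows = []
        for p in patches:
            codes = lbp_code_map(p.pixels)
            rows.append(np.concatenate([
                _l1(intensity_histogram(p)),
                _l1(lbp_histogram(codes)),
            ]))
        return np.asarray(rows)
    codes = lbp_code_map(face.pixels)
    return np.asarray([ite(p, codes, grid) for p in patches])


def face_lbp_histograms(face: NormalizedFace, grid: PatchGrid) -> np.ndarray:
    """Per-patch L1-normalized LBP histograms, row-major: (m*n, 256)."""
    codes = lbp_code_map(face.pixels)
    out = np.empty((grid.n_patches, 256))
    k = 0
    for i in range(grid.m):
        for j in range(grid.n):
            out[k] = _l1(lbp_histogram(codes, grid.bounds(i, j)))
            k += 1
    return out


@dataclasses.dataclass
class MinMaxModel:
    """Per-dimension (min, max) ranges learned on training descriptors."""

    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if np.any(self.maxs < self.mins):
            raise ValueError("max < min in some dimension")


def minmax_fit(descriptors: np.ndarray) -> MinMaxModel:
    X = np.atleast_2d(np.asarray(descriptors, dtype=float))
    if X.shape[0] < 1:
        raise ValueError("need at least one training descriptor")
    return MinMaxModel(X.min(axis=0), X.max(axis=0))


def minmax_apply(model: MinMaxModel, descriptors: np.ndarray) -> np.ndarray:
    """Map each dimension via (x - min) / (max - min), clamped into [0, 1].

    Dimensions constant in training map to 0.
    """
    X = np.asarray(descriptors, dtype=float)
    span = model.maxs - model.mins
    safe = np.where(span > 0, span, 1.0)
    out = (X - model.mins) / safe
    out = np.where(span > 0, out, 0.0)
    return np.clip(out, 0.0, 1.0)


def chi2_distance(h1: np.ndarray, h2: np.ndarray) -> float:
    """Chi-square histogram distance: sum (a-b)^2 / (a+b+eps).

    Symmetric, non-negative, and 0 exactly when the histograms coincide.
    """
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    if h1.shape != h2.shape:
        raise ValueError(f"histogram length mismatch: {h1.shape} vs {h2.shape}")
    return float(((h1 - h2) ** 2 / (h1 + h2 + CHI2_EPS)).sum())
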