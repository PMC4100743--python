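"""Image I/O, geometric normalization, and patch tessellation.

Faces are handled as 8-bit grayscale rasters on a canonical geometry
(130x150 by default: a 5x5 grid of 26x30-pixel patches). Alignment is a
two-point eye-based similarity transform; no landmark detection is done
here — eye coordinates come from the dataset manifest or generator.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import SimilarityTransform, warp

__all__ = [
    "PatchGrid",
    "NormalizedFace",
    "Patch",
    "DEFAULT_GRID",
    "to_grayscale",
    "normalize_face",
    "apply_elliptical_mask",
    "tessellate",
    "read_image",
    "write_image",
    "read_manifest",
    "write_manifest",
]

#: Luminance weights (ITU-R BT.601) used for color -> gray conversion.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

MANIFEST_COLUMNS = ["image_id", "subject_id", "path", "is_neutral", "split"]


@dataclasses.dataclass(frozen=True)
class PatchGrid:
    """Non-overlapping rectangular tessellation of the canonical face.

    ``m`` rows by ``n`` columns of ``patch_width`` x ``patch_height`` pixel
    patches; the grid must tile the face exactly.
    """

    m: int = 5
    n: int = 5
    patch_width: int = 26
    patch_height: int = 30

    @property
    def face_width(self) -> int:
        return self.n * self.patch_width

    @property
    def face_height(self) -> int:
        return self.m * self.patch_height

    @property
    def n_patches(self) -> int:
        return self.m * self.n

    def bounds(self, row: int, col: int) -> tuple[slice, slice]:
        """Row/column pixel slices of patch (row, col), 0-based row-major."""
        if not (0 <= row < self.m and 0 <= col < self.n):
            raise IndexError(f"patch ({row}, {col}) outside {self.m}x{self.n} grid")
        return (
            slice(row * self.patch_height, (row + 1) * self.patch_height),
            slice(col * self.patch_width, (col + 1) * self.patch_width),
        )


DEFAULT_GRID = PatchGrid()


@dataclasses.dataclass
class NormalizedFace:
    """Canonical-geometry grayscale face with identity metadata."""

    pixels: np.ndarray
    subject_id: str = ""
    is_neutral: bool = True
    image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("NormalizedFace requires a 2-D grayscale raster")


@dataclasses.dataclass(frozen=True)
class Patch:
    row_index: int
    col_index: int
    pixels: np.ndarray


def _validate_raster(pixels: np.ndarray) -> np.ndarray:
    pixels = np.asarray(pixels)
    if pixels.size == 0:
        raise ValueError("empty raster")
    if pixels.ndim not in (2, 3):
        raise ValueError(f"expected 2-D or 3-channel raster, got ndim={pixels.ndim}")
    if pixels.ndim == 3 and pixels.shape[2] != 3:
        raise ValueError(f"color raster must have 3 channels, got {pixels.shape[2]}")
    return pixels


def to_grayscale(pixels: np.ndarray) -> np.ndarray:
    """Convert an 8-bit raster to single-channel grayscale.

    Grayscale input is returned unchanged; color input is combined with the
    BT.601 luminance weights and rounded back to uint8.
    """
    pixels = _validate_raster(pixels)
    if pixels.ndim == 2:
        return pixels
    gray = pixels.astype(float) @ LUMA_WEIGHTS
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def canonical_eye_positions(grid: PatchGrid = DEFAULT_GRID) -> tuple[tuple[float, float], tuple[float, float]]:
    """Canonical (x, y) eye centers: 30%/70% of width, 35% of height."""
    w, h = grid.face_width, grid.face_height
    y = 0.35 * h
    return (0.3 * w, y), (0.7 * w, y)


def normalize_face(
    pixels: np.ndarray,
    eye_left: tuple[float, float],
    eye_right: tuple[float, float],
    grid: PatchGrid = DEFAULT_GRID,
    *,
    subject_id: str = "",
    is_neutral: bool = True,
    image_id: str = "",
) -> NormalizedFace:
    """Align a face by mapping its eye points to canonical positions.

    A similarity transform (rotation + uniform scale + translation) is the
    unique map taking the two input eye centers onto the canonical ones;
    samples falling outside the input frame are filled with 0.

    Eye points are (x, y) with x increasing rightwards; ``eye_right`` must be
    strictly to the right of ``eye_left``.
    """
    gray = to_grayscale(pixels)
    if gray.shape[0] < 2 or gray.shape[1] < 2:
        raise ValueError("raster too small to align")
    xl, yl = float(eye_left[0]), float(eye_left[1])
    xr, yr = float(eye_right[0]), float(eye_right[1])
    if np.hypot(xr - xl, yr - yl) < 1e-9:
        raise ValueError("coincident eye points: degenerate geometry")
    if xr <= xl:
        raise ValueError("eye_right must lie strictly right of eye_left")

    (cxl, cyl), (cxr, cyr) = canonical_eye_positions(grid)
    # two point pairs determine the similarity transform in closed form
    src_vec = complex(xr - xl, yr - yl)
    dst_vec = complex(cxr - cxl, cyr - cyl)
    scale = abs(dst_vec) / abs(src_vec)
    rotation = np.angle(dst_vec / src_vec)
    cos_t, sin_t = np.cos(rotation), np.sin(rotation)
    tx = cxl - scale * (cos_t * xl - sin_t * yl)
    ty = cyl - scale * (sin_t * xl + cos_t * yl)
    tform = SimilarityTransform(scale=scale, rotation=rotation,
                                translation=(tx, ty))

    out = warp(
        gray.astype(float),
        tform.inverse,
        output_shape=(grid.face_height, grid.face_width),
        order=1,
        mode="constant",
        cval=0.0,
        preserve_range=True,
    )
    return NormalizedFace(
        np.clip(np.rint(out), 0, 255).astype(np.uint8),
        subject_id=subject_id,
        is_neutral=is_neutral,
        image_id=image_id,
    )


def apply_elliptical_mask(face: NormalizedFace) -> NormalizedFace:
    """Zero pixels outside the axis-aligned ellipse inscribed in the frame.

    A stimulus/evaluation utility; off by default in the matching pipeline.
    """
    h, w = face.pixels.shape
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    inside = ((cols - cx) / (w / 2.0)) ** 2 + ((rows - cy) / (h / 2.0)) ** 2 <= 1.0
    return NormalizedFace(
        np.where(inside, face.pixels, 0).astype(face.pixels.dtype),
        subject_id=face.subject_id,
        is_neutral=face.is_neutral,
        image_id=face.image_id,
    )


def tessellate(face: NormalizedFace, grid: PatchGrid = DEFAULT_GRID) -> list[Patch]:
    """Split a canonical face into m*n patches in row-major order.

    The patches partition the face: reassembling them reproduces the raster.
    """
    h, w = face.pixels.shape
    if h != grid.face_height or w != grid.face_width:
        raise ValueError(
            f"face {w}x{h} does not match grid geometry "
            f"{grid.face_width}x{grid.face_height}"
        )
    patches = []
    for i in range(grid.m):
        for j in range(grid.n):
            rs, cs = grid.bounds(i, j)
            patches.append(Patch(i, j, face.pixels[rs, cs]))
    return patches


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/PGM image as a uint8 array (2-D gray or HxWx3 color)."""
    with Image.open(path) as img:
        if img.mode not in ("L", "RGB"):
            img = img.convert("RGB" if img.mode in ("RGBA", "P", "CMYK") else "L")
        return np.asarray(img)


def write_image(path: str | Path, pixels: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.asarray(pixels, dtype=np.uint8)).save(path)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"image_id": str, "subject_id": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    df["is_neutral"] = df["is_neutral"].astype(bool)
    return df


def write_manifest(path: str | Path, df: pd.DataFrame) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, columns=[c for c in MANIFEST_COLUMNS if c in df.columns])
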