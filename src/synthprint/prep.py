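"""Image loading and spatial preprocessing for fingerprint feature extraction.

A grayscale fingerprint image is represented throughout the package as a 2-D
``numpy`` array of gray values in ``[0, 255]`` (``float64`` after loading),
row-major with the origin at the top-left. This module computes the three
spatial prerequisites the feature operators need:

* a block-wise foreground mask (ridge area vs. blank background),
* a block orientation field (local ridge direction, defined modulo pi),
* the 96x96 analysis region centered on the foreground centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy import ndimage

from .errors import AnalysisError, InputError

__all__ = [
    "ForegroundMask",
    "OrientationField",
    "load_gray_image",
    "segment_foreground",
    "estimate_orientation",
    "select_center_block",
    "center_block_bounds",
]

#: Default side length (px) of the square analysis region at the foreground center.
CENTER_SIZE = 96

#: Default block size (px) for segmentation and orientation estimation.
BLOCK_SIZE = 16

#: Default gray-variance floor (gray^2) for a block to count as foreground.
VAR_FLOOR = 100.0

#: Default coherence floor below which a block's orientation is unreliable.
COHERENCE_FLOOR = 0.1


@dataclass
class ForegroundMask:
    """Binary foreground map with the centroid of the foreground pixels.

    ``centroid`` is ``None`` when the mask is empty; downstream operations
    that need a center must check and raise.
    """

    mask: np.ndarray
    centroid: tuple[float, float] | None = field(default=None)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.centroid is None and self.mask.any():
            rows, cols = np.nonzero(self.mask)
            self.centroid = (float(rows.mean()), float(cols.mean()))

    @property
    def fraction(self) -> float:
        return float(self.mask.mean())


@dataclass
class OrientationField:
    """Per-block ridge direction (radians, mod pi) with a coherence score.

    ``theta[i, j]`` is the ridge direction of block ``(i, j)``; ``coherence``
    in ``[0, 1]`` measures how consistently the gray gradients in the block
    point along one axis. Blocks with coherence below ``coherence_floor``
    (e.g. blank background) carry no usable direction.
    """

    theta: np.ndarray
    coherence: np.ndarray
    block_size: int
    coherence_floor: float = COHERENCE_FLOOR

    @property
    def reliable(self) -> np.ndarray:
        """Boolean grid: blocks whose orientation can be trusted."""
        return self.coherence >= self.coherence_floor

    def theta_at(self, row: float, col: float) -> tuple[float, bool]:
        """Ridge direction and reliability of the block containing a pixel."""
        i = min(int(row) // self.block_size, self.theta.shape[0] - 1)
        j = min(int(col) // self.block_size, self.theta.shape[1] - 1)
        return float(self.theta[i, j]), bool(self.reliable[i, j])


def load_gray_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale image (PNG/TIFF/BMP) as a float array.

    Multi-channel images are converted with the BT.601 luminance weights
    (0.299 R + 0.587 G + 0.114 B) and rounded to the nearest integer gray.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"image file not found: {path}")
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode in ("L", "I;16", "I"):
                arr = np.asarray(im.convert("I"), dtype=np.float64)
                if im.mode != "L":  # 16-bit gray: rescale to 8-bit range
                    arr = np.round(arr / arr.max() * 255.0) if arr.max() > 255 else arr
            else:
                rgb = np.asarray(im.convert("RGB"), dtype=np.float64)
                arr = np.round(
                    0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
                )
    except UnidentifiedImageError as exc:
        raise InputError(f"cannot decode image: {path}") from exc
    if arr.size == 0:
        raise InputError(f"zero-sized image: {path}")
    return arr


def segment_foreground(
    img: np.ndarray, block: int = BLOCK_SIZE, var_floor: float = VAR_FLOOR
) -> ForegroundMask:
    """Mark blocks whose gray variance reaches ``var_floor`` as foreground.

    The ridge area of a fingerprint oscillates between ridge and valley gray
    levels, so its local variance is large; blank background is nearly
    constant. An empty mask is legal (e.g. a constant image) — operations
    that need a foreground must check ``centroid``.
    """
    img = np.asarray(img, dtype=np.float64)
    H, L = img.shape
    if H < block or L < block:
        raise InputError(f"image {H}x{L} smaller than one {block}px block")
    mask = np.zeros((H, L), dtype=bool)
    for r0 in range(0, H - block + 1, block):
        for c0 in range(0, L - block + 1, block):
            blk = img[r0 : r0 + block, c0 : c0 + block]
            if blk.var() >= var_floor:
                # extend edge blocks to cover the partial remainder
                r1 = H if r0 + 2 * block > H else r0 + block
                c1 = L if c0 + 2 * block > L else c0 + block
                mask[r0:r1, c0:c1] = True
    return ForegroundMask(mask=mask)


def estimate_orientation(
    img: np.ndarray,
    block: int = BLOCK_SIZE,
    coherence_floor: float = COHERENCE_FLOOR,
) -> OrientationField:
    """Estimate the per-block ridge direction by gradient least squares.

    Sobel gradients are combined per block in doubled-angle form, which makes
    opposite gradient vectors reinforce rather than cancel: with
    ``gxx = sum(gx^2)``, ``gyy = sum(gy^2)``, ``gxy = sum(gx*gy)`` over a
    block, the dominant gradient direction is ``0.5 * atan2(2 gxy, gxx - gyy)``
    and the ridge runs perpendicular to it. Coherence is the length of the
    averaged doubled-angle vector normalized by the total gradient energy;
    it is 0 for isotropic or constant blocks.
    """
    img = np.asarray(img, dtype=np.float64)
    H, L = img.shape
    if H <= block or L <= block:
        raise InputError(f"image {H}x{L} not larger than one {block}px block")
    gx = ndimage.sobel(img, axis=1, mode="nearest")
    gy = ndimage.sobel(img, axis=0, mode="nearest")
    nbr, nbc = H // block, L // block
    theta = np.zeros((nbr, nbc))
    coherence = np.zeros((nbr, nbc))
    for i in range(nbr):
        for j in range(nbc):
            sl = np.s_[i * block : (i + 1) * block, j * block : (j + 1) * block]
            bx, by = gx[sl], gy[sl]
            gxx = np.sum(bx * bx)
            gyy = np.sum(by * by)
            gxy = np.sum(bx * by)
            energy = gxx + gyy
            vx, vy = gxx - gyy, 2.0 * gxy
            mag = np.hypot(vx, vy)
            if energy <= 0.0 or mag == 0.0:
                continue  # flat block: coherence 0, theta unreliable
            grad_dir = 0.5 * np.arctan2(vy, vx)
            theta[i, j] = (grad_dir + np.pi / 2.0) % np.pi
            coherence[i, j] = mag / energy
    return OrientationField(
        theta=theta,
        coherence=coherence,
        block_size=block,
        coherence_floor=coherence_floor,
    )


def center_block_bounds(
    shape: tuple[int, int], centroid: tuple[float, float], size: int = CENTER_SIZE
) -> tuple[int, int]:
    """Top-left corner of the ``size`` square centered on ``centroid``.

    The centroid is rounded half-up to an integer pixel ``c``; the region is
    the half-open square ``[c - size//2, c + size//2)`` on each axis, shifted
    minimally to lie inside the image.
    """
    H, L = shape
    half = size // 2
    r = int(np.floor(centroid[0] + 0.5)) - half
    c = int(np.floor(centroid[1] + 0.5)) - half
    r = min(max(r, 0), H - size)
    c = min(max(c, 0), L - size)
    return r, c


def select_center_block(
    img: np.ndarray, mask: ForegroundMask, size: int = CENTER_SIZE
) -> np.ndarray:
    """Extract the ``size`` x ``size`` analysis region at the foreground center."""
    img = np.asarray(img)
    H, L = img.shape
    if H < size or L < size:
        raise InputError(f"image {H}x{L} smaller than the {size}x{size} analysis region")
    if mask.centroid is None:
        raise AnalysisError("no foreground")
    r, c = center_block_bounds((H, L), mask.centroid, size)
    return img[r : r + size, c : c + size]
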