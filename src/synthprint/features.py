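"""The six discriminative features of a fingerprint image.

Synthetic fingerprint generators leave measurable traces: a constant ridge
period across the image (real ridge spacing varies within and between
fingers), a darker statistically-trained sensor background, discrete
high-frequency spectral energy from rendering artifacts, and corner-like
roughness from simulated noise blobs. Six scalar features capture these cues:

======================  =======================================================
``q_disavg``            mean ridge distance (px) over the central 96x96 region
``q_disstd``            population std of those ridge distances (px)
``q_grayavg``           global gray mean of the whole image
``q_grayvar``           global gray population variance
``q_fft``               mean DFT magnitude over a high-frequency annulus
``q_harris``            count of Harris corners (threshold + block maximum)
======================  =======================================================

Ridge distance is measured with an oriented 32x16 window per sample point:
the long axis crosses the ridges (perpendicular to the local ridge
direction), each of the 32 columns averages 16 bilinearly-interpolated
samples taken along the ridge direction, and the mean gap between the peaks
of the resulting gray profile is the local ridge distance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .errors import AnalysisError, InputError
from .prep import (
    BLOCK_SIZE,
    CENTER_SIZE,
    COHERENCE_FLOOR,
    VAR_FLOOR,
    ForegroundMask,
    OrientationField,
    center_block_bounds,
    estimate_orientation,
    load_gray_image,
    segment_foreground,
)

__all__ = [
    "FEATURE_NAMES",
    "FeatureConfig",
    "FeatureVector",
    "GrayProfile",
    "RidgeDistanceSample",
    "RidgeDistanceSummary",
    "gray_profile",
    "ridge_distance_at",
    "ridge_distance_features",
    "global_gray_features",
    "frequency_feature",
    "harris_feature",
    "extract_features",
    "extract_table",
]

#: Fixed feature order of the classifier input matrix.
FEATURE_NAMES = ("q_disavg", "q_disstd", "q_grayavg", "q_grayvar", "q_fft", "q_harris")

PROFILE_LEN = 32  # window length l (px): columns marching across the ridges
PROFILE_WIDTH = 16  # window width w (px): samples averaged along each ridge


@dataclass
class FeatureConfig:
    """Tunable parameters of the feature extractors.

    All values have sensible defaults; ``from_json``/``to_json`` round-trip a
    plain JSON object so pipelines can pin their settings in a config file.
    """

    inner_radius_frac: float = 0.25  # r0 = frac * min(H, L): hole of the annulus
    harris_threshold: float = 5500.0  # corner response floor
    harris_k: float = 0.04  # trace weight in the corner response
    harris_sigma: float = 1.0  # Gaussian smoothing width (px)
    harris_block: int = 8  # W: block tiling for the local-maximum rule
    peak_prominence: float = 2.0  # gray levels a profile peak must rise above
    center_size: int = CENTER_SIZE
    fg_block: int = BLOCK_SIZE
    fg_var_floor: float = VAR_FLOOR
    orient_block: int = BLOCK_SIZE
    coherence_floor: float = COHERENCE_FLOOR
    min_valid_fraction: float = 0.01  # below this, "ridge structure not found"

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown feature config keys: {sorted(unknown)}")
        return cls(**data)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


@dataclass
class GrayProfile:
    """The 32 column-averaged gray values of one oriented sampling window."""

    S: np.ndarray
    center: tuple[float, float]
    theta: float
    valid: bool = True

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=np.float64)


@dataclass
class RidgeDistanceSample:
    """Ridge distance at one sample point; ``valid`` is False when the
    profile had fewer than two peaks (or the window left the image)."""

    D: float
    valid: bool


@dataclass
class RidgeDistanceSummary:
    q_disavg: float
    q_disstd: float
    n_valid: int
    n_candidates: int


@dataclass
class FeatureVector:
    """The six features of one image, in the fixed classifier order."""

    q_disavg: float
    q_disstd: float
    q_grayavg: float
    q_grayvar: float
    q_fft: float
    q_harris: int

    def as_array(self) -> np.ndarray:
        return np.array(
            [getattr(self, name) for name in FEATURE_NAMES], dtype=np.float64
        )


# ---------------------------------------------------------------------------
# Oriented-window gray profiles
# ---------------------------------------------------------------------------


def _window_offsets() -> tuple[np.ndarray, np.ndarray]:
    """Sample offsets (across, along) of the 32x16 window, centered on 0."""
    across = np.arange(PROFILE_LEN, dtype=np.float64) - (PROFILE_LEN - 1) / 2.0
    along = np.arange(PROFILE_WIDTH, dtype=np.float64) - (PROFILE_WIDTH - 1) / 2.0
    return across, along


def _profiles_at(
    img: np.ndarray, rows: np.ndarray, cols: np.ndarray, thetas: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Sample oriented windows at many centers at once.

    Returns ``S`` of shape (N, 32) and a validity mask. A window is invalid
    when any of its 512 bilinear sample points falls outside the image; such
    windows are skipped, never padded.
    """
    img = np.asarray(img, dtype=np.float64)
    H, L = img.shape
    across, along = _window_offsets()
    cos_t, sin_t = np.cos(thetas), np.sin(thetas)
    # ridge direction u = (cos t, sin t) in (x, y); window long axis is the
    # normal v = (-sin t, cos t), so column k marches across the ridges.
    n = len(rows)
    coords = np.empty((2, n, PROFILE_LEN, PROFILE_WIDTH))
    # y = row + cos t * across + sin t * along ; x = col - sin t * across + cos t * along
    coords[0] = rows[:, None, None] + cos_t[:, None, None] * across[None, :, None]
    coords[0] += sin_t[:, None, None] * along[None, None, :]
    coords[1] = cols[:, None, None] - sin_t[:, None, None] * across[None, :, None]
    coords[1] += cos_t[:, None, None] * along[None, None, :]
    # the rotated window's axis-aligned half-extent, per center
    half_l, half_w = (PROFILE_LEN - 1) / 2.0, (PROFILE_WIDTH - 1) / 2.0
    ext_y = half_l * np.abs(cos_t) + half_w * np.abs(sin_t)
    ext_x = half_l * np.abs(sin_t) + half_w * np.abs(cos_t)
    valid = (
        (rows - ext_y >= 0.0)
        & (rows + ext_y <= H - 1.0)
        & (cols - ext_x >= 0.0)
        & (cols + ext_x <= L - 1.0)
    )
    samples = ndimage.map_coordinates(
        img, coords.reshape(2, -1), order=1, mode="nearest"
    )
    S = samples.reshape(n, PROFILE_LEN, PROFILE_WIDTH).mean(axis=2)
    return S, valid


def gray_profile(
    img: np.ndarray, center: tuple[float, float], theta: float
) -> GrayProfile:
    """Gray profile of the 32x16 window at ``center`` oriented by ``theta``.

    ``theta`` is the local ridge direction; the window's long axis runs
    perpendicular to it so the profile oscillates with the ridge period.
    """
    S, valid = _profiles_at(
        img,
        np.array([center[0]], dtype=np.float64),
        np.array([center[1]], dtype=np.float64),
        np.array([theta], dtype=np.float64),
    )
    return GrayProfile(S=S[0], center=center, theta=float(theta), valid=bool(valid[0]))


# ---------------------------------------------------------------------------
# Peak analysis of gray profiles
# ---------------------------------------------------------------------------


def _smooth3(S: np.ndarray) -> np.ndarray:
    """3-point moving average along the last axis, edges replicated."""
    return ndimage.uniform_filter1d(
        np.asarray(S, dtype=np.float64), size=3, axis=-1, mode="nearest"
    )


def _peak_mask(S: np.ndarray, prominence: float) -> np.ndarray:
    """Accepted peaks of each row of ``S`` (strict local maxima with the
    stated prominence, measured exactly as in standard peak finding: the
    base on each side is the minimum between the peak and the nearest
    strictly higher sample, or the row edge)."""
    S = np.atleast_2d(np.asarray(S, dtype=np.float64))
    N, Lp = S.shape
    ismax = np.zeros((N, Lp), dtype=bool)
    if Lp >= 3:
        ismax[:, 1:-1] = (S[:, 1:-1] > S[:, :-2]) & (S[:, 1:-1] > S[:, 2:])
    accepted = np.zeros_like(ismax)
    for k in range(1, Lp - 1):
        act = ismax[:, k]
        if not act.any():
            continue
        peak = S[:, k]
        bases = []
        for step in (-1, 1):
            base = np.full(N, np.inf)
            alive = act.copy()
            s = k + step
            while 0 <= s < Lp and alive.any():
                alive &= ~(alive & (S[:, s] > peak))
                base = np.where(alive, np.minimum(base, S[:, s]), base)
                s += step
            bases.append(base)
        prom = peak - np.maximum(bases[0], bases[1])
        accepted[:, k] = act & (prom >= prominence)
    return accepted


def _distances_from_peaks(peaks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean consecutive-peak gap per row; rows with < 2 peaks are invalid."""
    peaks = np.atleast_2d(peaks)
    N = peaks.shape[0]
    rows, ks = np.nonzero(peaks)
    D = np.zeros(N)
    valid = np.zeros(N, dtype=bool)
    if len(rows) > 1:
        same = rows[1:] == rows[:-1]
        gaps = (ks[1:] - ks[:-1])[same]
        gap_rows = rows[1:][same]
        sums = np.bincount(gap_rows, weights=gaps, minlength=N)
        counts = np.bincount(gap_rows, minlength=N)
        has = counts > 0
        D[has] = sums[has] / counts[has]
        valid = has & (D >= 2.0)
    return D, valid


def ridge_distance_at(profile: GrayProfile, prominence: float = 2.0) -> RidgeDistanceSample:
    """Ridge distance of one gray profile.

    The profile is smoothed with a 3-point moving average; peaks are strict
    local maxima with at least ``prominence`` gray levels of prominence, and
    the distance is the mean gap between consecutive peaks. Fewer than two
    peaks (a flat or monotone profile) yields an invalid sample.
    """
    if not profile.valid:
        return RidgeDistanceSample(D=0.0, valid=False)
    peaks = _peak_mask(_smooth3(profile.S), prominence)
    D, valid = _distances_from_peaks(peaks)
    return RidgeDistanceSample(D=float(D[0]), valid=bool(valid[0]))


def ridge_distance_features(
    img: np.ndarray,
    field: OrientationField,
    mask: ForegroundMask,
    config: FeatureConfig | None = None,
) -> RidgeDistanceSummary:
    """Mean and population std of the ridge distance over the central region.

    A ridge-distance sample is attempted at every pixel of the ``center_size``
    square centered on the foreground centroid (96x96 = 9,216 candidates by
    default). Samples whose window leaves the image, whose block orientation
    is unreliable, or whose profile shows fewer than two peaks are dropped;
    if fewer than ``min_valid_fraction`` of candidates survive the image has
    no measurable ridge structure.
    """
    cfg = config or FeatureConfig()
    img = np.asarray(img, dtype=np.float64)
    H, L = img.shape
    size = cfg.center_size
    if H < size or L < size:
        raise InputError(f"image {H}x{L} smaller than the {size}x{size} analysis region")
    if mask.centroid is None:
        raise AnalysisError("no foreground")
    r0, c0 = center_block_bounds((H, L), mask.centroid, size)
    rr, cc = np.meshgrid(
        np.arange(r0, r0 + size, dtype=np.float64),
        np.arange(c0, c0 + size, dtype=np.float64),
        indexing="ij",
    )
    rows, cols = rr.ravel(), cc.ravel()
    bi = np.minimum(rows.astype(int) // field.block_size, field.theta.shape[0] - 1)
    bj = np.minimum(cols.astype(int) // field.block_size, field.theta.shape[1] - 1)
    thetas = field.theta[bi, bj]
    reliable = field.reliable[bi, bj]
    n_candidates = len(rows)

    S, in_bounds = _profiles_at(img, rows, cols, thetas)
    usable = in_bounds & reliable
    D = np.zeros(n_candidates)
    valid = np.zeros(n_candidates, dtype=bool)
    if usable.any():
        peaks = _peak_mask(_smooth3(S[usable]), cfg.peak_prominence)
        Du, vu = _distances_from_peaks(peaks)
        D[usable], valid[usable] = Du, vu
    n_valid = int(valid.sum())
    if n_valid < cfg.min_valid_fraction * n_candidates:
        raise AnalysisError("ridge structure not found")
    Dv = D[valid]
    return RidgeDistanceSummary(
        q_disavg=float(Dv.mean()),
        q_disstd=float(Dv.std()),  # population std over the valid samples
        n_valid=n_valid,
        n_candidates=n_candidates,
    )


# ---------------------------------------------------------------------------
# Whole-image features
# ---------------------------------------------------------------------------


def global_gray_features(img: np.ndarray) -> tuple[float, float]:
    """Global gray mean and population variance of the entire image."""
    img = np.asarray(img, dtype=np.float64)
    if img.size == 0:
        raise InputError("empty image")
    return float(img.mean()), float(img.var())


def frequency_feature(img: np.ndarray, inner_radius_frac: float = 0.25) -> float:
    """Mean DFT magnitude over the high-frequency annulus.

    The centered 2-D DFT magnitude is averaged over all bins whose polar
    radius r (in bins from DC) satisfies ``r0 < r <= r_max`` with
    ``r_max = min(H, L) / 2`` and ``r0 = inner_radius_frac * min(H, L)``.
    The annulus excludes the central bright ring that carries the ridge
    fundamental; discrete rendering artifacts of generator software deposit
    energy out here, real sensor noise very little.
    """
    img = np.asarray(img, dtype=np.float64)
    H, L = img.shape
    if H < 8 or L < 8:
        raise InputError(f"image {H}x{L} too small for spectral analysis")
    mag = np.abs(np.fft.fftshift(np.fft.fft2(img)))
    rows = np.arange(H) - H // 2
    cols = np.arange(L) - L // 2
    r = np.hypot(rows[:, None], cols[None, :])
    m = min(H, L)
    ring = (r > inner_radius_frac * m) & (r <= m / 2.0)
    if not ring.any():
        return 0.0
    return float(mag[ring].mean())


def harris_feature(
    img: np.ndarray,
    threshold: float = 5500.0,
    W: int = 8,
    k: float = 0.04,
    sigma: float = 1.0,
) -> int:
    """Count of Harris corners: texture roughness at the minutia scale.

    Sobel gradients give the structure-tensor products ``Ix^2``, ``Iy^2``,
    ``Ix*Iy``; each is Gaussian-smoothed (width ``sigma``) and the corner
    response is ``R = det - k * trace^2``. A pixel is a corner iff
    ``R > threshold`` and R is the maximum of its WxW tile of the block
    tiling of the image. Smooth real captures produce few corners; the white
    noise blobs and crisp rendering of generated images produce many.
    """
    img = np.asarray(img, dtype=np.float64)
    H, L = img.shape
    if H <= W or L <= W:
        raise InputError(f"image {H}x{L} not larger than one {W}px block")
    ix = ndimage.sobel(img, axis=1, mode="nearest")
    iy = ndimage.sobel(img, axis=0, mode="nearest")
    a = ndimage.gaussian_filter(ix * ix, sigma, mode="nearest")
    b = ndimage.gaussian_filter(iy * iy, sigma, mode="nearest")
    c = ndimage.gaussian_filter(ix * iy, sigma, mode="nearest")
    R = (a * b - c * c) - k * (a + b) ** 2
    count = 0
    for r0 in range(0, H, W):
        for c0 in range(0, L, W):
            tile = R[r0 : r0 + W, c0 : c0 + W]
            tmax = tile.max()
            if tmax > threshold:
                count += int(np.count_nonzero(tile == tmax))
    return count


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def extract_features(
    img: np.ndarray | str | Path, config: FeatureConfig | None = None
) -> FeatureVector:
    """Run the full per-image pipeline and assemble the 6-feature vector.

    Accepts an image array or a path. Propagates ``AnalysisError`` ("no
    foreground", "ridge structure not found") with the path attached when
    one was given.
    """
    cfg = config or FeatureConfig()
    path = None
    if isinstance(img, (str, Path)):
        path = str(img)
        img = load_gray_image(img)
    img = np.asarray(img, dtype=np.float64)
    try:
        mask = segment_foreground(img, block=cfg.fg_block, var_floor=cfg.fg_var_floor)
        field = estimate_orientation(
            img, block=cfg.orient_block, coherence_floor=cfg.coherence_floor
        )
        ridge = ridge_distance_features(img, field, mask, cfg)
    except AnalysisError as exc:
        if path is not None:
            raise AnalysisError(f"{exc} ({path})") from exc
        raise
    q_grayavg, q_grayvar = global_gray_features(img)
    q_fft = frequency_feature(img, inner_radius_frac=cfg.inner_radius_frac)
    q_harris = harris_feature(
        img,
        threshold=cfg.harris_threshold,
        W=cfg.harris_block,
        k=cfg.harris_k,
        sigma=cfg.harris_sigma,
    )
    return FeatureVector(
        q_disavg=ridge.q_disavg,
        q_disstd=ridge.q_disstd,
        q_grayavg=q_grayavg,
        q_grayvar=q_grayvar,
        q_fft=q_fft,
        q_harris=q_harris,
    )


def extract_table(
    images: Iterable[np.ndarray | str | Path],
    labels: Sequence[str] | None = None,
    ids: Sequence[str] | None = None,
    config: FeatureConfig | None = None,
):
    """Feature table for a batch of images (rows aligned with the input).

    Returns a pandas DataFrame with columns ``path, label, q_disavg, ...``;
    row m is image m's feature vector, i.e. the classifier input matrix with
    its bookkeeping columns.
    """
    import pandas as pd

    rows = []
    for i, img in enumerate(images):
        ident = (
            ids[i]
            if ids is not None
            else (str(img) if isinstance(img, (str, Path)) else f"image_{i}")
        )
        vec = extract_features(img, config)
        row = {"path": ident, "label": labels[i] if labels is not None else ""}
        row.update(dict(zip(FEATURE_NAMES, vec.as_array())))
        rows.append(row)
    return pd.DataFrame(rows)
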