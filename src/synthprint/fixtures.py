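"""Labeled fingerprint-like test images with controlled ground truth.

The discrimination task is defined on three image populations whose
originals cannot be redistributed, so this module renders stand-ins that
reproduce only the cues the six features measure:

* ``real_like`` — ridge period drawn per image (person-to-person variation)
  with smooth within-image modulation, ridge width != valley width, a bright
  background, optical blur and small white Gaussian sensor noise;
* ``db4_like`` — Gabor-style rendering: constant ridge period, ridge width
  equal to valley width, crisp edges, a sparse sprinkling of small white
  noising blobs, darker statistically-trained-looking background;
* ``fpgen_like`` — constant period with unequal ridge/valley widths, white
  noise blobs, and a few strong discrete high-frequency spectral components.

Ridges are level sets of a smooth scalar potential (a tilted plane plus a
few low-frequency harmonics), so the orientation field is smooth and the
local ridge period is controlled by the potential's gradient magnitude. The
images are test vehicles, not realistic fingerprints: no minutiae, singular
points or sensor geometry.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import InputError
from .prep import OrientationField

__all__ = [
    "STYLES",
    "FixtureParams",
    "default_params",
    "make_orientation_field",
    "render_real_like",
    "render_synthetic_like",
    "render_image",
    "render_batch",
    "generate_dataset",
]

STYLES = ("real_like", "db4_like", "fpgen_like")

#: Fixed high-frequency components (cycles/px) of the fpgen-like artifacts;
#: all lie in the outer annulus of the spectral feature (|nu| in (0.25, 0.5]).
_HF_FREQS = ((0.30, 0.10), (0.12, 0.33), (0.28, 0.28), (0.42, 0.05))


@dataclass
class FixtureParams:
    """Rendering parameters of one image population.

    Gray units are 8-bit gray levels; lengths are pixels. ``period_modulation``
    is the fractional amplitude of the smooth within-image ridge-period
    variation (real captures vary, generated images do not).
    """

    image_size: int = 300
    ridge_period_mean: float = 10.0
    ridge_period_sd: float = 1.0
    duty_cycle: float = 0.42  # ridge-width fraction of one period
    period_modulation: float = 0.10
    contrast: float = 110.0  # gray drop from background to ridge center
    bg_gray_mean: float = 215.0
    bg_gray_sd: float = 10.0
    noise_sigma: float = 1.5  # white Gaussian sensor noise (gray)
    blur_sigma: float = 1.0  # optical point-spread blur (px)
    edge_softness: float = 0.30  # ridge-edge transition softness
    blob_density: float = 0.0  # white blobs per 10^4 px^2
    blob_radius: float = 2.0
    hf_artifact_amp: float = 0.0  # amplitude of each discrete HF cosine
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ridge_period_mean < 4.0:
            raise InputError("ridge_period_mean must be >= 4 px")
        if not 0.2 < self.duty_cycle < 0.8:
            raise InputError("duty_cycle must lie in (0.2, 0.8)")
        if self.image_size < 96:
            raise InputError("image_size must be >= 96 px")


def default_params(style: str, seed: int = 0) -> FixtureParams:
    """Population defaults for one of the three styles."""
    if style == "real_like":
        return FixtureParams(seed=seed)
    if style == "db4_like":
        return FixtureParams(
            ridge_period_mean=8.0,
            ridge_period_sd=0.0,
            duty_cycle=0.5,
            period_modulation=0.02,
            contrast=120.0,
            bg_gray_mean=175.0,
            bg_gray_sd=10.0,
            noise_sigma=1.0,
            blur_sigma=0.0,
            edge_softness=0.10,
            blob_density=1.2,
            blob_radius=1.5,
            seed=seed,
        )
    if style == "fpgen_like":
        return FixtureParams(
            ridge_period_mean=8.0,
            ridge_period_sd=0.0,
            duty_cycle=0.35,
            period_modulation=0.02,
            contrast=120.0,
            bg_gray_mean=180.0,
            bg_gray_sd=10.0,
            noise_sigma=1.0,
            blur_sigma=0.0,
            edge_softness=0.10,
            blob_density=1.5,
            blob_radius=2.0,
            hf_artifact_amp=15.0,
            seed=seed,
        )
    raise InputError(f"unknown style: {style!r}; expected one of {STYLES}")


# ---------------------------------------------------------------------------
# Potential / orientation machinery
# ---------------------------------------------------------------------------


def _potential(size: int, rng: np.random.Generator, wiggle: float):
    """Smooth scalar potential whose level sets are the ridges.

    psi = x cos(a0) + y sin(a0) + sum_j (c_j L_j / 2 pi) sin(2 pi s_j / L_j + p_j)
    with three low-frequency harmonics of combined gradient amplitude
    ``wiggle``; |grad psi| stays within ~[1 - wiggle, 1 + wiggle], so the
    local ridge period of a wave in psi varies by about +/- wiggle.

    Returns (psi, gx, gy) on the size x size grid.
    """
    y, x = np.mgrid[0:size, 0:size].astype(np.float64)
    a0 = rng.uniform(0.0, np.pi)
    psi = x * np.cos(a0) + y * np.sin(a0)
    gx = np.full((size, size), np.cos(a0))
    gy = np.full((size, size), np.sin(a0))
    for _ in range(3):
        c = wiggle / 3.0
        lam = rng.uniform(0.6, 1.2) * size
        beta = rng.uniform(0.0, 2.0 * np.pi)
        ph = rng.uniform(0.0, 2.0 * np.pi)
        s = x * np.cos(beta) + y * np.sin(beta)
        arg = 2.0 * np.pi * s / lam + ph
        psi += c * lam / (2.0 * np.pi) * np.sin(arg)
        gx += c * np.cos(arg) * np.cos(beta)
        gy += c * np.cos(arg) * np.sin(beta)
    return psi, gx, gy


def make_orientation_field(size: int, seed: int) -> OrientationField:
    """Dense smooth ridge-orientation field (one angle per pixel).

    Angles are in [0, pi); neighboring pixels differ by well under 0.05 rad
    because the potential's harmonics have wavelengths comparable to the
    image size.
    """
    if size < 96:
        raise InputError("size must be >= 96 px")
    rng = np.random.default_rng(seed)
    _, gx, gy = _potential(size, rng, wiggle=0.10)
    theta = (np.arctan2(gy, gx) + np.pi / 2.0) % np.pi
    return OrientationField(
        theta=theta, coherence=np.ones_like(theta), block_size=1, coherence_floor=0.0
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _render(p: FixtureParams, rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    size = p.image_size
    period = p.ridge_period_mean
    if p.ridge_period_sd > 0.0:
        period = float(rng.normal(p.ridge_period_mean, p.ridge_period_sd))
        period = max(period, 4.0)
    psi, _, _ = _potential(size, rng, wiggle=p.period_modulation)
    phase = 2.0 * np.pi * psi / period
    # smoothed square wave: ridge (dark) where cos(phase) > cos(pi * duty),
    # which covers exactly a duty_cycle fraction of each period
    edge = np.cos(np.pi * p.duty_cycle)
    wave = 1.0 / (1.0 + np.exp(-(np.cos(phase) - edge) / p.edge_softness))
    bg = float(rng.normal(p.bg_gray_mean, p.bg_gray_sd))
    img = bg - p.contrast * wave

    n_blobs = 0
    if p.blob_density > 0.0:
        n_blobs = int(rng.poisson(p.blob_density * size * size / 1e4))
        yy, xx = np.mgrid[0:size, 0:size]
        for _ in range(n_blobs):
            cy, cx = rng.uniform(0, size, size=2)
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= p.blob_radius**2
            img[disk] = 255.0
    if p.hf_artifact_amp > 0.0:
        yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
        for fx, fy in _HF_FREQS:
            ph = rng.uniform(0.0, 2.0 * np.pi)
            img += p.hf_artifact_amp * np.cos(2.0 * np.pi * (fx * xx + fy * yy) + ph)
    if p.blur_sigma > 0.0:
        img = ndimage.gaussian_filter(img, p.blur_sigma, mode="nearest")
    if p.noise_sigma > 0.0:
        img += rng.normal(0.0, p.noise_sigma, img.shape)
    img = np.round(np.clip(img, 0.0, 255.0)).astype(np.uint8)
    truth = {
        "period": period,
        "duty_cycle": p.duty_cycle,
        "background": bg,
        "n_blobs": n_blobs,
    }
    return img, truth


def render_real_like(p: FixtureParams) -> tuple[np.ndarray, dict]:
    """Render one real-capture-like image (seeded by ``p.seed``)."""
    return _render(p, np.random.default_rng(p.seed))


def render_synthetic_like(p: FixtureParams, style: str) -> tuple[np.ndarray, dict]:
    """Render one generated-looking image of the given synthetic style."""
    if style not in ("db4_like", "fpgen_like"):
        raise InputError(f"style must be 'db4_like' or 'fpgen_like', got {style!r}")
    return _render(p, np.random.default_rng(p.seed))


def render_image(style: str, seed: int, params: FixtureParams | None = None):
    """Render one image of ``style`` with the population defaults."""
    p = params if params is not None else default_params(style)
    p = dataclasses.replace(p, seed=seed)
    if style == "real_like":
        return render_real_like(p)
    return render_synthetic_like(p, style)


def _image_seed(master_seed: int, index: int) -> int:
    """Stable per-image seed: a hash of (master seed, image index)."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % 2**31)


def render_batch(
    n_real: int,
    n_db4: int,
    n_fpgen: int,
    seed: int,
    params: dict[str, FixtureParams] | None = None,
):
    """Render a labeled batch in memory.

    Yields ``(name, image, label, style, truth)`` with real/synthetic labels
    and per-image seeds derived from the master seed, so any subset is
    reproducible independently of the rest of the batch.
    """
    params = params or {}
    index = 0
    for style, count, label in (
        ("real_like", n_real, "real"),
        ("db4_like", n_db4, "synthetic"),
        ("fpgen_like", n_fpgen, "synthetic"),
    ):
        base = params.get(style, default_params(style))
        for i in range(count):
            img_seed = _image_seed(seed, index)
            img, truth = render_image(style, img_seed, base)
            truth["seed"] = img_seed
            name = f"{style}_{i:04d}.png"
            yield name, img, label, style, truth
            index += 1


def generate_dataset(
    n_real: int = 600,
    n_db4: int = 300,
    n_fpgen: int = 300,
    params: dict[str, FixtureParams] | None = None,
    seed: int = 42,
    out_dir: str | Path = "fixtures",
):
    """Write a labeled PNG fixture set and its manifest CSV.

    Default composition mirrors the study database: 600 real-like and
    300 + 300 synthetic-like images. Returns the manifest DataFrame
    (columns: path, label, style, true_period, seed); the CSV is written to
    ``out_dir/manifest.csv``.
    """
    import pandas as pd

    if min(n_real, n_db4, n_fpgen) < 0:
        raise InputError("image counts must be non-negative")
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out}: {exc}") from exc
    rows = []
    for name, img, label, style, truth in render_batch(
        n_real, n_db4, n_fpgen, seed, params
    ):
        Image.fromarray(img, mode="L").save(out / name)
        rows.append(
            {
                "path": name,
                "label": label,
                "style": style,
                "true_period": truth["period"],
                "seed": truth["seed"],
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
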