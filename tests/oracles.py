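"""Brute-force reference implementations used only by the tests.

These recompute the features and statistics by direct definition — explicit
loops over pixels, DFT bins or sample pairs — independently of the package's
vectorized code paths.
"""

from __future__ import annotations

import numpy as np


def block_variance_mask(img: np.ndarray, block: int, var_floor: float) -> np.ndarray:
    """Per-block gray-variance segmentation by a naive double loop."""
    H, L = img.shape
    mask = np.zeros((H, L), dtype=bool)
    for r0 in range(0, H - block + 1, block):
        for c0 in range(0, L - block + 1, block):
            vals = [img[r, c] for r in range(r0, r0 + block) for c in range(c0, c0 + block)]
            m = sum(vals) / len(vals)
            var = sum((v - m) ** 2 for v in vals) / len(vals)
            if var >= var_floor:
                r1 = H if r0 + 2 * block > H else r0 + block
                c1 = L if c0 + 2 * block > L else c0 + block
                mask[r0:r1, c0:c1] = True
    return mask


def gray_mean_var(img: np.ndarray) -> tuple[float, float]:
    """Global gray mean and population variance by a double loop."""
    H, L = img.shape
    total = 0.0
    for u in range(H):
        for v in range(L):
            total += img[u, v]
    mean = total / (H * L)
    ss = 0.0
    for u in range(H):
        for v in range(L):
            ss += (img[u, v] - mean) ** 2
    return mean, ss / (H * L)


def annulus_mean_magnitude(img: np.ndarray, inner_radius_frac: float = 0.25) -> float:
    """Mean centered-DFT magnitude over the high-frequency annulus, visiting
    every bin individually."""
    H, L = img.shape
    mag = np.abs(np.fft.fftshift(np.fft.fft2(img)))
    m = min(H, L)
    r0, rmax = inner_radius_frac * m, m / 2.0
    total, count = 0.0, 0
    for i in range(H):
        for j in range(L):
            r = np.hypot(i - H // 2, j - L // 2)
            if r0 < r <= rmax:
                total += mag[i, j]
                count += 1
    return total / count if count else 0.0


def _correlate2d_edge(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """2-D correlation with edge-replicated padding, looping over the kernel."""
    kh, kw = kernel.shape
    ry, rx = kh // 2, kw // 2
    padded = np.pad(img, ((ry, ry), (rx, rx)), mode="edge")
    out = np.zeros_like(img, dtype=np.float64)
    H, L = img.shape
    for dy in range(kh):
        for dx in range(kw):
            out += kernel[dy, dx] * padded[dy : dy + H, dx : dx + L]
    return out


def harris_count(
    img: np.ndarray,
    threshold: float = 5500.0,
    W: int = 8,
    k: float = 0.04,
    sigma: float = 1.0,
) -> int:
    """Harris corner count from first principles: explicit Sobel and Gaussian
    correlations, then the threshold + per-tile-maximum decision rule."""
    img = np.asarray(img, dtype=np.float64)
    sob_x = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
    ix = _correlate2d_edge(img, sob_x)
    iy = _correlate2d_edge(img, sob_x.T)
    radius = int(4.0 * sigma + 0.5)
    xs = np.arange(-radius, radius + 1, dtype=np.float64)
    g1 = np.exp(-(xs**2) / (2.0 * sigma**2))
    g1 /= g1.sum()
    g2 = np.outer(g1, g1)
    a = _correlate2d_edge(ix * ix, g2)
    b = _correlate2d_edge(iy * iy, g2)
    c = _correlate2d_edge(ix * iy, g2)
    R = (a * b - c * c) - k * (a + b) ** 2
    H, L = img.shape
    count = 0
    for r0 in range(0, H, W):
        for c0 in range(0, L, W):
            tile = R[r0 : r0 + W, c0 : c0 + W]
            tmax = tile.max()
            if tmax > threshold:
                count += int(np.count_nonzero(tile == tmax))
    return count


def mann_whitney_auc(y: np.ndarray, scores: np.ndarray, pos_label: int = 1) -> float:
    """AUC as the pairwise probability that a positive outscores a negative,
    ties counted half."""
    pos = scores[y == pos_label]
    neg = scores[y != pos_label]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))
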