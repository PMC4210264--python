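"""Shared fixtures: analytic gratings and session-wide feature tables."""

from __future__ import annotations

import numpy as np
import pytest

from synthprint import Dataset, extract_features, render_batch, render_image
from synthprint.svm import LABEL_REAL, LABEL_SYNTHETIC


def grating(
    period: float,
    angle_deg: float,
    size: int = 160,
    amplitude: float = 60.0,
    mean: float = 128.0,
    phase: float = 0.3,
) -> np.ndarray:
    """Sinusoidal ridge pattern: ridges run along ``angle_deg``, gray varies
    along the normal with the given period (px)."""
    y, x = np.mgrid[0:size, 0:size].astype(np.float64)
    a = np.deg2rad(angle_deg)
    s = -np.sin(a) * x + np.cos(a) * y
    return mean + amplitude * np.cos(2.0 * np.pi * s / period + phase)


@pytest.fixture(scope="session")
def fixture_dataset() -> Dataset:
    """Features of the default 400-image fixture set (200 real, 100 + 100
    synthetic), rendered in memory with a fixed master seed."""
    X, y, ids = [], [], []
    for name, img, label, style, _ in render_batch(200, 100, 100, seed=11):
        X.append(extract_features(img).as_array())
        y.append(LABEL_REAL if label == "real" else LABEL_SYNTHETIC)
        ids.append(name)
    return Dataset(np.array(X), np.array(y), ids)


@pytest.fixture(scope="session")
def style_features() -> dict[str, np.ndarray]:
    """Per-style (20, 6) feature arrays over 20 seeds, default parameters."""
    out = {}
    for style in ("real_like", "db4_like", "fpgen_like"):
        out[style] = np.array(
            [
                extract_features(render_image(style, 500 + i)[0]).as_array()
                for i in range(20)
            ]
        )
    return out
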