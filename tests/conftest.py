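"""Shared fixtures and independent oracle implementations."""

import numpy as np
import pytest

from markalign.synthetic_data import RenderSpec, render_mark_image


# ---------------------------------------------------------------------------
# Independent brute-force oracles (nested loops; never call the production path)


def filter_oracle(img: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Direct nested-loop Gaussian convolution with edge replication."""
    d = weights.shape[0]
    half = d // 2
    h, w = img.shape
    out = np.zeros_like(img, dtype=float)
    for y in range(h):
        for x in range(w):
            acc = 0.0
            for j in range(-half, half + 1):
                for i in range(-half, half + 1):
                    yy = min(max(y + j, 0), h - 1)
                    xx = min(max(x + i, 0), w - 1)
                    acc += weights[j + half, i + half] * img[yy, xx]
            out[y, x] = acc
    return out


def match_oracle(edges: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Direct nested-loop normalized template match; border positions 0."""
    d = weights.shape[0]
    c = d // 2
    h, w = edges.shape
    wsum = weights.sum()
    out = np.zeros((h, w), dtype=float)
    for y in range(h):
        for x in range(w):
            y0, x0 = y - c, x - c
            if y0 < 0 or x0 < 0 or y0 + d > h or x0 + d > w:
                continue
            acc = 0.0
            for j in range(d):
                for i in range(d):
                    acc += edges[y0 + j, x0 + i] * weights[j, i]
            out[y, x] = acc / wsum
    return out


def rotate_points(points, angle_deg, pivot):
    """Rotate (x, y) points about *pivot* in y-down image coordinates."""
    a = np.radians(angle_deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    pivot = np.asarray(pivot, dtype=float)
    return [tuple(rot @ (np.asarray(p, dtype=float) - pivot) + pivot) for p in points]


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture(scope="session")
def ideal_mark():
    """Noiseless rendered mark with its ground-truth pose (session-cached)."""
    spec = RenderSpec(shape=(160, 160), offset=(0.0, 0.0), noise_sigma=0.0)
    return render_mark_image(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
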