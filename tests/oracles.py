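"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by direct enumeration (or via an
unrelated library), never by calling the code path it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist
from shapely.geometry import Point, Polygon


def confusion_oracle(pred: np.ndarray, gt: np.ndarray) -> tuple[int, int, int]:
    """TP/FP/FN by explicit per-pixel enumeration."""
    tp = fp = fn = 0
    h, w = pred.shape
    for r in range(h):
        for c in range(w):
            p, g = bool(pred[r, c]), bool(gt[r, c])
            if p and g:
                tp += 1
            elif p and not g:
                fp += 1
            elif g and not p:
                fn += 1
    return tp, fp, fn


def iou_oracle(pred: np.ndarray, gt: np.ndarray) -> float:
    tp, fp, fn = confusion_oracle(pred, gt)
    return tp / (tp + fp + fn)


def miou_two_class_oracle(pred: np.ndarray, gt: np.ndarray) -> float:
    tp, fp, fn = confusion_oracle(pred, gt)
    tn = pred.size - tp - fp - fn
    iou_fg = tp / (tp + fp + fn)
    iou_bg = tn / (tn + fp + fn) if (tn + fp + fn) else 1.0
    return (iou_fg + iou_bg) / 2.0


def distance_transform_oracle(mask: np.ndarray) -> np.ndarray:
    """All-sources Euclidean distance: min over every background pixel and
    every out-of-frame border pixel, computed pairwise."""
    h, w = mask.shape
    padded = np.pad(mask.astype(bool), 1, constant_values=False)
    sources = np.argwhere(~padded).astype(float)  # padded coords
    fg = np.argwhere(padded)
    out = np.zeros_like(padded, dtype=float)
    if len(fg):
        d = cdist(fg.astype(float), sources).min(axis=1)
        out[fg[:, 0], fg[:, 1]] = d
    return out[1:-1, 1:-1]


def point_in_polygon_oracle(points_xy: np.ndarray, height: int, width: int) -> np.ndarray:
    """Pixel-centre containment via shapely (``covers`` counts boundary as
    inside), enumerated pixel by pixel."""
    poly = Polygon([tuple(p) for p in points_xy])
    mask = np.zeros((height, width), dtype=bool)
    for r in range(height):
        for c in range(width):
            mask[r, c] = poly.covers(Point(c + 0.5, r + 0.5))
    return mask


def shoelace_area(points_xy: np.ndarray) -> float:
    x = points_xy[:, 0]
    y = points_xy[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def percentile_oracle(values, q: float) -> float:
    """Linear interpolation between closest ranks on the sorted values."""
    xs = sorted(float(v) for v in values)
    n = len(xs)
    if n == 1:
        return xs[0]
    h = (n - 1) * q / 100.0
    lo = int(np.floor(h))
    hi = min(lo + 1, n - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def random_mask(rng: np.random.Generator, max_side: int = 32, p_fg: float | None = None) -> np.ndarray:
    h = int(rng.integers(1, max_side + 1))
    w = int(rng.integers(1, max_side + 1))
    p = float(rng.uniform(0.2, 0.8)) if p_fg is None else p_fg
    return rng.random((h, w)) < p


def random_polygon(rng: np.random.Generator, height: int, width: int, n_vertices: int = 8) -> np.ndarray:
    """Random star-shaped (non-self-intersecting) polygon in (x, y) coords."""
    cx = rng.uniform(width * 0.3, width * 0.7)
    cy = rng.uniform(height * 0.3, height * 0.7)
    rmax = 0.45 * min(height, width)
    angles = np.sort(rng.uniform(0, 2 * np.pi, size=n_vertices))
    radii = rng.uniform(0.2, 1.0, size=n_vertices) * rmax
    xs = np.clip(cx + radii * np.cos(angles), 0, width)
    ys = np.clip(cy + radii * np.sin(angles), 0, height)
    return np.column_stack([xs, ys])
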