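"""Prompt-point placement for promptable segmentation.

The foreground seed is placed at the most interior point of a mask — the
argmax of its Euclidean distance transform — so that a promptable backend
receives a point deep inside the FAZ rather than near its boundary.  A
reference-free variant estimates a seed from the image alone (dark central
region prior) for inference without annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .annotation_io import OctaImage, as_mask
from .errors import ParameterError

log = logging.getLogger(__name__)

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class PromptPoint:
    """A foreground seed at pixel ``(row, col)``."""

    row: int
    col: int
    role: str = "foreground"

    def to_json(self) -> dict:
        return {"row": int(self.row), "col": int(self.col), "role": self.role}


def distance_transform(mask: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance from each foreground pixel to the nearest
    background pixel, with the frame border acting as background.

    Border-as-background guarantees finite interior distances (and hence a
    well-defined argmax) even for masks touching the frame edge.  The map is
    zero exactly on background and positive on foreground.
    """
    m = as_mask(mask)
    if not m.any():
        raise ParameterError("distance transform of an empty mask is undefined")
    padded = np.pad(m, 1, constant_values=False)
    return ndi.distance_transform_edt(padded)[1:-1, 1:-1]


def place_prompt_point(mask: np.ndarray) -> PromptPoint:
    """Most interior point of a mask: the global argmax of its distance
    transform, ties broken by smallest row then smallest column."""
    d = distance_transform(mask)
    row, col = np.unravel_index(int(np.argmax(d)), d.shape)  # row-major => tie rule
    return PromptPoint(row=int(row), col=int(col))


def place_prompt_points(mask: np.ndarray, k: int = 1, min_distance: int = 5) -> list[PromptPoint]:
    """``k`` seeds at local maxima of the distance transform (the first is
    always the global argmax)."""
    if k < 1:
        raise ParameterError("k must be >= 1")
    if k == 1:
        return [place_prompt_point(mask)]
    from skimage.feature import peak_local_max

    d = distance_transform(mask)
    coords = peak_local_max(d, num_peaks=k, min_distance=min_distance)
    points = [PromptPoint(row=int(r), col=int(c)) for r, c in coords]
    best = place_prompt_point(mask)
    if best not in points:
        points = [best] + points[: k - 1]
    return points


def place_prompt_from_prior(
    image: OctaImage,
    quantile: float = 0.15,
    window_fraction: float = 0.5,
    smooth_sigma: float = 3.0,
) -> PromptPoint:
    """Reference-free seed: the FAZ is the dark region near the frame centre.

    Smooths the image, thresholds pixels at or below the given intensity
    quantile within a centred window covering ``window_fraction`` of each
    dimension, takes the largest dark connected component, and returns its
    distance-transform argmax.  Falls back to the image centre (logged) when
    the window carries no usable contrast or no component is found.
    """
    if not 0.0 < quantile < 1.0:
        raise ParameterError("quantile must be in (0, 1)")
    if not 0.0 < window_fraction <= 1.0:
        raise ParameterError("window_fraction must be in (0, 1]")
    h, w = image.shape
    centre = PromptPoint(row=h // 2, col=w // 2)

    smoothed = ndi.gaussian_filter(image.pixels.astype(float), smooth_sigma)
    r0 = int(h * (1 - window_fraction) / 2)
    r1 = h - r0
    c0 = int(w * (1 - window_fraction) / 2)
    c1 = w - c0
    window = smoothed[r0:r1, c0:c1]
    if window.max() - window.min() < 1e-6:
        log.warning("no intensity contrast in central window; falling back to centre")
        return centre

    dark = np.zeros((h, w), dtype=bool)
    dark[r0:r1, c0:c1] = window <= np.quantile(window, quantile)
    labels, n = ndi.label(dark, structure=_EIGHT_CONNECTED)
    if n == 0:
        log.warning("no dark component in central window; falling back to centre")
        return centre
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = np.argmax(sizes) + 1
    return place_prompt_point(labels == largest)
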