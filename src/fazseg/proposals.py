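"""Candidate FAZ mask generation for a prompt point.

Two routes produce :class:`MaskProposal` lists:

* :func:`propose_fallback` — the default, weight-free generator: a
  multi-threshold stability method that binarizes the smoothed image at a
  ladder of dark-intensity quantiles, keeps the connected component
  containing the prompt at each level, cleans it up morphologically, and
  scores each candidate by its IoU with the candidate at the adjacent
  threshold level (a deterministic analogue of proposal confidence).
* :func:`run_backend` — runs a registered external promptable-segmentation
  backend (e.g. a foundation-model wrapper) and validates its output
  against the proposal contract: masks match the image dimensions, are
  nonempty, and contain every prompt point.

Both routes are deterministic for fixed inputs and configuration.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import closing as _gray_closing, disk

from .annotation_io import OctaImage, as_mask
from .errors import ConfigurationError, ParameterError, ValidationError
from .prompting import PromptPoint

log = logging.getLogger(__name__)

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass(eq=False)
class MaskProposal:
    """One candidate segmentation: mask + generator confidence + provenance."""

    mask: np.ndarray
    generator_score: float
    source: str  # "fallback" | "external_backend"
    params_digest: str = ""

    def __post_init__(self) -> None:
        self.mask = as_mask(self.mask)
        if not self.mask.any():
            raise ValidationError("proposal mask must be nonempty")
        if not 0.0 <= self.generator_score <= 1.0:
            raise ValidationError(
                f"generator_score must be in [0, 1], got {self.generator_score}"
            )

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@runtime_checkable
class ProposalBackend(Protocol):
    """Contract for an external promptable-segmentation backend.

    ``propose`` must be deterministic for fixed inputs and declared
    configuration, and return at least one proposal whose mask matches the
    image dimensions and contains every prompt.
    """

    def propose(self, image: OctaImage, prompts: list[PromptPoint]) -> list[MaskProposal]:
        ...


def _mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    union = np.logical_or(a, b).sum()
    return float(np.logical_and(a, b).sum() / union) if union else 0.0


def proposal_thresholds(
    image: OctaImage,
    prompt: PromptPoint,
    levels: int = 8,
    smooth_sigma: float = 2.0,
    quantile_low: float = 0.05,
    quantile_high: float = 0.40,
    max_area_fraction: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed image and its dark-threshold ladder for one prompt.

    The ladder anchors are the ``quantile_low`` and ``quantile_high``
    intensity quantiles of the smoothed image inside the prompt's search
    window — a disk centred on the prompt covering ``max_area_fraction`` of
    the frame — and the ``levels`` thresholds are spaced linearly in
    intensity between them.  Anchoring the quantiles to the prompt's
    neighbourhood (rather than the whole frame) keeps the ladder straddling
    the FAZ boundary even when the FAZ occupies only a few percent of the
    scan.
    """
    smoothed = ndi.gaussian_filter(image.pixels.astype(float), smooth_sigma)
    h, w = smoothed.shape
    radius = np.sqrt(max_area_fraction * h * w / np.pi)
    rr, cc = np.ogrid[:h, :w]
    window = (rr - prompt.row) ** 2 + (cc - prompt.col) ** 2 <= radius * radius
    lo, hi = np.quantile(smoothed[window], [quantile_low, quantile_high])
    return smoothed, np.linspace(lo, hi, levels)


def threshold_dark_regions(smoothed: np.ndarray, thresholds: np.ndarray) -> list[np.ndarray]:
    """Raw dark-pixel masks at each threshold.

    For a nondecreasing threshold ladder the masks are nested (monotone
    thresholding); morphology is applied later, per component.
    """
    return [smoothed <= t for t in thresholds]


def propose_fallback(
    image: OctaImage,
    prompt: PromptPoint,
    levels: int = 8,
    smooth_sigma: float = 2.0,
    closing_radius: int = 2,
    max_area_fraction: float = 0.25,
    quantile_low: float = 0.05,
    quantile_high: float = 0.40,
) -> list[MaskProposal]:
    """Multi-threshold stability proposals for one prompt point.

    The smoothed image is binarized at ``levels`` dark-intensity thresholds
    (see :func:`proposal_thresholds`); at each level the connected component
    (8-connectivity) containing the prompt is extracted, morphologically
    closed (disk of ``closing_radius``) and hole-filled.  Components
    covering more than ``max_area_fraction`` of the frame are discarded, as
    are exact duplicates.  ``generator_score`` is the mean IoU with the
    surviving components at the adjacent threshold levels (boundary levels
    score against their single neighbour; a single level scores 1 by
    convention; a level with no surviving neighbour scores 0).

    Returns an empty list (logged, not raised) when no threshold yields a
    component containing the prompt.
    """
    if levels < 1:
        raise ParameterError("levels must be >= 1")
    h, w = image.shape
    if not (0 <= prompt.row < h and 0 <= prompt.col < w):
        raise ParameterError(f"prompt {prompt} outside {h}x{w} image")

    smoothed, thresholds = proposal_thresholds(
        image, prompt, levels, smooth_sigma, quantile_low, quantile_high, max_area_fraction
    )
    raw = threshold_dark_regions(smoothed, thresholds)
    footprint = disk(closing_radius) if closing_radius > 0 else None

    components: list[np.ndarray | None] = []
    for dark in raw:
        labels, _ = ndi.label(dark, structure=_EIGHT_CONNECTED)
        lab = labels[prompt.row, prompt.col]
        if lab == 0:
            components.append(None)
            continue
        comp = labels == lab
        if footprint is not None:
            comp = _gray_closing(comp, footprint).astype(bool)  # extensive: keeps the prompt
        comp = ndi.binary_fill_holes(comp)
        if comp.sum() > max_area_fraction * h * w:
            components.append(None)
            continue
        components.append(comp)

    digest = hashlib.sha256(
        repr((levels, smooth_sigma, closing_radius, max_area_fraction,
              quantile_low, quantile_high)).encode()
    ).hexdigest()[:12]

    proposals: list[MaskProposal] = []
    seen: set[bytes] = set()
    for i, comp in enumerate(components):
        if comp is None:
            continue
        if levels == 1:
            score = 1.0
        else:
            neighbours = [
                components[j]
                for j in (i - 1, i + 1)
                if 0 <= j < levels and components[j] is not None
            ]
            score = float(np.mean([_mask_iou(comp, nb) for nb in neighbours])) if neighbours else 0.0
        key = comp.tobytes()
        if key in seen:
            continue
        seen.add(key)
        proposals.append(
            MaskProposal(mask=comp, generator_score=score, source="fallback",
                         params_digest=digest)
        )
    if not proposals:
        log.warning("no threshold level yielded a component containing %s", prompt)
    return proposals


class FallbackBackend:
    """The classical multi-threshold generator wrapped in the backend contract."""

    def __init__(self, **kwargs) -> None:
        self.kwargs = kwargs

    def propose(self, image: OctaImage, prompts: list[PromptPoint]) -> list[MaskProposal]:
        out: list[MaskProposal] = []
        for prompt in prompts:
            out.extend(propose_fallback(image, prompt, **self.kwargs))
        return out


# ---------------------------------------------------------------------------
# Backend registry
# ---------------------------------------------------------------------------

_BACKENDS: dict[str, type] = {}


def register_backend(name: str, factory: type) -> None:
    """Register an external backend factory under ``external:<name>``."""
    _BACKENDS[name] = factory


def resolve_backend(spec: str, **kwargs) -> ProposalBackend:
    """Resolve a ``proposals.backend`` config value to a backend instance.

    ``"fallback"`` gives the built-in generator; ``"external:<name>"``
    looks up a registered adapter.  An unregistered backend is a
    configuration error, never a silent fallback.
    """
    if spec == "fallback":
        return FallbackBackend(**kwargs)
    if spec.startswith("external:"):
        name = spec.split(":", 1)[1]
        if name not in _BACKENDS:
            raise ConfigurationError(
                f"backend {name!r} is not registered (available: {sorted(_BACKENDS)})"
            )
        return _BACKENDS[name]()
    raise ConfigurationError(f"unknown backend spec {spec!r}")


def run_backend(
    backend: ProposalBackend,
    image: OctaImage,
    prompts: list[PromptPoint],
) -> list[MaskProposal]:
    """Run a backend and enforce the proposal contract on its output.

    Each returned mask must match the image dimensions, be nonempty, and
    contain every prompt point; violations raise :class:`ValidationError`
    naming the offending proposal.  Validated proposals are re-tagged with
    ``source="external_backend"`` unless they came from the built-in
    fallback generator.
    """
    raw = backend.propose(image, prompts)
    source = "fallback" if isinstance(backend, FallbackBackend) else "external_backend"
    validated = []
    for i, prop in enumerate(raw):
        if prop.mask.shape != image.shape:
            raise ValidationError(
                f"proposal {i}: mask shape {prop.mask.shape} != image shape {image.shape}"
            )
        for prompt in prompts:
            if not prop.mask[prompt.row, prompt.col]:
                raise ValidationError(f"proposal {i}: mask does not contain prompt {prompt}")
        validated.append(
            MaskProposal(
                mask=prop.mask,
                generator_score=prop.generator_score,
                source=source,
                params_digest=prop.params_digest,
            )
        )
    return validated
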