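"""Semantic re-ranking of mask proposals and final selection.

Each proposal is scored three ways and the scores are combined linearly:

* semantic — cosine similarity of an embedding of the proposal's image
  crop to embeddings of anatomically grounded text prompts (mean over
  positive phrases minus mean over negative phrases), min-max normalized
  within the proposal set of each image;
* geometric — a product of priors encoding where the FAZ sits: hard prompt
  containment, centrality ``exp(-||centroid - frame centre|| / D)`` with
  ``D`` a quarter of the frame diagonal, and a triangular area-plausibility
  factor peaking at a target FAZ area fraction;
* generator — the proposal generator's own confidence.

The embedding space is pluggable: any object mapping image crops and text
strings to unit-norm vectors in a common space satisfies the contract.
:class:`MockEmbeddingBackend` is a deterministic intensity-statistics
embedder with a fixed text table, suitable for tests and desk-scale runs;
a CLIP-style vision-language model can be dropped in without changing the
ranking logic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .annotation_io import OctaImage, as_mask
from .errors import ConfigurationError, ParameterError, SelectionError
from .prompting import PromptPoint
from .proposals import MaskProposal

log = logging.getLogger(__name__)

#: Default anatomically grounded text prompts.
DEFAULT_POSITIVE_PROMPTS = ("foveal avascular zone located at the center of the macula",)
DEFAULT_NEGATIVE_PROMPTS = ("retinal blood vessels", "image artifact")

#: Default score weights (semantic, geometric, generator).
DEFAULT_WEIGHTS = (0.5, 0.3, 0.2)


@dataclass(frozen=True)
class SemanticPrompt:
    """A descriptive phrase with a polarity ("positive" or "negative")."""

    text: str
    polarity: str = "positive"

    def __post_init__(self) -> None:
        if not self.text:
            raise ParameterError("semantic prompt text must be nonempty")
        if self.polarity not in ("positive", "negative"):
            raise ParameterError(f"polarity must be positive/negative, got {self.polarity!r}")


@dataclass(frozen=True)
class Crop:
    """An image crop plus its offset in the source frame (for audit)."""

    pixels: np.ndarray
    row_offset: int
    col_offset: int


@dataclass(eq=False)
class RankedProposal:
    """A proposal with its component scores and combined total."""

    proposal: MaskProposal
    semantic_score: float       # raw positive-minus-negative cosine score
    semantic_norm: float        # min-max normalized within the proposal set
    geometric_score: float
    total_score: float
    index: int                  # position in the original proposal list


def crop_for_embedding(image: OctaImage, mask: np.ndarray, margin: float = 0.25) -> Crop:
    """Axis-aligned bounding-box crop of the mask, expanded by ``margin``.

    The crop side grows to ``floor(side * (1 + 2 * margin))`` pixels
    (extra pixel, if odd, goes to the bottom/right), then is clipped to the
    frame.
    """
    m = as_mask(mask)
    if not m.any():
        raise ParameterError("cannot crop around an empty mask")
    if margin < 0:
        raise ParameterError("margin must be >= 0")
    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    pad_r = int(np.floor((r1 - r0) * 2 * margin))
    pad_c = int(np.floor((c1 - c0) * 2 * margin))
    r0e = max(0, r0 - pad_r // 2)
    r1e = min(image.shape[0], r1 + (pad_r - pad_r // 2))
    c0e = max(0, c0 - pad_c // 2)
    c1e = min(image.shape[1], c1 + (pad_c - pad_c // 2))
    return Crop(pixels=image.pixels[r0e:r1e, c0e:c1e], row_offset=r0e, col_offset=c0e)


def semantic_score(
    crop_vec: np.ndarray,
    prompts: list[SemanticPrompt],
    text_vecs: list[np.ndarray],
) -> float:
    """Mean cosine similarity to positive prompts minus mean cosine
    similarity to negative prompts (zero if there are no negatives).

    All vectors must be unit-norm in the same space; the score lies in
    [-2, 2].  At least one positive prompt is required.
    """
    if len(prompts) != len(text_vecs):
        raise ParameterError("prompts and text_vecs must align")
    pos = [float(crop_vec @ v) for p, v in zip(prompts, text_vecs) if p.polarity == "positive"]
    neg = [float(crop_vec @ v) for p, v in zip(prompts, text_vecs) if p.polarity == "negative"]
    if not pos:
        raise ConfigurationError("at least one positive semantic prompt is required")
    return float(np.mean(pos)) - (float(np.mean(neg)) if neg else 0.0)


def centrality_factor(centroid: tuple[float, float], image_shape: tuple[int, int]) -> float:
    """``exp(-d / D)`` with d the centroid's distance to the frame centre
    and D a quarter of the frame diagonal."""
    h, w = image_shape
    centre = ((h - 1) / 2.0, (w - 1) / 2.0)
    d = float(np.hypot(centroid[0] - centre[0], centroid[1] - centre[1]))
    scale = float(np.hypot(h, w)) / 4.0
    return float(np.exp(-d / scale))


def area_factor(
    area_fraction: float,
    target: float = 0.015,
    upper: float = 0.20,
) -> float:
    """Triangular plausibility score: 0 at zero area, 1 at the target
    fraction, 0 again at ``upper`` and beyond."""
    if area_fraction <= 0 or area_fraction >= upper:
        return 0.0
    if area_fraction <= target:
        return area_fraction / target
    return (upper - area_fraction) / (upper - target)


def geometric_score(
    mask: np.ndarray,
    prompt: PromptPoint,
    image_shape: tuple[int, int],
    target_area_fraction: float = 0.015,
    max_area_fraction: float = 0.20,
) -> float:
    """Product of containment (hard 0/1), centrality and area plausibility."""
    m = as_mask(mask)
    if not m.any():
        raise ParameterError("geometric score of an empty mask is undefined")
    if not m[prompt.row, prompt.col]:
        return 0.0
    rr, cc = np.nonzero(m)
    centroid = (float(rr.mean()), float(cc.mean()))
    af = m.sum() / (image_shape[0] * image_shape[1])
    return centrality_factor(centroid, image_shape) * area_factor(
        af, target_area_fraction, max_area_fraction
    )


def _check_weights(weights) -> tuple[float, float, float]:
    w = tuple(float(x) for x in weights)
    if len(w) != 3 or any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
        raise ConfigurationError(
            f"weights must be 3 nonnegative values summing to 1, got {weights}"
        )
    return w


def rank_proposals(
    proposals: list[MaskProposal],
    semantic_scores: list[float],
    geometric_scores: list[float],
    weights=DEFAULT_WEIGHTS,
) -> list[RankedProposal]:
    """Combine component scores into totals, preserving input order.

    Semantic scores are min-max normalized across the proposal set before
    weighting; a single proposal (or an all-equal set) normalizes to 1.
    """
    if not proposals:
        raise SelectionError("no proposals to rank")
    if not (len(proposals) == len(semantic_scores) == len(geometric_scores)):
        raise ParameterError("score lists must align with proposals")
    w_sem, w_geo, w_gen = _check_weights(weights)
    sem = np.asarray(semantic_scores, dtype=float)
    span = sem.max() - sem.min()
    sem_norm = (sem - sem.min()) / span if span > 0 else np.ones_like(sem)
    ranked = []
    for i, prop in enumerate(proposals):
        total = (
            w_sem * float(sem_norm[i])
            + w_geo * float(geometric_scores[i])
            + w_gen * prop.generator_score
        )
        ranked.append(
            RankedProposal(
                proposal=prop,
                semantic_score=float(sem[i]),
                semantic_norm=float(sem_norm[i]),
                geometric_score=float(geometric_scores[i]),
                total_score=total,
                index=i,
            )
        )
    return ranked


def rank_and_select(
    proposals: list[MaskProposal],
    semantic_scores: list[float],
    geometric_scores: list[float],
    weights=DEFAULT_WEIGHTS,
) -> RankedProposal:
    """Select the proposal with the maximal total score.

    Ties break by larger generator score, then smaller proposal index.
    An empty proposal list raises :class:`SelectionError` (the caller
    records a segmentation failure — an empty prediction — downstream).
    """
    ranked = rank_proposals(proposals, semantic_scores, geometric_scores, weights)
    return min(ranked, key=lambda r: (-r.total_score, -r.proposal.generator_score, r.index))


# ---------------------------------------------------------------------------
# Mock embedding backend
# ---------------------------------------------------------------------------

class MockEmbeddingBackend:
    """Deterministic stand-in for a vision-language embedding model.

    Image crops map to a unit-norm vector of five intensity statistics
    computed on a lightly smoothed copy of the crop (a real embedding model
    is likewise insensitive to pixel noise):

    1. mean intensity,
    2. intensity spread,
    3. centre-vs-periphery contrast (central third against the rest),
    4. dark-pixel fraction, where "dark" is below the midpoint of the
       darkest-percentile and median intensities — i.e. the FAZ/background
       boundary level rather than a fixed gray value,
    5. framing: how closely the dark blob's bounding-box extent matches the
       fraction of the crop a well-framed mask implies.  With the default
       25% crop margin a mask that coincides with the dark zone occupies
       ``1/(1 + 2 * margin) = 2/3`` of the crop per axis (0.66 after the
       one-pixel bounding-box inflation); the score decays as a Gaussian
       whose width (0.012) sits between the extent-measurement jitter and
       the step between adjacent proposal levels, so over-tight (all-dark)
       and over-loose (mostly background) crops both score low.

    Text maps through a fixed lookup table keyed by the exact prompt
    string.  A well-framed dark-centred crop therefore aligns with the FAZ
    phrase, and bright or high-spread crops with the negative phrases.
    """

    dim = 5

    #: Crop-axis fraction a well-framed dark blob occupies (default margin).
    FRAMING_TARGET = 0.66
    FRAMING_WIDTH = 0.012
    _SMOOTH_SIGMA = 2.0

    TEXT_TABLE = {
        # well-framed dark zone at the crop centre
        DEFAULT_POSITIVE_PROMPTS[0]: (0.05, 0.05, 0.25, 0.10, 0.95),
        # vessel texture: bright, moderate spread, no framing
        "retinal blood vessels": (0.85, 0.40, 0.50, 0.05, 0.10),
        # artifacts: high spread, neutral geometry
        "image artifact": (0.50, 0.90, 0.50, 0.30, 0.10),
    }

    @staticmethod
    def _unit(v: np.ndarray) -> np.ndarray:
        n = float(np.linalg.norm(v))
        if n == 0:
            raise ValueError("zero feature vector")
        return v / n

    def embed_image(self, crop: Crop | np.ndarray) -> np.ndarray:
        from scipy import ndimage as ndi

        pixels = crop.pixels if isinstance(crop, Crop) else np.asarray(crop)
        p = ndi.gaussian_filter(pixels.astype(float) / 255.0, self._SMOOTH_SIGMA)
        h, w = p.shape
        ch, cw = max(1, h // 3), max(1, w // 3)
        r0, c0 = (h - ch) // 2, (w - cw) // 2
        centre = p[r0 : r0 + ch, c0 : c0 + cw]
        n_all, n_c = p.size, centre.size
        peripheral = (
            (p.sum() - centre.sum()) / (n_all - n_c) if n_all > n_c else float(p.mean())
        )
        contrast = float(np.clip((peripheral - centre.mean() + 1.0) / 2.0, 0.0, 1.0))

        dark_level = (float(np.quantile(p, 0.02)) + float(np.median(p))) / 2.0
        dark = p < dark_level
        if dark.any():
            rows = np.flatnonzero(dark.any(axis=1))
            cols = np.flatnonzero(dark.any(axis=0))
            extent = ((rows[-1] - rows[0] + 1) / h + (cols[-1] - cols[0] + 1) / w) / 2.0
        else:
            extent = 0.0
        framing = float(np.exp(-(((extent - self.FRAMING_TARGET) / self.FRAMING_WIDTH) ** 2)))

        feats = np.array(
            [float(p.mean()), float(p.std()), contrast, float(dark.mean()), framing]
        )
        return self._unit(feats)

    def embed_text(self, text: str) -> np.ndarray:
        if text not in self.TEXT_TABLE:
            raise ConfigurationError(
                f"no mock embedding for text {text!r}; known prompts: "
                f"{sorted(self.TEXT_TABLE)}"
            )
        return self._unit(np.array(self.TEXT_TABLE[text], dtype=float))


def rerank(
    image: OctaImage,
    proposals: list[MaskProposal],
    prompt: PromptPoint,
    embedder,
    positive_prompts=DEFAULT_POSITIVE_PROMPTS,
    negative_prompts=DEFAULT_NEGATIVE_PROMPTS,
    weights=DEFAULT_WEIGHTS,
    crop_margin: float = 0.25,
    target_area_fraction: float = 0.015,
    max_area_fraction: float = 0.20,
) -> tuple[RankedProposal, list[RankedProposal]]:
    """Score every proposal (semantic + geometric) and select the winner.

    Returns ``(selected, all_ranked)``; the full list feeds the per-image
    ranking audit log.
    """
    prompts = [SemanticPrompt(t, "positive") for t in positive_prompts] + [
        SemanticPrompt(t, "negative") for t in negative_prompts
    ]
    text_vecs = [embedder.embed_text(p.text) for p in prompts]
    sem_scores = []
    geo_scores = []
    for prop in proposals:
        crop = crop_for_embedding(image, prop.mask, margin=crop_margin)
        sem_scores.append(semantic_score(embedder.embed_image(crop), prompts, text_vecs))
        geo_scores.append(
            geometric_score(
                prop.mask, prompt, image.shape, target_area_fraction, max_area_fraction
            )
        )
    ranked = rank_proposals(proposals, sem_scores, geo_scores, weights)
    selected = rank_and_select(proposals, sem_scores, geo_scores, weights)
    return selected, ranked
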