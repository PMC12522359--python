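"""Seeded synthetic en-face OCT-A scenes with known FAZ ground truth.

Real en-face OCT-A shows the foveal avascular zone (FAZ) as a dark,
irregular, roughly central region surrounded by bright curvilinear vessel
texture, degraded by speckle noise and acquisition artifacts (motion
stripes, scan decentration).  This module emulates exactly those features
with a parametric model so that every downstream stage — prompting,
proposal generation, re-ranking, evaluation — can be exercised end to end
with no clinical data:

* FAZ shape: a radial-harmonic closed curve
  ``r(theta) = R * (1 + sum_k a_k * sin(k*theta + phi_k))``
  about ``faz_center``, with the harmonic amplitudes drawn deterministically
  from the seed and bounded so that ``sum_k |a_k| = irregularity_amplitude``.
* Texture: a mid-gray background, brighter random-walk vessel strokes
  outside the FAZ, a low flat intensity inside it, additive Gaussian noise.
* Artifacts: ``motion_stripe`` replaces a horizontal band with shifted
  replicated rows (corrupting the image but not the ground truth);
  ``decentered`` places the FAZ well away from the frame centre.

Determinism: identical parameters (including the seed) give bit-identical
masks and images.  Per-sample seeds in a cohort are ``base_seed + index``
so any sample can be regenerated in isolation.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from .annotation_io import (
    OctaImage,
    PolygonAnnotation,
    rasterize_polygon,
    save_image,
    write_labelme,
    write_mask_png,
)
from .errors import ParameterError

log = logging.getLogger(__name__)

ARTIFACT_KINDS = ("none", "motion_stripe", "decentered")

#: Nominal 8-bit intensity levels of the rendered scene.
BACKGROUND_LEVEL = 110.0
VESSEL_LEVEL = 160.0
FAZ_LEVEL = 25.0

#: quality_index = 10 - severity; the scan-quality gate (default minimum 7)
#: therefore excludes motion-stripe scans but keeps decentered ones.
_ARTIFACT_SEVERITY = {"none": 0, "decentered": 2, "motion_stripe": 4}

_POLYGON_VERTICES = 360


@dataclass
class SceneParams:
    """Parameters of one synthetic OCT-A scene.

    ``faz_center`` is ``(row, col)`` in pixel-index space; ``None`` defaults
    to the frame centre.  ``irregularity_amplitude`` is a fraction of
    ``base_radius`` bounding the total harmonic perturbation.
    """

    height: int = 256
    width: int = 256
    faz_center: tuple[float, float] | None = None
    base_radius: float = 24.0
    irregularity_harmonics: int = 4
    irregularity_amplitude: float = 0.12
    vessel_density: float = 0.5
    noise_sd: float = 8.0
    artifact_kind: str = "none"
    quality_index: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.faz_center is None:
            self.faz_center = (self.height / 2.0, self.width / 2.0)
        if self.base_radius < 3:
            raise ParameterError(f"base_radius must be >= 3, got {self.base_radius}")
        if self.base_radius >= min(self.height, self.width) / 2:
            raise ParameterError("base_radius must be < min(height, width)/2")
        if not 0.0 <= self.irregularity_amplitude <= 0.5:
            raise ParameterError("irregularity_amplitude must be in [0, 0.5]")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not 0.0 <= self.vessel_density <= 1.0:
            raise ParameterError("vessel_density must be in [0, 1]")
        if self.artifact_kind not in ARTIFACT_KINDS:
            raise ParameterError(f"artifact_kind must be one of {ARTIFACT_KINDS}")
        if not 0 <= self.quality_index <= 10:
            raise ParameterError("quality_index must be in 0-10")


@dataclass
class SyntheticSample:
    """One generated scene: image, ground-truth mask, generating polygon."""

    image: OctaImage
    gt_mask: np.ndarray
    params: SceneParams
    polygon: PolygonAnnotation
    sample_id: str = ""


def generate_faz_polygon(params: SceneParams) -> PolygonAnnotation:
    """Build the FAZ boundary polygon for a scene.

    The radius is perturbed by ``irregularity_harmonics`` sinusoids whose
    amplitudes are drawn from the seed and rescaled so their absolute sum
    equals ``irregularity_amplitude`` (zero amplitude gives a circle).
    Raises :class:`ParameterError` if the perturbed curve would leave the
    frame.
    """
    rng = np.random.default_rng([params.seed, 1])
    k = params.irregularity_harmonics
    if k > 0 and params.irregularity_amplitude > 0:
        raw = rng.uniform(-1.0, 1.0, size=k)
        total = np.abs(raw).sum()
        amps = params.irregularity_amplitude * raw / total if total > 0 else raw * 0
        phases = rng.uniform(0.0, 2.0 * np.pi, size=k)
    else:
        amps = np.zeros(0)
        phases = np.zeros(0)

    r_max = params.base_radius * (1.0 + params.irregularity_amplitude)
    cr, cc = params.faz_center
    if (
        cr - r_max < 0
        or cr + r_max > params.height
        or cc - r_max < 0
        or cc + r_max > params.width
    ):
        raise ParameterError(
            f"FAZ of max radius {r_max:.1f} at centre ({cr:.1f}, {cc:.1f}) "
            f"exits the {params.height}x{params.width} frame"
        )

    theta = np.linspace(0.0, 2.0 * np.pi, _POLYGON_VERTICES, endpoint=False)
    radius = params.base_radius * (
        1.0
        + sum(a * np.sin((i + 1) * theta + p) for i, (a, p) in enumerate(zip(amps, phases)))
    )
    # LabelMe (x, y): pixel (r, c) centre at (c + 0.5, r + 0.5)
    xs = cc + 0.5 + radius * np.cos(theta)
    ys = cr + 0.5 + radius * np.sin(theta)
    return PolygonAnnotation(
        label="FAZ",
        points=np.column_stack([xs, ys]),
        image_height=params.height,
        image_width=params.width,
    )


def generate_faz_mask(params: SceneParams) -> np.ndarray:
    """Rasterize the seeded FAZ polygon to a binary ground-truth mask."""
    return rasterize_polygon(generate_faz_polygon(params))


def _draw_vessel_strokes(canvas: np.ndarray, rng: np.random.Generator, density: float) -> None:
    """Overlay bright curvilinear strokes (random walks) in place."""
    h, w = canvas.shape
    n_strokes = int(round(density * 120))
    for _ in range(n_strokes):
        r = rng.uniform(0, h)
        c = rng.uniform(0, w)
        heading = rng.uniform(0, 2 * np.pi)
        length = int(rng.uniform(0.4, 1.0) * min(h, w))
        thick = int(rng.integers(1, 3))
        level = rng.uniform(VESSEL_LEVEL - 12, VESSEL_LEVEL + 12)
        turns = rng.normal(0.0, 0.15, size=length)
        headings = heading + np.cumsum(turns)
        rr = np.clip(np.rint(r + np.cumsum(np.sin(headings))).astype(int), 0, h - 1)
        cc = np.clip(np.rint(c + np.cumsum(np.cos(headings))).astype(int), 0, w - 1)
        canvas[rr, cc] = level
        if thick == 2:
            canvas[np.clip(rr + 1, 0, h - 1), cc] = level


def render_octa_image(gt_mask: np.ndarray, params: SceneParams) -> OctaImage:
    """Render the scene for a ground-truth mask.

    The FAZ interior gets a low flat intensity, the exterior a mid-gray
    background with brighter vessel strokes, then Gaussian noise (sd
    ``noise_sd``) clipped to the 8-bit range.  ``motion_stripe`` afterwards
    replaces a horizontal band crossing the FAZ with horizontally shifted,
    vertically replicated rows.  ``decentered`` scenes are realized through
    an off-centre ``faz_center`` at parameter-construction time, so the
    image and mask stay consistent by construction.
    """
    if gt_mask.shape != (params.height, params.width):
        raise ParameterError(
            f"mask shape {gt_mask.shape} does not match params "
            f"({params.height}, {params.width})"
        )
    rng = np.random.default_rng([params.seed, 2])
    img = np.full((params.height, params.width), BACKGROUND_LEVEL)
    if params.vessel_density > 0:
        _draw_vessel_strokes(img, rng, params.vessel_density)
    img[gt_mask] = FAZ_LEVEL
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    if params.artifact_kind == "motion_stripe":
        band = 8
        shift = int(rng.integers(5, 9))
        r0 = int(round(params.faz_center[0])) - band // 2 + int(rng.integers(-3, 4))
        r0 = int(np.clip(r0, 3, params.height - band))
        src = img[r0 - 3 : r0 - 3 + band]
        img[r0 : r0 + band] = np.roll(src, shift, axis=1)

    return OctaImage(
        pixels=img,
        scan_width_mm=3.0,
        quality_index=params.quality_index,
        source_id=f"syn-{params.seed}",
    )


def generate_sample(params: SceneParams, sample_id: str = "") -> SyntheticSample:
    polygon = generate_faz_polygon(params)
    gt_mask = rasterize_polygon(polygon)
    image = render_octa_image(gt_mask, params)
    return SyntheticSample(
        image=image,
        gt_mask=gt_mask,
        params=params,
        polygon=polygon,
        sample_id=sample_id or f"sample_{params.seed:06d}",
    )


def generate_cohort(
    n: int,
    base_seed: int,
    artifact_fraction: float = 0.0,
    height: int = 256,
    width: int = 256,
) -> list[SyntheticSample]:
    """Generate ``n`` seeded samples; ``round(n * artifact_fraction)`` of
    them (the last ones, alternating motion-stripe / decentered) carry an
    artifact.

    Per-sample scene geometry (radius, irregularity, centre jitter) is drawn
    from the per-sample seed ``base_seed + index``, so each sample is
    regenerable in isolation.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if not 0.0 <= artifact_fraction <= 1.0:
        raise ParameterError("artifact_fraction must be in [0, 1]")
    n_artifact = int(round(n * artifact_fraction))
    samples = []
    for i in range(n):
        seed = base_seed + i
        rng = np.random.default_rng([seed, 0])
        if i >= n - n_artifact:
            kind = "motion_stripe" if (i - (n - n_artifact)) % 2 == 0 else "decentered"
        else:
            kind = "none"
        dim = min(height, width)
        radius = rng.uniform(0.07, 0.11) * dim
        amplitude = rng.uniform(0.05, 0.18)
        if kind == "decentered":
            sign_r = 1 if rng.uniform() < 0.5 else -1
            sign_c = 1 if rng.uniform() < 0.5 else -1
            centre = (
                height / 2.0 + sign_r * 0.18 * height + rng.uniform(-3, 3),
                width / 2.0 + sign_c * 0.18 * width + rng.uniform(-3, 3),
            )
        else:
            centre = (
                height / 2.0 + rng.uniform(-0.03, 0.03) * height,
                width / 2.0 + rng.uniform(-0.03, 0.03) * width,
            )
        params = SceneParams(
            height=height,
            width=width,
            faz_center=centre,
            base_radius=radius,
            irregularity_amplitude=amplitude,
            artifact_kind=kind,
            quality_index=10 - _ARTIFACT_SEVERITY[kind],
            seed=seed,
        )
        samples.append(generate_sample(params, sample_id=f"sample_{i:03d}"))
    return samples


def write_cohort(samples: list[SyntheticSample], out_dir: str | Path) -> Path:
    """Write a cohort to disk: images/, masks/, annotations/ and a manifest.

    Images are 8-bit grayscale PNG (with metadata sidecars), masks 0/255
    PNG, annotations LabelMe JSON containing the generating FAZ polygon.
    """
    out = Path(out_dir)
    for sub in ("images", "masks", "annotations"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with manifest.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "sample_id", "seed", "artifact_kind", "quality_index",
                "faz_center_row", "faz_center_col", "base_radius", "gt_area_px",
            ]
        )
        for s in samples:
            save_image(s.image, out / "images" / f"{s.sample_id}.png")
            write_mask_png(s.gt_mask, out / "masks" / f"{s.sample_id}.png")
            write_labelme(
                [s.polygon],
                out / "annotations" / f"{s.sample_id}.json",
                image_path=f"../images/{s.sample_id}.png",
            )
            writer.writerow(
                [
                    s.sample_id,
                    s.params.seed,
                    s.params.artifact_kind,
                    s.params.quality_index,
                    f"{s.params.faz_center[0]:.2f}",
                    f"{s.params.faz_center[1]:.2f}",
                    f"{s.params.base_radius:.2f}",
                    int(s.gt_mask.sum()),
                ]
            )
    log.info("wrote %d samples to %s", len(samples), out)
    return out
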