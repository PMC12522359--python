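"""Read/write the artifacts the pipeline touches.

Images are 8-bit grayscale en-face OCT-A scans (PNG); reference FAZ
annotations are LabelMe-format JSON polygons or binary mask PNGs.

Coordinate convention (stated once, tested): pixel indices are 0-based,
row-major, origin at the top-left.  LabelMe polygon points are sub-pixel
``(x, y) = (col, row)`` coordinates, so the centre of pixel ``(r, c)`` is
the point ``(c + 0.5, r + 0.5)``.  A mask ("SegMask") is a 2-D boolean
numpy array aligned with its companion image.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import FormatError, ValidationError

log = logging.getLogger(__name__)

#: Minimum PNG value treated as mask foreground (midpoint of the 8-bit range).
MASK_FOREGROUND_THRESHOLD = 128

#: Rec. 601 luminance weights used when collapsing RGB input to grayscale.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


def as_mask(arr: np.ndarray) -> np.ndarray:
    """Coerce ``arr`` to a valid binary mask (2-D boolean array).

    Accepts boolean arrays or integer arrays with values in {0, 1}.
    """
    a = np.asarray(arr)
    if a.ndim != 2:
        raise ValidationError(f"mask must be 2-D, got shape {a.shape}")
    if a.dtype == bool:
        return a
    uniq = np.unique(a)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValidationError(f"mask values must be in {{0, 1}}, got {uniq[:8]}")
    return a.astype(bool)


@dataclass(eq=False)
class OctaImage:
    """A 2-D grayscale en-face OCT-A image plus scan metadata.

    Parameters
    ----------
    pixels
        2-D uint8 intensity grid.
    scan_width_mm
        Physical width of the scanned field (nominally 3 mm).
    quality_index
        Device-reported signal quality score in 0-10, or ``None`` if absent.
    source_id
        Opaque identifier for audit trails.
    """

    pixels: np.ndarray
    scan_width_mm: float = 3.0
    quality_index: int | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 2 or p.shape[0] < 1 or p.shape[1] < 1:
            raise ValidationError(f"image must be 2-D and nonempty, got {p.shape}")
        if p.dtype != np.uint8:
            if p.min() < 0 or p.max() > 255:
                raise ValidationError("image intensities must lie in [0, 255]")
            p = p.astype(np.uint8)
        self.pixels = p
        if self.quality_index is not None and not 0 <= int(self.quality_index) <= 10:
            raise ValidationError(f"quality_index must be in 0-10, got {self.quality_index}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(eq=False)
class PolygonAnnotation:
    """A labelled polygon in LabelMe sub-pixel ``(x, y)`` coordinates."""

    label: str
    points: np.ndarray  # (N, 2) float, columns (x, y)
    image_height: int
    image_width: int

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise ValidationError(
                f"polygon '{self.label}' needs >= 3 (x, y) points, got shape {pts.shape}"
            )
        if (
            pts[:, 0].min() < 0
            or pts[:, 0].max() > self.image_width
            or pts[:, 1].min() < 0
            or pts[:, 1].max() > self.image_height
        ):
            raise ValidationError(
                f"polygon '{self.label}' has points outside "
                f"[0, {self.image_width}] x [0, {self.image_height}]"
            )
        self.points = pts


# ---------------------------------------------------------------------------
# LabelMe JSON
# ---------------------------------------------------------------------------

def read_labelme(document: str) -> list[PolygonAnnotation]:
    """Parse a LabelMe JSON document into polygon annotations.

    Non-polygon shapes (points, rectangles, ...) are skipped with a logged
    warning.  A polygon shape with fewer than three points raises
    :class:`ValidationError` naming the shape index.
    """
    try:
        doc = json.loads(document)
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed LabelMe JSON: {exc}") from exc
    try:
        height = int(doc["imageHeight"])
        width = int(doc["imageWidth"])
        shapes = doc.get("shapes", [])
    except KeyError as exc:
        raise FormatError(f"LabelMe document missing required field {exc}") from exc

    annotations: list[PolygonAnnotation] = []
    for i, shape in enumerate(shapes):
        stype = shape.get("shape_type", "polygon")
        if stype != "polygon":
            log.warning("skipping non-polygon shape %d of type %r", i, stype)
            continue
        points = shape.get("points", [])
        if len(points) < 3:
            raise ValidationError(f"shape {i} is a polygon with {len(points)} < 3 points")
        annotations.append(
            PolygonAnnotation(
                label=str(shape.get("label", "")),
                points=np.asarray(points, dtype=float),
                image_height=height,
                image_width=width,
            )
        )
    return annotations


def read_labelme_file(path: str | Path) -> list[PolygonAnnotation]:
    return read_labelme(Path(path).read_text())


def write_labelme(
    annotations: list[PolygonAnnotation],
    path: str | Path | None = None,
    image_path: str = "",
) -> str:
    """Serialize annotations as a LabelMe JSON document (optionally to disk)."""
    if not annotations:
        raise ValidationError("cannot write a LabelMe document with no annotations")
    h = annotations[0].image_height
    w = annotations[0].image_width
    doc = {
        "version": "5.2.1",
        "flags": {},
        "shapes": [
            {
                "label": a.label,
                "points": [[float(x), float(y)] for x, y in a.points],
                "group_id": None,
                "shape_type": "polygon",
                "flags": {},
            }
            for a in annotations
        ],
        "imagePath": image_path,
        "imageData": None,
        "imageHeight": int(h),
        "imageWidth": int(w),
    }
    text = json.dumps(doc, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def _points_in_polygon(px: np.ndarray, py: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Even-odd point-in-polygon test; points on an edge count as inside.

    ``px``/``py`` are flat coordinate arrays, ``poly`` an (N, 2) vertex array.
    Vectorized crossing-number test over (edges x points).
    """
    x1 = poly[:, 0][:, None]
    y1 = poly[:, 1][:, None]
    x2 = np.roll(poly[:, 0], -1)[:, None]
    y2 = np.roll(poly[:, 1], -1)[:, None]
    px = px[None, :]
    py = py[None, :]

    crosses = (y1 > py) != (y2 > py)
    with np.errstate(divide="ignore", invalid="ignore"):
        x_at = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
    inside = np.bitwise_xor.reduce(crosses & (px < x_at), axis=0)

    # boundary-coincident centres resolve as inside
    dx, dy = x2 - x1, y2 - y1
    seg_len2 = dx * dx + dy * dy
    cross = (px - x1) * dy - (py - y1) * dx
    t = (px - x1) * dx + (py - y1) * dy
    eps = 1e-9
    on_edge = (
        (np.abs(cross) <= eps * np.maximum(1.0, np.sqrt(seg_len2)))
        & (t >= -eps)
        & (t <= seg_len2 + eps)
    ).any(axis=0)
    return inside | on_edge


def rasterize_polygon(annotation: PolygonAnnotation) -> np.ndarray:
    """Rasterize a polygon: pixel (r, c) is foreground iff its centre
    ``(c + 0.5, r + 0.5)`` lies inside the polygon (even-odd rule, boundary
    counts as inside).

    Self-intersecting polygons are handled by the even-odd rule with a
    logged warning; a degenerate sliver may legitimately produce an empty
    mask.
    """
    h, w = annotation.image_height, annotation.image_width
    mask = np.zeros((h, w), dtype=bool)
    pts = annotation.points
    # only pixels whose centres fall inside the polygon's bbox can be hit
    r0 = max(0, int(np.floor(pts[:, 1].min() - 0.5)))
    r1 = min(h, int(np.ceil(pts[:, 1].max() + 0.5)))
    c0 = max(0, int(np.floor(pts[:, 0].min() - 0.5)))
    c1 = min(w, int(np.ceil(pts[:, 0].max() + 0.5)))
    if r1 <= r0 or c1 <= c0:
        log.warning("polygon '%s' rasterized to an empty mask", annotation.label)
        return mask
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    inside = _points_in_polygon(cc.ravel() + 0.5, rr.ravel() + 0.5, pts)
    mask[r0:r1, c0:c1] = inside.reshape(rr.shape)
    if not mask.any():
        log.warning("polygon '%s' rasterized to an empty mask", annotation.label)
    return mask


def annotations_to_mask(
    annotations: list[PolygonAnnotation],
    label: str | None = None,
) -> np.ndarray:
    """Union-merge the rasterizations of the annotations with a matching label.

    ``label=None`` accepts all labels (the default; annotations are merged by
    union because reference masks may be drawn as several polygons).
    """
    selected = [a for a in annotations if label is None or a.label == label]
    if not selected:
        raise ValidationError(f"no annotation with label {label!r}")
    dims = {(a.image_height, a.image_width) for a in selected}
    if len(dims) > 1:
        raise ValidationError(f"annotations disagree on image dimensions: {dims}")
    mask = np.zeros(dims.pop(), dtype=bool)
    for a in selected:
        mask |= rasterize_polygon(a)
    return mask


# ---------------------------------------------------------------------------
# PNG I/O
# ---------------------------------------------------------------------------

def read_mask_png(path: str | Path) -> np.ndarray:
    """Read a binary mask from an 8-bit single-channel PNG.

    Foreground iff pixel value >= 128 (so anti-aliased 127 is background).
    """
    img = Image.open(path)
    if img.mode != "L":
        raise FormatError(
            f"mask PNG must be 8-bit single-channel, got mode {img.mode!r}: {path}"
        )
    return np.asarray(img) >= MASK_FOREGROUND_THRESHOLD


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit PNG (foreground 255, background 0)."""
    m = as_mask(mask)
    Image.fromarray(np.where(m, 255, 0).astype(np.uint8), mode="L").save(path)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def load_image(path: str | Path) -> OctaImage:
    """Load a grayscale OCT-A image from PNG.

    RGB input is converted by Rec. 601 luminance (rounded to nearest
    integer).  Scan metadata is read from a ``<stem>.meta.json`` sidecar if
    one exists next to the image.
    """
    path = Path(path)
    try:
        img = Image.open(path)
        img.load()
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read image {path}: {exc}") from exc

    if img.mode == "L":
        pixels = np.asarray(img)
    elif img.mode in ("RGB", "RGBA"):
        rgb = np.asarray(img.convert("RGB")).astype(float)
        pixels = np.rint(rgb @ _LUMA_WEIGHTS).clip(0, 255).astype(np.uint8)
    else:
        raise FormatError(f"unsupported image mode {img.mode!r}: {path}")

    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return OctaImage(
        pixels=pixels,
        scan_width_mm=float(meta.get("scan_width_mm", 3.0)),
        quality_index=meta.get("quality_index"),
        source_id=str(meta.get("source_id", path.stem)),
    )


def save_image(image: OctaImage, path: str | Path, sidecar: bool = True) -> None:
    """Write an image as 8-bit grayscale PNG plus a metadata sidecar."""
    path = Path(path)
    Image.fromarray(image.pixels, mode="L").save(path)
    if sidecar:
        _sidecar_path(path).write_text(
            json.dumps(
                {
                    "scan_width_mm": image.scan_width_mm,
                    "quality_index": image.quality_index,
                    "source_id": image.source_id,
                },
                indent=2,
            )
        )
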