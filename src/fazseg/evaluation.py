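"""Overlap metrics and cohort statistics for FAZ segmentation.

Per image, prediction and reference masks are compared pixelwise:
``IoU = TP / (TP + FP + FN)`` for the FAZ class, and the two-class mean
IoU averages the FAZ IoU with the background IoU ``TN / (TN + FP + FN)``.
Across a cohort, the headline aggregate is the arithmetic mean of the
per-image FAZ IoUs, reported alongside the full distribution panel
(median, quartiles, 10th/5th/1st percentiles, extremes, SD, 95% CI).

Conventions (documented because the panel depends on them): percentiles
use linear interpolation between closest ranks; SD is the sample standard
deviation (n-1 denominator); the 95% CI is the normal approximation
``mean +/- 1.96 * sd / sqrt(n)``, unclipped, with a seeded percentile
bootstrap available as an alternative.  A failed segmentation (empty
prediction) scores IoU 0 and is retained, not excluded.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .annotation_io import as_mask
from .errors import ParameterError, ValidationError

log = logging.getLogger(__name__)


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> tuple[int, int, int]:
    """Pixel counts (TP, FP, FN) of a prediction against a reference."""
    p = as_mask(pred)
    g = as_mask(gt)
    if p.shape != g.shape:
        raise ValidationError(f"mask shapes differ: {p.shape} vs {g.shape}")
    tp = int(np.logical_and(p, g).sum())
    fp = int(np.logical_and(p, ~g).sum())
    fn = int(np.logical_and(~p, g).sum())
    return tp, fp, fn


def iou(pred: np.ndarray, gt: np.ndarray) -> float:
    """FAZ-class intersection over union ``TP / (TP + FP + FN)``.

    An empty prediction against a nonempty reference scores 0; both masks
    empty is undefined (0/0) and raises :class:`ParameterError`.
    """
    tp, fp, fn = confusion_counts(pred, gt)
    denom = tp + fp + fn
    if denom == 0:
        raise ParameterError("IoU undefined for two empty masks")
    return tp / denom


def miou_two_class(pred: np.ndarray, gt: np.ndarray) -> float:
    """Mean of FAZ-class IoU and background-class IoU."""
    p = as_mask(pred)
    g = as_mask(gt)
    tp, fp, fn = confusion_counts(p, g)
    if tp + fp + fn == 0:
        raise ParameterError("IoU undefined for two empty masks")
    tn = p.size - tp - fp - fn
    iou_fg = tp / (tp + fp + fn)
    bg_denom = tn + fp + fn
    iou_bg = tn / bg_denom if bg_denom > 0 else 1.0
    return (iou_fg + iou_bg) / 2.0


@dataclass
class EvalRecord:
    """Per-image comparison of a prediction with its reference mask."""

    sample_id: str
    tp: int
    fp: int
    fn: int
    iou_faz: float
    iou_background: float
    miou_two_class: float


def evaluate_pair(sample_id: str, pred: np.ndarray, gt: np.ndarray) -> EvalRecord:
    """Build the per-image record for one prediction/reference pair."""
    p = as_mask(pred)
    g = as_mask(gt)
    if not g.any():
        raise ValidationError(f"{sample_id}: reference mask is empty")
    tp, fp, fn = confusion_counts(p, g)
    tn = p.size - tp - fp - fn
    iou_fg = tp / (tp + fp + fn)
    iou_bg = tn / (tn + fp + fn) if (tn + fp + fn) > 0 else 1.0
    return EvalRecord(
        sample_id=sample_id,
        tp=tp,
        fp=fp,
        fn=fn,
        iou_faz=iou_fg,
        iou_background=iou_bg,
        miou_two_class=(iou_fg + iou_bg) / 2.0,
    )


def cohort_mean_iou(records: list[EvalRecord]) -> float:
    """Headline aggregate: mean per-image FAZ IoU across the cohort."""
    if not records:
        raise ParameterError("cannot aggregate an empty cohort")
    return float(np.mean([r.iou_faz for r in records]))


@dataclass
class CohortStats:
    """The cohort distribution panel of per-image IoU values."""

    n: int
    mean_iou: float
    median: float
    q1: float
    q3: float
    p10: float
    p5: float
    p1: float
    min: float
    max: float
    sd: float | None
    ci95_low: float | None
    ci95_high: float | None


def cohort_stats(
    ious: list[float],
    bootstrap: bool = False,
    bootstrap_resamples: int = 2000,
    bootstrap_seed: int = 0,
) -> CohortStats:
    """Distribution panel for a list of per-image IoU values.

    With ``bootstrap=True`` the CI is a seeded percentile bootstrap of the
    mean instead of the normal approximation.  A single value yields a
    panel with SD and CI absent.
    """
    x = np.asarray(ious, dtype=float)
    if x.size == 0:
        raise ParameterError("cohort_stats requires at least one value")
    mean = float(x.mean())
    if x.size >= 2:
        sd = float(x.std(ddof=1))
        if bootstrap:
            rng = np.random.default_rng(bootstrap_seed)
            means = rng.choice(x, size=(bootstrap_resamples, x.size), replace=True).mean(axis=1)
            lo, hi = (float(v) for v in np.percentile(means, [2.5, 97.5]))
        else:
            half = 1.96 * sd / np.sqrt(x.size)
            lo, hi = mean - half, mean + half
    else:
        sd, lo, hi = None, None, None
    q = np.percentile(x, [50, 25, 75, 10, 5, 1], method="linear")
    return CohortStats(
        n=int(x.size),
        mean_iou=mean,
        median=float(q[0]),
        q1=float(q[1]),
        q3=float(q[2]),
        p10=float(q[3]),
        p5=float(q[4]),
        p1=float(q[5]),
        min=float(x.min()),
        max=float(x.max()),
        sd=sd,
        ci95_low=lo,
        ci95_high=hi,
    )


def _get_quality(sample):
    if isinstance(sample, dict):
        return sample.get("quality_index")
    q = getattr(sample, "quality_index", None)
    if q is None:
        params = getattr(sample, "params", None)
        q = getattr(params, "quality_index", None)
        if q is None:
            image = getattr(sample, "image", None)
            q = getattr(image, "quality_index", None)
    return q


def quality_gate(samples: list, min_quality: int = 7) -> list:
    """Retain samples with ``quality_index >= min_quality``.

    A sample without a quality index is retained with a logged warning.
    The number of excluded samples is logged.
    """
    kept = []
    excluded = 0
    for s in samples:
        q = _get_quality(s)
        if q is None:
            log.warning("sample %r has no quality_index; retained", s)
            kept.append(s)
        elif q >= min_quality:
            kept.append(s)
        else:
            excluded += 1
    log.info("quality gate (>= %d): excluded %d of %d samples", min_quality, excluded, len(samples))
    return kept


def report(
    stats: CohortStats,
    records: list[EvalRecord],
    destination: str | Path,
    extra: dict | None = None,
) -> tuple[Path, Path]:
    """Write the cohort panel as JSON and per-sample records as CSV.

    Floats are serialized at 4 decimal places.  Returns the two paths.
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)

    def _round(v):
        return None if v is None else round(float(v), 4)

    panel = {k: (_round(v) if k != "n" else int(v)) for k, v in asdict(stats).items()}
    if extra:
        panel.update(extra)
    json_path = dest / "report.json"
    json_path.write_text(json.dumps(panel, indent=2))

    csv_path = dest / "per_sample.csv"
    with csv_path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "tp", "fp", "fn", "iou_faz", "miou_two_class"])
        for r in records:
            writer.writerow(
                [r.sample_id, r.tp, r.fp, r.fn, _round(r.iou_faz), _round(r.miou_two_class)]
            )
    return json_path, csv_path
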