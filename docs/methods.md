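# Methods

This note documents the models, conventions and design choices behind
`fazseg`: what each stage computes, which knobs matter, what the
synthetic scenes do and do not emulate, and the numerical details a
careful user should know.

## Synthetic OCT-A scenes

Real en-face OCT-A of the macula shows the FAZ as a dark, irregular,
roughly central region inside bright curvilinear vessel texture, degraded
by speckle noise and acquisition artifacts. The generator reproduces
exactly those geometric and photometric features:

* **FAZ shape.** A radial-harmonic closed curve
  `r(θ) = R·(1 + Σₖ aₖ·sin(kθ + φₖ))` about `faz_center`, sampled at 360
  vertices and rasterized by the package's pixel-centre rule. The
  harmonic amplitudes are drawn from the scene seed and rescaled so
  `Σ|aₖ| = irregularity_amplitude` (≤ 0.5, so the radius stays positive);
  zero amplitude gives a circle. The generating polygon is retained and
  exported as the LabelMe annotation, so annotation → mask round trips
  are exact.
* **Texture.** Mid-gray background (110), brighter random-walk vessel
  strokes (≈160) outside the FAZ, a low flat interior (25), additive
  Gaussian noise clipped to the 8-bit range. The moderate
  vessel/background contrast relative to the FAZ/background contrast
  keeps the image's dominant intensity split at the FAZ boundary (a
  global Otsu threshold on the smoothed image recovers the FAZ), which is
  the regime the proposal stage is designed for.
* **Artifacts.** `motion_stripe` replaces an 8-row band crossing the FAZ
  with horizontally shifted, vertically replicated rows — it corrupts the
  image but not the ground truth, as registration failures do.
  `decentered` places the FAZ ~18% of the frame off centre at
  parameter-construction time; realizing decentration through the
  generating parameters (rather than translating a rendered scene) keeps
  image, mask and polygon consistent by construction.
* **Quality index.** Synthesized as 10 − artifact severity (none 10,
  decentered 8, motion stripe 6), so the standard inclusion gate
  (quality ≥ 7) excludes motion-striped scans but keeps decentered ones.

Cohorts draw per-scene geometry (radius 7–11% of the frame side, i.e.
FAZ areas of roughly 1.5–4% of a 3 × 3 mm field, matching clinically
typical FAZ sizes; irregularity 0.05–0.18; small centre jitter) from
per-sample seeds `base_seed + index`, so any sample is regenerable in
isolation. Identical parameters give bit-identical scenes.

**What the scenes do not emulate:** physical speckle/decorrelation
statistics, multilayer (superficial/deep plexus) anatomy, projection
artifacts, media opacities, pathology. Passing tests therefore
demonstrate the pipeline's mechanics — prompt placement, proposal
generation, re-ranking, and the evaluation protocol — not clinical
accuracy on patient scans.

## Prompt placement

`distance_transform` is the exact Euclidean distance to the nearest
background pixel, with the frame border acting as background (pad with a
background ring, `scipy.ndimage.distance_transform_edt`, crop). Border-
as-background guarantees finite interior distances, hence a well-defined
argmax, even for masks touching the frame. `place_prompt_point` returns
the global argmax with ties broken by smallest row then column
(deterministic across platforms). One seed point is the default; k seeds
at distance-transform local maxima are available.

The reference-free prior (`place_prompt_from_prior`) smooths the image
(σ = 3 px), thresholds at the 0.15 intensity quantile inside the central
50% window, and seeds the largest dark component; degenerate inputs fall
back to the frame centre. Mask-derived prompting leaks reference
information into inference (though not into the mask generator), so the
two modes are kept explicit and reported separately.

## Proposal generation

The fallback generator smooths the image (σ = 2 px) and binarizes it at
`levels = 8` dark-intensity thresholds. The threshold ladder's anchors
are the 0.05 and 0.40 intensity quantiles of the smoothed image **inside
the prompt's search window** (a disk centred on the prompt covering the
25% max-area fraction), and the levels are spaced linearly in intensity
between them. Anchoring to the prompt's neighbourhood — rather than the
global histogram — keeps the ladder straddling the FAZ boundary even when
the FAZ occupies only a few percent of the scan; global-histogram
quantiles would place every threshold above the FAZ edge for small
targets and systematically over-segment. At each level the connected
component (8-connectivity) containing the prompt is closed (disk,
radius 2), hole-filled, discarded if it covers more than 25% of the
frame, and deduplicated. The stability score — mean IoU with the
surviving components at adjacent levels, single level scoring 1 by
convention — is a deterministic analogue of proposal confidence: it peaks
where the component changes least per threshold step, which is the
intensity plateau at the object boundary.

External promptable backends register under `proposals.backend =
external:<name>` and are validated against the proposal contract (masks
match image dimensions, are nonempty, contain every prompt); a missing
backend is a configuration error, never a silent fallback. No model
weights are bundled or downloaded.

## Semantic re-ranking

Per proposal, the image crop is the mask's bounding box expanded by a
25% margin per side (total size `floor(side·1.5)`, clipped to the
frame). The semantic score is the mean cosine similarity of the crop
embedding to the positive text prompts minus the mean over negative
prompts (range [−2, 2]); scores are min–max normalized within each
image's proposal set so the weights stay meaningful across backends
(single proposal or an all-equal set normalizes to 1). The geometric
score multiplies hard prompt containment, centrality
`exp(−‖centroid − centre‖/(diag/4))`, and a triangular area-plausibility
factor (0 at zero area, 1 at 1.5% of the frame, 0 at 20%). The total is
the 0.5/0.3/0.2 weighted sum; ties break by generator score, then
proposal index. An empty proposal list is a recorded segmentation
failure: the prediction is an empty mask and scores IoU 0 downstream
(failed cases are retained in the cohort statistics, not excluded).

Whether a vision–language embedding should influence mask *generation*
or only post-hoc *selection* is an open modelling question; `fazseg`
implements selection-only re-ranking, which keeps the proposal stage
backend-agnostic.

### The mock embedding backend

`MockEmbeddingBackend` is a deterministic test double for a CLIP-style
model: crops map to a unit vector of five statistics computed on a
σ = 2 px smoothed copy of the crop (mean, spread, centre-vs-periphery
contrast, dark-pixel fraction below the FAZ/background boundary level,
and a *framing* score), and text maps through a fixed table. The framing
statistic measures the dark blob's bounding-box extent as a fraction of
the crop: a mask that coincides with the dark zone yields
`1/(1 + 2·margin) = 2/3` per axis under the default margin — 0.66 after
the one-pixel bounding-box inflation of rasterized blobs — and the score
decays as a Gaussian of width 0.012, set between the extent measurement
jitter (~0.007 on the synthetic scenes) and the extent step between
adjacent proposal levels (~0.02). Over-tight masks produce all-dark
crops and over-loose masks mostly-background crops; both score low
against the FAZ phrase. The framing constants assume the default 25%
crop margin. This double exists so ranking behaviour is testable at desk
scale; swapping in a real embedding model changes only the text table
and `embed_image`.

## Evaluation conventions

* `IoU = TP/(TP+FP+FN)` per image; empty prediction vs nonempty
  reference is 0; two empty masks are undefined (error). The two-class
  mean IoU averages the FAZ IoU with the background IoU
  `TN/(TN+FP+FN)`. The per-image FAZ IoU aggregated across the cohort is
  the headline number; both readings appear in reports under
  unambiguous names (`iou_faz`, `miou_two_class`).
* Percentiles use linear interpolation between closest ranks
  (`numpy` `method="linear"`); the 1st/5th/10th percentiles of small
  cohorts depend on this choice, so it is fixed and tested.
* SD is the sample standard deviation (n−1). The 95% CI is the normal
  approximation `mean ± 1.96·sd/√n`, unclipped; a seeded percentile
  bootstrap of the mean (2000 resamples) is available behind
  `evaluation.bootstrap_ci`. A single-scan cohort reports SD and CI as
  absent rather than zero.
* The quality gate retains scans with `quality_index ≥ 7` by default;
  scans without a quality index are retained with a warning.

## Reproducibility and problem sizes

Every stage is deterministic given (inputs, config, seed); the effective
configuration's SHA-256 digest is echoed into reports and audit logs.
The canonical study cohorts used by the test suite and
`scripts/acceptance.py` are n = 20 scenes at 256 × 256 — large enough
for stable cohort statistics, small enough that the full suite runs in
well under a minute on one CPU. The acceptance script derives all cohort
seeds from its `--seed` argument.

## Known limitations

* The fallback proposal generator assumes the target is the darkest
  coherent region around the prompt; it will not segment bright or
  texture-defined structures.
* The geometric centrality prior penalizes strongly eccentric FAZs, a
  deliberate bias toward macula-centred scans.
* The mock embedder's framing constants are tied to the default crop
  margin; a real embedding backend has no such coupling.
* Cohort statistics assume independent scans; repeated scans of one eye
  would need hierarchical treatment out of scope here.
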