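# Methods

## Problem and pipeline

`beetraffic` quantifies *omnidirectional bee traffic* — the total count of
flying-bee detections across the frames of a short on-hive video, regardless
of flight direction — for videos recorded by downward-looking cameras above
the entrance of unmodified Langstroth hives. Three stages run sequentially on
each frame:

1. **Object inference.** Any detector producing scored axis-aligned boxes can
   be plugged in; boxes with score ≥ 0.7 are kept. The package ships a
   synthetic oracle detector (ground truth corrupted by a configurable miss
   rate, spurious-box rate, and corner jitter) and a file-replay adapter for
   externally produced detections. No inference engine is bundled.
2. **Motion detection** between consecutive frames: grayscale (BT.601 luma),
   5×5 Gaussian blur, pixelwise absolute difference, 5×5 grey dilation (one
   iteration), binary threshold at 20 (strictly greater → foreground),
   external-boundary contour tracing with collinear-run simplification, and a
   polygon-area filter at 1000 px. Each survivor becomes a *motion region*
   with its smallest enclosing rectangle `(x, y, w, h)` and center
   `(x + w/2, y + h/2)`.
3. **Object-motion alignment.** A detection is *motion-aligned* if at least
   one region center lies within Euclidean distance ≤ 50 px of its box
   center (k-d tree radius query; the recorded match is the nearest region,
   ties broken by lowest region index). The video's traffic measurement is
   the total count of motion-aligned detections; a bee in flight across k
   frames contributes k — a deliberate property of the measurement, not a
   tracking error.

## Numerical conventions

- **Coordinates** are 0-based pixels, x = column, y = row, origin top-left.
  Frame indices are 1-based; the middle-n window of a T-frame video starts at
  `floor((T − n)/2) + 1` (middle 30 of 744 → frames 358..387).
- **Box centers** are geometric: `cy = y1 + (y2 − y1)/2`. One published
  description of the pipeline prints `cy = y2 + (y2 − y1)/2`, which places
  the center outside the box; we implement the geometric center.
- **Gaussian sigma** is derived from the kernel size k as
  `0.3·((k−1)/2 − 1) + 0.8` (the de-facto convention for kernel-only blurs),
  overridable via `MotionParams.sigma`. Blur borders are mirror-reflected;
  dilation borders replicate the edge.
- **Contour area** is the shoelace polygon area of the traced boundary
  through pixel centers (a filled w×h rectangle has area (w−1)(h−1)), not
  the pixel count and not the enclosing-rectangle area. Chain simplification
  collapses collinear runs and leaves the area unchanged.
- **Region attribution**: regions from the pair (i−1, i) belong to frame i;
  frame 1 has none, so its detections are all unaligned.
- **Thresholds at their boundary**: score 0.70 is kept (≥), difference value
  20 is background (>), alignment distance exactly 50 is aligned (≤),
  contour area exactly at the minimum is retained (<).
- The 1000 px minimum contour area was tuned for 1080-row video; on other
  geometries `scaled_min_area` rescales it proportionally to frame area
  (tests use 240×320 frames → ≈ 37 px).

## Seven-category evaluation

Each (ground-truth bee, detection, motion) configuration in a frame maps to
exactly one of seven categories (see `beetraffic.evaluation`); the first four
count as TP, the next two as FN, the last as FP. A motion region "confirms"
an event when it satisfies C1 (center within the alignment radius of the
event center) *and* C2 (strictly positive rectangle-intersection area with
the event box — our objective operationalization of a "visually detectable"
overlap, which was a human judgment in the original protocol). Detection-to-
truth matching is greedy one-to-one by descending box IoU with positive-
overlap acceptance and deterministic tie-breaks; the original evaluation was
manual, so no published matching rule exists. The crawling-vs-stationary
distinction comes from the ground-truth motion-state field (the simulator
knows it; for real videos it would come from a human audit file). Two edge
decisions: a detected stationary bee whose box *is* confirmed by motion maps
to `BTP_BCRMTP` (wing-motion/slight-reorientation semantics), and an
*undetected* non-flying bee is no event at all — the FN categories cover
flying bees only. Detections overlapping an optional "ignore" mask (e.g.
deliberately unlabeled partial bees) are excluded from all tallies.

The four summary metrics are implemented exactly as reported in the study
this package reproduces: `precision = TP/(TP+FN)`, `recall = TP/(TP+FP)` —
note the denominators are **swapped** relative to standard usage — with
`f1` their harmonic mean and `iou = TP/(TP+FP+FN)`. All fields carry the
`_as_printed` suffix. Stratum totals are **pooled counts**, not metric means
(pooling is what reproduces the published TOTAL rows; the unweighted mean is
exposed separately as `mean_metrics`). Table reproduction rounds
half-away-from-zero to 2 decimals.

## Energy accounting

`EFF(M, A) = λ·M/A` with λ = 100 estimates performance-metric units per kW-h
of a model's data-engineering footprint A (curation + training + evaluation
cumulative power amounts). The operational energy footprint of a deployed
pipeline is `monthly_model + n_loggers × per_logger_monthly` with a 672-hour
month (24×7×4) and a 5-month season; the per-logger monthly amount is
rounded to 2 decimals before multiplication because that is the published
arithmetic (141.12 + 2.02×10 = 161.32), with the unrounded combination
available via `round_per_logger=False`.

Documented errata in the published figures (recomputed from components, not
reproduced): the stated 351.55 kW-h total CPA (component sum: 321.55); the
YOLOv3 seasonal OEF printed as both 807.60 and 813.60 (5 × 161.32 = 806.60);
a logger rate written once as 0.0003 kW-h/h (only 0.003 yields the printed
2.02); and the YOLOv3 recall energy-efficacy cell printed as 0.56 where
100 × 1.00/170.74 rounds to 0.59. The other 11 EFF cells and all three
worked examples reproduce exactly.

## Synthetic scenes

The simulator renders bees as uniform anti-aliased dark ellipses (oriented
along their velocity) over a static procedural background — a smooth
textured field with a bright landing-pad band along the bottom — plus
Gaussian pixel noise (σ = 2 by default; the threshold-20 difference stage is
far above the resulting frame-to-frame noise). Trajectories follow five
pattern classes: *straight* (8–12 px/frame, the fastest of the mix, slight
heading noise), *inward/outward zigzag* (3.5–6 px/frame with 2–4 sign
reversals of the approach component), *land-and-crawl* (4–8 px/frame flight
ending on the pad, then crawling at 1–2 px/frame or stillness), and
*parallel* (3.5–6 px/frame with zero approach component). Motion states are
derived from per-frame displacement: flying ≥ 3 px/frame, crawling ≥ 1,
else stationary; the thresholds are config-exposed because the real-video
distinction was judgment-based, and the speed ranges are plausible defaults
at the 240×320 test geometry, not measured bee kinematics. A second
camera-height class shrinks apparent bee size by 0.55×. Only fully visible,
in-frame bees are emitted as ground truth, mirroring the full-size-
unoccluded-only labeling protocol.

What passing tests on synthetic scenes show — and what they do not: the
pipeline stages compose correctly (a perfect oracle detector on an
all-flying scene yields all four metrics 1.0 and a traffic count equal to
the ground-truth flying-bee-frame count, and detector degradation moves the
metrics in the expected directions), but nothing about the accuracy of any
real trained detector on real imagery, which depends on illumination, bee
appearance, occlusion, and shadows that the ellipse renderer deliberately
does not model.

## Problem sizes

The default test suite runs scenes of 240×320 × 30 frames with 3–8 bees,
motion-oracle cross-checks on ≤ 64×64 frames, and alignment cross-checks on
up to 1000 regions per scene — sizes chosen so the full suite completes in
about a minute while still exercising every code path at realistic bee/frame
area ratios.

## Known limitations

- MP4 decoding requires an imageio backend with video support; the canonical
  input is a PNG frame sequence (an MP4 is decoded once and cached as PNGs).
- Grey dilation uses a rectangular structuring element and one iteration;
  multi-iteration dilation is not exposed.
- The evaluation module does not re-derive crawling/stationary states from
  pixels.
- No trajectory tracking, background-subtraction models, or optical flow —
  out of scope by design.
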