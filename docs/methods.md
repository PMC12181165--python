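# Methods

## Overview

`nematrack` measures *C. elegans* locomotion from plate (crawling) or
liquid (thrashing) videos. The pipeline is: decode → background model →
per-frame segmentation → skeletonization → ID tracking with collision
censoring → metric computation → tabular export. Every stage is
deterministic: a fixed input and configuration yields byte-identical
tables regardless of how frames are chunked across worker threads, because
per-frame segmentation depends only on (frame, background model) and
chunk results are merged strictly in frame order before tracking consumes
them sequentially.

## Segmentation

Frames are converted to 8-bit grayscale (BT.601 luma). A per-pixel
**temporal median** over the video serves as the background/artifact
model. Foreground is found by Otsu thresholding the frame itself,
oriented by a polarity flag (dark-on-light by default), followed by
**opening by reconstruction** (erosion with a 3×3 element, then geodesic
dilation back within the original mask). Reconstruction removes isolated
speckle — anything a 3×3 erosion annihilates — while restoring every
surviving component pixel-exactly; plain opening would shave the
single-pixel tapered tips off the worms.

The median reference is applied at the *component* level: a candidate
whose mean |frame − reference| over its own pixels is below a small
contrast floor (10 intensity levels) has not moved during the video and
is removed as a static artifact. This is deliberately different from
thresholding |frame − reference| directly: a worm thrashing in place
covers its body-core pixels in well over half of all frames, so the core
leaks into the median and difference thresholding cuts the animal in two.
Component-level artifact removal keeps such worms intact while static
debris can still never become a tracked worm. A corollary is that a worm
that never moves at all is indistinguishable from debris — by
construction, and acceptably so for locomotion assays.

Candidates are then gated by the **worm minimum size** (pixel count,
inclusive ≥) and any component whose tight bounding box touches the frame
border is discarded (a clipped body would bias every metric). Components
use 8-connectivity; the outer boundary polygon is extracted for rendering.

## Skeletonization

Each mask (interior holes below 16 px are pre-filled as threshold
speckle) is thinned to a 1-px skeleton. The **midline** is the longest
endpoint-to-endpoint geodesic through the skeleton's pixel graph. Side
branches shorter than max(10% of the main path, 4 px) are pruning
artifacts; anything longer, a skeleton cycle, or a sizable interior hole
flags a **self-collision** (curl or body overlap) and the observation is
censored. Because thinning stops short of a blunt shape's extremities,
each midline end is extended along its local tangent until it exits the
mask; worm tips taper to a point, so the extension recovers the full body
length rather than overshooting. The path is then smoothed with a 5-px
moving average (ends anchored): the raw pixel staircase otherwise
overestimates oblique arclengths by up to ~8% and injects noise into the
tracking-point curvature. The midline length is the polyline arclength in
pixel units (diagonal steps count √2) — for axis-aligned bodies this
coincides with the pixel count within a pixel.

Seven tracking points are interpolated at exact arclength fractions
{0, 1/6, …, 1}; spacing is therefore equal by construction. Point 3 is
the midpoint. Head and tail are not distinguished; skeleton orientation
is made temporally consistent per track by matching ends to the previous
frame (the flip that minimizes end-to-end displacement wins), which keeps
the curvature sign continuous in time.

## Tracking and censoring

Association is greedy and uses only contours and their positions:
mask-overlap with a track's last contour is the primary evidence (largest
overlap first, one-to-one), with nearest-centroid within one median body
length as the fallback gate — at 7.5–14 fps inter-frame motion is small
relative to body size, so overlap is almost always decisive. An
observation overlapping **two or more** live tracks opens a worm–worm
collision event: the participant IDs are terminated permanently, the
merged blob is carried frame-to-frame by overlap (rendered yellow, never
measured), and when it resolves into ≥ 2 separate size-gated contours the
event closes and each survivor receives a fresh ID. IDs are monotonically
increasing and never reused. A track unseen for more than 5 consecutive
frames without a collision is closed; the patience keeps identities
honest across 1–2 frame detection dropouts without inventing long
occlusion bridges.

Self-collision frames stay on their track (the worm never merged with
another animal) but are moved to a censored set: they count as *observed*
for the frame-percentage filter, yet contribute no metric samples, and
stroke detection resets across the gap so no event spans it. The **frame
percentage** filter is applied once, globally: a track is reported iff
100 · observed frames / total frames ≥ the threshold (inclusive).

## Metrics

Coordinates are converted to µm *before* any physical quantity is formed,
so curvature is reported in µm⁻¹. Menger curvature of consecutive
tracking points (x, y, z) is 4·area(x,y,z)/(|xy|·|yz|·|zx|) — the inverse
circumradius — signed by the z-component of (y−x)×(z−y); collinear
triples give exactly 0 and coincident points are skipped. Menger
curvature is unsigned by definition; the sign-by-turn-direction extension
is what makes "curvature crosses zero" well defined for stroke counting,
and it matches the intuitive curvature-vs-time picture of an undulating
body.

Strokes are counted at tracking point 1 — the end-most point at which
curvature is defined (configurable). A stroke is a sign change between
the current nonzero sign and the last nonzero sign; exact zeros pass
through uncounted. Waves = ⌊strokes/2⌋ (partial strokes round down), and
the wave initiation rate divides by the *un-censored* tracked time only.
Swim speed takes midpoint positions only at every second stroke; any
interval containing a censored or missing frame is dropped. Dynamic
amplitude implements the formula |max| − |min| over all defined points
and frames of each two-stroke interval literally; a `mode="range"` switch
computes max − min instead for users who want the full curvature range
(the two differ only for one-sided bending).

Per-worm summaries are arithmetic means over defined samples only — gaps
are excluded, never zero-filled. Wave initiation rate appears only in the
summary table (it is a rate over the whole record, not a frame series);
its per-metric CSV is intentionally header-only.

## Synthetic data

The generator renders serpenoid worms: centerline curvature
κ(s, t) = κ₀ sin(2πs/λ − 2πft + φ) along arclength s. The heading
integral is closed-form, so the curve has *exact* length and known signed
curvature at every arclength fraction — the oracle for all recovery
tests. Bodies are tubes whose half-width tapers elliptically to a point
over the outer 15% of each end; scripted curls pose the body as a
1.2-turn constant-curvature loop (guaranteeing a real interior hole).
Worms are rasterized dark (60) on light (200) with additive Gaussian
noise (σ = 3) and a fixed seed makes output byte-identical.

Defaults mirror the two assay protocols: crawling at 7.5 fps (worm ≈
700 µm, wave ≈ 0.35 Hz, λ ≈ 0.65 L, drift ≈ 120 µm/s) and thrashing at
14 fps for 30 s (1 Hz, λ = 0.9 L, κ₀ = 0.008 µm⁻¹). Test and acceptance
scenes use 2–4 worms on 200–420 px fields and clips of 5–30 s — CI-scale
versions of plate recordings that would hold 20–50 animals.

What the generator does **not** emulate: illumination gradients, focus
drift, worm-shaped debris, self-overlap short of a closed loop, omega
turns, reversals, body-width variation between animals, and the optics
of real cameras. Passing recovery tests therefore demonstrates that the
algorithms are correct on well-posed input, not that segmentation is
robust to every real-world artifact; the three user parameters exist
precisely to adapt the gate to real footage.

## Numerical choices and edge cases

- Otsu comparison is inclusive (`≤`), so a noiseless two-level image —
  where Otsu returns the foreground level itself — still segments.
- A frame whose max |difference| from the reference is < 10 levels is
  declared empty before Otsu is attempted (Otsu on a near-constant image
  is meaningless).
- Contours that thin to ≤ 1 px, or whose midline has < 7 vertices or
  < 2 px of length, raise a degenerate-shape error and are dropped with a
  log record (e.g. a perfect disc has no two-endpoint midline).
- Crawl speed emits no value across observation gaps; stroke detection
  resets after any gap; swim/amplitude intervals containing gaps are
  dropped whole.
- Chunk size defaults to ⌈n_frames / workers⌉; worker count affects wall
  time only.

## Known limitations

- Collision detection requires the merged blob to resolve into ≥ 2
  size-gated contours; three-way pile-ups resolve when any two animals
  separate, and a blob that drifts out of frame closes its event with no
  successors.
- Head/tail identity is not assigned, so the stroke point is "an end",
  not "the head"; stroke counts are unaffected (zero crossings at either
  end-adjacent point alternate identically).
- The midline of a strongly coiled but not-yet-closed posture shortens
  slightly (thinning geometry); such frames are rare between curl
  censoring and the 15% spur threshold.
- Frame-rate metadata in GIF containers is stored in 10 ms quanta;
  prefer TIFF (exact JSON metadata) or pass an explicit override.
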