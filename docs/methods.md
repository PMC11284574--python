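# Methods

This note records the model behind `petalseg`, the parameters that matter,
the numerical conventions, and the design decisions taken where the procedure
was genuinely open. It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## Strip-crop geometry

A crop frame is a rotated rectangle of `length × width` pixels (defaults
900 × 32) centred on the flower center, at angle θ. Crop pixel `(u, v)` maps
to slice coordinates

    (row, col) = center + R(θ) · (u − (length−1)/2, v − (width−1)/2)

with `R` the counterclockwise rotation in (col, row) axes, row increasing
downward; θ = 0 is a horizontal strip with the long axis along columns. The
angle convention is arbitrary in principle — any consistent choice gives
equivalent pipelines — but it is fixed and documented so results are
reproducible. Frames are emitted at θ = 0, step, …, 360° − step; θ and
θ + 180° cover the same physical strip in flipped orientation and are both
kept, because the per-slice crop count of the protocol (360 at a 1° step) is
defined that way.

Resampling is nearest-neighbour, with half-integers rounded away from zero so
results do not depend on platform rounding. Crop pixels whose source falls
outside the slice raster are drawn i.i.d. from `Normal(μ_bg, σ² = 5)` — the
stated fill parameter is read as a *variance* (std = √5 intensity units), the
alternative reading (std = 5) being equally defensible but not chosen — and
clamped to the image dtype range to avoid wraparound in unsigned rasters.
Only coordinates outside the image raster are treated as "empty" and filled;
background inside the raster is kept as imaged. Fill draws are seeded per
crop from (pipeline seed, slice index, angle index), which makes whole runs
bit-reproducible.

The flower center defaults to the intensity centroid of the Otsu foreground,
recomputed per slice; a fixed mid-stack estimate (`fixed_center`) or explicit
coordinates can be supplied instead. "Background" for the fill statistics is
defined as the sub-Otsu-threshold pixels — a reproducible, parameter-free
convention.

## Per-crop segmentation backends

The segmentation contract is one function: crop in, scored instance masks
out. Masks are stored as sorted flat pixel-index sets, not dense grids; a
slice under integration holds ~360 × 15 candidate masks and dense storage
would be ~1.4 GB per slice.

* **Oracle backend** — extracts the ground-truth labels into crop
  coordinates, takes connected components per label, then perturbs them:
  drop with probability `p_drop`; split with probability `p_split` in two at
  a cut perpendicular to the component's principal (elongation) axis, the
  cut position uniform over the central half of the axis extent so both
  parts are substantial; erode/dilate boundaries by a random offset within
  `±boundary_jitter_px`. With all noise off, output is exactly the GT
  components at score 1.0; with noise on, scores are 1 − U(0, 0.2) so that
  score-rank-dependent AP curves are exercised. All draws are seeded per
  (seed, slice, angle).
* **Classical backend** — Otsu (or fixed) threshold of the non-fill crop
  pixels, connected components, area floor (`min_area_px`, default 20),
  score = component mean intensity normalized to the crop range (making the
  output invariant to affine intensity rescaling in Otsu mode).
* **COCO interchange** — annotations (RLE, one category "petal") are
  exported with the crop PNGs and a sidecar binding image ids to crop
  frames; scored detections (RLE counts list, compressed counts string, or
  polygons) are imported back. The RLE codec (column-major runs; compressed
  form with difference coding and 6-bit chunks) is implemented in the
  package and round-trips losslessly. Imported detections below a score
  threshold (default 0.5, configurable) are discarded before integration.

## 2D integration

For every cyclically adjacent angle pair (the pair last-angle/first-angle is
included), masks are compared inside the **shared footprint** of the two
strips. Two rules apply, in order:

1. **Error removal** ("the divided result is correct"): a mask that overlaps
   two or more masks of the adjacent crop — each overlap at least
   `min_overlap_px` pixels (default 5, which ignores 1–2 px resampling
   slivers) — is marked. Marking is evaluated in both directions of every
   pair against the *original* sets, and all marked masks are deleted at
   once, so the outcome is independent of processing order.
2. **IoU merging**: surviving masks of adjacent crops are connected when
   their IoU is ≥ 0.8. IoU is computed with both masks restricted to the
   shared footprint, because adjacent strips cover different slice regions
   near their ends and full-mask IoU of a correctly matched petal can fall
   far below the threshold there; a flag switches to full-mask IoU for
   comparison. Petal groups are the connected components of the match graph
   (union-find); group ids are assigned by each group's smallest
   (angle, instance) member, so results are deterministic and independent of
   pair order. Only adjacent angle pairs are compared — non-adjacent crops
   share too little footprint for the rules to be meaningful.

### Consensus rasterization

Per-pixel fusion of a group's member masks is not prescribed by the
procedure and is a design choice here. Two rules are implemented:

* **Covering-count vote** (`rasterize_consensus`, pipeline option
  `fusion="vote"`): each pixel goes to the group with the most covering
  member masks, ties to the lowest group id, uncovered pixels to background.
  This is effectively a union over members within a group. Because each
  member is a slice→crop→slice nearest-neighbour resampling of the petal,
  boundaries jitter by up to ~1.4 px per angle, and the union over ~150
  members dilates every petal by roughly a pixel per side: on phantoms this
  costs ~15–25 % area error and caps per-petal IoU near 0.8.
* **Visible-member majority** (`rasterize_consensus_majority`, the pipeline
  default): a pixel joins a group's consensus only if at least half of the
  member strips whose band covers the pixel also mark it. A strip at angle θ
  covers a pixel at polar coordinates (r, α) relative to the crop center iff
  |r sin(θ − α)| ≤ width/2, so the per-pixel count of observing members is
  evaluated in closed form from the sorted member angles. This recovers the
  *median* boundary of the resampled copies instead of their union; measured
  on the reference phantom it brings per-petal 3D IoU from ~0.8 to ≥ 0.99
  and the area MAPE from ~20 % to ~0.03 %.

Final label regions smaller than `min_region_px` (default 20 px) are cleared.
The floor removes sub-resolution debris produced by boundary jitter at patch
ends; 20 px is an order of magnitude below a plausible petal cross-section at
this resolution (the study data's median is 223 px), so no real petal is at
risk. Each petal is represented twice among the groups (the θ and θ + 180°
copy chains are pixel-identical); the deterministic tie-break assigns every
pixel to the lower-id copy, so the duplicate chain rasterizes to nothing and
does not surface as a detection.

## 3D integration

Label maps are stitched sequentially from the top slice: every label of
slice k+1 is matched one-to-one to slice k labels by greedy descending IoU,
accepting only IoU ≥ 0.8, ties broken by larger intersection then smaller
label pair. Matched labels inherit the global id; unmatched labels open
fresh ids; a discontinued id is never revived, so each petal's slice support
is a contiguous interval by construction (asserted on outputs). Greedy
one-to-one matching is the simplest reading of "the pair with the highest
IoU"; when a petal splits or merges between slices the forced choice is
logged, not silently resolved. An optional `bridge=k` allows matching up to
k slices back (off by default; it breaks the contiguity guarantee).

## Evaluation

AP/AR follow the standard COCO detection protocol for a single category:
per-image greedy matching of score-sorted detections at each IoU threshold,
101-point interpolated precision, recall at 100 detections per image,
averaged over thresholds 0.50:0.05:0.95 (AP50/AP75/mAP and AR analogues).
The implementation is vectorized and is cross-checked to 1e-6 against an
independent plain-loop implementation of the protocol kept in the test suite.
Consensus regions enter as detections with the mean score of their group
members (configurable to 1.0).

Petal areas are pixel counts × (pixel side)², reported in mm²; with the
46.252 µm pixel of the reference scanner one pixel is 2.1392 × 10³ µm². The
area MAPE uses greedy best-IoU (≥ 0.5) matching of predicted to ground-truth
regions — a stand-in for the manual matching of the original protocol — with
a manual-override path available. Variance of petal areas is the sample
variance (n − 1).

## Phantom generator

Petal k follows the radius curve r(φ) = scale · (r₀ + pitch·k +
amp·sin(2π·d/arc)) over an `arc` span starting at the golden-angle offset
k·137.508°; pixels within half the thickness of the curve belong to the
petal. r₀ = max(3·thickness, 2·pitch) and amp = 0.4·(pitch − thickness −
gap), so pairwise disjointness holds by construction and is rejected at
construction when the inequality fails. `scale` shrinks linearly by `taper`
toward the top of the stack, emulating a closing bud; the generator warns
when the taper makes the analytic adjacent-slice IoU of the outermost petal
fall below 0.85, since 3D matching at 0.8 would then fail on clean data.

Defaults — 20 petals, 40 slices of 512 × 512 px, thickness 6 px, pitch 11 px,
gap 2 px, arc 140°, intensities 200/20 with σ = 5 Gaussian noise, taper
0.001, pixel size 46.252 µm — define the package's reference volume: a
desk-scale analogue of a real scan (which is ~900 slices of ~900² px with
dozens of petal cross-sections per slice). What the phantom does *not*
emulate: CT reconstruction artifacts (beam hardening, rings, drift noise),
petals in contact, intra-petal texture, sepals and stamens. Passing the
closure tests therefore demonstrates the correctness of the geometry,
integration and evaluation machinery — not detector robustness on real CT
appearance, which depends on the plugged-in backend.

## Problem sizes and runtime

The reference acceptance run (40 × 512² slices, 360 angles, oracle backend)
takes ~2.5 minutes on one CPU; the test suite about the same again. These
sizes were chosen as the smallest volume that still exercises every failure
mode (petal multiplicity, taper, both copy chains, tips); the stages scale
linearly in slices × angles × strip area.

## Known limitations

* The error-removal rule trusts the finer division. Under pure
  over-segmentation noise (spurious splits) it removes *correct* coarse
  masks; its benefit targets under-segmentations that span several petals.
  With heavy split noise the adjacent-angle merge chains fragment and
  integration degrades regardless of the rule — measured and reported by
  the degradation entries of the acceptance script.
* Petals thinner than ~3 px or touching petals (no gap) violate the
  resampling and disjointness assumptions and are not recoverable.
* Sub-pixel resampling (bilinear/bicubic) is deliberately out of scope; the
  nearest-neighbour convention matches the original acquisition protocol.
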