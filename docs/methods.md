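# Methods

This note records the models, conventions and parameter choices behind
`mwmaze`, including the places where the underlying procedure is
under-specified in the literature and the package had to fix a
definition of its own.

## Arena model and calibration

The pool is a disc of diameter 1.80 m (radius R = 0.90 m) holding a
circular platform of diameter D = 0.14 m. All analysis happens in a
metric frame with origin at the pool centre, +x right, +y up. Pixel
coordinates map into this frame by translation to the detected pool
centre, scaling by `pool_diameter_m / (2 · pool_radius_px)` and a y-axis
flip; the round trip is exact to < 1e-9 m. The default frame rate is
25 Hz: one trajectory sample per frame.

The default platform position is (0.39, −0.39) m — mid-quadrant
placement at 0.55 m from the pool centre. With the standard annulus
width of one platform diameter this yields K = ⌈(0.5515 + 0.90)/0.14⌉ =
11 rings and therefore 32·(4+11) = 480 combined features per trial, the
canonical layout of the combined feature set. All geometry is
configurable through a YAML block (`PoolGeometry.from_config`).

## Zone partitions

**Quadrants** are bounded by the two diameters aligned with the wall
markers. Zone 1 is the quadrant containing the platform centre; zones
2–4 follow clockwise. Sectors are half-open so the partition tiles the
disc exactly: a boundary ray belongs to the quadrant on its clockwise
side, and a platform sitting exactly on a boundary is assigned by the
same rule (the clockwise-first adjacent quadrant). The quadrant
reference "centre" used by distance measures is the point on the
angular bisector at half the pool radius — a fixed, easily documented
reference; features only need a stable anchor point.

**Annuli** are rings of width w = (width multiple) · D centred on the
*platform* centre, numbered innermost (zone 1: the disc of radius w)
to outermost, each clipped to the pool disc. The ring count
K = ⌈(d + R)/w⌉, where d is the platform offset from the pool centre,
is derived from the configured geometry rather than hard-coded: it is
the number of rings whose area intersects the pool. Rings are half-open
`[inner, outer)`, with the outermost ring closed at its outer rim. The
annulus "zone centre" is the platform centre for every ring (the rings
are concentric, so any per-ring centroid degenerates to that point).

Distance-to-border queries treat the zone boundary as a curve set
(radial segments plus wall arc for quadrants; clipped circles plus wall
arc for annuli) and return the unsigned minimum distance, computed
analytically with circle–circle intersection endpoints as fallbacks.
Tests verify them against a dense boundary-discretization oracle to
1e-3 m.

## Pool localization and rotation

"Find the pool" is a matched filter: a zero-mean ring kernel modelling
the border (bright just inside the wall, dark just outside, band width
6 px) is correlated with the frame. The correlation is normalized *over
the kernel's annular support only* (masked NCC, computed with FFT
convolutions), so the score is invariant to global lighting and is not
diluted by the rectangular window; a true border match scores ≈ 1. A
radius scan of ±10% in 2 px steps picks the best radius. Scores below
0.3 raise `PoolNotFound`; uniform-noise frames are rejected at this
threshold in ≥ 95% of seeded trials.

Rotation is estimated from the wall markers, which are rendered (and
expected) as four *distinct* shapes — disc, square, triangle, bar — so
that 90° rotations are distinguishable. The marker band (0.82–0.96 R)
of the frame and of the canonical template are resampled into angular
intensity profiles; circular normalized cross-correlation on a 1° grid
plus 3-point parabolic refinement yields the angle. A flat correlation
profile (no angular structure) raises `RotationAmbiguous`. On noise-free
renders the recovery error is well below the 1° grid step.

`normalize_frame` rotates about the *detected pool centre* (not the
image centre), then crops to a (2r+1)² square with the pool centred and
zeroes everything outside the disc. Gaussian blur (σ = 1.5 px, chosen so
a 1-px line artifact is attenuated below a third of its amplitude while
the ~15 px animal blob is preserved) is applied before background
modelling.

## Background subtraction

The background is a pixelwise weighted mean of all (blurred) frames with
weights ∝ exp(−λ·age); λ = 0 (plain mean) is the default and reduces to
the classical "average out the moving animal" background. Detection
binarizes |frame − background| at 25 intensity levels, applies a 3×3
morphological opening, and keeps the largest connected component with
area ≥ 30 px as a tight bounding box; confidence is the component's fill
fraction of its box. Threshold and area defaults were calibrated once on
the synthetic renderer's contrast (animal ≈ 55, water ≈ 150 on a 0–255
scale). The largest-component rule resolves multi-blob frames
(reflections, splashes). Absence of a detection is a valid per-frame
outcome; the trajectory layer handles the gaps.

## Trajectory cleaning

Three steps, applied exactly once each, in order.

1. **Entropy filter.** The published procedure says only that static
   sections are found by "entropy within sliding windows"; this package
   defines the quantity as *positional occupancy entropy*: within each
   25-sample (≈ 1 s) window, positions are binned on an 8×8 grid over
   the window's bounding square and the Shannon entropy of the occupancy
   distribution, normalized by log 64, is compared with the threshold
   0.1. Two deliberate details: the grid side has a floor of 0.05 m
   (below that scale the animal is effectively stationary within the
   window) and is anchored at the window minimum, so sub-centimetre
   tracker jitter collapses into a single bin and scores exactly zero —
   without the floor, jitter over an arbitrarily small bounding square
   would look maximum-entropy. A sample is removed only if *every*
   window containing it is below threshold, which preserves the
   boundary between a static head/tail and genuine swimming.
2. **Percentile filter.** Displacements between consecutive valid
   samples are pooled; the arrival sample of any step strictly longer
   than the 95th percentile is invalidated. Single pass: the threshold
   is computed once from all displacements, and ties at the threshold
   are kept. (Re-applying the filter would keep shaving the
   distribution's tail — a property the tests document — hence the
   explicit single-pass contract.)
3. **Interpolation.** Leading and trailing invalid runs are trimmed (no
   extrapolation); interior gaps are filled linearly in time and marked
   `interpolated`. The absolute clock is preserved, so latency measures
   still count from the first raw frame.

## The 32 zone measures

The measure list gives names and units; the per-measure arithmetic is
this package's operationalization, chosen to be deterministic,
unit-consistent and checkable by an independent per-frame oracle:

- A displacement step belongs to the zone of its **starting** sample;
  step speed = step length × frame rate.
- Headings come from displacement vectors (east = 0°, north = 90°);
  steps shorter than 1e-4 m carry no heading. Turn angle is the wrapped
  difference of consecutive valid headings, attributed to the zone of
  the later step's starting sample; a full revolution sums to 360°.
- Heading error is the wrapped absolute difference between a step's
  heading and the bearing to the reference point (platform centre, or
  zone centre; for the platform-containing zone the "zone" reference is
  the platform centre itself, which is why the initial-heading measures
  name both). The signed initial error is positive clockwise.
- "Moving towards (away from)" a zone counts out-of-zone steps whose
  distance to the zone centre strictly decreases (increases); in-zone
  steps count toward neither. "Oriented towards" measures count in-zone
  time with absolute heading error below 20° (configurable).
- A visit is a maximal run of in-zone samples; starting inside counts an
  entry at t = 0, and an exit is only counted when the animal leaves
  before trial end, so entries − exits ∈ {0, 1}.
- Line crossings are quadrant-boundary transitions over the whole path,
  stored identically for every zone of a partition.
- Censoring keeps every cell numeric: a never-entered zone gets
  latencies equal to the trial duration, distance-until-first-entry
  equal to the total path length, zero visit/occupancy sums, and
  min/max/average distance statistics computed over *all* samples.
- Cumulative distance from zone sums border distances over out-of-zone
  samples and therefore scales with the frame rate; it is retained in
  this form because all trials share one frame rate.

Conservation holds by construction: per-partition occupancy times sum to
the trial duration within one frame, and in-zone path lengths sum to the
total path length exactly.

## Classification protocol

Stratified 10-fold cross-validation, features standardized inside each
training fold; accuracy is the mean over folds and confusion matrices
are pooled over validation folds. Feature selection, when enabled, is
re-fit inside every training fold (no leakage; a permuted-label run sits
at chance and is tested). Classifier hyperparameters are fixed: LR
(lbfgs, max_iter 2000), Gaussian NB, decision tree (min leaf 2), random
forest (100 trees), MLP (one hidden layer of 64 units). Per-trial rows
are the default; `group_by="animal_id"` switches to grouped folds that
keep an animal's nine trials together, trading fold-size balance for
independence between folds.

Feature selection is best-first forward search over subsets scored by
the CFS merit `k·r̄_cf / √(k + k(k−1)·r̄_ff)` — the canonical companion
evaluator of best-first search in the attribute-selection literature
(the published protocol names the search but not the evaluator). The
search keeps an open list of evaluated subsets, expands the
highest-merit one, and stops after five consecutive expansions without
improving the best merit (bounded backtracking). On ≤ 10-feature tables
it recovers the exhaustive-search optimum in every seeded replicate
tested. Feature "relevance order" is the admission order into the best
subset. Constant columns are dropped with a warning before the search.

## Synthetic data

The generator supplies everything the real recordings would:

- **Swims** are correlated random walks at 25 Hz: per-step speed
  ~ N(mean, sd), heading updated by Gaussian noise, a constant turn bias
  and partial alignment with the platform bearing
  (`platform_attraction` ∈ [0, 1]); thigmotaxis adds steering toward the
  outer 15% radial band, circling a constant angular drift. Walls
  reflect. Trials end on platform contact or at 60 s.
- **Cohorts**: each animal swims 3 trials/day for 3 days. The default
  contrast gives young animals faster, platform-directed swims
  (0.22 m/s, mostly direct swim) and old animals slower, less directed
  mixtures with thigmotaxis and circling (0.15 m/s). This reproduces
  the canonical aged-cohort signature — longer escape latency, lower
  speed — and, because thigmotaxis redistributes time toward the outer
  annuli at matched quadrant occupancy, part of the group difference is
  a *proximity* effect that annulus features resolve better than
  quadrant features.
- **Renders**: 444×444 grayscale frames; water disc at 150, rim at 210,
  surround at 30, four distinct dark markers at 45°/135°/225°/315°
  (optionally pre-rotated), the animal as a dark heading-aligned ellipse
  (9×6 px). Optional degradations: additive shimmer noise on the water
  and random 1-px bright/dark line segments per frame. Ground-truth
  boxes are returned for closure tests.

All randomness flows from one seed through spawned NumPy generators, so
cohorts, trials and renders are independently reproducible.

What the generator does **not** emulate: real water-surface optics,
reflections and splashes, animal body articulation, lighting drift
between recordings, lens distortion, or biologically calibrated swim
kinematics. Passing tests therefore demonstrate the correctness and
internal consistency of the pipeline and the discriminability of
constructed contrasts — not field performance on real videos, where a
learned detector satisfying the `DetectionSeries` contract is expected
to replace background subtraction in difficult footage.

## Problem sizes and numerical conventions

The test suite and acceptance script use desk-scale problem sizes chosen
as the package's own defaults: 200 ten-second random walks for the
feature-oracle and conservation checks, 300-frame renders for detection
closure, cohorts of 8–10 animals per group (144–180 trials) for the
classification experiments, and 5–20 seed replicates where a mean over
seeds is reported. Angle wrapping uses (−180°, 180°]; oracle agreement
is asserted to 1e-9 (relative and absolute); degenerate inputs (empty
detection series, < 2 valid samples, constant feature columns,
single-ring partitions) raise typed errors or warn, as documented in
each module.

## Known limitations

- The entropy and percentile filters are rule-based; no smoothing model
  (Kalman/particle) is applied, by design.
- Path length recovered through the full render→detect→clean loop is
  inflated by pixel-quantization jitter by a few percent; latency
  recovery is sub-frame-accurate.
- The CFS evaluator assumes roughly linear feature–label association;
  measures informative only through interactions may be passed over.
- Per-trial cross-validation folds let trials of one animal appear in
  both training and validation sets; use `group_by="animal_id"` when
  animal-level generalization is the question.
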