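# Methods

This note documents the models implemented in `pentrack`, the defaults and
why they were chosen, the numerical machinery, and what the synthetic test
world does and does not establish about real footage.

## Problem setting and assumptions

A fixed camera observes a closed pen holding a constant number N of
similar-looking animals. Nothing enters or leaves, so tracking is the
maintenance of exactly N identities over time. Three failure sources are
modelled explicitly: per-frame detectors produce false negatives, false
positives, and merged boxes when animals overlap; template trackers drift
under occlusion and appearance change; and illumination fluctuates (including
a day/night switch to grayscale infrared imaging). Inter-frame motion is
assumed small relative to the animal size — the cameras this design targets
run at tens of frames per second.

## Detector head geometry

The detection side is a pluggable interface (`detect(frame) ->
DetectionOutput`); what the package implements as first-class, testable code
is the geometric and loss machinery of a single-shot multi-scale detector
head:

* **Anchor lattice.** `f` feature maps of sizes m×n carry k default boxes
  per cell at scales `s_i = s_min + (s_max − s_min)(i−1)/(f−1)` and aspect
  ratios {1, 2, 3, 1/2, 1/3} (plus one unit-ratio box at the geometric-mean
  scale when k exceeds the ratio count). The canonical six-layer arrangement
  (38, 19, 10, 5, 3, 1 with k = 4, 6, 6, 6, 4, 4) yields exactly 8732 boxes.
  `s_min = 0.2`, `s_max = 0.9` are defaults, configurable; the total count is
  what pins the configuration.
* **Matching.** Stage 1 gives every ground-truth box its argmax-overlap
  anchor (so no GT is unmatched); stage 2 additionally marks anchors with
  Jaccard overlap > 0.5 positive. An anchor serves at most one GT; ties go
  to the higher overlap, then the lower GT index (the tie rule is ours).
* **Loss.** Two-class log loss over positives plus 1:3 hard-mined negatives,
  and smooth-L1 regression between offset encodings
  `t = ((cx−cx_d)/w_d, (cy−cy_d)/h_d, log w/w_d, log h/h_d)`, averaged over
  the N matched anchors with a β weight on the localization term.

Training a network is out of scope; synthetic detection streams (below)
stand in for a trained detector throughout the tests.

## Tag-box correlation tracking

### Features

Two cell descriptors, both built to vary smoothly under sub-pixel shifts:

* **Oriented-gradient histograms** (9 unsigned orientation bins, 6 px cell).
  Gradient magnitude is soft-assigned between neighbouring orientation bins,
  spatially pooled with a Gaussian of σ = cell/2, sampled at cell centres,
  and normalized per cell. Hard cell binning (as in common off-the-shelf HOG
  implementations) is deliberately avoided: it is shift-variant below the
  cell scale and measurably biases the sub-pixel correlation peak (in our
  translating-target experiment, mean displacement error 0.66 px/frame with
  hard binning vs ≈0.05 px with the smooth descriptor).
* **Colour names** (11 channels, 4 px cell; day mode only). Pixels are softly
  assigned to the 11 basic colour terms by distance to representative sRGB
  prototypes and pooled the same way. This is a prototype-based construction,
  not the learned colour-name lookup table of the photometric literature;
  it is adequate for the synthetic scenes shipped here and is clearly marked
  in `features.py`. Night (infrared) sequences are grayscale and use
  gradients only; a grayscale input in day mode degrades the same way with a
  logged notice.

Blocks at different cell resolutions are fused onto one common grid (stride
2 px) by Fourier zero-padding — the trigonometric-interpolation realization
of the continuous-domain interpolation operator — then rolled so the target
centre sits at the grid origin.

### Filter model and training

Filters minimize

    Σ_l π_l ‖ Σ_c f^c ∗ (P^T μ_l)^c − y* ‖² + Σ_c ‖ w · f^c ‖²

* `P` is a D×C orthonormal channel projection (C = 8 by default) taken as
  the top eigenvectors of the first-frame channel Gram matrix. It is learned
  once at initialization and kept fixed rather than refined jointly with the
  filters each update; the first frame carries the full iteration budget.
* The sample model is a Gaussian mixture over feature stacks: a new sample
  enters with weight equal to the learning rate (0.09), existing weights
  shrink by the complement, and when the component count exceeds L = 30 the
  two closest components (L2 distance between means) merge into their
  weighted mean. Weights are renormalized to sum to one after every update.
* `y*` is a circularly wrapped Gaussian with peak 1 at the origin and
  σ = max(1, 0.1·diag(tag-box in cells)).
* `w` is a quadratic bowl: `reg_min = 0.15` at the centre growing by
  `reg_slope = 3.0` per squared tag-box half-size, so boundary filter
  coefficients are strongly suppressed (the periodic training samples are
  fictions outside the target).
* The normal equations `(Σ_l π_l Z_l^H Z_l + w²) f = Σ_l π_l Z_l^H y` are
  solved by conjugate gradients with data-term products evaluated
  per-frequency (FFT) and the regularizer applied spatially. CG budgets: 120
  iterations on the first frame, 5 per subsequent update (the post-first-
  frame count is unstated in the design source; 5 suffices with warm
  starts). The stopping tolerance is relative (‖r‖²/‖b‖² < 1e−26, i.e.
  effectively iteration-bounded); the best iterate by objective value is
  returned, making the objective non-increasing by construction. On a
  single-sample, single-channel, constant-regularizer problem the solution
  coincides with the closed-form Fourier ridge filter
  `conj(X̂)Ŷ/(|X̂|² + λ)`; both this and an explicit dense circulant solve
  serve as oracles in the test suite.

### Localization and stepping

The response `R = Σ_c f^c ∗ z^c` is band-limited, so its value, gradient and
Hessian are available anywhere from the Fourier coefficients; sub-pixel
localization runs Newton iterations (clamped to half a cell per step) from
the grid argmax. A constant response raises an *untrackable* signal: the
tag-box stays in place, flagged for the association layer.

Per frame, the search patch is evaluated at scales {0.98, 1.0, 1.02} with a
0.985 peak penalty on the non-unit scales; the tag-box scale is the running
product, clamped to [0.5, 2]. Two further choices matter:

* **Search area.** A square of side `4·√(tag_w·tag_h)`, centred on the
  tag-box. A per-axis factor (4× each dimension) was tried first and
  rejected: for elongated targets it produces a patch as narrow as ~3 tag
  widths, boundary content dominates the periodic response, and localization
  can jump tens of pixels. Area-based square scaling gives every target the
  same spatial context in both axes.
* **Motion prior.** Because inter-frame motion is limited under a fixed
  camera, response values beyond a per-frame displacement radius of 6 px are
  discounted by a Gaussian fall-off (σ = 6 px) *outside* the radius only.
  The flat top is essential: a prior peaked at zero displacement shrinks the
  sub-pixel estimate toward zero, and the resulting under-measurement is
  absorbed into the model updates as a self-reinforcing tracking lag
  (~1.3 px/frame in our experiments) — the flat-topped form suppresses
  far-field false peaks without biasing plausible motion at all.

Samples and filters are refreshed every 2 frames (sparse updating); filter
coefficients are bit-identical between an update frame and the following
non-update frame.

`init_tracker` centres the tag-box on the given animal bounding box with
dimensions `fraction = 0.4` of it (the fraction is a package choice; the
originating design names the concept but not the number).

## Hierarchical data association

Detections and tag-boxes are matched by the Hungarian algorithm (SciPy's
solver, with an infinitesimal index perturbation for deterministic
lowest-row/column tie-breaks) under the containment cost given in the
README. Two deliberate interpretations:

* **Zero overlap.** The cost formula's printed value for disjoint pairs (a
  constant 1) would be *lower* than the cost of any small positive overlap,
  perversely favouring disjoint assignments; disjoint pairs are treated as
  infeasible (sentinel cost, never assigned) instead.
* **Containment threshold.** "A detection contains a tag-box" is
  operationalized as containment overlap ≥ 0.5 of the tag-box area
  (configurable).

Each animal gets exactly one state per frame, with this precedence for an
unassigned tag-box: pending → drift; inside an assigned detection →
multi-assignment drift (the contested detection keeps the lower-cost
tag-box); still covered by its own default box (its last tracked box, lag
l = 1, no motion extrapolation) → unstable detection; otherwise drift.

Consequences per state: unstable detections are refined — unassigned
detections are matched to the default box by the same cost, the best match
(or the default box itself) becomes the frame's output; multi-drift
tag-boxes are pended (a flag equivalent to moving the centre off-canvas),
excluding them from matching so subsequent frames route them through the
drift branch; every id passing the unassigned branch moves its age counter —
+1 if its default box no longer covers its tag-box, −1 (floored at 0)
otherwise — and an age exceeding T = 20 triggers re-initialization of the
tracker from the animal's currently associated detection box, resetting the
age and the pending flag. If that frame's output is not detection-derived,
re-initialization defers; the age keeps growing, so the next
detection-backed frame triggers it. Ages of actively tracked ids are left
untouched (the decay rule is read as applying within the unassigned branch
only).

The layer always emits N boxes with the fixed id set — a tracked id emits
its matched detection, everything else emits its refined or default box —
and each tracklet's history grows by exactly one entry per frame.

## Evaluation

CLEAR-MOT matching runs per frame at IoU ≥ 0.5 with continuation preference
(last frame's pairs that still clear the threshold are kept before the
Hungarian step on the remainder). An identity switch is counted when a
ground-truth object's matched hypothesis id differs from its last known
match; a fragmentation when its tracked status toggles off after first
acquisition. MT/PT/ML use 80% / 20% coverage. MOTA = 1 − (FN+FP+IDs)/GT.
Recall, precision and MOTA are reported as percentages, FAF per frame.
Files use the MOTChallenge CSV convention (1-based frames externally,
0-based internally, 2-decimal coordinates).

## Synthetic pen world

The generator emulates the statistical structure the method assumes, not the
appearance of any real farm:

* agents are ellipses with per-agent rigid speckle textures (so gradient
  features are informative and identity-bearing), slowly oscillating axis
  ratio (deformation), smooth random-walk motion (speed 0.5–2 px/frame,
  heading diffusion 0.08 rad/frame ≈ 1.6 rad/s at the emulated 20 fps — a
  briskly moving animal; values far above this correspond to physically
  impossible spinning and defeat any appearance tracker), soft collision
  avoidance and reflective walls keeping every ellipse inside the pen;
* an "insect" occluder: a dark soft-edged blob following a waypoint path
  (or holding position for a long stay), composited over the scene;
* per-frame illumination gain/offset schedules; night mode renders a single
  channel;
* a detection-stream corrupter: independent drops (probability `p_fn`),
  Gaussian box jitter, Poisson spurious boxes (`p_fp` per frame), and union
  replacement of ground-truth pairs above a merge-IoU threshold — the
  classic merged-detection failure on overlapping animals.

Everything is reproducible from `(spec, seed)`.

What passing on this world shows: the geometry, optimization, state machine
and metric code are correct, and the closed-loop design recovers the
scripted failure modes end-to-end. What it does not show: performance on
real animals — real pigs deform non-rigidly, touch for long periods, and
have far weaker texture identity than per-agent speckle; the published
farm-footage numbers are not reproducible from this repository and no claim
about them is made.

## Problem sizes in the shipped runs

The test suite and acceptance script use scenes of 9 agents at 480×360 px
for 70–80 frames, filter problems of 16×16 and 8×8 grids for the solver
oracles, 1000 assignment matrices up to 6×6 for the Hungarian oracle, and a
50-frame translating-target sequence for displacement recovery — sizes
chosen so the whole suite runs in minutes on one CPU while every mechanism
is exercised.

## Known limitations

* The detector is not trained here; real deployments must register a
  detector plug-in (any callable producing scored boxes) or supply
  precomputed detection CSVs.
* Translation-only correlation tracking under sustained body rotation
  wanders tangentially (the template has no rotation state); the
  association layer absorbs this by design, but a rotation-augmented scale
  space would reduce re-initialization frequency.
* The channel projection is frozen after the first frame; severe appearance
  regime changes (day→night within a sequence) warrant re-initialization.
* Pending is binary and per-id; simultaneous multi-way contests among three
  or more animals resolve sequentially over frames rather than jointly.
* The colour-name descriptor is prototype-based, not the learned mapping;
  on real footage a learned table would likely be stronger in daylight.
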