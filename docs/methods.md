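# Methods

This note records the modelling choices, parameter defaults, numerical
conventions and known limitations of the toolkit, in the order the
pipeline uses them.

## Contour geometry and the half-perimeter rule

Masks are boolean H×W rasters, 0-based, row 0 at the top; contour points
are (x, y) = (column, row) pixel centres. `extract_contours` returns one
closed outer contour per 8-connected foreground component (interior holes
ignored), ordered by decreasing component pixel count. The tracer is Moore
border following starting from the topmost-leftmost pixel with the initial
backtrack to its west, scanning the 8-neighbour ring clockwise in screen
coordinates. Termination is by repeat of the (pixel, backtrack) walk
state, not by the classic "re-enter the start from the initial direction"
criterion: on one-pixel-wide spurs the steady-state entry direction at the
start pixel can differ from the initial one, in which case the classic
criterion never fires; the deterministic walk must instead revisit *some*
state, and the cycle between the two visits is exactly the closed
boundary. The implementation is verified against an independent
brute-force border follower on every one of the 65 535 non-empty 4×4
binary masks (component counts and per-contour perimeters).

Perimeter is the plain closed-polygon sum of Euclidean inter-vertex
distances with k_0 ≡ k_n; a single-point contour has perimeter zero. No
sub-pixel smoothing or corner-correction is applied — the perimeter is a
function of the raw pixel vertices only, so a measured number can always
be reproduced by hand from the contour.

Root length is L = S_p / (2r). The rule is exact for a digital curve: the
outer contour of a 1-px-wide chain of pixel-step length *a* traverses the
chain once in each direction, so S_p = 2a and L = a/r. Two systematic
biases are worth knowing:

* **Chain-code digitisation bias.** Comparing L against the *continuous*
  arc length of the curve that was rasterised, the 8-connected pixel chain
  overestimates by the factor f(θ) = cos θ + (√2 − 1)·sin θ per local
  orientation θ ∈ [0°, 45°] — zero at 0° and 45°, a maximum of +8.2% at
  22.5°, and ≈ +5.5% averaged over uniform orientations. The synthetic
  generator therefore records both truths (see below), and recovery
  against the continuous truth plateaus at a ~5.5–5.7% median error that
  no measurement-side change can remove without abandoning the raw-vertex
  perimeter definition.
* **Width bias.** For a root of width w px the contour also rounds the two
  end caps, overestimating length by roughly w/r per root. No width
  correction is applied; with the default calibration (7 px/mm) this is
  ≈ 0.3–0.7 mm for realistic 2–5 px root widths.

Fragmented masks (one root split into several components by a
discontinuous segmentation) are measured on the largest-area contour only,
with the fragment count logged — one root yields one measurement, and the
fragmentation is reported rather than silently summed. Seeds are never
measured. Calibration default r = 7 px/mm (steel-ruler calibration of the
reference acquisition setup); minimum component area default 1 px.

## Synthetic germination scenes

`synthgerm` renders what the measurement pipeline needs and nothing more:
a light mottled background resembling wet filter paper (optional specular
speckle as a hard-mode toggle), seeds as rotated ellipses (default
diameter 7.2 mm ≈ 50 px), and one primary root per germinated seed, drawn
as a cubic spline through a direction-random-walk control polygon, width
1–5 px, default target lengths 2–16 mm. Defaults mirror the emulated
protocol: 30 seeds per dish, r = 7, canvas 1024×1024 (the full acquisition
frame is larger; the canvas is scaled down to keep desk runtimes while
preserving the px/mm scale). Every root records:

* `true_arc_length_mm` — dense polyline integral of the generating spline
  divided by r (the continuous truth);
* `pixel_arc_length_mm` — length of the rasterised centreline chain
  (diagnostic; sample-rounding jitter makes it systematically longer than
  the drawn mask's effective digital length, so it is not used as a test
  truth).

Roots that would leave the canvas are redrawn up to a retry cap and then
truncated, with the truncated length recorded. Augmentations are
brightness shift (clipped at [0, 255]), mirror/horizontal flips (geometry
transformed consistently; an involution), and Gaussian pixel noise; none
of them changes a recorded truth. The 70/10/20 split assigns
round(fraction·N) to validation and test with the remainder to train.

What passing tests on these scenes shows: the geometry, bookkeeping,
training loop, compression machinery and evaluation code are correct, and
lengths are recovered to the accuracy the digitisation allows. What they
do **not** show: segmentation robustness on real imagery — real scenes
have touching roots, reflections, condensation and lighting drift that
the generator deliberately does not model.

## The desk-scale backbone

`TinySegNet` is a one-pool encoder–decoder (conv–BN–ReLU blocks, a concat
skip, a 1×1 three-class head; ~1.2×10⁴ parameters at default widths
16/32/16) on hand-written numpy kernels with exact backward passes
(gradient-checked in the suite). Instances are connected components of the
argmax class mask gated by a probability threshold (default 0.5), with
component mean probability as confidence and a 3-px minimum area. The
training loss is per-pixel softmax cross-entropy with class weights
(1, 2, 8) for background/seed/root — the root class occupies well under 1%
of pixels and is unlearnable at desk scale without reweighting. The
optimiser is SGD with momentum 0.9, weight decay 5×10⁻⁴, and a geometric
learning-rate decay from 10⁻² to 10⁻⁴ (the reference schedule), scaled to
desk-size epoch counts. Production backbones attach through the
`BackboneHandle` contract (named taps, predictor, graph description,
training loss) via the plug-in registry; nothing in the package depends on
any specific one.

## Channel-wise distillation

The softened distribution φ is a per-channel softmax over spatial
positions only (no normalisation across channels), computed with
max-subtraction, and the KL term is evaluated as a log-softmax difference
so no probability is ever materialised at zero. Temperature default
T = 1.0: the loss weight α = 1 is a stated reference setting while T is
not, so the neutral value is the default and both are config-exposed. The
teacher's parameters and running statistics are never touched (asserted by
checksum). One subtlety: during distillation the teacher's tapped features
are computed with *batch* statistics (buffers frozen) rather than its
running averages, so that teacher and student channel distributions are
normalised identically — otherwise self-distillation of an identical
frozen copy would not produce the expected zero CWD loss. Multiple layer
pairs contribute additively; a per-pair 1×1 adapter (identity-initialised
when widths match, random otherwise) is trained jointly with the student.
The reference backbone's published layer-index selections are shipped as
named presets (`yolov8-seg-3layer`, `-6layer`, `-8layer`) rather than
hard-coded, because the indices are meaningful only for that backbone's
numbering.

## Structured pruning

Sparsity training adds λ·Σ|γ| over all prunable BN scales (subgradient
λ·sign(γ); λ default 10⁻⁴, deliberately small relative to the segmentation
loss). The threshold is the floor(ratio·n)-th order statistic of the
pooled |γ| across prunable layers — a single global quantile, with strict
inequality so threshold ties are kept and a uniform-|γ| layer loses
nothing. Protected layers (the output head by default) keep all channels;
a plan that would empty a layer keeps its largest-|γ| channel and logs.
Element-wise-add groups share the union of their keep-masks (the only
choice that keeps the graph valid); concatenation inputs keep their own
masks, concatenated in order. Surgery slices producer rows, consumer
columns and all BN vectors including running statistics, and the analytic
parameter count of the pruned graph description must equal the live tensor
count (asserted). The iteration loop is {sparse-train, threshold, plan,
slice, fine-tune} with ratio ≈ 10% and fine-tuning at λ = 0
(sparsify-then-recover); sparsity training runs before every iteration. A
guard stops early if mAP collapses more than a configurable margin below
the best seen. Whether a fixed-|γ| cutoff or an exact per-iteration
quantile is the better reading of "~10% per iteration" is open; the
quantile is implemented because it makes the schedule deterministic.

## Evaluation

Matching is per image and per class, greedy in descending confidence, each
prediction taking the unmatched ground truth of highest mask IoU when that
IoU ≥ 0.5 (threshold inclusive — pinned by test, since prose definitions
of "exceeds" are ambiguous at equality). AP integrates the
precision–recall curve under the monotone precision envelope with
all-points interpolation; mAP@0.5 is the arithmetic mean over classes,
excluding (and logging) classes with no ground truth anywhere. The greedy
matcher is checked against exhaustive enumeration of one-to-one
assignments (lexicographically maximising each prediction's matched IoU in
confidence order) on all small cases.

## Complexity accounting

The conv FLOPs formula counts one multiply-accumulate as two FLOPs and
includes the +1 bias-slot term regardless of whether a bias is present;
pooling counts K² comparisons per output element; pass-through nodes
(concat, add, upsample) count zero. BN contributes 2·C trainable
parameters (γ, β); running statistics are buffers and not counted. The
bundled `yolov8_seg_n_2class.yaml` expresses the two-class n-scale
single-stage segmentation architecture (depth multiple 0.33, width
multiple 0.25, max channels 1024, 32 prototype masks, 640×640 input) in
the module's declarative format: 79 counted layers totalling 3.264 M
parameters and 12.01 GFLOPs. Weight-file size is reported both at 4
bytes/parameter (the formula as defined, 12.45 MB for the bundled spec)
and at 2 bytes/parameter (6.23 MB), because serialised checkpoint sizes in
the wild correspond to half-precision storage; the package makes no claim
about matching any particular checkpoint's on-disk size. FPS is arithmetic
on a supplied timing breakdown — no wall-clock benchmark is performed or
reproduced.

## Time-series reporting

`summarise_timeseries` bins per-root measurements into [k·Δ, (k+1)·Δ) hour
windows (Δ default 12 h, the granularity at which germination onset is
usually described) and reports per-group per-bin arithmetic means with
counts; empty cells are omitted. The drought demo parameterises six
treatment groups (control and five osmoticum concentrations) with endpoint
mean lengths (15.75, 15.32, 12.55, 11.73, 11.04, 9.95) mm, saturating
growth curves, later onset under stress, and unit-variance Gaussian noise
per observation; it exists to exercise the reporting path, not to model
osmotic-stress physiology.

## Numerical conventions and degenerate inputs

Float64 throughout the numpy kernels. Softmax and cross-entropy use
max-subtraction; log-probabilities are clipped at 10⁻¹². BN ε default
10⁻⁵; the standalone `bn_forward` accepts ε ≥ 0 provided σ² + ε > 0, so
exact-arithmetic examples with ε = 0 evaluate while division by zero stays
impossible. Empty masks measure to nothing rather than erroring; a
prediction without a mask produces a per-instance error record and the
rest of the batch proceeds. Max-pool gradient goes to the first argmax per
window. All randomness is `numpy.random.Generator`-seeded; dataset
generation derives per-scene seeds from one master seed via
`SeedSequence.spawn`.

## Problem sizes

The test suite and the acceptance script run training at desk scale by
design: 96×96 canvases, 3 seeds per scene, 10–12 scenes, TinySegNet widths
16/32/16 (teacher) and 12/24/12 (student), 20–30 epochs, two pruning
iterations — sizes at which a full train → distill → prune → evaluate →
measure pipeline completes in about a minute on one CPU while still
exercising every contract. Geometry checks use 100 scenes at 512×512 with
1-px roots of 10–16 mm. These sizes are the package's validation
conditions; nothing about the implementation is specific to them.

## Known limitations

* Length is contour-based; skeleton/medial-axis estimation, root diameter,
  branching and touching-root disentanglement are out of scope.
* The half-perimeter rule overestimates wide roots by ≈ width/r and
  continuous arc lengths by the chain-code factor above; both biases are
  documented rather than corrected, keeping the measured number an exact
  function of the mask.
* mAP is reported at a single IoU threshold (0.5) for masks; no
  mAP@[.5:.95] or box-IoU evaluation.
* The numpy training stack is for desk-scale validation; it makes no
  performance claims and no GPU path exists.
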