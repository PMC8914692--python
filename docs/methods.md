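# Methods

`sleepose` implements a contact-free sleep-posture monitoring pipeline
for single-camera (RGB or infrared) overnight video: sample-based
background subtraction gates a two-stage multi-task detector that
localizes the sleeper's head and upper body and classifies each into
four poses; per-frame results are merged into a posture timeline from
which four posture-based sleep-quality indicators and a circular night
synopsis are computed.  This note records the models, the parameters
that matter, the numerical choices, and what the synthetic experiments
do and do not demonstrate.

## Motion detection (ViBe)

Each pixel x keeps a set of N past intensities M(x) = {v1..vN}.  A
pixel of the current frame is **background** when at least `#min`
stored samples lie strictly within intensity radius R of its current
value v(x), i.e. `#{S_R(v(x)) ∩ M(x)} ≥ #min`, and foreground
otherwise.  The model is seeded from the first frame: every pixel's N
samples are drawn from its 8-neighborhood (edge-replicated at borders).
A background-classified pixel is selected for update with probability
1/φ; a selected pixel overwrites one uniformly random sample of its own
set with v(x) and — with the spatial-diffusion rule enabled — one
random sample of a uniformly random 8-neighbor.

Defaults: N = 20, R = 20, `#min` = 2, φ = 16, diffusion on.  φ = 16 is
the printed one-in-sixteen update odds; N, R and `#min` are the
canonical settings of the sample-based background-subtraction
literature, and all are overridable.  Distance is the absolute
intensity difference (the per-pixel value is scalar luminance; RGB
frames are collapsed with ITU-R 601 weights before modeling, so day
and night camera modes are handled uniformly).

Two consequences of the conservative update are worth knowing.  A
*ghost* (a region whose object has left, so the current pixel values
are genuine background but the model is stale) is reabsorbed by the
diffusion rule, from the edges inward, on a timescale of roughly
`φ × region-radius` frames; without diffusion it persists indefinitely
(both behaviors are property-tested).  A *newly appeared static object*
is never absorbed, because foreground values are never inserted into
any model — for a sleeper this is the desired behavior (the subject was
present at initialization and only transiently creates foreground), but
it means post-movement foreground decays over minutes, not seconds, and
motion events are correspondingly generous.

Mask cleanup is erosion then dilation with a 3×3 square element
(outside of the frame counts as background), removal of 8-connected
components below 0.1% of the frame area, then interior hole filling.
Frames whose cleaned foreground fraction reaches `trigger_fraction`
(default 2%) form motion events; events shorter than
`min_event_frames` (default 3) are dropped.

Histogram equalization (exact integer equalization onto 0–255) is
available as preprocessing for footage with varying room lighting but
is off by default: on low-dynamic-range scenes it stretches sensor
noise across the full intensity range and corrupts the background
model.  Enable it (`equalize: true`) for real night-mode recordings
with strong illumination drift.

## The multi-task detector

The network is a two-stage detector with a shared backbone and three
sibling heads.

**Backbone.**  A stride-16 feature extractor mapping a 1-channel
luminance image (scaled to roughly [-0.25, 0.75]) to a
`ceil(H/16) × ceil(W/16)` grid.  Two registered backbones honor this
contract: `tiny_test`, a four-stage conv(3×3)/ReLU/max-pool stack with
8→16→32→48 channels used for all desk-scale experiments, and
`paper_resnet50`, a randomly initialized network with the ResNet-50
bottleneck stage layout up to its 1024-channel stage.  The latter
exists to keep the backbone swappable at full scale; without pretrained
weights it offers no accuracy advantage, and downsampling is realized
with ceil-mode max pooling rather than strided convolution (there is no
batch normalization).  Input sizing follows the shortest-side-600 /
longest-side-1000 rule with aspect ratio preserved; the rule is
bypassed (`resize_enforce=False`) for small synthetic scenes.

**Proposals.**  Nine anchors per feature-map location — three areas ×
three aspect ratios (1:1, 1:2, 2:1), non-square anchors preserving the
area of their scale — are scored and regressed by a 3×3 conv (512
channels at paper scale, 128 in the tiny preset) with two sibling 1×1
convs.  Box regression uses the center-offset / log-size
parameterization `t = ((cx−cx_r)/w_r, (cy−cy_r)/h_r, ln(w/w_r),
ln(h/h_r))`.  Decoded proposals are clipped to the image, sub-pixel
degenerates dropped, the top scores kept, and greedy NMS applied at
IoU 0.7.

**Per-region heads.**  Each surviving box is max-pooled from the
feature map to a fixed grid (14×14 default, 6×6 in the tiny preset
where feature maps are only 6×6), passed through a 1×1 reduction, a
residual block, and global average pooling, then through four linear
heads: region class (head / upper-body / background, softmax), box
refinement (4 deltas per non-background class), and two independent
4-way pose heads (supine, prone, left, right).  At inference a
detection's pose is read from the pose head matching its region class,
and per-class NMS prunes duplicates (0.3 by default; 0.15 in the tiny
preset — at stride 16 a 20-px head spans barely more than one feature
cell, so near-duplicate boxes carry almost identical pooled features
and must be separated geometrically).

**Losses.**  With y one-hot and ŷ softmax scores: region
classification is categorical cross-entropy averaged over sampled
regions; the head-pose and body-pose cross-entropies are averaged only
over regions whose assigned class matches (zero when none); box
regression is smooth L1 (0.5d² for |d|<1 else |d|−0.5) summed over the
four coordinates of matched foreground regions.  The total is the
weighted sum `L = λ_class L_class + λ_head L_head + λ_body L_body +
λ_box L_box` with all λ defaulting to 1.  The surrounding RPN trains
with its own objectness cross-entropy and smooth-L1 loss, added to the
total with unit weight.

**Target assignment.**  RPN anchors: positive at IoU ≥ 0.7, negative at
≤ 0.3, in-between ignored, and every ground-truth box claims its
best-IoU anchor regardless.  Second stage: foreground at IoU ≥ 0.5,
background below.  Per image up to 64 regions are sampled (≤ 50%
foreground; 20 in the tiny preset).  During training the RoI pool is
the RPN proposals plus the ground-truth boxes plus jittered copies of
the ground truth at three perturbation magnitudes (10%, 25%, 50% of the
box size): the mild jitters supply well-overlapping foreground that
calibrates the box regressor, the strong ones land below the
foreground threshold and serve as hard negatives — without them the
classifier, which at stride 16 sees nearly identical pooled features
for any box near the object, assigns confident scores to badly
localized duplicates.

**Optimization.**  Adam end to end, gradients hand-derived (the
package has no autodiff dependency).  Proposal box coordinates are
treated as constants — gradients reach the RPN through its own losses,
not through the pooled windows — the standard approximate joint
training scheme.  Validation-based early stopping monitors the total
loss on the validation split (computed deterministically, without RoI
sampling) and restores the best-validation parameters; default
patience 5.  The default learning rate is 1e-5, the printed setting
for a pretrained full-scale backbone.  The desk-scale preset trains a
randomly initialized tiny network and uses 2e-3 with a ×0.3 step at
epoch 7 and at most 12 epochs — at desk scale the printed rate barely
moves a random initialization.  All randomness (weight init, shuffling,
RoI/anchor sampling, jitter) flows from one integer seed; two runs with
the same seed produce identical loss histories.

**Checkpoints** are `.npz` archives carrying the full configuration,
the class orderings (region: head, upper_body, background; pose:
supine, prone, left, right) and every parameter array, so a checkpoint
reloads without external context.

## Data augmentation

Optional training augmentation rotates images by a uniform angle in
[0°, 15°], replaces each box by the axis-aligned bounding box of its
rotated corners (clipped to the frame; samples whose boxes leave the
frame are rejected and logged), and jitters contrast (×0.9–1.1 around
mid-gray) and brightness (±10).  Labels are unchanged.

## Evaluation

Detections are matched per class, greedily in descending score, to the
highest-IoU unmatched ground-truth box at a fixed threshold (default
IoU 0.5; each ground truth matches at most once, so duplicates are
false positives).  Average precision integrates the precision envelope
over all recall points (all-point interpolation, not the 11-point
variant; ties broken by input order), and mAP averages the head and
upper-body APs.  Pose accuracy is the percentage of images whose
best-scoring detection of a region carries the correct pose label,
counting images without such a detection as errors; 4×4 confusion
matrices (rows = truth) accompany it.

## Sleep analysis

Per-frame (head pose, body pose) labels — frames without a detection
inherit the previous labels — are smoothed with a centered 5-frame
majority vote (ties keep the previous label) and merged into maximal
constant episodes.  Motion events longer than 5 minutes mark their
frames as wake.  From the timeline:

| indicator | definition | unit |
|---|---|---|
| posture shifts | body-pose transitions between consecutive episodes, per hour of span | 1/h |
| long postures | episodes strictly longer than 15 min, per hour | 1/h |
| average duration | mean episode duration | min |
| sleep efficiency | 100 × (span − turning time) / span | % |

Turning time is the union of motion intervals of at least 10 s,
clipped to the timeline span.  Head-pose transitions are reported in
the timeline but do not count toward the shift indicator (a single
shift series is reported; the choice is switchable).  The synopsis is
a 12-hour polar dial, one arc per episode with angular extent
proportional to duration, colored by body pose, grey for wake.

## Synthetic data

No overnight recordings can ship with the package, so every stage is
exercised on generated scenes with exact ground truth.  A scene is a
grayscale image with one rectangular body blob (aspect 0.62) and an
adjacent inscribed-ellipse head; pose is encoded as a bright marker
strip on the matching side of each blob (top/bottom/left/right for
supine/prone/left/right), occlusion as a translucent rectangle blended
over the lower body fraction (blanket stand-in), illumination
variation as a global brightness offset, and sensor noise as additive
Gaussian noise.  Defaults: 256×256 images with 28–40 px heads;
desk-scale preset 96×96 with 18–24 px heads and 40–54 px bodies,
background 60, blob intensities 140/175, markers 215/245, occlusion
fraction 0.3, noise σ 4, jitter ±10.  Annotated boxes equal the
rendered geometry exactly.  Datasets cycle the pose class sample by
sample (head and body share a sample's pose, as they usually do in
real sleep), so contiguous split slices stay class-balanced and
stratified.  Night videos hold each episode's geometry fixed and slide
the blobs between episode geometries over a transition window,
creating genuine motion at posture changes.

What passing on this data shows: the detector can jointly localize two
regions and read out a 4-way appearance cue under occlusion, noise and
illumination shifts; the losses, assignment, NMS and metrics are
correct; the pipeline glue preserves counts and timing.  What it does
not show: robustness to real human appearance variation, deformable
blankets, camera angle, or IR noise statistics — the synthetic
occlusion is a uniform rectangle and the pose cue is far cleaner than
a real silhouette, so the reported desk-scale accuracies are
machine-correctness checks, not clinical performance claims.

## Problem sizes and numerical choices

Desk-scale experiments use 500 scenes (400 train / 50 validation / 50
test), three independent seeds, and the tiny backbone — sized so a
full three-seed study trains in minutes on one CPU core.  The
memorization check (re-evaluating a fitted model on its own training
scenes) plateaus slightly below perfect mAP: at stride 16 an
occasional disjoint duplicate of a small head survives, which is the
same feature-ambiguity limit that motivates the tight inference NMS;
the binding quality gate is the held-out criterion (median mAP and
pose accuracy ≥ 0.90), which the study conditions meet.

Numerics: float64 throughout; cross-entropy clamps zero scores at
machine epsilon (logged); NMS and AP break score ties by input order;
max-pool ceil-mode pads with −inf; RoI windows cover at least one
feature cell, with a logged nearest-cell fallback for boxes that
project outside the map; colliding neighbor writes in the vectorized
ViBe update resolve last-write-wins, which is unbiased on average.

## Known limitations

Single subject only; no shadow or camera-motion modeling; the
`paper_resnet50` backbone is a structural stand-in without pretrained
weights, so full-scale accuracy is out of reach by design; motion
events are generous around posture changes (see the static-object note
above), so posture-based sleep efficiency is conservative; wake
detection is a motion-duration heuristic, not sleep staging.
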