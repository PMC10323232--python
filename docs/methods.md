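# Methods

`epievents` detects cellular events — primarily cell extrusions, optionally
cell divisions and sensory organ precursors (SOPs) — in 2D time-lapse
fluorescence movies of epithelia whose cell contours are labelled (e.g.
E-cadherin), without segmenting or tracking cells.  This note records the
model, its assumptions, the tunable parameters, and the design choices made
where the design was genuinely open.

## The reference scale

Movies from different set-ups are resampled to a fixed reference
calibration before anything else: **0.275 µm/pixel and 5 min/frame**, at
which a typical cell is ~25 px across and an extrusion takes 4–5 frames.
Two ways to compute the resampling factors are provided:

* from absolute calibration — `spatial_factor = pixel_size / 0.275`,
  `temporal_factor = frame_interval / 5`; multiplying a movie's shape and
  point coordinates by these factors lands them on the reference scale;
* from cellular features (for tissues where absolute scales mislead, e.g.
  squamous larval cells ~80 px across with ~10-frame extrusions) —
  `spatial_factor = 25 / observed_cell_diameter`,
  `temporal_factor = 4.5 / observed_extrusion_frames`, where 4.5 frames is
  the midpoint of the typical 4-to-5-frame extrusion duration.

Spatial resampling is bilinear (with anti-aliasing when shrinking); the
interpolation kernel is our choice — the procedure itself only requires a
size-preserving intensity rescale.  Temporal resampling picks nearest
frames and never blends across time, matching how movie frame-rate
augmentation is done (frame decimation) and avoiding invented intermediate
frames.  Output shapes round half away from zero, which is deterministic
across platforms.  Point annotations map with the same factors and the
same rounding.  Note that integer rounding makes the point round trip exact
to 1 px only for factors ≥ 0.5; below that, several original pixels
collapse onto one rescaled pixel and the inverse carries up to
`0.5/factor + 0.5` px of quantisation error.

## The window classifier

The unit of classification is a **10-frame sequence of 45×45-px crops**
(50 min, two-to-three cells).  Each frame passes through four blocks of
[3×3 same-padded convolution → batch normalisation → ReLU], with 8, 16, 32
and 64 filters; blocks 1–3 end in a 2×2 max pool (spatial side 45 → 22 →
11 → 5, by floor division) and the fourth block's pooling step is a global
max pool that collapses the remaining 5×5 grid into a 64-vector.  The
resulting 10×64 sequence feeds a GRU (64 units); its final state passes
through dropout (rate 0.5), a 32-unit dense layer and a softmax over the
classes `(none, extrusion[, sop[, division]])` — 2, 3 or 4 classes, fixed
in that order.  Windows are min–max normalised to [0, 1] individually
before entering the network.

The network, its training loop and persistence are implemented directly in
NumPy (`epievents.nn`): im2col-based convolutions, analytic backward passes
for every layer (verified against finite differences in the test suite),
Adam (learning rate 1e-3, halved at 70% of the epochs), and categorical
cross-entropy.  Inference is deterministic: batch normalisation uses
running statistics and dropout is inactive.

Hyperparameters the architecture description leaves open, and the choices
made: 3×3 kernels with same-size padding (forced by the printed 45→22→11→5
chain, which pools without convolutional shrinkage); GRU hidden size 64;
one 32-unit dense hidden layer; dropout 0.5; batch normalisation before
the ReLU; Adam with batch size 32 (16 in the scaled-down tests).  All are
recorded in the model directory's sidecar for reproducibility.

## Training data

Windows are sampled from annotated movies at the reference scale:

* **event windows** — centred on each annotation, temporally 5 frames
  before the event frame and 4 after (the constriction dynamics precede
  termination, so the extra frame goes before), displaced by a uniform
  random jitter of **±11 px and ±2 frames**.  The jitter is deliberately
  half the inference stride: the sliding-window grid places events up to
  11 px / 2 frames from a window centre, and a classifier trained only
  with smaller offsets scores off-centre events low, which collapses the
  assembled probability right where the allocation patch needs it.
* **control windows** — rejection-sampled positions whose full 45×45×10
  extent contains no annotation of any class; centres are drawn so the
  window lies fully inside the movie, matching inference-time windows
  (which are never zero-padded).
* **aftermath negatives** — windows at each annotation's location, jittered
  like event windows, at times from 8 frames after the event to the end of
  the movie, labelled "none".  After an extrusion the neighbours stay met
  at a junction vertex, after a division the daughter interface persists;
  without explicit negatives there, a classifier trained on few events
  keys on the remnant morphology instead of the constriction dynamics and
  re-fires on every later frame.
* **halo negatives** — windows in which the event is visible but
  off-centre (16-32 px from the annotation, at the event's time), labelled
  "none".  These force the classifier to answer "is there an event near
  the centre", not "is there an event somewhere in the window"; without
  them every tile neighbouring an event fires too and each event spawns
  detached duplicate detections one tile away.
* classes not known to the model (e.g. divisions for a 2-class network)
  are kept as training windows but labelled "none", so lookalike events
  are rejected rather than unseen.

With `balance` set (the default), every epoch trains on a fresh balanced
subsample — each class downsampled to the minimum class count — so epochs
are class-balanced while the network still sees the whole negative pool
over the run.  The window pool is split 75/25 into train/validation,
stratified by class, and the weights of the best-validation-loss epoch are
kept at the end of training (checkpoint selection).  Window augmentation (applied on the fly,
`augmentation_factor − 1` copies per window per epoch) combines small
spatiotemporal shifts, additive Gaussian noise (2% of the window's dynamic
range), a white or black square occluder, and a multiplicative illumination
change on all frames or one frame.  Movie-level augmentation for
high-frame-rate acquisitions (2× temporal decimation with a one-frame
offset, doubling the movie count) is available as
`augment_movie_temporal`.

## Whole-movie detection

The movie is covered by windows with 50% spatial overlap (stride 22 px)
and 10-frame sequences every 2 frames; an extra flush-with-edge origin per
axis keeps borders covered.  Each window's class probability is allocated
uniformly into a **5-frame × 22×22-px patch** around the window centre
(half-open spans, the extra voxel after the centre), and each voxel's final
value is the mean over all patches covering it — one probability map per
event class, averaged voxel-wise across networks when two independently
trained networks are ensembled.  Assembly is exact: the test suite checks
it against a brute-force per-voxel mean.

Post-processing converts a map to point events:

1. threshold at **180** on the 0–255 display scale (voxel kept iff
   `round(p·255) ≥ 180`);
2. 26-connected components in (t, y, x) — an extrusion blob drifts a little
   between frames and face-only connectivity would fragment it — discarding
   volumes under **800 voxels** (reference-scale voxels, so the filter is
   scale-invariant).  Fragments separated by gaps up to half a tile
   (2 frames, 11 px) are bridged into one component before labelling: a
   single event's volume can fragment across adjacent allocation tiles
   when individual windows dip under the threshold, and sub-cell-scale
   gaps never separate real events;
3. watershed separation of merged blobs on the inverted smoothed map
   (σ = 1 frame, 2 px), seeded at local maxima at least **one cell
   diameter (25 px) apart spatially** — events closer than a cell cannot
   be distinct, and smaller separations split one event's volume into
   duplicate detections.  The temporal seed separation is the component's
   whole span, because a cell extrudes or divides once — one connected
   volume cannot hold two events at the same place at different times, so
   splitting is spatial.  Fragments below the volume threshold are merged
   into their largest neighbouring fragment, conserving voxels;
4. each surviving component becomes one point event at its rounded
   centroid, carrying the component's peak probability, mapped back to
   original-movie coordinates.

Raising either threshold can only remove detections (a property test
enforces this monotonicity).

## Evaluation

A detection and an annotation match when their xy Euclidean distance is
≤ **15 px** (≈ 4.12 µm, one cell radius) and their frame distance ≤ **4
frames** (± 20 min); both tolerances scale for other tissues (e.g. 50 px /
8 frames for larval cells).  Matching is a one-to-one optimal assignment
on the candidate graph — maximum number of matches first, minimum total
spatial distance (ties by temporal distance) second, via the Hungarian
algorithm.  A greedy nearest-first assignment was considered and rejected:
it is provably not maximum-cardinality (the exhaustive-oracle test found
counterexamples at realistic densities), whereas the optimal assignment is
deterministic and matches exhaustive enumeration exactly.

Reported metrics: precision TP/(TP+FP), recall TP/(TP+FN),
F1 = TP/(TP+(FP+FN)/2) (identical to the harmonic mean 2PR/(P+R)).  When a
denominator is zero, the metric is 0 unless there are neither predictions
nor annotations (then 1).  Accuracy (TP+TN)/total is reported only for
window-level classification, where true negatives exist.  Supporting
diagnostics: the 2D histogram of spatial × temporal distances (1 px × 1
frame bins) with the fraction inside the tolerance box, cumulative event
counts over time with the mean absolute per-10-min-bin difference, and
uniform random ROI subsets for manual review of unannotated movies (with
`precision_from_verdicts` ingesting the verdicts).

## Reinforcement and ensembling

`reinforce` runs detection on annotated movies, collects detections that
match no annotation, extracts windows at their coordinates labelled
"none", appends them to the training set and retrains — repeated
`reinforcement_iterations` times (default 5), stopping early if a round
finds no false positives.  `classify_movie` accepts several networks and
averages their maps voxel-wise ("2net" ensembling), exploiting training
stochasticity to suppress single-network false positives.

## The synthetic data generator

The generator exists so the whole pipeline is trainable and testable at
desk scale with exact ground truth.  A tissue is a Lloyd-relaxed Voronoi
tessellation (3 relaxation iterations over mirrored seeds, so boundary
cells are bounded); cells share vertices, so deforming one cell deforms
its neighbours.  Junctions are rendered as anti-aliased polygon edges,
blurred (σ 0.8 px) to a finite width, at intensity 200 over background 20,
plus Gaussian noise σ 5 — a high signal-to-noise setting.  Vertices take a
small clipped random walk between frames (junction fluctuation).  The
default field is 256×256 px × 60 frames with ~134 cells of mean diameter
25 px, carrying 12 extrusions and 8 divisions; these defaults are the
conditions under which the scaled-down end-to-end tests run.

Event animations:

* **extrusion** — the cell's vertices move linearly toward its centroid
  over 4–5 frames, pulling neighbour junctions into a rosette; at the
  closure frame (the annotated point) the ring merges into a single
  higher-degree vertex, which persists — as after rosette resolution
  in vivo — with no residual small cell;
* **division** — the cell rounds slightly for two frames, then a bright
  furrow chord appears through the centroid (the annotated frame) and
  persists as the daughter interface;
* **SOP** — a cell statically shrunk to 45% linear scale for the whole
  movie, the classic extrusion confuser;
* **confuser** — a transient constriction to 50% area that relaxes back,
  planted *without* an annotation, for reinforcement experiments.

Events are placed on non-adjacent cells, pairwise separated by at least
one window in space (48 px) or time (12 frames), inside a 30-px margin.
Ground truth is exact by construction; a leave-one-out nearest-centroid
classifier on the event cells' area trajectories separates extrusions from
divisions with accuracy > 0.9, confirming the learning task is well-posed.

What the generator does **not** emulate: photobleaching, tissue flows,
curvature-projection artefacts, variable junction brightness between
cells, cell neighbour exchanges (T1 transitions), and the morphological
diversity of real extrusions (anisotropic constriction, junction loss).
Passing the synthetic end-to-end tests therefore shows the pipeline's
machinery is correct and the architecture can learn constriction dynamics
from few examples; it does not certify detection quality on real tissue,
which depends on training data breadth in ways only real annotated movies
probe.

## Scaled-down problem sizes

The self-contained end-to-end experiments (tests and the acceptance
script) use a reduced setting chosen to exercise every stage at desk
scale: 256×256 px × 60-frame movies, a 2-class network with 4 base filters
(instead of 8), 20 jittered samples per annotated event, batch size 16 and
10 epochs (instead of 40); training two movies and detecting on a third
held-out movie takes a few minutes on one CPU.  The reinforcement
experiment uses 12 extrusions, 8 divisions and 6 planted confusers per
movie with a single reinforcement round.

## Known limitations

* Training at the published full scale (thousands of events, 40 epochs)
  is computationally heavy in pure NumPy; the implementation is exact but
  not GPU-accelerated.
* The window-level validation split is drawn from the same movies as the
  training windows, so validation accuracy overstates cross-movie
  generalisation (a caveat inherited from the training protocol).
* Detection variance across training seeds is substantial in the
  scaled-down setting — two-network ensembling reduces it at twice the
  inference cost.
* Anisotropic pixel sizes, 3D (z) stacks and drift correction are out of
  scope; movies are assumed single-channel with bright junctions on dark
  background.
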