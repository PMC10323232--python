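# epievents

Segmentation-free detection of cellular events — cell extrusions, and
optionally cell divisions and sensory organ precursors (SOPs) — in 2D
time-lapse fluorescence movies of epithelia with labelled cell contours
(e.g. E-cadherin).  Instead of segmenting and tracking every cell, the
pipeline slides overlapping spatiotemporal windows over the movie,
classifies each 10-frame 45×45-px sequence with a convolutional-recurrent
network, assembles the window scores into per-class probability maps, and
converts high-probability volumes into point detections with a position
and a frame.  It is aimed at quantitative studies of epithelial cell death
and remodelling, where thousands of events per movie make manual
annotation the bottleneck.

## The method in brief

Movies are first resampled to a fixed reference scale (0.275 µm/px,
5 min/frame; ~25-px cells, 4–5-frame extrusions).  Each window
`x ∈ R^(10×45×45)` is scored by a classifier: per frame, four blocks of
[3×3 conv → batch norm → ReLU] with 8→16→32→64 filters and 2×2 max pools
shrink the side 45→22→11→5, a final max pool collapses the 5×5 grid to a
64-vector, and the 10×64 sequence feeds a GRU and dense head ending in a
softmax over classes `(none, extrusion[, sop[, division]])`.  Windows are
enumerated with 50% spatial overlap (stride 22 px) every 2 frames; each
window's class probability is spread over a 5×22×22 patch at its centre
and voxels average all covering patches.  The map is thresholded at
180/255, 26-connected volumes under 800 voxels are discarded, watershed
splits merged blobs, and each surviving volume becomes one event at its
centroid.  Detections match annotations when within 15 px and 4 frames;
precision TP/(TP+FP), recall TP/(TP+FN) and F1 = TP/(TP+(FP+FN)/2) are
reported.  Training utilities include class balancing, on-the-fly
augmentation, false-positive reinforcement and two-network map averaging.
`docs/methods.md` documents every parameter and design choice.

The network and its training loop are implemented in NumPy
(`epievents.nn`) with analytic gradients — no deep-learning framework is
required.

## A worked example

The package ships a synthetic-epithelium generator with exact ground
truth, so everything below runs offline in a few minutes on one CPU
(scripts in `examples/`):

```
python examples/01_generate_synthetic_data.py
python examples/02_train_classifier.py
python examples/03_detect_events.py
python examples/04_evaluate_detections.py
```

`02` trains a reduced 2-class model (4 base filters, 10 epochs) on two
synthetic movies (12 extrusions + 8 divisions each) and prints the
training curve, ending with

```
epoch  loss   acc    val_loss  val_acc
    9  0.137  0.951  0.127     0.953
```

`03` detects extrusions on an unseen movie ("detected 28 extrusion
candidates; movie has 12 planted extrusions") and `04` scores them
against the planted ground truth:

```
TP=11 FP=17 FN=1
precision=0.39 recall=0.92 F1=0.55
92% of matched annotations lie inside the 15 px / 4 frame tolerance box
mean |cumulative count difference| per 10-min bin: 6.41 events
```

i.e. nearly all planted extrusions are recovered within one cell radius
and ±20 min of their true position, with residual false positives from
event-like static structures.  Detection precision varies considerably
with the training seed at this tiny training-set size (one movie pair);
the acceptance benchmark below, which uses its own seed ladder, averages
precision ≈ 0.6-0.7 at recall ≈ 0.9.

There is also a thin CLI mirroring the library:

```
epievents synth --out-dir data --n-movies 3
epievents train --movie data/movie_000.tif --rois data/movie_000_rois.zip \
    --pixel-size 0.275 --frame-interval 5 --out-dir model
epievents detect data/movie_002.tif --model model \
    --pixel-size 0.275 --frame-interval 5 --out-dir detections
epievents evaluate detections/events.zip data/movie_002_rois.zip
```

Calibration flags are mandatory: the pipeline never guesses physical
scales from file metadata.

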