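"""High-level workflows: training-set assembly, training, reinforcement.

These glue the modules into the user-facing operations: build labelled
windows from annotated movies, train or retrain a classifier, and run the
reinforcement loop in which false-positive detections are folded back into
the training set as "no event" examples.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .errors import InvalidInputError
from .evaluation import MatchConfig, match_events
from .io import RunConfig
from .nn.model import (
    NetworkSpec,
    WindowClassifier,
    build_network,
    train_network,
)
from .postprocess import detect_events
from .scaling import (
    AnnotationSet,
    CLASS_ORDER,
    EventClass,
    EventPoint,
    Movie,
    ReferenceScale,
    compute_scale_factors,
    map_points,
    rescale_movie_to_reference,
)
from .windows import (
    TrainingSet,
    extract_window,
    sample_control_windows,
    sample_event_windows,
    split_train_validation,
)

__all__ = [
    "build_training_set",
    "train_pipeline",
    "retrain_pipeline",
    "reinforce",
]


def build_training_set(
    pairs: Sequence[tuple],
    config: RunConfig,
    n_classes: int = 2,
    rng: Optional[np.random.Generator] = None,
    ref: ReferenceScale = ReferenceScale(),
    samples_per_event: int = 1,
    controls_per_event: float = 0.5,
    aftermath_negatives_per_event: int = 12,
    halo_negatives_per_event: int = 12,
) -> TrainingSet:
    """Labelled windows from ``(Movie, AnnotationSet)`` pairs.

    Movies and annotations are rescaled to the reference scale first.  Event
    classes outside the ``n_classes`` ordering (e.g. divisions for a 2-class
    extrusion-vs-nothing model) are kept as windows but labelled "none", so
    the classifier learns to reject them.  Controls are rejection-sampled
    away from all annotations; in addition, "aftermath" negatives are taken
    at each annotation's location from 8 frames after the event onwards,
    where the static remnant (resolved rosette, daughter interface) persists — without them a
    classifier keys on the remnant morphology instead of the constriction
    dynamics and fires on every post-event frame; "halo" negatives show
    the event off-centre so the classifier localises it.  Class balancing
    happens per epoch inside :func:`train_network`; the result carries a
    stratified 75/25 train/validation split over the full pool.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    keep = set(CLASS_ORDER[:n_classes])
    overrides = {c: EventClass.NONE for c in CLASS_ORDER if c not in keep}
    windows = []
    for k, (movie, annotations) in enumerate(pairs):
        sf, tf = compute_scale_factors(
            (movie.pixel_size, movie.frame_interval), ref
        )
        movie_ref = rescale_movie_to_reference(movie, ref)
        annot_ref = map_points(annotations, sf, tf, "to_reference")
        event_windows = []
        for _ in range(samples_per_event):
            event_windows.extend(
                sample_event_windows(
                    movie_ref, annot_ref,
                    jitter_space=config.jitter_space,
                    jitter_time=config.jitter_time,
                    rng=rng, window_shape=config.window_shape,
                    movie_id=f"movie{k}", label_overrides=overrides,
                )
            )
        n_controls = int(round(controls_per_event * len(event_windows)))
        windows.extend(event_windows)
        windows.extend(
            sample_control_windows(
                movie_ref, annot_ref, n_controls, rng=rng,
                window_shape=config.window_shape, movie_id=f"movie{k}",
                interior=True,
            )
        )
        nt, ny, nx = movie_ref.frames.shape
        for e in annot_ref:
            # "halo" negatives: the event visible but off-centre, beyond the
            # ±11-px offsets event windows cover.  The classifier must learn
            # "event near the centre", not "event somewhere in the window",
            # or every neighbouring tile fires too and each event spawns
            # detached duplicate detections one tile away.
            for _ in range(halo_negatives_per_event):
                dx, dy = 0, 0
                while max(abs(dx), abs(dy)) < 16:
                    dx = int(rng.integers(-32, 33))
                    dy = int(rng.integers(-32, 33))
                cx = int(np.clip(e.x + dx, 0, nx - 1))
                cy = int(np.clip(e.y + dy, 0, ny - 1))
                ct = int(np.clip(e.t + rng.integers(-2, 3), 0, nt - 1))
                windows.append(
                    extract_window(
                        movie_ref,
                        EventPoint(cx, cy, ct, EventClass.NONE),
                        config.window_shape, movie_id=f"movie{k}",
                    )
                )
            if e.t + 8 >= nt:
                continue
            # spread over the remnant's whole lifetime, not just right after,
            # with the same ±half-stride offsets the detection grid produces
            for _ in range(aftermath_negatives_per_event):
                t_after = int(rng.integers(e.t + 8, nt))
                j = config.jitter_space
                cx = int(np.clip(e.x + rng.integers(-j, j + 1), 0, nx - 1))
                cy = int(np.clip(e.y + rng.integers(-j, j + 1), 0, ny - 1))
                windows.append(
                    extract_window(
                        movie_ref,
                        EventPoint(cx, cy, t_after, EventClass.NONE),
                        config.window_shape, movie_id=f"movie{k}",
                    )
                )
    # class balancing happens per epoch inside train_network (fresh balanced
    # subsample each epoch), so the full pool is kept here
    return split_train_validation(windows, config.validation_fraction, rng=rng)


def train_pipeline(
    pairs: Sequence[tuple],
    config: RunConfig,
    n_classes: int = 2,
    spec: Optional[NetworkSpec] = None,
    seed: Optional[int] = None,
    samples_per_event: int = 1,
) -> tuple:
    """Build windows, build a network and train it; returns (net, history)."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    training_set = build_training_set(
        pairs, config, n_classes=n_classes, rng=rng,
        samples_per_event=samples_per_event,
    )
    if spec is None:
        spec = NetworkSpec(
            base_filters=config.base_filters, n_classes=n_classes,
            window_shape=config.window_shape,
        )
    net = build_network(spec, seed=seed)
    return train_network(net, training_set, config, rng_seed=seed)


def retrain_pipeline(
    net: WindowClassifier,
    pairs: Sequence[tuple],
    config: RunConfig,
    seed: Optional[int] = None,
    samples_per_event: int = 1,
) -> tuple:
    """Continue training an existing network on new annotated movies.

    The class count is fixed by the loaded network; annotated classes it
    does not know are folded into "none".
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    training_set = build_training_set(
        pairs, config, n_classes=net.spec.n_classes, rng=rng,
        samples_per_event=samples_per_event,
    )
    return train_network(net, training_set, config, rng_seed=seed)


def reinforce(
    net: WindowClassifier,
    movies: Sequence[Movie],
    annotations: Sequence[AnnotationSet],
    config: RunConfig,
    training_set: Optional[TrainingSet] = None,
    seed: Optional[int] = None,
    ref: ReferenceScale = ReferenceScale(),
    retrain_epochs: Optional[int] = None,
) -> tuple:
    """Reinforcement loop: force recurring false positives toward "none".

    Each round runs detection on the given movies, collects detections that
    match no annotation under the standard tolerances, extracts windows at
    their reference-scale coordinates labelled "none", appends them to the
    training set and retrains.  Runs ``config.reinforcement_iterations``
    rounds (stops early, with a log notice, when a round finds no false
    positives).  ``retrain_epochs`` bounds the per-round retraining
    (default: the full ``config.epochs`` schedule) — continuing from
    trained weights needs far fewer passes than the initial training.
    Returns ``(net, log)`` with one log record per round.
    """
    if len(movies) != len(annotations):
        raise InvalidInputError("one annotation set per movie required")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    if training_set is None:
        training_set = build_training_set(
            list(zip(movies, annotations)), config,
            n_classes=net.spec.n_classes, rng=rng,
        )
    match_cfg = MatchConfig(config.match_spatial_tol, config.match_temporal_tol)
    log = []
    for round_idx in range(int(config.reinforcement_iterations)):
        fp_windows = []
        n_fp = 0
        for movie, annot in zip(movies, annotations):
            predicted, _ = detect_events(net, movie, config, ref=ref)
            sf, tf = compute_scale_factors(
                (movie.pixel_size, movie.frame_interval), ref
            )
            movie_ref = rescale_movie_to_reference(movie, ref)
            for cls in net.spec.class_order:
                if cls is EventClass.NONE:
                    continue
                preds_c = predicted.of_class(cls)
                annots_c = annot.of_class(cls)
                counts, pairs_m = match_events(
                    map_points(preds_c, sf, tf, "to_reference"),
                    map_points(annots_c, sf, tf, "to_reference"),
                    match_cfg,
                )
                matched = {p[0] for p in pairs_m}
                ref_preds = map_points(preds_c, sf, tf, "to_reference")
                for i, e in enumerate(ref_preds):
                    if i in matched:
                        continue
                    n_fp += 1
                    cx = int(np.clip(e.x, 0, movie_ref.frames.shape[2] - 1))
                    cy = int(np.clip(e.y, 0, movie_ref.frames.shape[1] - 1))
                    ct = int(np.clip(e.t, 0, movie_ref.frames.shape[0] - 1))
                    w = extract_window(
                        movie_ref,
                        type(e)(x=cx, y=cy, t=ct, event_class=EventClass.NONE),
                        config.window_shape,
                    )
                    fp_windows.append(w)
        if n_fp == 0:
            log.append({"round": round_idx, "false_positives": 0,
                        "note": "no false positives; network unchanged"})
            break
        training_set.windows.extend(fp_windows)
        training_set.split = np.concatenate(
            [training_set.split, np.array(["train"] * len(fp_windows),
                                          dtype=object)]
        )
        retrain_cfg = config
        if retrain_epochs is not None:
            import dataclasses as _dc

            retrain_cfg = _dc.replace(config, epochs=int(retrain_epochs))
        train_network(net, training_set, retrain_cfg,
                      rng_seed=seed + 101 + round_idx)
        log.append({"round": round_idx, "false_positives": n_fp,
                    "windows_added": len(fp_windows)})
    return net, log
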