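"""Whole-movie inference: overlapping windows → per-voxel probability maps.

The movie (already at the reference scale) is covered by 45×45-px windows
with 50% spatial overlap (stride 22) and 10-frame sequences every 2 frames.
Each window's class probabilities are allocated uniformly into a small patch
(22×22 px × 5 frames) around the window centre, and every voxel's final
value is the mean over all patches covering it, giving one probability map
per event class ("none" gets no map).  Two independently trained networks
can be ensembled by voxel-wise averaging of their maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidInputError
from .nn.model import WindowClassifier, normalize_windows
from .scaling import EventClass, Movie

__all__ = [
    "ProbabilityMap",
    "enumerate_windows",
    "classify_movie",
    "ensemble_maps",
]


@dataclass
class ProbabilityMap:
    """Per-voxel event probabilities, one channel per (non-"none") class.

    ``values`` is ``(class, t, y, x)`` in [0, 1] at the reference scale;
    ``coverage`` counts contributing windows per voxel (zero-coverage voxels
    hold probability 0).
    """

    values: np.ndarray
    class_names: list
    coverage: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.coverage = np.asarray(self.coverage)
        if self.values.ndim != 4:
            raise InvalidInputError("values must be (class, t, y, x)")
        if self.values.shape[0] != len(self.class_names):
            raise InvalidInputError("one channel per class name required")
        if self.values.size and (
            self.values.min() < 0 or self.values.max() > 1
        ):
            raise InvalidInputError("probabilities must lie in [0, 1]")

    @property
    def shape(self) -> tuple:
        return tuple(self.values.shape)

    def channel(self, name: str) -> np.ndarray:
        return self.values[self.class_names.index(name)]


def _axis_origins(length: int, window: int, stride: int) -> list:
    """Origins at stride multiples plus a final flush-with-edge origin."""
    if length < window:
        raise InvalidInputError(
            f"axis of length {length} smaller than window {window}"
        )
    last = length - window
    origins = list(range(0, last + 1, stride))
    if origins[-1] != last:
        origins.append(last)
    return origins


def enumerate_windows(
    movie_shape: Sequence[int],
    window_shape: Sequence[int] = (10, 45, 45),
    spatial_stride: int = 22,
    temporal_stride: int = 2,
) -> list:
    """All window origins ``(t, y, x)`` covering the movie.

    Origins advance by the stride on each axis; when the stride does not land
    flush on the far edge an extra edge-aligned origin is appended so border
    voxels stay covered.
    """
    nt, ny, nx = movie_shape
    T, H, W = window_shape
    ts = _axis_origins(nt, T, temporal_stride)
    ys = _axis_origins(ny, H, spatial_stride)
    xs = _axis_origins(nx, W, spatial_stride)
    return [(t, y, x) for t in ts for y in ys for x in xs]


def _patch_slices(center: int, extent: int, limit: int) -> slice:
    """Half-open allocation span of ``extent`` voxels around ``center``.

    Even extents put the extra voxel after the centre: span
    ``[c − extent//2, c + extent − extent//2)``, clipped to [0, limit).
    """
    lo = center - extent // 2
    hi = lo + extent
    return slice(max(0, lo), min(limit, hi))


def classify_movie(
    nets,
    movie: Movie,
    config,
    batch_size: int = 64,
) -> ProbabilityMap:
    """Run the sliding-window classifier over a reference-scale movie.

    With several networks, each produces its own map and the maps are
    averaged voxel-wise (ensembling).  Results are independent of
    ``batch_size``.
    """
    if isinstance(nets, WindowClassifier):
        nets = [nets]
    if not nets:
        raise InvalidInputError("need at least one network")
    spec = nets[0].spec
    for net in nets[1:]:
        if net.spec.window_shape != spec.window_shape or (
            net.spec.n_classes != spec.n_classes
        ):
            raise InvalidInputError("ensembled networks must share one spec")
    T, H, W = spec.window_shape
    nt, ny, nx = movie.frames.shape
    origins = enumerate_windows(
        (nt, ny, nx), (T, H, W), config.spatial_stride, config.temporal_stride
    )
    pt, ph, pw = config.allocation_patch
    event_classes = [c.value for c in spec.class_order if c is not EventClass.NONE]
    class_idx = [i for i, c in enumerate(spec.class_order)
                 if c is not EventClass.NONE]

    frames = movie.frames.astype(np.float32, copy=False)
    maps = []
    coverage = None
    for net in nets:
        acc = np.zeros((len(event_classes), nt, ny, nx), dtype=np.float64)
        cnt = np.zeros((nt, ny, nx), dtype=np.int32)
        for i in range(0, len(origins), batch_size):
            chunk = origins[i : i + batch_size]
            batch = np.stack(
                [frames[t : t + T, y : y + H, x : x + W] for (t, y, x) in chunk]
            )
            probs = net.predict_proba(normalize_windows(batch))
            for (t, y, x), p in zip(chunk, probs):
                ct, cy, cx = t + T // 2, y + H // 2, x + W // 2
                st = _patch_slices(ct, pt, nt)
                sy = _patch_slices(cy, ph, ny)
                sx = _patch_slices(cx, pw, nx)
                cnt[st, sy, sx] += 1
                for k, ci in enumerate(class_idx):
                    acc[k, st, sy, sx] += p[ci]
        with np.errstate(invalid="ignore"):
            values = np.where(cnt > 0, acc / np.maximum(cnt, 1), 0.0)
        maps.append(values)
        coverage = cnt if coverage is None else coverage

    values = maps[0] if len(maps) == 1 else np.mean(maps, axis=0)
    return ProbabilityMap(values, event_classes, coverage)


def ensemble_maps(maps: Sequence[ProbabilityMap]) -> ProbabilityMap:
    """Voxel-wise arithmetic mean of probability maps of identical shape."""
    if not maps:
        raise InvalidInputError("need at least one map")
    shape = maps[0].shape
    names = maps[0].class_names
    for m in maps[1:]:
        if m.shape != shape or m.class_names != names:
            raise InvalidInputError("maps must share shape and classes")
    values = np.mean([m.values for m in maps], axis=0)
    return ProbabilityMap(values, list(names), maps[0].coverage)
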