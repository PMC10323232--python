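"""Labelled training-window generation: cropping, jitter, controls, balance,
augmentation and train/validation splitting.

A training example is a short cropped image sequence (default 10 frames of
45×45 px at the reference scale, i.e. 50 min covering two or three cells)
labelled with the event class at its centre.  Event windows are temporally
centred on the annotated frame — five frames before, the event frame, four
after — so the pre-termination constriction dynamics dominate the sequence.
Out-of-bounds voxels are zero-padded (dark background), keeping edge events
detectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import InvalidInputError, SamplingError
from .scaling import AnnotationSet, EventClass, EventPoint, Movie

__all__ = [
    "WindowSequence",
    "TrainingSet",
    "extract_window",
    "sample_event_windows",
    "sample_control_windows",
    "balance_classes",
    "augment_window",
    "augment_movie_temporal",
    "split_train_validation",
    "save_windows",
    "load_windows",
]

DEFAULT_WINDOW_SHAPE = (10, 45, 45)


@dataclass
class WindowSequence:
    """A fixed-shape ``(T, H, W)`` cropped image sequence with a class label."""

    voxels: np.ndarray
    label: EventClass = EventClass.NONE
    origin: tuple = ("", -1, -1, -1)  # (movie id, x, y, t) of the centre

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise InvalidInputError("window voxels must be (T, H, W)")
        if not np.all(np.isfinite(self.voxels)):
            raise InvalidInputError("window intensities must be finite")

    @property
    def shape(self) -> tuple:
        return tuple(self.voxels.shape)


@dataclass
class TrainingSet:
    """Windows plus a per-window train/validation flag (75/25 by default)."""

    windows: list
    split: np.ndarray  # array of "train" / "validation" strings

    def subset(self, which: str) -> list:
        return [w for w, s in zip(self.windows, self.split) if s == which]


def _crop_centered(frames: np.ndarray, x: int, y: int, t: int,
                   window_shape: Sequence[int]) -> np.ndarray:
    T, H, W = window_shape
    nt, ny, nx = frames.shape
    out = np.zeros((T, H, W), dtype=np.float32)
    # temporal span [t - T//2, t + T - T//2): 5 before, event frame, 4 after
    t0 = t - T // 2
    y0 = y - H // 2
    x0 = x - W // 2
    ts0, ts1 = max(0, t0), min(nt, t0 + T)
    ys0, ys1 = max(0, y0), min(ny, y0 + H)
    xs0, xs1 = max(0, x0), min(nx, x0 + W)
    if ts0 < ts1 and ys0 < ys1 and xs0 < xs1:
        out[ts0 - t0 : ts1 - t0, ys0 - y0 : ys1 - y0, xs0 - x0 : xs1 - x0] = (
            frames[ts0:ts1, ys0:ys1, xs0:xs1]
        )
    return out


def extract_window(
    movie: Movie,
    center: EventPoint,
    window_shape: Sequence[int] = DEFAULT_WINDOW_SHAPE,
    movie_id: str = "",
) -> WindowSequence:
    """Crop a window centred at an event point (centre pixel at index H//2).

    The temporal span is ``[t − T//2, t + T − T//2)``; voxels outside the
    movie are zero.  The centre itself must lie inside the movie.
    """
    if not movie.contains(center.x, center.y, center.t):
        raise InvalidInputError(
            f"window centre ({center.x}, {center.y}, t={center.t}) outside movie"
        )
    vox = _crop_centered(movie.frames, center.x, center.y, center.t, window_shape)
    return WindowSequence(
        vox, label=center.event_class,
        origin=(movie_id, center.x, center.y, center.t),
    )


def sample_event_windows(
    movie: Movie,
    annotations: AnnotationSet,
    jitter_space: int = 5,
    jitter_time: int = 1,
    rng: Optional[np.random.Generator] = None,
    window_shape: Sequence[int] = DEFAULT_WINDOW_SHAPE,
    movie_id: str = "",
    label_overrides: Optional[dict] = None,
) -> list:
    """One window per annotation, centre displaced by a small uniform jitter.

    The jitter (default ±5 px, ±1 frame — well below matching tolerances)
    prevents the classifier from keying on perfect centring.  Jittered
    centres are clipped to movie bounds.  ``label_overrides`` maps event
    classes to a replacement label (used to fold extra classes into "none"
    when training a reduced-class network).
    """
    if jitter_space < 0 or jitter_time < 0:
        raise InvalidInputError("jitter bounds must be >= 0")
    rng = np.random.default_rng() if rng is None else rng
    nt, ny, nx = movie.frames.shape
    windows = []
    for e in annotations:
        dx = int(rng.integers(-jitter_space, jitter_space + 1)) if jitter_space else 0
        dy = int(rng.integers(-jitter_space, jitter_space + 1)) if jitter_space else 0
        dt = int(rng.integers(-jitter_time, jitter_time + 1)) if jitter_time else 0
        cx = int(np.clip(e.x + dx, 0, nx - 1))
        cy = int(np.clip(e.y + dy, 0, ny - 1))
        ct = int(np.clip(e.t + dt, 0, nt - 1))
        label = e.event_class
        if label_overrides and label in label_overrides:
            label = label_overrides[label]
        vox = _crop_centered(movie.frames, cx, cy, ct, window_shape)
        windows.append(
            WindowSequence(vox, label=label, origin=(movie_id, cx, cy, ct))
        )
    return windows


def window_contains(center_x, center_y, center_t, window_shape, event) -> bool:
    """Does an annotation fall inside the spatiotemporal extent of a window?"""
    T, H, W = window_shape
    t0 = center_t - T // 2
    y0 = center_y - H // 2
    x0 = center_x - W // 2
    return (
        x0 <= event.x < x0 + W
        and y0 <= event.y < y0 + H
        and t0 <= event.t < t0 + T
    )


def sample_control_windows(
    movie: Movie,
    annotations: AnnotationSet,
    n: int,
    rng: Optional[np.random.Generator] = None,
    window_shape: Sequence[int] = DEFAULT_WINDOW_SHAPE,
    movie_id: str = "",
    max_attempts_per_window: int = 200,
    interior: bool = False,
) -> list:
    """Rejection-sample ``n`` event-free windows labelled ``none``.

    A candidate centre is discarded if *any* annotation of any class falls
    inside the full window extent.  With ``interior=True`` centres are drawn
    so the window lies fully inside the movie (no zero padding), matching
    the statistics of inference-time sliding windows.  Raises
    :class:`SamplingError` when the annotation density leaves too few
    admissible positions.
    """
    T, H, W = window_shape
    nt, ny, nx = movie.frames.shape
    if ny < H or nx < W or nt < 1:
        raise InvalidInputError("movie smaller than the window")
    rng = np.random.default_rng() if rng is None else rng
    events = list(annotations)
    windows = []
    attempts = 0
    budget = max_attempts_per_window * max(n, 1)
    if interior:
        lo = (T // 2, H // 2, W // 2)
        hi = (max(lo[0] + 1, nt - (T - T // 2) + 1),
              ny - (H - H // 2) + 1, nx - (W - W // 2) + 1)
    else:
        lo, hi = (0, 0, 0), (nt, ny, nx)
    while len(windows) < n:
        if attempts >= budget:
            raise SamplingError(
                f"placed {len(windows)}/{n} control windows in {budget} attempts; "
                "annotations too dense"
            )
        attempts += 1
        cx = int(rng.integers(lo[2], hi[2]))
        cy = int(rng.integers(lo[1], hi[1]))
        ct = int(rng.integers(lo[0], hi[0]))
        if any(window_contains(cx, cy, ct, window_shape, e) for e in events):
            continue
        vox = _crop_centered(movie.frames, cx, cy, ct, window_shape)
        windows.append(
            WindowSequence(vox, label=EventClass.NONE, origin=(movie_id, cx, cy, ct))
        )
    return windows


def balance_classes(
    windows: Sequence[WindowSequence],
    rng: Optional[np.random.Generator] = None,
) -> list:
    """Downsample every present class to the minimum class count.

    Kept windows are chosen uniformly at random (seeded via ``rng``); the
    original ordering of the survivors is preserved.
    """
    windows = list(windows)
    if not windows:
        return []
    rng = np.random.default_rng() if rng is None else rng
    by_class: dict = {}
    for i, w in enumerate(windows):
        by_class.setdefault(w.label, []).append(i)
    m = min(len(v) for v in by_class.values())
    keep: set = set()
    for indices in by_class.values():
        chosen = rng.choice(len(indices), size=m, replace=False)
        keep.update(indices[j] for j in chosen)
    return [w for i, w in enumerate(windows) if i in keep]


def augment_window(
    window: WindowSequence,
    rng: Optional[np.random.Generator] = None,
    max_shift: int = 2,
    max_tshift: int = 1,
    noise_sigma: float = 0.02,
    patch_prob: float = 0.5,
    patch_size: tuple = (4, 10),
    illum_range: float = 0.2,
) -> WindowSequence:
    """Randomly perturb a window; shape and label are preserved.

    Perturbations mirror acquisition variability: a small spatiotemporal
    shift, additive Gaussian noise (``noise_sigma`` as a fraction of the
    window dynamic range), a white or black square occluder, and a
    multiplicative illumination change applied to all frames or one frame.
    All strengths at zero is the identity.
    """
    rng = np.random.default_rng() if rng is None else rng
    vox = window.voxels.copy()
    T, H, W = vox.shape
    lo, hi = float(vox.min()), float(vox.max())
    dyn = hi - lo if hi > lo else 1.0

    if max_shift > 0 or max_tshift > 0:
        dt = int(rng.integers(-max_tshift, max_tshift + 1)) if max_tshift else 0
        dy = int(rng.integers(-max_shift, max_shift + 1)) if max_shift else 0
        dx = int(rng.integers(-max_shift, max_shift + 1)) if max_shift else 0
        vox = _shift_zero_fill(vox, dt, dy, dx)
    if illum_range > 0:
        gain = 1.0 + float(rng.uniform(-illum_range, illum_range))
        if rng.random() < 0.5:
            vox *= gain  # whole sequence
        else:
            vox[int(rng.integers(0, T))] *= gain  # a single frame
    if patch_prob > 0 and rng.random() < patch_prob:
        size = int(rng.integers(patch_size[0], patch_size[1] + 1))
        py = int(rng.integers(0, max(1, H - size)))
        px = int(rng.integers(0, max(1, W - size)))
        value = hi if rng.random() < 0.5 else lo
        vox[:, py : py + size, px : px + size] = value
    if noise_sigma > 0:
        vox += rng.normal(0.0, noise_sigma * dyn, size=vox.shape).astype(np.float32)
    return WindowSequence(vox.astype(np.float32), label=window.label,
                          origin=window.origin)


def _shift_zero_fill(vox: np.ndarray, dt: int, dy: int, dx: int) -> np.ndarray:
    out = np.zeros_like(vox)
    T, H, W = vox.shape
    src = []
    dst = []
    for d, n in ((dt, T), (dy, H), (dx, W)):
        if d >= 0:
            src.append(slice(0, n - d))
            dst.append(slice(d, n))
        else:
            src.append(slice(-d, n))
            dst.append(slice(0, n + d))
    out[tuple(dst)] = vox[tuple(src)]
    return out


def augment_movie_temporal(movie: Movie) -> tuple:
    """Double a movie by 2× temporal downsampling with a one-frame offset.

    Returns the even-frame and odd-frame submovies, each with a doubled frame
    interval; their frame indices partition the input.  Used to balance
    high-frame-rate acquisitions that shrink after rescaling.
    """
    if movie.n_frames < 4:
        raise InvalidInputError("need >= 4 frames for temporal augmentation")
    a = Movie(movie.frames[0::2].copy(), movie.pixel_size, movie.frame_interval * 2)
    b = Movie(movie.frames[1::2].copy(), movie.pixel_size, movie.frame_interval * 2)
    return a, b


def split_train_validation(
    windows: Sequence[WindowSequence],
    validation_fraction: float = 0.25,
    rng: Optional[np.random.Generator] = None,
) -> TrainingSet:
    """Stratified random train/validation split (default 75/25)."""
    windows = list(windows)
    rng = np.random.default_rng() if rng is None else rng
    split = np.array(["train"] * len(windows), dtype=object)
    by_class: dict = {}
    for i, w in enumerate(windows):
        by_class.setdefault(w.label, []).append(i)
    for indices in by_class.values():
        n_val = int(round(len(indices) * validation_fraction))
        chosen = rng.choice(len(indices), size=n_val, replace=False)
        for j in chosen:
            split[indices[j]] = "validation"
    return TrainingSet(windows, split)


def save_windows(windows: Sequence[WindowSequence], out_dir) -> Path:
    """Persist windows as TIFF stacks in class-named folders plus an index CSV."""
    out_dir = Path(out_dir)
    rows = []
    counters: dict = {}
    for w in windows:
        cls = w.label.value
        k = counters.get(cls, 0)
        counters[cls] = k + 1
        sub = out_dir / cls
        sub.mkdir(parents=True, exist_ok=True)
        fname = f"{cls}_{k:05d}.tif"
        tifffile.imwrite(str(sub / fname), w.voxels.astype(np.float32),
                         photometric="minisblack")
        rows.append(
            {
                "file": f"{cls}/{fname}",
                "label": cls,
                "movie_id": w.origin[0],
                "x": w.origin[1],
                "y": w.origin[2],
                "t": w.origin[3],
            }
        )
    index = out_dir / "index.csv"
    pd.DataFrame(rows).to_csv(index, index=False)
    return index


def load_windows(out_dir) -> list:
    """Load a window folder written by :func:`save_windows`."""
    out_dir = Path(out_dir)
    index = pd.read_csv(out_dir / "index.csv")
    windows = []
    for _, row in index.iterrows():
        vox = tifffile.imread(str(out_dir / row["file"]))
        windows.append(
            WindowSequence(
                vox,
                label=EventClass(row["label"]),
                origin=(str(row["movie_id"]), int(row["x"]), int(row["y"]),
                        int(row["t"])),
            )
        )
    return windows
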