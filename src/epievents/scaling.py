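"""Domain types and rescaling to/from the reference spatiotemporal scale.

Every movie is resampled to a fixed reference calibration (0.275 µm/pixel,
5 min/frame — roughly 25-pixel cells and 4-5-frame extrusions) before window
classification, so a single trained network serves movies acquired at any
resolution.  Axis order is ``(t, y, x)`` throughout; coordinates are 0-based;
``t`` is a frame index and is converted to minutes only at reporting
boundaries.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

from .errors import InvalidInputError

__all__ = [
    "Movie",
    "ReferenceScale",
    "EventClass",
    "EventPoint",
    "AnnotationSet",
    "round_half_away",
    "compute_scale_factors",
    "scale_factors_from_cell_features",
    "rescale_movie_to_reference",
    "rescale_movie",
    "map_points",
]


def round_half_away(x):
    """Round to nearest integer, halves away from zero (platform stable)."""
    arr = np.asarray(x, dtype=float)
    out = np.sign(arr) * np.floor(np.abs(arr) + 0.5)
    if np.isscalar(x) or arr.ndim == 0:
        return int(out)
    return out.astype(np.int64)


class EventClass(enum.Enum):
    """Closed set of cellular event classes; ``NONE`` is always valid."""

    NONE = "none"
    EXTRUSION = "extrusion"
    SOP = "sop"
    DIVISION = "division"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @classmethod
    def from_string(cls, s: str) -> "EventClass":
        try:
            return cls(s.strip().lower())
        except ValueError as exc:
            raise InvalidInputError(f"unknown event class {s!r}") from exc


#: Canonical class ordering used by classifiers: truncating to ``n`` gives the
#: label set of an ``n``-class model.
CLASS_ORDER = (
    EventClass.NONE,
    EventClass.EXTRUSION,
    EventClass.SOP,
    EventClass.DIVISION,
)


@dataclass(frozen=True)
class ReferenceScale:
    """The fixed calibration to which movies are resampled before inference.

    Parameters
    ----------
    pixel_size_ref : float
        Reference pixel size, µm/pixel.
    frame_interval_ref : float
        Reference frame interval, min/frame.
    cell_diameter_px : float
        Typical cell diameter at the reference scale, pixels.
    extrusion_duration_frames : float
        Typical extrusion duration at the reference scale, frames
        (midpoint of the observed four-to-five-frame range).
    """

    pixel_size_ref: float = 0.275
    frame_interval_ref: float = 5.0
    cell_diameter_px: float = 25.0
    extrusion_duration_frames: float = 4.5

    def __post_init__(self):
        for name in (
            "pixel_size_ref",
            "frame_interval_ref",
            "cell_diameter_px",
            "extrusion_duration_frames",
        ):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")


@dataclass
class Movie:
    """A single-channel time-lapse: intensity stack ordered ``(t, y, x)``.

    ``pixel_size`` is µm/pixel and ``frame_interval`` min/frame; both must be
    strictly positive.  All frames share one ``(y, x)`` shape.
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise InvalidInputError(
                f"frames must be a (t, y, x) stack with >=1 frame, "
                f"got shape {self.frames.shape}"
            )
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise InvalidInputError("calibration must be strictly positive")
        if np.issubdtype(self.frames.dtype, np.floating) and np.any(
            ~np.isfinite(self.frames)
        ):
            raise InvalidInputError("frames contain non-finite values")
        if self.frames.size and self.frames.min() < 0:
            raise InvalidInputError("intensities must be non-negative")

    @property
    def shape(self) -> tuple:
        return tuple(self.frames.shape)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def contains(self, x: int, y: int, t: int) -> bool:
        nt, ny, nx = self.frames.shape
        return 0 <= x < nx and 0 <= y < ny and 0 <= t < nt


@dataclass(frozen=True)
class EventPoint:
    """A classed point event at pixel ``(x, y)`` and frame ``t``."""

    x: int
    y: int
    t: int
    event_class: EventClass = EventClass.NONE
    probability: Optional[float] = None

    def __post_init__(self):
        if self.t < 0:
            raise InvalidInputError("t must be a frame index >= 0")
        if self.probability is not None and not (0.0 <= self.probability <= 1.0):
            raise InvalidInputError("probability must lie in [0, 1]")

    def key(self) -> tuple:
        return (self.x, self.y, self.t, self.event_class)


@dataclass
class AnnotationSet:
    """A collection of :class:`EventPoint` with its source calibration.

    Duplicate ``(x, y, t, class)`` entries are rejected.  ``source_scale`` is
    the ``(pixel_size, frame_interval)`` of the coordinate frame the points
    live in (``None`` components mean unknown).
    """

    events: list = field(default_factory=list)
    source_scale: tuple = (None, None)

    def __post_init__(self):
        keys = [e.key() for e in self.events]
        if len(set(keys)) != len(keys):
            raise InvalidInputError("duplicate (x, y, t, class) annotation")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def of_class(self, event_class: EventClass) -> "AnnotationSet":
        return AnnotationSet(
            [e for e in self.events if e.event_class is event_class],
            self.source_scale,
        )

    def class_counts(self) -> dict:
        counts: dict = {}
        for e in self.events:
            counts[e.event_class] = counts.get(e.event_class, 0) + 1
        return counts


def compute_scale_factors(
    movie_calibration: Sequence[float], ref: ReferenceScale = ReferenceScale()
) -> tuple:
    """Spatial and temporal resampling factors for a given calibration.

    Returns ``(spatial_factor, temporal_factor)`` such that multiplying the
    movie's pixel coordinates/shape by ``spatial_factor`` (and frame indices
    by ``temporal_factor``) lands it on the reference scale: a movie with
    *larger* pixels than the reference is upsampled (factor > 1).
    """
    pixel_size, frame_interval = movie_calibration
    if pixel_size <= 0 or frame_interval <= 0:
        raise InvalidInputError("calibration must be strictly positive")
    return pixel_size / ref.pixel_size_ref, frame_interval / ref.frame_interval_ref


def scale_factors_from_cell_features(
    observed_cell_diameter_px: float,
    observed_extrusion_frames: float,
    ref: ReferenceScale = ReferenceScale(),
) -> tuple:
    """Resampling factors from observed cell size and extrusion duration.

    For tissues whose absolute calibration is uninformative (very different
    cell sizes or event kinetics), the reference scale is defined in cellular
    features instead: the factors map the observed typical cell diameter to
    ``ref.cell_diameter_px`` (~25 px) and the observed extrusion duration to
    ``ref.extrusion_duration_frames`` (~4.5 frames).  Orientation matches
    :func:`compute_scale_factors`: coordinates are *multiplied* by the factors
    to reach the reference scale (80-px cells give spatial factor 25/80).
    """
    if observed_cell_diameter_px <= 0 or observed_extrusion_frames <= 0:
        raise InvalidInputError("observed features must be positive")
    return (
        ref.cell_diameter_px / observed_cell_diameter_px,
        ref.extrusion_duration_frames / observed_extrusion_frames,
    )


def _resample_temporal(frames: np.ndarray, n_out: int) -> np.ndarray:
    """Nearest-frame temporal resampling to ``n_out`` frames (no blending)."""
    n_in = frames.shape[0]
    if n_out < 1:
        raise InvalidInputError("temporal rescaling leaves no frames")
    idx = round_half_away(np.arange(n_out) * (n_in / n_out))
    idx = np.clip(idx, 0, n_in - 1)
    return frames[idx]


def rescale_movie(
    movie: Movie, spatial_factor: float, temporal_factor: float,
    target_calibration: Optional[tuple] = None,
) -> Movie:
    """Resample a movie by explicit factors (bilinear in space, nearest in time).

    Output spatial shape is ``round(shape × spatial_factor)`` per axis
    (half-away-from-zero) and frame count ``round(n × temporal_factor)``.
    Intensity range is preserved up to interpolation.
    """
    if spatial_factor <= 0 or temporal_factor <= 0:
        raise InvalidInputError("factors must be strictly positive")
    nt, ny, nx = movie.frames.shape
    out_t = round_half_away(nt * temporal_factor)
    out_y = round_half_away(ny * spatial_factor)
    out_x = round_half_away(nx * spatial_factor)
    if out_t < 1 or out_y < 1 or out_x < 1:
        raise InvalidInputError("rescaled movie would be empty")
    frames = _resample_temporal(movie.frames, out_t)
    if (out_y, out_x) != (ny, nx):
        frames = frames.astype(np.float32, copy=False)
        frames = _sk_resize(
            frames,
            (out_t, out_y, out_x),
            order=1,
            mode="edge",
            anti_aliasing=spatial_factor < 1.0,
            preserve_range=True,
        ).astype(np.float32)
    if target_calibration is None:
        target_calibration = (
            movie.pixel_size / spatial_factor,
            movie.frame_interval / temporal_factor,
        )
    return Movie(frames, *target_calibration)


def rescale_movie_to_reference(
    movie: Movie, ref: ReferenceScale = ReferenceScale()
) -> Movie:
    """Resample a movie onto the reference calibration (identity at reference)."""
    sf, tf = compute_scale_factors((movie.pixel_size, movie.frame_interval), ref)
    if sf == 1.0 and tf == 1.0:
        return Movie(movie.frames.copy(), ref.pixel_size_ref, ref.frame_interval_ref)
    return rescale_movie(
        movie, sf, tf, (ref.pixel_size_ref, ref.frame_interval_ref)
    )


def map_points(
    points: AnnotationSet,
    spatial_factor: float,
    temporal_factor: float,
    direction: str = "to_reference",
) -> AnnotationSet:
    """Map annotation coordinates across a rescaling.

    ``to_reference`` multiplies coordinates by the factors, ``to_original``
    divides; results are rounded half away from zero.  Class and probability
    are preserved.
    """
    if spatial_factor <= 0 or temporal_factor <= 0:
        raise InvalidInputError("factors must be strictly positive")
    if direction not in ("to_reference", "to_original"):
        raise InvalidInputError(f"unknown direction {direction!r}")
    if direction == "to_original":
        spatial_factor = 1.0 / spatial_factor
        temporal_factor = 1.0 / temporal_factor
    mapped = []
    seen = set()
    for e in points:
        p = EventPoint(
            x=round_half_away(e.x * spatial_factor),
            y=round_half_away(e.y * spatial_factor),
            t=max(0, round_half_away(e.t * temporal_factor)),
            event_class=e.event_class,
            probability=e.probability,
        )
        # rounding may collide distinct points; keep first occurrence
        if p.key() not in seen:
            seen.add(p.key())
            mapped.append(p)
    src = points.source_scale
    out_scale = (
        src[0] / spatial_factor if src[0] else None,
        src[1] / temporal_factor if src[1] else None,
    )
    return AnnotationSet(mapped, out_scale)
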