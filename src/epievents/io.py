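"""Readers and writers: TIFF stacks, ImageJ point ROIs, CSV event tables, config.

The ImageJ ROI codec implements the published binary layout of ImageJ/Fiji
``.roi`` files (64-byte big-endian header, optional 64-byte header2, UTF-16BE
name) for *point* ROIs only, which is what event annotations use.  The frame
index travels in the 1-based ``position`` field on disk (plus the header2
T-position) and is 0-based in memory.  The event class is encoded as a name
prefix (``extrusion_``, ``division_``, ``sop_``, ``none_``) because the ROI
format has no class field and names survive Fiji editing.
"""

from __future__ import annotations

import dataclasses
import io as _io
import struct
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, InvalidInputError
from .scaling import (
    AnnotationSet,
    EventClass,
    EventPoint,
    Movie,
    round_half_away,
)

__all__ = [
    "RunConfig",
    "read_tiff_movie",
    "write_tiff_movie",
    "write_probability_map",
    "read_imagej_rois",
    "write_imagej_rois",
    "read_events_csv",
    "write_events_csv",
]


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Every tunable default of the pipeline, in one flat record.

    Defaults are the published operating point of the method: 10×45×45
    windows, 22-px / 2-frame strides, a 5×22×22 allocation patch, probability
    threshold 180 (0-255 scale), volume threshold 800 voxels, 15-px / 4-frame
    matching tolerances, 40 epochs, augmentation factor 2, 8 base filters,
    75/25 train/validation split and 5 reinforcement rounds.
    """

    window_shape: tuple = (10, 45, 45)
    spatial_stride: int = 22
    temporal_stride: int = 2
    allocation_patch: tuple = (5, 22, 22)
    probability_threshold: float = 180.0
    volume_threshold: int = 800
    match_spatial_tol: float = 15.0
    match_temporal_tol: float = 4.0
    n_networks: int = 1
    epochs: int = 40
    augmentation_factor: int = 2
    base_filters: int = 8
    validation_fraction: float = 0.25
    reinforcement_iterations: int = 5
    balance: bool = True
    batch_size: int = 32
    learning_rate: float = 1e-3
    jitter_space: int = 11  # half the spatial stride: covers grid offsets
    jitter_time: int = 2
    seed: int = 0

    def to_text(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name}={v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        raw = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise FormatError(f"bad config line {line!r}")
            key, val = line.split("=", 1)
            raw[key.strip()] = val.strip()
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            val = raw.pop(f.name)
            default = getattr(cls, f.name, f.default)
            if isinstance(default, tuple):
                kwargs[f.name] = tuple(int(x) for x in val.split(","))
            elif isinstance(default, bool):
                kwargs[f.name] = val.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                kwargs[f.name] = int(val)
            elif isinstance(default, float):
                kwargs[f.name] = float(val)
            else:  # pragma: no cover - no other field types
                kwargs[f.name] = val
        if raw:
            raise FormatError(f"unknown config keys: {sorted(raw)}")
        return cls(**kwargs)

    def save(self, path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_text(Path(path).read_text())


# ---------------------------------------------------------------------------
# TIFF movies and probability maps
# ---------------------------------------------------------------------------

def read_tiff_movie(path, pixel_size: float, frame_interval: float) -> Movie:
    """Read a single-channel multi-page TIFF time series as a :class:`Movie`.

    Calibration always comes from the arguments; TIFF metadata is never
    trusted.  RGB pages are converted to grayscale by channel averaging.
    """
    try:
        arr = tifffile.imread(str(path))
    except Exception as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if arr is None or arr.size == 0:
        raise FormatError(f"{path}: empty TIFF")
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim == 4 and arr.shape[-1] in (3, 4):
        arr = arr[..., :3].mean(axis=-1)
    if arr.ndim != 3:
        raise FormatError(
            f"{path}: expected a 2D time series, got array of shape {arr.shape}"
        )
    return Movie(arr, pixel_size=pixel_size, frame_interval=frame_interval)


def write_tiff_movie(movie: Movie, path) -> None:
    """Write a movie as a multi-page TIFF (one page per frame)."""
    tifffile.imwrite(str(path), np.asarray(movie.frames),
                     photometric="minisblack")


def write_probability_map(prob_map, path) -> list:
    """Export a probability map as one 8-bit TIFF per event class.

    Voxel values are ``round(p × 255)`` (half away from zero), the 0-255
    display convention.  Returns the list of files written; for a single-class
    map the file is exactly ``path``.
    """
    values = np.asarray(prob_map.values)
    if values.min() < 0 or values.max() > 1:
        raise InvalidInputError("probabilities must lie in [0, 1]")
    path = Path(path)
    written = []
    names = list(getattr(prob_map, "class_names", [])) or [
        f"class{i}" for i in range(values.shape[0])
    ]
    for i, name in enumerate(names):
        scaled = round_half_away(values[i] * 255.0).astype(np.uint8)
        if len(names) == 1:
            out = path
        else:
            out = path.with_name(f"{path.stem}_{name}{path.suffix or '.tif'}")
        tifffile.imwrite(str(out), scaled, photometric="minisblack")
        written.append(out)
    return written


# ---------------------------------------------------------------------------
# ImageJ point ROIs
# ---------------------------------------------------------------------------

_ROI_MAGIC = b"Iout"
_ROI_VERSION = 228
_ROI_TYPE_POINT = 10

_CLASS_PREFIXES = {c.value: c for c in EventClass}


def _encode_point_roi(event: EventPoint, name: str) -> bytes:
    """Serialise a single point ROI with its name and 1-based position."""
    x, y, t1 = int(event.x), int(event.y), int(event.t) + 1
    header = bytearray(64)
    header[0:4] = _ROI_MAGIC
    struct.pack_into(">h", header, 4, _ROI_VERSION)
    header[6] = _ROI_TYPE_POINT
    # top, left, bottom, right
    struct.pack_into(">hhhh", header, 8, y, x, y + 1, x + 1)
    struct.pack_into(">H", header, 16, 1)  # nCoordinates
    struct.pack_into(">i", header, 56, t1)  # position
    name_bytes = name.encode("utf-16-be")
    coords = struct.pack(">hh", 0, 0)  # x, y relative to (left, top)
    header2_offset = 64 + len(coords)
    struct.pack_into(">i", header, 60, header2_offset)
    header2 = bytearray(64)
    struct.pack_into(">i", header2, 12, t1)  # T position
    struct.pack_into(">i", header2, 16, header2_offset + 64)  # name offset
    struct.pack_into(">i", header2, 20, len(name))  # name length (chars)
    return bytes(header) + coords + bytes(header2) + name_bytes


def _decode_point_roi(data: bytes, fallback_name: str = "") -> Optional[EventPoint]:
    """Parse one .roi blob; returns ``None`` (with a warning) if not a point."""
    if len(data) < 64 or data[0:4] != _ROI_MAGIC:
        raise FormatError("not an ImageJ ROI file")
    roi_type = data[6]
    if roi_type != _ROI_TYPE_POINT:
        warnings.warn(f"skipping non-point ROI (type {roi_type})")
        return None
    top, left = struct.unpack_from(">hh", data, 8)
    n = struct.unpack_from(">H", data, 16)[0]
    if n < 1:
        warnings.warn("skipping point ROI with no coordinates")
        return None
    xs = struct.unpack_from(f">{n}h", data, 64)
    ys = struct.unpack_from(f">{n}h", data, 64 + 2 * n)
    x, y = left + xs[0], top + ys[0]
    position = struct.unpack_from(">i", data, 56)[0]
    header2_offset = struct.unpack_from(">i", data, 60)[0]
    name = fallback_name
    t_position = 0
    if 0 < header2_offset <= len(data) - 64:
        t_position = struct.unpack_from(">i", data, header2_offset + 12)[0]
        name_offset = struct.unpack_from(">i", data, header2_offset + 16)[0]
        name_length = struct.unpack_from(">i", data, header2_offset + 20)[0]
        if name_offset > 0 and name_length > 0:
            raw = data[name_offset : name_offset + 2 * name_length]
            name = raw.decode("utf-16-be", errors="replace")
    if t_position > 0:  # hyperstack T field takes precedence
        t = t_position - 1
    elif position > 0:
        t = position - 1
    else:
        warnings.warn("point ROI without position; assuming t=0")
        t = 0
    event_class = EventClass.NONE
    for prefix, cls in _CLASS_PREFIXES.items():
        if name.lower().startswith(prefix):
            event_class = cls
            break
    return EventPoint(x=x, y=y, t=t, event_class=event_class)


def write_imagej_rois(annotations: AnnotationSet, path) -> None:
    """Write annotations as a Fiji-compatible ROI set.

    ``.zip`` paths get one ``.roi`` member per point; a ``.roi`` path is
    allowed for a single event.
    """
    path = Path(path)
    entries = []
    for i, e in enumerate(annotations):
        name = f"{e.event_class.value}_{i:04d}"
        entries.append((f"{name}.roi", _encode_point_roi(e, name)))
    if path.suffix.lower() == ".roi":
        if len(entries) != 1:
            raise InvalidInputError(".roi holds one ROI; use .zip for a set")
        path.write_bytes(entries[0][1])
        return
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for member, blob in entries:
            zf.writestr(member, blob)


def read_imagej_rois(path, source_scale: tuple = (None, None)) -> AnnotationSet:
    """Read a ``.roi`` file or ``.zip`` ROI set into an :class:`AnnotationSet`."""
    path = Path(path)
    events = []
    if path.suffix.lower() == ".roi":
        e = _decode_point_roi(path.read_bytes(), path.stem)
        if e is not None:
            events.append(e)
    else:
        try:
            zf = zipfile.ZipFile(path)
        except zipfile.BadZipFile as exc:
            raise FormatError(f"{path}: not a ROI zip") from exc
        with zf:
            for member in zf.namelist():
                if not member.lower().endswith(".roi"):
                    continue
                e = _decode_point_roi(zf.read(member), Path(member).stem)
                if e is not None:
                    events.append(e)
    return AnnotationSet(_dedupe(events), source_scale)


def _dedupe(events: list) -> list:
    seen, out = set(), []
    for e in events:
        if e.key() not in seen:
            seen.add(e.key())
            out.append(e)
    return out


# ---------------------------------------------------------------------------
# CSV event tables
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["x", "y", "t", "class", "probability"]


def write_events_csv(annotations: AnnotationSet, path) -> None:
    """Write events as CSV with header ``x,y,t,class,probability``."""
    rows = [
        {
            "x": e.x,
            "y": e.y,
            "t": e.t,
            "class": e.event_class.value,
            "probability": "" if e.probability is None else e.probability,
        }
        for e in annotations
    ]
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_events_csv(path, source_scale: tuple = (None, None)) -> AnnotationSet:
    """Read a CSV event table; missing columns or unknown classes are errors."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty or headerless CSV") from exc
    missing = [c for c in _CSV_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    events = []
    for i, row in df.iterrows():
        try:
            cls = EventClass(str(row["class"]).strip().lower())
        except ValueError as exc:
            raise FormatError(
                f"{path}: unknown class {row['class']!r} in row {i}"
            ) from exc
        prob = row.get("probability")
        if prob is None or (isinstance(prob, float) and np.isnan(prob)):
            prob = None
        else:
            prob = float(prob)
        events.append(
            EventPoint(
                x=int(row["x"]), y=int(row["y"]), t=int(row["t"]),
                event_class=cls, probability=prob,
            )
        )
    return AnnotationSet(events, source_scale)
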