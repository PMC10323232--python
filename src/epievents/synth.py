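"""Synthetic junction-labelled epithelium movies with planted, ground-truthed
cellular events.

The tissue is a Lloyd-relaxed Voronoi tessellation rendered as a bright
junction skeleton over a dark interior, with slow per-vertex fluctuations
between frames and additive Gaussian noise.  Events animate the shared
vertex mesh, so neighbours deform realistically:

* extrusion — the cell's apical area shrinks linearly to a point over 4-5
  frames, pulling neighbour junctions into a rosette; ground truth is the
  closure point and frame;
* division — the cell rounds up for two frames, then a bright furrow splits
  it (ground truth at furrow onset) and persists as the daughter interface;
* SOP — a persistently small-apex cell throughout the movie, the classic
  extrusion confuser;
* confuser — a transient constriction that relaxes back, planted *without*
  an annotation (for reinforcement experiments).

Ground truth is exact by construction: every planted event has one
annotation and nothing else in the movie constitutes an event.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import Voronoi
from skimage.draw import line_aa

from .errors import ConfigError
from .io import write_imagej_rois, write_tiff_movie
from .scaling import AnnotationSet, EventClass, EventPoint, Movie

__all__ = [
    "SynthConfig",
    "TissueGeometry",
    "PlantedEvent",
    "generate_epithelium",
    "plant_events",
    "generate_movie",
    "generate_dataset",
    "event_area_trajectories",
]


@dataclass
class SynthConfig:
    """Study conditions for one synthetic movie (reference scale).

    Defaults give a 256×256-px, 60-frame movie of ~25-px cells at high SNR
    (junction/background contrast 180 against noise σ 5) with 12 extrusions
    and 8 divisions — a desk-scale stand-in for a notum acquisition.
    """

    size: tuple = (256, 256)  # (y, x) pixels
    n_frames: int = 60
    n_cells: Optional[int] = None  # None -> tiled from cell_diameter
    cell_diameter: float = 25.0  # px, reference-scale typical cell
    junction_intensity: float = 200.0
    junction_sigma: float = 0.8  # px, junction width after smoothing
    background: float = 20.0
    noise_sigma: float = 5.0
    n_extrusions: int = 12
    n_divisions: int = 8
    n_sops: int = 0
    n_confusers: int = 0
    extrusion_duration: tuple = (4, 5)  # frames, drawn per event
    division_duration: tuple = (2, 3)
    jitter_amplitude: float = 0.4  # px per frame, junction fluctuation
    margin: int = 30  # px, event-free border
    seed: int = 0

    def resolved_n_cells(self) -> int:
        if self.n_cells is not None:
            return int(self.n_cells)
        ny, nx = self.size
        area = np.pi * (self.cell_diameter / 2.0) ** 2
        return max(4, int(round(ny * nx / area)))

    def validate(self) -> None:
        ny, nx = self.size
        n = self.resolved_n_cells()
        if ny < 64 or nx < 64:
            raise ConfigError("field must be at least 64×64 px")
        if n * (self.cell_diameter / 2) ** 2 * np.pi > 4 * ny * nx:
            raise ConfigError("n_cells incompatible with field size")
        if self.n_frames < 12:
            raise ConfigError("need at least 12 frames to plant events")


@dataclass
class PlantedEvent:
    cell: int
    event_class: EventClass
    t0: int  # annotation frame (closure / furrow onset / reference frame)
    duration: int
    theta: float = 0.0  # furrow orientation (divisions)


@dataclass
class TissueGeometry:
    """Shared-vertex cell mesh plus the frozen per-frame fluctuation field."""

    vertices: np.ndarray  # (V, 2) float (y, x)
    cells: list  # per cell: ordered vertex index list
    centroids: np.ndarray  # (n_cells, 2) float (y, x)
    jitter: np.ndarray  # (T, V, 2) float
    noise_seed: int
    config: SynthConfig
    events: list = field(default_factory=list)  # PlantedEvent list

    def cell_area(self, i: int, positions: Optional[np.ndarray] = None) -> float:
        pos = self.vertices if positions is None else positions
        poly = pos[self.cells[i]]
        return _shoelace_area(poly)

    def adjacent(self, i: int, j: int) -> bool:
        return bool(set(self.cells[i]) & set(self.cells[j]))


def _shoelace_area(poly: np.ndarray) -> float:
    y, x = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _polygon_centroid(poly: np.ndarray) -> np.ndarray:
    y, x = poly[:, 0], poly[:, 1]
    cross = x * np.roll(y, -1) - np.roll(x, -1) * y
    a = cross.sum() / 2.0
    if abs(a) < 1e-9:
        return poly.mean(axis=0)
    cy = ((y + np.roll(y, -1)) * cross).sum() / (6.0 * a)
    cx = ((x + np.roll(x, -1)) * cross).sum() / (6.0 * a)
    return np.array([cy, cx])


def _mirrored_voronoi(points: np.ndarray, ny: int, nx: int) -> Voronoi:
    """Voronoi of points plus their reflections across the four borders,
    which bounds every original cell inside the domain."""
    refl = [
        points * [1, -1],
        points * [1, -1] + [0, 2 * nx],
        points * [-1, 1],
        points * [-1, 1] + [2 * ny, 0],
    ]
    return Voronoi(np.vstack([points] + refl)[:, ::-1])  # scipy wants (x, y)


def _build_mesh(config: SynthConfig, rng: np.random.Generator):
    ny, nx = config.size
    n = config.resolved_n_cells()
    pts = rng.uniform([0, 0], [ny, nx], size=(n, 2))
    for _ in range(3):  # Lloyd relaxation toward a centroidal tessellation
        vor = _mirrored_voronoi(pts, ny, nx)
        new = pts.copy()
        for i in range(n):
            region = vor.regions[vor.point_region[i]]
            if -1 in region or not region:
                continue
            poly = vor.vertices[region][:, ::-1]  # back to (y, x)
            new[i] = _polygon_centroid(poly)
        pts = np.clip(new, [1, 1], [ny - 2, nx - 2])
    vor = _mirrored_voronoi(pts, ny, nx)
    # re-index only the vertices used by the first n regions
    used: dict = {}
    cells = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        idx = []
        for v in region:
            if v not in used:
                used[v] = len(used)
            idx.append(used[v])
        cells.append(idx)
    vertices = np.empty((len(used), 2))
    for old, newi in used.items():
        vertices[newi] = vor.vertices[old][::-1]
    centroids = np.array([_polygon_centroid(vertices[c]) for c in cells])
    return vertices, cells, centroids


def _event_scale(ev: PlantedEvent, t: int) -> Optional[float]:
    """Apical scale factor of an event cell at frame ``t`` (None = resting)."""
    if ev.event_class is EventClass.EXTRUSION:
        start = ev.t0 - ev.duration + 1
        if t < start:
            return None
        if t >= ev.t0:
            # after closure the ring vertices stay merged at the closure
            # point: the neighbours meet at one (higher-degree) junction
            # vertex, as after rosette resolution in vivo
            return 0.0
        return (ev.t0 - t) / float(ev.duration - 1)
    if ev.event_class is EventClass.SOP:
        return 0.45
    if ev.event_class is EventClass.NONE:  # confuser: constrict then relax
        half = max(2, ev.duration // 2)
        dt = t - (ev.t0 - half)
        if dt < 0 or dt > 2 * half:
            return None
        frac = 1.0 - abs(dt - half) / float(half)
        return 1.0 - 0.5 * frac
    if ev.event_class is EventClass.DIVISION:  # rounding before the furrow
        if ev.t0 - 2 <= t < ev.t0:
            return 0.92
        return None
    return None


def _render_movie(geometry: TissueGeometry) -> np.ndarray:
    cfg = geometry.config
    ny, nx = cfg.size
    T = cfg.n_frames
    # unique undirected edges of the mesh
    edge_set = set()
    for cell in geometry.cells:
        for a, b in zip(cell, cell[1:] + cell[:1]):
            edge_set.add((a, b) if a < b else (b, a))
    edges = np.array(sorted(edge_set))
    noise_rng = np.random.default_rng(geometry.noise_seed)
    frames = np.empty((T, ny, nx), dtype=np.float32)
    for t in range(T):
        pos = geometry.vertices + geometry.jitter[t]
        for ev in geometry.events:
            s = _event_scale(ev, t)
            if s is None:
                continue
            c = geometry.centroids[ev.cell]
            vidx = geometry.cells[ev.cell]
            pos[vidx] = c + s * (pos[vidx] - c)
        skel = np.zeros((ny, nx), dtype=np.float32)
        for a, b in edges:
            _draw_edge(skel, pos[a], pos[b])
        for ev in geometry.events:  # division furrow, persists after onset
            if ev.event_class is not EventClass.DIVISION or t < ev.t0:
                continue
            c = geometry.centroids[ev.cell]
            r = 0.75 * np.sqrt(geometry.cell_area(ev.cell) / np.pi) * 2
            d = np.array([np.sin(ev.theta), np.cos(ev.theta)])
            _draw_edge(skel, c - r / 2 * d, c + r / 2 * d)
        img = ndi.gaussian_filter(skel, cfg.junction_sigma)
        peak = img.max()
        if peak > 0:
            img = img * (cfg.junction_intensity / peak)
        img += cfg.background
        img += noise_rng.normal(0.0, cfg.noise_sigma, size=img.shape)
        frames[t] = np.clip(img, 0.0, None)
    return frames


def _draw_edge(canvas: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> None:
    ny, nx = canvas.shape
    r0, c0 = int(round(p0[0])), int(round(p0[1]))
    r1, c1 = int(round(p1[0])), int(round(p1[1]))
    r0 = int(np.clip(r0, 0, ny - 1))
    r1 = int(np.clip(r1, 0, ny - 1))
    c0 = int(np.clip(c0, 0, nx - 1))
    c1 = int(np.clip(c1, 0, nx - 1))
    rr, cc, val = line_aa(r0, c0, r1, c1)
    np.maximum.at(canvas, (rr, cc), val.astype(np.float32))


def generate_epithelium(config: SynthConfig) -> tuple:
    """Render an event-free epithelium movie; returns ``(Movie, geometry)``.

    Bit-identical for a fixed seed: the geometry carries the frozen jitter
    field and noise seed, so re-rendering (with or without planted events)
    reuses exactly the same background tissue.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    vertices, cells, centroids = _build_mesh(config, rng)
    walk = rng.normal(0.0, config.jitter_amplitude,
                      size=(config.n_frames, len(vertices), 2))
    jitter = np.clip(np.cumsum(walk, axis=0), -1.5, 1.5)
    geometry = TissueGeometry(
        vertices=vertices, cells=cells, centroids=centroids, jitter=jitter,
        noise_seed=int(rng.integers(0, 2**31 - 1)), config=config,
    )
    movie = Movie(_render_movie(geometry), pixel_size=0.275, frame_interval=5.0)
    return movie, geometry


def _pick_event_cells(geometry: TissueGeometry, rng: np.random.Generator):
    cfg = geometry.config
    ny, nx = cfg.size
    wanted = (
        [(EventClass.EXTRUSION, cfg.extrusion_duration)] * cfg.n_extrusions
        + [(EventClass.DIVISION, cfg.division_duration)] * cfg.n_divisions
        + [(EventClass.SOP, (1, 1))] * cfg.n_sops
        + [(EventClass.NONE, (6, 6))] * cfg.n_confusers
    )
    m = cfg.margin
    interior = [
        i for i, c in enumerate(geometry.centroids)
        if m <= c[0] <= ny - m and m <= c[1] <= nx - m
    ]
    rng.shuffle(interior)
    if len(interior) < len(wanted):
        raise ConfigError(
            f"cannot place {len(wanted)} events: only {len(interior)} interior cells"
        )
    min_space = 48.0  # px; events closer than this must be far apart in time
    min_time = 12  # frames
    t_lo, t_hi = 7, cfg.n_frames - 7
    for _restart in range(200):  # greedy placement with random restarts
        events: list = []
        pool = list(interior)
        failed = False
        for event_class, dur_range in wanted:
            placed = False
            attempts = 0
            while pool and attempts < 200 and not placed:
                attempts += 1
                cell = pool[int(rng.integers(0, len(pool)))]
                dur = int(rng.integers(dur_range[0], dur_range[1] + 1))
                t0 = int(rng.integers(t_lo, t_hi))
                ok = True
                for other in events:
                    if cell == other.cell or geometry.adjacent(cell, other.cell):
                        ok = False
                        break
                    d = np.linalg.norm(
                        geometry.centroids[cell] - geometry.centroids[other.cell]
                    )
                    close_time = abs(t0 - other.t0) < min_time
                    # an SOP is "active" for the whole movie, so it keeps
                    # spatial distance from everything regardless of time
                    sop_involved = (EventClass.SOP in
                                    (event_class, other.event_class))
                    if d < min_space and (close_time or sop_involved):
                        ok = False
                        break
                if not ok:
                    continue
                events.append(
                    PlantedEvent(cell=cell, event_class=event_class, t0=t0,
                                 duration=dur,
                                 theta=float(rng.uniform(0, np.pi)))
                )
                pool.remove(cell)
                placed = True
            if not placed:
                failed = True
                break
        if not failed:
            return events
    raise ConfigError("cannot place requested events; relax counts")


def plant_events(movie: Movie, geometry: TissueGeometry,
                 config: Optional[SynthConfig] = None) -> tuple:
    """Animate planted events into the tissue; returns ``(Movie, AnnotationSet)``.

    With zero requested events the rendered movie is identical to the
    event-free one.  Annotations carry the closure point/frame (extrusion),
    furrow onset (division) or small-cell centre (SOP); confusers get none.
    """
    cfg = config or geometry.config
    rng = np.random.default_rng(cfg.seed + 0x5EED)
    geometry.config = cfg  # events are recorded on the geometry in place
    geometry.events = _pick_event_cells(geometry, rng)
    frames = _render_movie(geometry)
    annotations = []
    for ev in geometry.events:
        if ev.event_class is EventClass.NONE:
            continue  # confusers are deliberately unannotated
        cy, cx = geometry.centroids[ev.cell]
        annotations.append(
            EventPoint(x=int(round(cx)), y=int(round(cy)), t=int(ev.t0),
                       event_class=ev.event_class)
        )
    out = Movie(frames, movie.pixel_size, movie.frame_interval)
    return out, AnnotationSet(annotations, (out.pixel_size, out.frame_interval))


def generate_movie(config: SynthConfig) -> tuple:
    """Convenience: epithelium + planted events → (Movie, AnnotationSet, geometry)."""
    base, geometry = generate_epithelium(config)
    movie, annotations = plant_events(base, geometry, config)
    return movie, annotations, geometry


def generate_dataset(config: SynthConfig, n_movies: int,
                     out_dir=None) -> tuple:
    """Independent seeded movies plus a manifest of files, seeds and counts."""
    pairs = []
    rows = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for i in range(n_movies):
        cfg = replace(config, seed=config.seed + 1000 * i)
        movie, annotations, _ = generate_movie(cfg)
        pairs.append((movie, annotations))
        row = {
            "movie": f"movie_{i:03d}.tif",
            "rois": f"movie_{i:03d}_rois.zip",
            "seed": cfg.seed,
            "n_events": len(annotations),
        }
        for cls, count in annotations.class_counts().items():
            row[f"n_{cls.value}"] = count
        rows.append(row)
        if out_dir is not None:
            write_tiff_movie(movie, out_dir / row["movie"])
            write_imagej_rois(annotations, out_dir / row["rois"])
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return pairs, manifest


def event_area_trajectories(geometry: TissueGeometry,
                            half_span: int = 5) -> list:
    """Apical-area trajectory of each planted event cell around its event.

    Returns ``(event_class, areas)`` pairs, the handcrafted feature used to
    verify that planted classes are discriminable (well-posed learning task).
    """
    out = []
    for ev in geometry.events:
        areas = []
        for t in range(ev.t0 - half_span, ev.t0 + half_span):
            tt = int(np.clip(t, 0, geometry.config.n_frames - 1))
            pos = geometry.vertices + geometry.jitter[tt]
            s = _event_scale(ev, tt)
            if s is not None:
                c = geometry.centroids[ev.cell]
                vidx = geometry.cells[ev.cell]
                pos = pos.copy()
                pos[vidx] = c + s * (pos[vidx] - c)
            areas.append(geometry.cell_area(ev.cell, pos))
        out.append((ev.event_class, np.array(areas)))
    return out
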