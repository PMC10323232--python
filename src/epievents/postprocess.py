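"""From probability maps to discrete point events.

A detected event shows up as a contiguous ``(t, y, x)`` volume of high
probability.  The map is thresholded on the user-facing 0-255 scale
(default 180), 26-connected components below a minimum volume (default 800
reference-scale voxels, the published operating point) are discarded as
false positives, merged blobs are separated by watershed on the inverted
smoothed probability relief, and each surviving component is reported as a
point event at its centroid, mapped back to original-movie coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .detection import ProbabilityMap, classify_movie
from .errors import InvalidInputError
from .io import RunConfig
from .scaling import (
    AnnotationSet,
    EventClass,
    EventPoint,
    Movie,
    ReferenceScale,
    compute_scale_factors,
    map_points,
    rescale_movie_to_reference,
    round_half_away,
)

__all__ = [
    "DetectionComponent",
    "threshold_map",
    "extract_components",
    "watershed_split",
    "components_to_events",
    "detect_events",
]

#: 26-connectivity in (t, y, x): an extrusion blob drifts slightly between
#: frames, and face-only connectivity would fragment it.
_STRUCTURE = np.ones((3, 3, 3), dtype=bool)


@dataclass
class DetectionComponent:
    """One connected high-probability volume for one event class."""

    voxels: tuple  # (t_idx, y_idx, x_idx) integer index arrays
    event_class: EventClass
    peak_probability: float
    volume: int
    centroid: tuple  # (t, y, x) floats

    @classmethod
    def from_indices(cls, idx: tuple, event_class: EventClass,
                     prob: np.ndarray) -> "DetectionComponent":
        values = prob[idx]
        return cls(
            voxels=idx,
            event_class=event_class,
            peak_probability=float(values.max()) if values.size else 0.0,
            volume=int(idx[0].size),
            centroid=tuple(float(np.mean(a)) for a in idx),
        )


def threshold_map(prob_map: ProbabilityMap, probability_threshold: float,
                  class_name: str = "extrusion") -> np.ndarray:
    """Binary mask: voxel true iff ``round(p × 255) ≥ threshold``."""
    if not 0 <= probability_threshold <= 255:
        raise InvalidInputError("threshold must lie in [0, 255]")
    channel = prob_map.channel(class_name)
    scaled = np.sign(channel) * np.floor(np.abs(channel) * 255.0 + 0.5)
    return scaled >= probability_threshold


def extract_components(mask: np.ndarray, volume_threshold: int,
                       prob: Optional[np.ndarray] = None,
                       event_class: EventClass = EventClass.EXTRUSION,
                       bridge: tuple = (0, 0)) -> list:
    """26-connected components of a mask, keeping volumes ≥ threshold.

    ``bridge=(frames, px)`` optionally links fragments separated by gaps up
    to that radius before labelling (components still consist of original
    mask voxels only).  One event's high-probability volume can fragment
    across adjacent allocation tiles when single windows dip below the
    threshold; sub-cell-scale gaps do not separate real events, so
    :func:`detect_events` bridges up to (2 frames, 11 px) — half a tile.
    """
    mask = np.asarray(mask, dtype=bool)
    if prob is None:
        prob = mask.astype(np.float64)
    if bridge != (0, 0) and mask.any():
        rt, rs = bridge
        t, y, x = np.ogrid[-rt : rt + 1, -rs : rs + 1, -rs : rs + 1]
        st = np.broadcast_to(y**2 + x**2 <= rs**2,
                             (2 * rt + 1, 2 * rs + 1, 2 * rs + 1))
        dilated = ndi.binary_dilation(mask, structure=st)
        labels, n = ndi.label(dilated, structure=_STRUCTURE)
        labels = np.where(mask, labels, 0)
    else:
        labels, n = ndi.label(mask, structure=_STRUCTURE)
    comps = []
    for obj_slice, lab in zip(ndi.find_objects(labels), range(1, n + 1)):
        if obj_slice is None:
            continue
        local = labels[obj_slice] == lab
        if int(local.sum()) < volume_threshold:
            continue
        idx_local = np.nonzero(local)
        idx = tuple(
            a + s.start for a, s in zip(idx_local, obj_slice)
        )
        comps.append(DetectionComponent.from_indices(idx, event_class, prob))
    return comps


def watershed_split(prob_map_channel: np.ndarray, components: Sequence,
                    volume_threshold: int,
                    smooth_sigma: tuple = (1.0, 2.0, 2.0),
                    min_seed_distance: tuple = (None, 25)) -> list:
    """Separate merged events within each component by watershed.

    The relief is the inverted probability, smoothed (σ = 1 frame, 2 px) so
    sub-cell-scale maxima do not seed; seeds are local probability maxima
    at least one cell diameter (25 px) apart spatially — events closer than
    a cell cannot be distinct, and smaller separations split one event's
    volume into duplicate detections.  The temporal seed
    separation defaults to the component's whole temporal span: a cell
    extrudes (or divides) once, so one connected volume cannot contain two
    events at the same place at different times — splitting is spatial.
    Watershed fragments smaller than the volume threshold are merged into
    their largest neighbouring fragment, so the voxel multiset is conserved.
    """
    out = []
    smoothed = ndi.gaussian_filter(prob_map_channel.astype(np.float64),
                                   sigma=smooth_sigma)
    shape = prob_map_channel.shape
    for comp in components:
        # work inside the component's padded bounding box
        lo = [max(0, int(a.min()) - 2) for a in comp.voxels]
        hi = [min(s, int(a.max()) + 3) for a, s in zip(comp.voxels, shape)]
        box = tuple(slice(a, b) for a, b in zip(lo, hi))
        mask = np.zeros(tuple(b - a for a, b in zip(lo, hi)), dtype=bool)
        local_idx = tuple(a - o for a, o in zip(comp.voxels, lo))
        mask[local_idx] = True
        sm = smoothed[box]
        sep_t, sep_s = min_seed_distance
        if sep_t is None:
            sep_t = mask.shape[0]  # whole temporal span of the component
        peaks = peak_local_max(
            sm * mask,
            footprint=np.ones((2 * sep_t + 1, 2 * sep_s + 1, 2 * sep_s + 1),
                              dtype=bool),
            labels=mask.astype(np.int32),
            exclude_border=False,
        )
        if len(peaks) <= 1:
            out.append(comp)
            continue
        markers = np.zeros(mask.shape, dtype=np.int32)
        for i, p in enumerate(peaks, start=1):
            markers[tuple(p)] = i
        labels = watershed(-sm, markers=markers, mask=mask,
                           connectivity=_STRUCTURE)
        labels = _merge_small_fragments(labels, volume_threshold)
        for lab in np.unique(labels):
            if lab == 0:
                continue
            idx_local = np.nonzero(labels == lab)
            idx = tuple(a + o for a, o in zip(idx_local, lo))
            out.append(
                DetectionComponent.from_indices(idx, comp.event_class,
                                                prob_map_channel)
            )
    return out


def _merge_small_fragments(labels: np.ndarray, volume_threshold: int
                           ) -> np.ndarray:
    """Absorb sub-threshold watershed fragments into their largest neighbour."""
    labels = labels.copy()
    while True:
        ids, counts = np.unique(labels[labels > 0], return_counts=True)
        if len(ids) <= 1:
            break
        small = [i for i, c in zip(ids, counts) if c < volume_threshold]
        if not small:
            break
        sizes = dict(zip(ids, counts))
        lab = min(small, key=lambda i: sizes[i])
        region = labels == lab
        ring = ndi.binary_dilation(region, structure=_STRUCTURE) & ~region
        neighbours = np.unique(labels[ring])
        neighbours = [n for n in neighbours if n > 0]
        if not neighbours:
            # isolated small fragment: absorb into the largest fragment overall
            target = max((i for i in ids if i != lab), key=lambda i: sizes[i])
        else:
            target = max(neighbours, key=lambda n: sizes[n])
        labels[region] = target
    return labels


def components_to_events(components: Sequence, spatial_factor: float = 1.0,
                         temporal_factor: float = 1.0) -> AnnotationSet:
    """One point event per component at its rounded centroid.

    Probability is the component's peak probability; coordinates are mapped
    back to the original movie frame by dividing out the reference-scale
    factors.
    """
    events = []
    for comp in components:
        ct, cy, cx = comp.centroid
        events.append(
            EventPoint(
                x=round_half_away(cx),
                y=round_half_away(cy),
                t=max(0, round_half_away(ct)),
                event_class=comp.event_class,
                probability=min(1.0, comp.peak_probability),
            )
        )
    ref_set = AnnotationSet(_dedupe(events))
    if spatial_factor == 1.0 and temporal_factor == 1.0:
        return ref_set
    return map_points(ref_set, spatial_factor, temporal_factor,
                      direction="to_original")


def _dedupe(events):
    seen, out = set(), []
    for e in events:
        if e.key() not in seen:
            seen.add(e.key())
            out.append(e)
    return out


def detect_events(
    nets,
    movie: Movie,
    config: RunConfig = RunConfig(),
    ref: ReferenceScale = ReferenceScale(),
    classes: Optional[Sequence[str]] = None,
) -> tuple:
    """Full pipeline: rescale → classify → threshold → filter → watershed →
    centroids → events in original-movie coordinates.

    Returns ``(AnnotationSet, ProbabilityMap)``; the map is at the reference
    scale.  Deterministic given the networks and config.
    """
    sf, tf = compute_scale_factors((movie.pixel_size, movie.frame_interval), ref)
    movie_ref = rescale_movie_to_reference(movie, ref)
    prob_map = classify_movie(nets, movie_ref, config)
    wanted = list(classes) if classes is not None else list(prob_map.class_names)
    all_events = []
    for name in wanted:
        mask = threshold_map(prob_map, config.probability_threshold, name)
        comps = extract_components(
            mask, config.volume_threshold, prob_map.channel(name),
            EventClass(name), bridge=(2, 11),
        )
        comps = watershed_split(prob_map.channel(name), comps,
                                config.volume_threshold)
        all_events.extend(components_to_events(comps).events)
    ref_set = AnnotationSet(_dedupe(all_events),
                            (ref.pixel_size_ref, ref.frame_interval_ref))
    events = map_points(ref_set, sf, tf, direction="to_original")
    events.source_scale = (movie.pixel_size, movie.frame_interval)
    return events, prob_map
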