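"""Scoring detections against annotations.

Predicted and annotated point events are matched one-to-one when their xy
Euclidean distance is within 15 px and their frame distance within 4 frames
(reference scale; both tolerances are overridable for tissues with larger
cells).  Matching is an optimal one-to-one assignment on the candidate
graph (maximum matches, then minimum total distance), checked against an
exhaustive oracle on small instances.  From the TP/FP/FN counts we report precision
TP/(TP+FP), recall TP/(TP+FN) and F1 = TP/(TP+(FP+FN)/2); accuracy
(TP+TN)/total is defined only at window level where true negatives exist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidInputError
from .scaling import AnnotationSet

__all__ = [
    "MatchConfig",
    "ScoreCounts",
    "MetricReport",
    "match_events",
    "compute_scores",
    "distance_histogram",
    "cumulative_counts",
    "sample_rois_for_review",
    "precision_from_verdicts",
]


@dataclass(frozen=True)
class MatchConfig:
    """Spatiotemporal tolerances defining a correct detection."""

    spatial_tol: float = 15.0  # px, ~one cell radius at reference scale
    temporal_tol: float = 4.0  # frames (±20 min at 5 min/frame)

    def __post_init__(self):
        if self.spatial_tol <= 0 or self.temporal_tol <= 0:
            raise InvalidInputError("tolerances must be positive")


@dataclass
class ScoreCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0
    TN: Optional[int] = None  # window-level classification only


@dataclass
class MetricReport:
    precision: float
    recall: float
    f1: float
    accuracy: Optional[float] = None
    spatial_tol: float = 15.0
    temporal_tol: float = 4.0


def match_events(
    predicted: AnnotationSet,
    annotated: AnnotationSet,
    cfg: MatchConfig = MatchConfig(),
) -> tuple:
    """Optimal one-to-one matching inside the tolerance box.

    Candidate pairs have xy distance ≤ ``spatial_tol`` and |Δt| ≤
    ``temporal_tol``.  The assignment maximises the number of matched pairs
    and, among those, minimises the total spatial distance (ties broken by
    temporal distance) via the Hungarian algorithm — deterministic and
    equal to exhaustive optimal assignment.  Returns ``(ScoreCounts,
    pairs)`` with pairs as ``(pred_index, annot_index, spatial_distance,
    dt)``.
    """
    from scipy.optimize import linear_sum_assignment

    preds = list(predicted)
    annots = list(annotated)
    n, m = len(preds), len(annots)
    pairs = []
    if n and m:
        big = 1e9  # dominates any admissible distance: cardinality first
        cost = np.full((n, m), big)
        dts = np.zeros((n, m))
        for i, p in enumerate(preds):
            for j, a in enumerate(annots):
                dt = abs(p.t - a.t)
                if dt > cfg.temporal_tol:
                    continue
                d = math.hypot(p.x - a.x, p.y - a.y)
                if d <= cfg.spatial_tol:
                    cost[i, j] = d + 1e-6 * dt
                    dts[i, j] = dt
        rows, cols = linear_sum_assignment(cost)
        for i, j in zip(rows, cols):
            if cost[i, j] < big:
                d = math.hypot(preds[i].x - annots[j].x,
                               preds[i].y - annots[j].y)
                pairs.append((int(i), int(j), d, int(dts[i, j])))
    counts = ScoreCounts(
        TP=len(pairs),
        FP=len(preds) - len(pairs),
        FN=len(annots) - len(pairs),
    )
    return counts, pairs


def compute_scores(counts: ScoreCounts,
                   cfg: MatchConfig = MatchConfig()) -> MetricReport:
    """Precision/recall/F1 (and accuracy when TN is defined).

    0/0 convention: a metric whose denominator is zero is 0 when anything was
    missed or mispredicted, and 1 when there are neither predictions nor
    annotations.
    """
    tp, fp, fn = counts.TP, counts.FP, counts.FN
    if tp + fp + fn == 0:
        precision = recall = f1 = 1.0
    else:
        precision = tp / (tp + fp) if (tp + fp) else 0.0
        recall = tp / (tp + fn) if (tp + fn) else 0.0
        f1 = tp / (tp + (fp + fn) / 2.0) if (tp + fp + fn) else 0.0
    accuracy = None
    if counts.TN is not None:
        total = tp + fp + fn + counts.TN
        accuracy = (tp + counts.TN) / total if total else 1.0
    return MetricReport(precision=precision, recall=recall, f1=f1,
                        accuracy=accuracy, spatial_tol=cfg.spatial_tol,
                        temporal_tol=cfg.temporal_tol)


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic-mean form 2PR/(P+R); equals TP/(TP+(FP+FN)/2) exactly."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def distance_histogram(
    predicted: AnnotationSet,
    annotated: AnnotationSet,
    cfg: MatchConfig = MatchConfig(),
    max_spatial: float = 50.0,
    max_temporal: float = 12.0,
) -> dict:
    """2D histogram of spatiotemporal distances, binned 1 px × 1 frame.

    Each annotation is paired with its nearest prediction (spatial first,
    then temporal) within the wide cutoff.  Returns the 2D counts, both
    marginals, the pair count and the fraction inside the tolerance box.
    """
    preds = list(predicted)
    annots = list(annotated)
    dists = []
    for a in annots:
        best = None
        for p in preds:
            dt = abs(p.t - a.t)
            d = math.hypot(p.x - a.x, p.y - a.y)
            if d > max_spatial or dt > max_temporal:
                continue
            if best is None or (d, dt) < best:
                best = (d, dt)
        if best is not None:
            dists.append(best)
    n_s = int(np.ceil(max_spatial)) + 1
    n_t = int(np.ceil(max_temporal)) + 1
    hist = np.zeros((n_s, n_t), dtype=int)
    inside = 0
    for d, dt in dists:
        hist[min(int(d), n_s - 1), min(int(dt), n_t - 1)] += 1
        if d <= cfg.spatial_tol and dt <= cfg.temporal_tol:
            inside += 1
    return {
        "hist": hist,
        "spatial_marginal": hist.sum(axis=1),
        "temporal_marginal": hist.sum(axis=0),
        "n_pairs": len(dists),
        "fraction_inside": inside / len(dists) if dists else 0.0,
    }


def cumulative_counts(
    events: AnnotationSet,
    annotations: AnnotationSet,
    frame_interval: float = 5.0,
    bin_minutes: float = 10.0,
) -> dict:
    """Cumulative event counts over time for both sets, binned in minutes.

    Returns the shared bin edges (minutes), both cumulative curves sampled at
    the right edge of each bin, the per-bin absolute difference and its mean.
    """
    t_pred = np.array([e.t for e in events], dtype=float) * frame_interval
    t_annot = np.array([e.t for e in annotations], dtype=float) * frame_interval
    t_max = max(t_pred.max() if t_pred.size else 0.0,
                t_annot.max() if t_annot.size else 0.0)
    n_bins = max(1, int(np.ceil((t_max + 1e-9) / bin_minutes)))
    edges = np.arange(1, n_bins + 1) * bin_minutes
    cum_pred = np.array([(t_pred <= e).sum() for e in edges])
    cum_annot = np.array([(t_annot <= e).sum() for e in edges])
    diff = np.abs(cum_pred - cum_annot)
    return {
        "bin_edges_min": edges,
        "cumulative_predicted": cum_pred,
        "cumulative_annotated": cum_annot,
        "abs_difference": diff,
        "mean_abs_difference": float(diff.mean()),
    }


def plot_distance_histogram(hist: dict, path,
                            cfg: MatchConfig = MatchConfig()) -> None:
    """Render the 2D spatial × temporal distance histogram with marginals.

    The tolerance box is drawn dashed; counts use a perceptual colormap.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    h = hist["hist"]
    fig, axes = plt.subplots(
        2, 2, figsize=(6, 6), sharex="col", sharey="row",
        gridspec_kw={"width_ratios": [4, 1], "height_ratios": [1, 4]},
    )
    axes[0, 1].axis("off")
    im = axes[1, 0].imshow(h, origin="lower", aspect="auto", cmap="viridis",
                           extent=(0, h.shape[1], 0, h.shape[0]))
    axes[1, 0].axvline(cfg.temporal_tol, ls="--", c="red")
    axes[1, 0].axhline(cfg.spatial_tol, ls="--", c="red")
    axes[1, 0].set_xlabel("temporal distance (frames)")
    axes[1, 0].set_ylabel("spatial distance (px)")
    axes[0, 0].bar(np.arange(h.shape[1]) + 0.5, hist["temporal_marginal"],
                   width=1.0, color="grey")
    axes[1, 1].barh(np.arange(h.shape[0]) + 0.5, hist["spatial_marginal"],
                    height=1.0, color="grey")
    fig.colorbar(im, ax=axes[1, 0], fraction=0.04, label="pairs")
    fig.suptitle(f"{hist['fraction_inside']:.0%} of pairs inside tolerance")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def sample_rois_for_review(
    predicted: AnnotationSet, n: int,
    rng: Optional[np.random.Generator] = None,
) -> AnnotationSet:
    """Uniform random subset (without replacement) for manual review.

    For movies without annotations, precision is estimated by manually
    scoring such a subset; :func:`precision_from_verdicts` ingests the
    verdicts.
    """
    events = list(predicted)
    if n > len(events):
        raise InvalidInputError(f"cannot sample {n} of {len(events)} events")
    rng = np.random.default_rng() if rng is None else rng
    idx = sorted(rng.choice(len(events), size=n, replace=False))
    return AnnotationSet([events[i] for i in idx], predicted.source_scale)


def precision_from_verdicts(verdicts: Sequence[bool]) -> float:
    """Estimated precision from manual verdicts: correct / reviewed."""
    verdicts = list(verdicts)
    if not verdicts:
        raise InvalidInputError("no verdicts given")
    return sum(bool(v) for v in verdicts) / len(verdicts)
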