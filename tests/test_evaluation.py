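"""Spatiotemporal matching and detection metrics."""

import itertools
import math

import numpy as np
import pytest

from epievents.errors import InvalidInputError
from epievents.evaluation import (
    MatchConfig,
    ScoreCounts,
    compute_scores,
    cumulative_counts,
    distance_histogram,
    f1_from_precision_recall,
    match_events,
    precision_from_verdicts,
    sample_rois_for_review,
)
from epievents.scaling import AnnotationSet, EventClass, EventPoint


def _set(coords):
    return AnnotationSet(
        [EventPoint(x, y, t, EventClass.EXTRUSION) for (x, y, t) in coords]
    )


def _optimal_tp(preds, annots, cfg):
    """Exhaustive maximum-cardinality matching oracle (small instances)."""
    ok = [
        [
            math.hypot(p.x - a.x, p.y - a.y) <= cfg.spatial_tol
            and abs(p.t - a.t) <= cfg.temporal_tol
            for a in annots
        ]
        for p in preds
    ]
    n, m = len(preds), len(annots)
    best = 0
    for k in range(min(n, m), 0, -1):
        for ps in itertools.combinations(range(n), k):
            for perm in itertools.permutations(range(m), k):
                if all(ok[i][j] for i, j in zip(ps, perm)):
                    return k
    return best


class TestMatching:
    def test_inside_tolerance_box_matches(self):
        counts, pairs = match_events(
            _set([(100, 100, 10)]), _set([(110, 105, 12)])
        )
        assert (counts.TP, counts.FP, counts.FN) == (1, 0, 0)
        assert pairs[0][2] == pytest.approx(math.sqrt(125))

    def test_temporal_distance_five_fails(self):
        counts, _ = match_events(_set([(100, 100, 10)]), _set([(100, 100, 15)]))
        assert (counts.TP, counts.FP, counts.FN) == (0, 1, 1)

    def test_counts_identities(self, rng):
        preds = _set([(int(x), int(y), int(t)) for x, y, t in
                      rng.integers(0, 60, (12, 3))])
        annots = _set([(int(x), int(y), int(t)) for x, y, t in
                       rng.integers(0, 60, (9, 3))])
        counts, _ = match_events(preds, annots)
        assert counts.TP + counts.FP == len(preds)
        assert counts.TP + counts.FN == len(annots)
        assert counts.TP <= min(len(preds), len(annots))

    def test_swap_symmetry(self, rng):
        preds = _set([(int(x), int(y), int(t)) for x, y, t in
                      rng.integers(0, 50, (8, 3))])
        annots = _set([(int(x), int(y), int(t)) for x, y, t in
                       rng.integers(0, 50, (6, 3))])
        c1, _ = match_events(preds, annots)
        c2, _ = match_events(annots, preds)
        assert (c1.TP, c1.FP, c1.FN) == (c2.TP, c2.FN, c2.FP)

    def test_matching_equals_exhaustive_optimal_on_small_instances(self, rng):
        cfg = MatchConfig()
        for _ in range(300):
            n, m = int(rng.integers(0, 7)), int(rng.integers(0, 7))
            preds = [EventPoint(int(x), int(y), int(t), EventClass.EXTRUSION)
                     for x, y, t in zip(rng.integers(0, 40, n),
                                        rng.integers(0, 40, n),
                                        rng.integers(0, 10, n))]
            annots = [EventPoint(int(x), int(y), int(t), EventClass.EXTRUSION)
                      for x, y, t in zip(rng.integers(0, 40, m),
                                         rng.integers(0, 40, m),
                                         rng.integers(0, 10, m))]
            counts, _ = match_events(
                AnnotationSet([], (None, None)) if not preds else
                _wrap(preds), _wrap(annots) if annots else
                AnnotationSet([], (None, None)), cfg)
            assert counts.TP == _optimal_tp(preds, annots, cfg)


def _wrap(events):
    out, seen = [], set()
    for e in events:
        if e.key() not in seen:
            seen.add(e.key())
            out.append(e)
    return AnnotationSet(out)


class TestScores:
    def test_perfect(self):
        rep = compute_scores(ScoreCounts(TP=1, FP=0, FN=0))
        assert (rep.precision, rep.recall, rep.f1) == (1.0, 1.0, 1.0)

    def test_published_worked_example(self):
        # harmonic mean of precision 0.72 and recall 0.86, to two decimals
        assert round(f1_from_precision_recall(0.72, 0.86), 2) == 0.78

    def test_all_wrong(self):
        rep = compute_scores(ScoreCounts(TP=0, FP=5, FN=5))
        assert (rep.precision, rep.recall, rep.f1) == (0.0, 0.0, 0.0)

    def test_empty_sets_convention(self):
        rep = compute_scores(ScoreCounts(TP=0, FP=0, FN=0))
        assert (rep.precision, rep.recall, rep.f1) == (1.0, 1.0, 1.0)

    def test_f1_forms_agree_and_bounded(self, rng):
        for _ in range(200):
            tp = int(rng.integers(1, 30))
            fp = int(rng.integers(0, 30))
            fn = int(rng.integers(0, 30))
            rep = compute_scores(ScoreCounts(TP=tp, FP=fp, FN=fn))
            direct = tp / (tp + (fp + fn) / 2)
            assert rep.f1 == pytest.approx(direct)
            assert rep.f1 == pytest.approx(
                f1_from_precision_recall(rep.precision, rep.recall)
            )
            assert min(rep.precision, rep.recall) - 1e-12 <= rep.f1
            assert rep.f1 <= max(rep.precision, rep.recall) + 1e-12

    def test_window_level_accuracy(self):
        rep = compute_scores(ScoreCounts(TP=40, FP=2, FN=1, TN=57))
        assert rep.accuracy == pytest.approx(97 / 100)


class TestDistanceHistogram:
    def test_coincident_pairs_single_hot_bin(self):
        s = _set([(10, 10, 3), (20, 20, 5)])
        out = distance_histogram(s, s)
        assert out["hist"][0, 0] == 2
        assert out["hist"].sum() == out["n_pairs"] == 2
        assert out["fraction_inside"] == 1.0

    def test_fraction_inside_counts_directly(self):
        preds = _set([(0, 0, 0), (30, 0, 0)])
        annots = _set([(5, 0, 0), (30, 40, 0)])
        out = distance_histogram(preds, annots)
        # first annotation matched at 5 px (inside), second at 40 px (outside)
        assert out["n_pairs"] == 2
        assert out["fraction_inside"] == 0.5

    def test_marginals_conserve_total(self, rng):
        preds = _set([(int(x), int(y), int(t)) for x, y, t in
                      rng.integers(0, 30, (10, 3))])
        out = distance_histogram(preds, preds)
        assert out["spatial_marginal"].sum() == out["n_pairs"]
        assert out["temporal_marginal"].sum() == out["n_pairs"]


class TestCumulativeCounts:
    def test_identical_sets_zero_difference(self):
        s = _set([(1, 1, 2), (2, 2, 8), (3, 3, 14)])
        out = cumulative_counts(s, s)
        assert out["mean_abs_difference"] == 0.0
        assert np.all(out["abs_difference"] == 0)

    def test_curves_non_decreasing_and_total(self, rng):
        preds = _set([(int(x), 0, int(t)) for x, t in
                      zip(range(20), rng.integers(0, 50, 20))])
        annots = _set([(int(x), 1, int(t)) for x, t in
                       zip(range(15), rng.integers(0, 50, 15))])
        out = cumulative_counts(preds, annots)
        assert np.all(np.diff(out["cumulative_predicted"]) >= 0)
        assert out["cumulative_predicted"][-1] == 20
        assert out["cumulative_annotated"][-1] == 15


class TestReviewSampling:
    def test_full_sample_is_whole_set(self, random_events, rng):
        sub = sample_rois_for_review(random_events, len(random_events), rng)
        assert {e.key() for e in sub} == {e.key() for e in random_events}

    def test_seeded_subsets_identical(self, random_events):
        s1 = sample_rois_for_review(random_events, 10,
                                    np.random.default_rng(3))
        s2 = sample_rois_for_review(random_events, 10,
                                    np.random.default_rng(3))
        assert [e.key() for e in s1] == [e.key() for e in s2]

    def test_oversampling_errors(self, random_events, rng):
        with pytest.raises(InvalidInputError):
            sample_rois_for_review(random_events, len(random_events) + 1, rng)

    def test_precision_estimate(self):
        assert precision_from_verdicts([True] * 7 + [False] * 3) == 0.7


def test_distance_histogram_figure_written(tmp_path):
    from epievents.evaluation import plot_distance_histogram

    s = _set([(10, 10, 3), (20, 20, 5), (30, 12, 7)])
    out = distance_histogram(s, s)
    path = tmp_path / "hist.png"
    plot_distance_histogram(out, path)
    assert path.exists() and path.stat().st_size > 0
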