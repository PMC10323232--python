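"""Window extraction, jitter, control sampling, balancing, augmentation."""

import numpy as np
import pytest

from epievents.errors import InvalidInputError, SamplingError
from epievents.scaling import AnnotationSet, EventClass, EventPoint, Movie
from epievents.windows import (
    WindowSequence,
    augment_movie_temporal,
    augment_window,
    balance_classes,
    extract_window,
    load_windows,
    sample_control_windows,
    sample_event_windows,
    save_windows,
    split_train_validation,
    window_contains,
)


def _indexed_movie(nt=20, ny=64, nx=64):
    """Movie whose voxel values encode (t, y, x) for easy span checks."""
    t, y, x = np.meshgrid(
        np.arange(nt), np.arange(ny), np.arange(nx), indexing="ij"
    )
    return Movie((t * 10000 + y * 100 + x).astype(np.float32), 0.275, 5.0)


class TestExtractWindow:
    def test_temporal_span_five_before_four_after(self):
        movie = _indexed_movie()
        w = extract_window(movie, EventPoint(32, 32, 5))
        # frames 0..9: first frame of the window is movie frame 0
        assert w.voxels[0, 22, 22] == 0 * 10000 + 32 * 100 + 32
        assert w.voxels[9, 22, 22] == 9 * 10000 + 32 * 100 + 32

    def test_event_at_t0_pads_first_five_frames(self):
        movie = _indexed_movie()
        w = extract_window(movie, EventPoint(32, 32, 0))
        assert np.all(w.voxels[:5] == 0)
        assert w.voxels[5, 22, 22] == 32 * 100 + 32

    def test_corner_event_pads_two_margins(self):
        movie = _indexed_movie()
        w = extract_window(movie, EventPoint(0, 0, 10))
        assert w.shape == (10, 45, 45)
        assert np.all(w.voxels[:, :22, :] == 0)
        assert np.all(w.voxels[:, :, :22] == 0)
        assert w.voxels[5, 22, 22] == 10 * 10000

    def test_centre_pixel_at_22_22(self):
        movie = _indexed_movie()
        w = extract_window(movie, EventPoint(30, 40, 10))
        assert w.voxels[5, 22, 22] == 10 * 10000 + 40 * 100 + 30

    def test_centre_outside_movie_errors(self):
        movie = _indexed_movie()
        with pytest.raises(InvalidInputError):
            extract_window(movie, EventPoint(100, 10, 5))

    def test_translation_equivariance(self, rng):
        frames = rng.random((16, 80, 80)).astype(np.float32)
        m1 = Movie(frames, 0.275, 5.0)
        m2 = Movie(np.roll(frames, (3, 5), axis=(1, 2)), 0.275, 5.0)
        w1 = extract_window(m1, EventPoint(35, 30, 8))
        w2 = extract_window(m2, EventPoint(40, 33, 8))
        np.testing.assert_array_equal(w1.voxels, w2.voxels)


class TestEventWindows:
    def test_zero_jitter_equals_extract(self, small_movie):
        annots = AnnotationSet(
            [EventPoint(30, 30, 10, EventClass.EXTRUSION),
             EventPoint(10, 50, 5, EventClass.DIVISION)]
        )
        ws = sample_event_windows(small_movie, annots, 0, 0)
        for w, e in zip(ws, annots):
            np.testing.assert_array_equal(
                w.voxels, extract_window(small_movie, e).voxels
            )
            assert w.label is e.event_class

    def test_one_window_per_annotation(self, small_movie, rng):
        annots = AnnotationSet(
            [EventPoint(int(x), int(y), int(t), EventClass.EXTRUSION)
             for x, y, t in zip(rng.integers(5, 60, 20),
                                rng.integers(5, 60, 20),
                                rng.integers(0, 20, 20))]
        )
        assert len(sample_event_windows(small_movie, annots, 5, 1, rng)) == 20

    def test_jitter_bound_chebyshev(self, small_movie, rng):
        annots = AnnotationSet([EventPoint(30, 30, 10, EventClass.SOP)])
        for _ in range(50):
            w = sample_event_windows(small_movie, annots, 3, 1, rng)[0]
            _, cx, cy, ct = w.origin
            assert max(abs(cx - 30), abs(cy - 30)) <= 3
            assert abs(ct - 10) <= 1

    def test_label_overrides(self, small_movie, rng):
        annots = AnnotationSet([EventPoint(30, 30, 10, EventClass.DIVISION)])
        w = sample_event_windows(
            small_movie, annots, 0, 0, rng,
            label_overrides={EventClass.DIVISION: EventClass.NONE},
        )[0]
        assert w.label is EventClass.NONE


class TestControlWindows:
    def test_no_annotations_any_position(self, small_movie, rng):
        ws = sample_control_windows(small_movie, AnnotationSet([]), 25, rng)
        assert len(ws) == 25
        assert all(w.label is EventClass.NONE for w in ws)

    def test_controls_contain_no_annotation(self, small_movie, rng):
        annots = AnnotationSet(
            [EventPoint(int(x), int(y), int(t), EventClass.EXTRUSION)
             for x, y, t in zip(rng.integers(0, 64, 15),
                                rng.integers(0, 64, 15),
                                rng.integers(0, 20, 15))]
        )
        ws = sample_control_windows(small_movie, annots, 200, rng)
        for w in ws:  # brute-force containment oracle
            _, cx, cy, ct = w.origin
            for e in annots:
                assert not window_contains(cx, cy, ct, (10, 45, 45), e)

    def test_dense_annotations_raise_sampling_error(self, rng):
        movie = Movie(np.zeros((6, 50, 50), np.float32), 0.275, 5.0)
        annots = AnnotationSet(
            [EventPoint(x, y, t, EventClass.EXTRUSION)
             for x in range(0, 50, 10) for y in range(0, 50, 10)
             for t in range(6)]
        )
        with pytest.raises(SamplingError):
            sample_control_windows(movie, annots, 5, rng,
                                   max_attempts_per_window=50)


class TestBalance:
    def _mk(self, label):
        return WindowSequence(np.zeros((2, 3, 3), np.float32), label)

    @pytest.mark.parametrize(
        "counts, expected",
        [
            ({EventClass.NONE: 100, EventClass.EXTRUSION: 40}, 40),
            ({EventClass.NONE: 90, EventClass.EXTRUSION: 30,
              EventClass.SOP: 60, EventClass.DIVISION: 45}, 30),
        ],
    )
    def test_min_rule(self, counts, expected, rng):
        ws = [self._mk(c) for c, n in counts.items() for _ in range(n)]
        out = balance_classes(ws, rng)
        got = {}
        for w in out:
            got[w.label] = got.get(w.label, 0) + 1
        assert all(v == expected for v in got.values())
        assert max(got.values()) - min(got.values()) == 0

    def test_already_balanced_unchanged(self, rng):
        ws = [self._mk(EventClass.NONE)] * 7 + [self._mk(EventClass.SOP)] * 7
        assert balance_classes(ws, rng) == ws


class TestAugmentation:
    def test_shape_and_label_preserved(self, rng):
        w = WindowSequence(rng.random((10, 45, 45)).astype(np.float32),
                           EventClass.EXTRUSION)
        for _ in range(200):
            a = augment_window(w, rng)
            assert a.shape == w.shape
            assert a.label is w.label

    def test_zero_strength_is_identity(self, rng):
        w = WindowSequence(rng.random((10, 45, 45)).astype(np.float32))
        a = augment_window(w, rng, max_shift=0, max_tshift=0, noise_sigma=0,
                           patch_prob=0, illum_range=0)
        np.testing.assert_array_equal(a.voxels, w.voxels)

    def test_noise_sigma_calibrated(self, rng):
        # window with dynamic range exactly 100 -> absolute sigma = 5
        vox = rng.random((10, 45, 45)).astype(np.float32) * 90 + 5
        vox[0, 0, 0], vox[0, 0, 1] = 0.0, 100.0
        w = WindowSequence(vox)
        a = augment_window(w, rng, max_shift=0, max_tshift=0,
                           noise_sigma=0.05, patch_prob=0, illum_range=0)
        sd = float((a.voxels - w.voxels).std())
        assert abs(sd - 5.0) / 5.0 < 0.1


class TestTemporalAugmentation:
    def test_split_even_odd(self):
        movie = _indexed_movie(nt=10)
        a, b = augment_movie_temporal(movie)
        assert a.n_frames == 5 and b.n_frames == 5
        np.testing.assert_array_equal(a.frames, movie.frames[0::2])
        np.testing.assert_array_equal(b.frames, movie.frames[1::2])
        assert a.frame_interval == 2 * movie.frame_interval

    def test_too_short_errors(self):
        with pytest.raises(InvalidInputError):
            augment_movie_temporal(
                Movie(np.zeros((3, 8, 8), np.float32), 0.275, 5.0)
            )


class TestSplitAndPersistence:
    def test_split_fraction(self, rng):
        ws = [WindowSequence(np.zeros((2, 3, 3), np.float32), c)
              for c in (EventClass.NONE, EventClass.EXTRUSION) for _ in range(40)]
        ts = split_train_validation(ws, 0.25, rng)
        n_val = sum(s == "validation" for s in ts.split)
        assert n_val == 20  # 25% of 80, stratified 10+10
        assert len(ts.subset("train")) == 60

    def test_save_load_round_trip(self, tmp_path, rng):
        ws = [
            WindowSequence(rng.random((4, 9, 9)).astype(np.float32),
                           EventClass.EXTRUSION, ("m0", 5, 6, 7)),
            WindowSequence(rng.random((4, 9, 9)).astype(np.float32),
                           EventClass.NONE, ("m1", 1, 2, 3)),
        ]
        save_windows(ws, tmp_path)
        back = load_windows(tmp_path)
        assert len(back) == 2
        for w, b in zip(ws, back):
            np.testing.assert_array_equal(w.voxels, b.voxels)
            assert w.label is b.label
            assert tuple(w.origin) == tuple(b.origin)
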