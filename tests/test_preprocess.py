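"""Segmentation, normalization and balancing contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deepeeg.errors import DegenerateChannelError
from deepeeg.preprocess import (
    SegmentSet,
    balance_classes,
    invert_minmax,
    minmax_scale,
    reshape_for_model,
    segment_recording,
    zscore,
)
from deepeeg.records import EEGRecording, SeizureInterval


def _rec(duration_s, fs=10.0, n_channels=2, annotations=(), seed=0):
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    return EEGRecording(
        signal=rng.standard_normal((n_channels, n)),
        fs=fs,
        annotations=list(annotations),
    )


class TestSegmentation:
    def test_floor_count_without_annotations(self):
        # 23.6 s at 4-s windows -> floor(23.6/4) = 5 segments
        segs = segment_recording(_rec(23.6), 4.0)
        assert len(segs) == 5
        assert set(segs.labels) == {0}

    def test_containment_labeling(self):
        rec = _rec(10.0, annotations=[SeizureInterval(4.0, 8.0)])
        segs = segment_recording(rec, 2.0)
        assert segs.labels.tolist() == [0, 0, 1, 1, 0]

    def test_straddling_windows_dropped(self):
        rec = _rec(10.0, annotations=[SeizureInterval(3.0, 5.0)])
        segs = segment_recording(rec, 4.0)
        # [0,4) and [4,8) both straddle the seizure; [8,10) is incomplete
        assert len(segs) == 0

    def test_reassembly_exact(self):
        rec = _rec(13.0)
        segs = segment_recording(rec, 2.0)
        rebuilt = np.concatenate(list(segs.tensor), axis=1)
        assert np.array_equal(rebuilt, rec.signal[:, : rebuilt.shape[1]])

    def test_short_recording_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="shorter than one"):
            segs = segment_recording(_rec(1.5), 2.0)
        assert len(segs) == 0

    def test_ictal_window_count_matches_interval_arithmetic(self):
        rec = _rec(60.0, annotations=[SeizureInterval(10.0, 30.0)])
        segs = segment_recording(rec, 4.0)
        # fully-ictal windows: [12,16) [16,20) [20,24) [24,28) -> 4
        # (window grid is 0,4,8,...; [8,12) and [28,32) straddle)
        assert int(segs.labels.sum()) == 4
        assert len(segs) == 15 - 2


class TestZScore:
    def test_pooled_moments(self, rng):
        segs = SegmentSet(
            tensor=3.0 + 2.0 * rng.standard_normal((100, 3, 100)),
            labels=np.zeros(100), fs=100.0, segment_length_s=1.0,
        )
        out, params = zscore(segs)
        pooled = out.tensor.transpose(1, 0, 2).reshape(3, -1)
        assert np.all(np.abs(pooled.mean(axis=1)) < 1e-6)
        assert np.all(np.abs(pooled.std(axis=1) - 1.0) < 1e-6)

    def test_idempotent(self, rng):
        segs = SegmentSet(
            tensor=rng.standard_normal((20, 2, 50)), labels=np.zeros(20),
            fs=50.0, segment_length_s=1.0,
        )
        once, _ = zscore(segs)
        twice, _ = zscore(once)
        assert np.allclose(once.tensor, twice.tensor, atol=1e-6)

    def test_constant_channel_rejected_by_name(self, rng):
        t = rng.standard_normal((10, 3, 20))
        t[:, 1, :] = 4.2
        segs = SegmentSet(tensor=t, labels=np.zeros(10), fs=20.0,
                          segment_length_s=1.0)
        with pytest.raises(DegenerateChannelError, match=r"\[1\]"):
            zscore(segs)

    def test_params_reused_on_held_out(self, rng):
        train = SegmentSet(tensor=rng.standard_normal((30, 2, 40)),
                           labels=np.zeros(30), fs=40.0, segment_length_s=1.0)
        test = SegmentSet(tensor=5 + rng.standard_normal((10, 2, 40)),
                          labels=np.zeros(10), fs=40.0, segment_length_s=1.0)
        _, params = zscore(train)
        out, _ = zscore(test, params)
        expected = (test.tensor - params.mu[None, :, None]) / params.sigma[None, :, None]
        assert np.allclose(out.tensor, expected)


class TestMinMax:
    def test_fitted_data_spans_unit_interval(self, rng):
        segs = SegmentSet(tensor=-3 + 8 * rng.random((10, 2, 30)),
                          labels=np.zeros(10), fs=30.0, segment_length_s=1.0)
        out, params = minmax_scale(segs)
        assert out.tensor.min() == 0.0
        assert out.tensor.max() == 1.0

    def test_held_out_values_clipped(self, rng):
        train = SegmentSet(tensor=rng.random((10, 1, 20)), labels=np.zeros(10),
                           fs=20.0, segment_length_s=1.0)
        _, params = minmax_scale(train)
        test = SegmentSet(tensor=10 * np.ones((2, 1, 20)), labels=np.zeros(2),
                          fs=20.0, segment_length_s=1.0)
        out, _ = minmax_scale(test, params)
        assert np.all(out.tensor == 1.0)

    def test_inverse_round_trip(self, rng):
        segs = SegmentSet(tensor=rng.standard_normal((10, 2, 25)),
                          labels=np.zeros(10), fs=25.0, segment_length_s=1.0)
        out, params = minmax_scale(segs)
        back = invert_minmax(out.tensor, params)
        assert np.max(np.abs(back - segs.tensor)) < 1e-12

    def test_degenerate_range_rejected(self):
        segs = SegmentSet(tensor=np.full((4, 1, 10), 2.0), labels=np.zeros(4),
                          fs=10.0, segment_length_s=1.0)
        with pytest.raises(ValueError, match="degenerate"):
            minmax_scale(segs)


class TestBalance:
    def _segments(self, n0, n1, rng):
        n = n0 + n1
        # unique per-segment constant values let us track identity
        tensor = np.arange(n, dtype=float)[:, None, None] * np.ones((n, 1, 10))
        labels = np.array([0] * n0 + [1] * n1)
        perm = rng.permutation(n)
        return SegmentSet(tensor=tensor[perm], labels=labels[perm], fs=10.0,
                          segment_length_s=1.0)

    def test_downsamples_majority_to_minority(self, rng):
        segs = self._segments(300, 100, rng)
        out = balance_classes(segs, seed=0)
        assert out.class_counts() == (100, 100)

    def test_no_duplication_and_minority_untouched(self, rng):
        segs = self._segments(300, 100, rng)
        out = balance_classes(segs, seed=1)
        ids = out.tensor[:, 0, 0]
        assert len(np.unique(ids)) == len(ids)
        minority_ids = set(segs.tensor[segs.labels == 1, 0, 0])
        assert set(ids[out.labels == 1]) == minority_ids

    def test_already_balanced_keeps_multiset(self, rng):
        segs = self._segments(50, 50, rng)
        out = balance_classes(segs, seed=2)
        assert sorted(out.tensor[:, 0, 0]) == sorted(segs.tensor[:, 0, 0])

    def test_deterministic(self, rng):
        segs = self._segments(80, 40, rng)
        a = balance_classes(segs, seed=3)
        b = balance_classes(segs, seed=3)
        assert np.array_equal(a.tensor, b.tensor)
        assert np.array_equal(a.labels, b.labels)

    def test_empty_class_rejected(self, rng):
        segs = self._segments(10, 0, rng)
        segs.labels[:] = 0
        with pytest.raises(ValueError, match="balance"):
            balance_classes(segs, seed=0)


@settings(deadline=None, max_examples=20)
@given(
    n=st.integers(1, 8),
    c=st.integers(1, 5),
    t=st.sampled_from([16, 32, 64]),
)
def test_reshape_for_model_shapes(n, c, t):
    segs = SegmentSet(tensor=np.zeros((n, c, t)), labels=np.zeros(n),
                      fs=float(t), segment_length_s=1.0)
    planes = reshape_for_model(segs)
    assert planes.shape == (n, c, t, 1)
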