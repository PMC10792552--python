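"""Suppression segmentation: oracle equivalence, merge rules, ratios, timestamps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from anesmap import Annotations, Recording, detect_band_suppressions, detect_ies
from anesmap.segments import intersect, total_duration
from anesmap.signal_io import make_grid
from anesmap.suppression import (
    SegmentList,
    detect_suppressions,
    ies_summary,
    suppression_ratios,
    sweep_ies_threshold,
)

FS = 500.0


def oracle_detect(signal, fs, threshold, min_dur_s=1.0, merge_gap_s=0.5):
    """Brute-force run-length scanner implementing the same definition:
    maximal |x| < threshold runs, duration filter, then gap merging."""
    below = np.abs(signal) < threshold
    runs = []
    i = 0
    n = len(signal)
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            if (j + 1 - i) / fs >= min_dur_s:
                runs.append([i / fs, (j + 1) / fs])
            i = j + 1
        else:
            i += 1
    merged = []
    for s, e in runs:
        if merged and s - merged[-1][1] < merge_gap_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return np.asarray(merged).reshape(-1, 2)


def am_noise(rng, dur_s, fs, block_s=0.5):
    """Noise whose amplitude jumps between blocks, creating quiet runs of
    assorted lengths around the detection threshold."""
    n = int(dur_s * fs)
    nb = int(block_s * fs)
    env = np.repeat(rng.uniform(0.0, 2.0, n // nb + 1), nb)[:n]
    return rng.normal(0, 1, n) * env


class TestDetectSuppressions:
    def test_flat_region_detected(self):
        x = np.sin(2 * np.pi * 8 * np.arange(int(30 * FS)) / FS) * 10
        x[int(10 * FS) : int(20 * FS)] = 0.0
        segs = detect_suppressions(x, FS, threshold=1.0)
        assert len(segs) == 1
        assert segs[0, 1] - segs[0, 0] == pytest.approx(10.0, abs=0.1)

    def test_close_detections_merged(self):
        x = np.full(int(4 * FS), 10.0)
        x[: int(1.2 * FS)] = 0.0
        x[int(1.5 * FS) : int(2.7 * FS)] = 0.0  # 0.3 s gap between runs
        segs = detect_suppressions(x, FS, threshold=1.0)
        assert len(segs) == 1
        assert segs[0, 1] - segs[0, 0] == pytest.approx(2.7, abs=0.05)

    def test_oscillation_zero_crossings_not_detected(self):
        x = 2.0 * np.sin(2 * np.pi * 8 * np.arange(int(30 * FS)) / FS)
        segs = detect_suppressions(x, FS, threshold=1.0)
        assert len(segs) == 0

    def test_masked_samples_never_suppression(self):
        x = np.zeros(int(10 * FS))
        mask = np.zeros(x.size, bool)
        mask[: x.size // 2] = True
        segs = detect_suppressions(x, FS, threshold=1.0, mask=mask)
        assert segs[0, 0] == pytest.approx(5.0, abs=0.01)

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            detect_suppressions(np.array([]), FS, 1.0)

    def test_matches_oracle_on_random_signals(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            x = am_noise(rng, 10.0, 100.0)
            got = detect_suppressions(x, 100.0, threshold=0.8)
            want = oracle_detect(x, 100.0, threshold=0.8)
            assert np.array_equal(got, want)


@given(seed=st.integers(0, 10_000), thr=st.floats(0.1, 2.0))
@settings(max_examples=40, deadline=None)
def test_oracle_equivalence_property(seed, thr):
    rng = np.random.default_rng(seed)
    x = am_noise(rng, 8.0, 100.0)
    assert np.array_equal(
        detect_suppressions(x, 100.0, thr), oracle_detect(x, 100.0, thr)
    )


@given(seed=st.integers(0, 10_000))
@settings(max_examples=25, deadline=None)
def test_duration_monotone_in_threshold(seed):
    rng = np.random.default_rng(seed)
    x = am_noise(rng, 8.0, 100.0)
    durs = [
        total_duration(detect_suppressions(x, 100.0, t))
        for t in (0.2, 0.5, 1.0, 2.0, 5.0)
    ]
    assert all(a <= b + 1e-9 for a, b in zip(durs, durs[1:]))


class TestDetectIesOnScenarios:
    def test_light_scenario_detects_nothing(self, light_bundle):
        assert len(light_bundle.result.ies) == 0

    def test_all_flat_recording_single_segment(self):
        rec = Recording(eeg=np.zeros(int(10 * FS)) + 1e-6, fs=FS)
        segs = detect_ies(rec)
        assert len(segs) == 1
        assert segs.segments[0, 1] - segs.segments[0, 0] == pytest.approx(10.0, abs=0.01)

    def test_band_suppressions_disjoint_from_ies(self, deep_bundle):
        res = deep_bundle.result
        for band_segs in (res.theta_suppression, res.delta_suppression):
            assert total_duration(intersect(res.ies.segments, band_segs.segments)) == 0.0

    def test_pure_delta_yields_theta_suppression(self):
        # 3 Hz oscillation only: the 5-10 Hz band is empty, so nearly the
        # whole trace is a theta suppression and none of it delta.
        t = np.arange(int(120 * FS)) / FS
        rec = Recording(eeg=30 * np.sin(2 * np.pi * 3 * t), fs=FS)
        ies = detect_ies(rec)
        th = detect_band_suppressions(rec, "theta", ies)
        de = detect_band_suppressions(rec, "delta", ies)
        assert total_duration(th.segments) > 0.9 * 120
        assert total_duration(de.segments) == 0.0

    def test_unknown_band_rejected(self, deep_bundle):
        with pytest.raises(ValueError):
            detect_band_suppressions(deep_bundle.rec, "alpha", deep_bundle.result.ies)


class TestRatiosAndSummary:
    def grid(self, dur=100.0):
        return make_grid(dur, 20.0, 10.0)

    def test_full_half_empty_windows(self):
        grid = self.grid()
        segs = {"ies": np.array([[0.0, 30.0], [40.0, 50.0]])}
        r = suppression_ratios(segs, grid).ies_ratio
        # window centered 10 = [0,20) fully inside -> 1.0
        assert r[0] == pytest.approx(1.0)
        # window centered 40 = [30,50): covered on [40,50) -> 0.5
        assert r[3] == pytest.approx(0.5)
        # window centered 80 = [70,90): empty
        assert r[7] == pytest.approx(0.0)

    def test_ratios_bounded(self, deep_bundle):
        r = deep_bundle.result.ratios
        for arr in (r.ies_ratio, r.theta_ratio, r.delta_ratio):
            vals = arr[~np.isnan(arr)]
            assert np.all(vals >= 0.0) and np.all(vals <= 1.0)

    def test_no_ies_gives_absent_events(self):
        grid = self.grid()
        ann = Annotations(tau_iso_start=10.0, tau_iso_stop=90.0)
        empty = SegmentList("ies", np.empty((0, 2)))
        ratios = suppression_ratios({"ies": empty.segments}, grid)
        summ = ies_summary(empty, ratios, ann)
        assert summ.tau_ies1 is None
        assert summ.delta_ies == 0.0
        assert summ.tau_s is None

    def test_single_short_segment_no_strong_ies(self):
        grid = make_grid(200.0, 20.0, 10.0)
        ann = Annotations(tau_iso_start=10.0, tau_iso_stop=190.0)
        sl = SegmentList("ies", np.array([[50.0, 80.0]]))
        ratios = suppression_ratios({"ies": sl.segments}, grid)
        summ = ies_summary(sl, ratios, ann)
        assert summ.delta_ies == pytest.approx(30.0)
        assert summ.tau_ies1 == pytest.approx(40.0)
        # a 30 s segment cannot keep the ratio above 0.25 for a full 40 s run
        # of windows... it actually can (windows overlapping the segment span
        # 50 s); verify against the directly computed ratio series instead.
        ok = ratios.ies_ratio > 0.25
        runs_ok = any(ok[i : i + 5].all() for i in range(len(ok) - 4))
        assert (summ.tau_s is not None) == runs_ok

    def test_strong_ies_time_on_deep_scenario(self, deep_bundle):
        det = deep_bundle.result.ies_sum.tau_s
        true = deep_bundle.truth.true_events.tau_s
        assert det == pytest.approx(true, abs=10.0)


class TestThresholdSweep:
    def test_monotone_and_plateau(self, deep_bundle):
        rs = np.array([0.0, 0.1, 0.3, 0.5, 0.7, 0.9, 2.0, 50.0])
        table = sweep_ies_threshold(deep_bundle.rec, rs)
        durs = table[:, 1]
        assert durs[0] == 0.0
        assert np.all(np.diff(durs) >= -1e-9)
        # r large enough swallows the entire recording
        assert durs[-1] == pytest.approx(deep_bundle.rec.duration_s, rel=0.01)
        # plateau around the operating point: detected ~ planted duration
        planted = total_duration(deep_bundle.truth.planted_ies)
        at = lambda r: durs[np.flatnonzero(rs == r)[0]]
        for r in (0.5, 0.7, 0.9):
            assert at(r) == pytest.approx(planted, rel=0.1)
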