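"""Recording I/O, artifact masking, filtering and window-grid behavior."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from anesmap import Recording, bandpass, make_grid, mask_artifacts, read_recording, rms, write_edf, write_text
from anesmap.signal_io import FormatError

FS = 500.0


def sine(f, dur, fs=FS, amp=1.0):
    return amp * np.sin(2 * np.pi * f * np.arange(int(dur * fs)) / fs)


class TestMakeGrid:
    def test_enumerated_centers(self):
        grid = make_grid(100.0, 20.0, 10.0)
        assert np.allclose(grid.centers, np.arange(10.0, 91.0, 10.0))
        assert len(grid.centers) == 9

    def test_single_window(self):
        grid = make_grid(60.0, 60.0, 30.0)
        assert np.allclose(grid.centers, [30.0])

    def test_width_exceeding_duration_rejected(self):
        with pytest.raises(ValueError):
            make_grid(10.0, 20.0, 10.0)

    def test_spacing_and_coverage(self):
        grid = make_grid(200.0, 20.0, 10.0)
        assert np.allclose(np.diff(grid.centers), grid.width_s - grid.overlap_s)
        b = grid.bounds()
        assert b[0, 0] == 0.0
        assert b[-1, 1] <= 200.0
        # windows overlap: the union covers [0, last end] without holes
        assert np.all(b[1:, 0] <= b[:-1, 1])


class TestRms:
    def test_hand_arithmetic(self):
        assert rms(np.array([3.0, 4.0])) == pytest.approx(np.sqrt(12.5))

    def test_constant(self):
        assert rms(np.full(100, -5.0)) == pytest.approx(5.0)

    def test_sinusoid(self):
        assert rms(sine(8, 10)) == pytest.approx(1 / np.sqrt(2), rel=1e-3)

    def test_fully_masked_rejected(self):
        with pytest.raises(ValueError):
            rms(np.ones(10), mask=np.ones(10, bool))


class TestBandpass:
    def test_passband_amplitude_and_phase(self):
        x = sine(8, 30)
        y = bandpass(x, 5, 10, FS)
        core = slice(5000, 10000)
        assert np.max(np.abs(y[core])) > 0.85
        # zero-phase: cross-correlation peaks at zero lag
        c = np.correlate(y[core], x[core], "same")
        assert abs(np.argmax(c) - len(c) // 2) <= 1

    def test_stopband_attenuation(self):
        x = sine(8, 30)
        y = bandpass(x, 2.5, 4.5, FS)
        assert np.std(y) < 0.2 * np.std(x)

    def test_zero_signal(self):
        assert np.allclose(bandpass(np.zeros(1000), 5, 10, FS), 0.0)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(1000), 10, 5, FS)

    def test_center_frequency_preserved_under_repeated_filtering(self):
        # at the filter's geometric center the gain is unity, so repeated
        # passes leave the tone unchanged
        fc = np.sqrt(5.0 * 10.0)
        x = sine(fc, 30)
        once = bandpass(x, 5, 10, FS)
        twice = bandpass(once, 5, 10, FS)
        core = slice(5000, 10000)
        assert np.std(twice[core]) == pytest.approx(np.std(once[core]), rel=1e-4)
        assert np.std(once[core]) == pytest.approx(np.std(x[core]), rel=1e-3)


class TestMaskArtifacts:
    def test_flat_dropout_run_masked_exactly(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 10, int(20 * FS))
        i0, i1 = int(5 * FS), int(10 * FS)
        x[i0:i1] = 0.0
        rec = mask_artifacts(Recording(eeg=x, fs=FS))
        # brute-force oracle: scan for constant runs >= 0.5 s
        expect = np.zeros(x.size, bool)
        j = 0
        while j < x.size:
            k = j
            while k + 1 < x.size and x[k + 1] == x[j]:
                k += 1
            if k - j + 1 >= 0.5 * FS:
                expect[j : k + 1] = True
            j = k + 1
        assert np.array_equal(rec.artifact_mask, expect)

    def test_hysteresis_masks_whole_excursion(self):
        # 2000 uV spike decaying exponentially through 1200 -> 0.08 uV,
        # embedded in a quiet but nonzero baseline.
        n = int(20 * FS)
        rng = np.random.default_rng(2)
        x = rng.normal(0, 0.02, n)  # below the low threshold
        t = np.arange(int(5 * FS)) / FS
        spike = 2000.0 * np.exp(-t / 0.4)
        x[int(5 * FS) : int(10 * FS)] += spike
        rec = mask_artifacts(Recording(eeg=x, fs=FS))
        # flood-fill oracle: the connected region above 0.08 touching 1200
        above = np.abs(x) > 0.08
        strong = np.flatnonzero(np.abs(x) >= 1200.0)
        expect = np.zeros(n, bool)
        for s in strong:
            a = s
            while a > 0 and above[a - 1]:
                a -= 1
            b = s
            while b + 1 < n and above[b + 1]:
                b += 1
            expect[a : b + 1] = True
        assert np.array_equal(rec.artifact_mask, expect)
        assert expect.any()

    def test_clean_trace_unmasked_and_values_untouched(self):
        x = sine(8, 20, amp=50.0) + 5.0
        rec = mask_artifacts(Recording(eeg=x, fs=FS))
        assert not rec.artifact_mask.any()
        assert np.array_equal(rec.eeg, x)


class TestFileRoundTrips:
    def test_text_round_trip_infers_rate(self, tmp_path):
        rng = np.random.default_rng(3)
        rec = Recording(eeg=rng.normal(0, 20, 1000), fs=250.0)
        path = write_text(rec, tmp_path / "rec.txt")
        back = read_recording(path)
        assert back.fs == pytest.approx(250.0, rel=1e-6)
        assert np.allclose(back.eeg, rec.eeg, atol=1e-5)

    def test_irregular_time_column_reports_first_bad_row(self, tmp_path):
        t = np.arange(100) / 100.0
        t[40:] += 0.05  # jump
        path = tmp_path / "bad.txt"
        np.savetxt(path, np.column_stack([t, np.zeros(100)]))
        with pytest.raises(FormatError, match="row 40"):
            read_recording(path)

    def test_edf_round_trip_within_quantization(self, tmp_path):
        rng = np.random.default_rng(4)
        rec = Recording(eeg=rng.normal(0, 30, 5000), emg=rng.normal(0, 100, 5000), fs=500.0)
        path = write_edf(rec, tmp_path / "rec.edf")
        back = read_recording(path)
        assert back.fs == 500.0
        quant = np.max(np.abs(rec.eeg)) / 32767
        assert np.max(np.abs(back.eeg - rec.eeg)) < 2 * quant
        assert np.max(np.abs(back.emg - rec.emg)) < 2 * np.max(np.abs(rec.emg)) / 32767

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(FormatError):
            read_recording(tmp_path / "nope.txt")


@given(
    width=st.floats(1.0, 30.0),
    frac=st.floats(0.0, 0.9),
    duration=st.floats(31.0, 500.0),
)
@settings(max_examples=50, deadline=None)
def test_grid_invariants(width, frac, duration):
    """Every window lies inside the recording; spacing is width - overlap."""
    overlap = width * frac
    grid = make_grid(duration, width, overlap)
    b = grid.bounds()
    assert b[0, 0] >= -1e-9
    assert b[-1, 1] <= duration + 1e-9
    if len(grid.centers) > 1:
        assert np.allclose(np.diff(grid.centers), width - overlap)
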