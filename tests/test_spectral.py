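"""Spectral decomposition: PSD, IRASA, aperiodic/Gaussian fits, tracking."""

import numpy as np
import pytest

from anesmap import Annotations, Recording, generate_aperiodic
from anesmap.params import SpectralParams
from anesmap.spectral import (
    AperiodicFit,
    GaussianComponent,
    PowerRatioSeries,
    SpectralFrame,
    band_prominence_times,
    fit_aperiodic,
    fit_oscillatory,
    irasa_aperiodic,
    power_ratios,
    theta_decay,
    track_rhythms,
    welch_psd,
)
from anesmap.signal_io import make_grid

FS = 500.0
PARAMS = SpectralParams()


def tone(f, dur, amp=1.0):
    return amp * np.sin(2 * np.pi * f * np.arange(int(dur * FS)) / FS)


class TestWelch:
    def test_peak_at_tone_frequency(self):
        f, p = welch_psd(tone(8.0, 60), FS)
        assert f[np.argmax(p)] == pytest.approx(8.0, abs=0.11)

    def test_grid_resolution_and_range(self):
        f, _ = welch_psd(np.random.default_rng(0).normal(size=int(60 * FS)), FS)
        assert np.allclose(np.diff(f), 0.2)
        assert f[0] == pytest.approx(0.2) and f[-1] == pytest.approx(15.0)

    def test_white_noise_parseval(self):
        x = np.random.default_rng(1).normal(size=int(120 * FS))
        f, p = welch_psd(x, FS)
        # PSD of unit-variance white noise: 1/fs per Hz -> integral over the
        # 0.2-15 Hz slice is the band fraction of the variance
        band_power = np.trapezoid(p, f)
        assert band_power == pytest.approx((15.0 - 0.2) / 250.0, rel=0.1)

    def test_zero_signal(self):
        _, p = welch_psd(np.zeros(int(10 * FS)), FS)
        assert np.allclose(p, 0.0)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            welch_psd(np.zeros(int(2 * FS)), FS)


class TestIrasa:
    def test_fractal_part_left_intact(self):
        x = generate_aperiodic(1, 0.1, 2, 120, FS, seed=2)
        f, m = irasa_aperiodic(x, FS)
        _, raw = welch_psd(x, FS)
        sel = (f >= 1) & (f <= 10)
        assert np.median(np.abs(m[sel] / raw[sel] - 1)) < 0.2

    def test_oscillation_suppressed_at_peak(self):
        x = generate_aperiodic(1, 0.1, 2, 120, FS, seed=3) + tone(8.0, 120, amp=2.0)
        f, m = irasa_aperiodic(x, FS)
        _, raw = welch_psd(x, FS)
        at8 = np.argmin(np.abs(f - 8.0))
        assert m[at8] < 0.2 * raw[at8]

    def test_zero_signal(self):
        _, m = irasa_aperiodic(np.zeros(int(60 * FS)), FS)
        assert np.allclose(m, 0.0)


class TestFitAperiodic:
    GRID = np.arange(0.2, 15.0001, 0.2)

    def test_exact_curve_recovered(self):
        psd = 2.0 / (0.5 + self.GRID**2)
        fit = fit_aperiodic(self.GRID, psd)
        assert fit.a == pytest.approx(2.0, rel=0.01)
        assert fit.c == pytest.approx(0.5, abs=0.01)
        assert fit.p == pytest.approx(2.0, rel=0.01)

    def test_zero_offset_power_law(self):
        psd = 1.0 / self.GRID
        fit = fit_aperiodic(self.GRID, psd)
        assert fit.p == pytest.approx(1.0, rel=0.01)
        assert fit.c < 0.01

    def test_flat_psd_zero_exponent(self):
        fit = fit_aperiodic(self.GRID, np.full(self.GRID.size, 3.0))
        assert fit.p < 0.05


class TestFitOscillatory:
    GRID = np.arange(0.2, 15.0001, 0.2)

    def raw(self, components, noise=0.0, seed=0):
        ap = AperiodicFit(a=1.0, c=0.1, p=2.0, rss=0.0)
        psd = ap(self.GRID).copy()
        for b, f0, s in components:
            psd += b * np.exp(-((self.GRID - f0) ** 2) / (2 * s**2))
        if noise:
            psd *= 1 + noise * np.random.default_rng(seed).normal(size=psd.size)
        return psd, ap

    def test_planted_theta_recovered(self):
        psd, ap = self.raw([(1.0, 8.0, 0.5)])
        comps = fit_oscillatory(self.GRID, psd, ap)
        th = [c for c in comps if c.band == "theta"]
        assert len(th) == 1
        assert th[0].f == pytest.approx(8.0, abs=0.3)
        assert th[0].sigma == pytest.approx(0.5, abs=0.15)

    def test_narrow_peak_pruned(self):
        psd, ap = self.raw([(1.0, 8.0, 0.05)])
        assert fit_oscillatory(self.GRID, psd, ap) == []

    def test_broad_peak_pruned(self):
        psd, ap = self.raw([(1.0, 8.0, 3.0)])
        comps = fit_oscillatory(self.GRID, psd, ap)
        assert all(c.band != "theta" or not (0.2 <= c.sigma <= 2) for c in comps) or comps == []
        assert comps == []

    def test_small_amplitude_pruned(self):
        # a weak peak riding on a broad component: the broad spread sets the
        # residual std well above the peak amplitude -> discarded
        psd, ap = self.raw([(1.0, 4.0, 3.0), (0.1, 10.0, 0.5)])
        assert fit_oscillatory(self.GRID, psd, ap) == []

    def test_area_rule_selects_larger(self):
        psd, ap = self.raw([(1.0, 6.0, 0.5), (2.0, 9.0, 0.5)])
        th = [c for c in fit_oscillatory(self.GRID, psd, ap) if c.band == "theta"]
        assert len(th) == 1
        assert th[0].f == pytest.approx(9.0, abs=0.3)

    def test_delta_band_assignment(self):
        psd, ap = self.raw([(2.0, 3.0, 0.5)])
        de = [c for c in fit_oscillatory(self.GRID, psd, ap) if c.band == "delta"]
        assert len(de) == 1
        assert de[0].f == pytest.approx(3.0, abs=0.3)


def frame(t, theta=None, delta=None):
    mk = lambda fd: None if fd is None else GaussianComponent(b=1.0, f=fd[0], sigma=fd[1], band="x")
    return SpectralFrame(center_s=t, aperiodic=None, theta=mk(theta), delta=mk(delta), valid=True)


class TestTracking:
    def test_linear_interpolation_between_detections(self):
        frames = [frame(30, theta=(8.0, 0.4)), frame(60, theta=(7.0, 0.6))]
        tr = track_rhythms(frames)["theta"]
        assert tr.f_at(45.0) == pytest.approx(7.5)
        assert tr.sigma_at(45.0) == pytest.approx(0.5)

    def test_isolated_detection_dropped(self):
        frames = [frame(30), frame(60, theta=(8.0, 0.5)), frame(90)]
        tr = track_rhythms(frames)["theta"]
        assert tr.runs == []
        assert np.isnan(tr.f_at(60.0))

    def test_envelope_identity(self):
        frames = [frame(30, theta=(8.0, 0.4)), frame(60, theta=(8.0, 0.4)), frame(90, theta=(8.0, 0.4))]
        tr = track_rhythms(frames)["theta"]
        t = np.linspace(30, 90, 13)
        assert np.allclose(tr.up(t) - tr.low(t), 2 * tr.sigma_at(t))

    def test_exact_at_frame_centers(self):
        frames = [frame(30, theta=(8.0, 0.4)), frame(60, theta=(7.2, 0.5)), frame(90, theta=(6.1, 0.6))]
        tr = track_rhythms(frames)["theta"]
        assert tr.f_at(60.0) == pytest.approx(7.2)


class TestThetaDecay:
    ANN = Annotations(tau_iso_start=180.0, tau_iso_stop=900.0)

    def synthetic_track(self, f_of_t, centers):
        frames = [frame(t, theta=(f_of_t(t), 0.5)) for t in centers]
        return track_rhythms(frames)["theta"], centers

    def test_decay_at_induction(self):
        centers = np.arange(30.0, 1200.0, 30.0)
        f_of_t = lambda t: 8.0 if t < 180 else max(6.0, 8.0 - (t - 180) / 60.0)
        tr, c = self.synthetic_track(f_of_t, centers)
        res = theta_decay(tr, self.ANN, c)
        assert res.tau_decay is not None and res.tau_decay <= 60.0
        assert res.slope_hz_per_min == pytest.approx(-1.0, abs=0.35)

    def test_constant_frequency_never_decays(self):
        centers = np.arange(30.0, 1200.0, 30.0)
        tr, c = self.synthetic_track(lambda t: 8.0, centers)
        res = theta_decay(tr, self.ANN, c)
        assert res.tau_decay is None and res.slope_hz_per_min is None

    def test_delayed_decay_located(self):
        centers = np.arange(30.0, 1200.0, 30.0)
        start = 360.0  # 3 min after induction
        f_of_t = lambda t: 8.0 if t < start else max(5.0, 8.0 - (t - start) / 60.0)
        tr, c = self.synthetic_track(f_of_t, centers)
        res = theta_decay(tr, self.ANN, c)
        assert res.tau_decay == pytest.approx(start - 180.0, abs=30.0)


class TestPowerRatios:
    # The soft (order-1) Butterworth bands do not have unit gain away from
    # their center frequency, so a pure tone's ratio sits below 1; the test
    # checks near-complete capture in-band and near-zero leakage cross-band.

    def test_pure_theta_tone(self):
        rec = Recording(eeg=tone(8.0, 120, amp=10.0), fs=FS)
        pr = power_ratios(rec)
        assert np.nanmedian(pr.p_theta) > 0.8
        assert np.nanmedian(pr.p_delta) < 0.05

    def test_pure_delta_tone(self):
        rec = Recording(eeg=tone(3.0, 120, amp=10.0), fs=FS)
        pr = power_ratios(rec)
        assert np.nanmedian(pr.p_delta) > 0.7
        assert np.nanmedian(pr.p_theta) < 0.05

    def test_zero_signal_missing(self):
        rec = Recording(eeg=np.zeros(int(60 * FS)), fs=FS)
        pr = power_ratios(rec)
        assert np.isnan(pr.p_theta).all()

    def test_bounded_up_to_leakage(self, deep_bundle):
        pr = deep_bundle.result.power
        for arr in (pr.p_theta, pr.p_delta):
            vals = arr[~np.isnan(arr)]
            assert np.all(vals >= 0.0) and np.all(vals <= 1.05)


class TestProminence:
    ANN = Annotations(tau_iso_start=100.0, tau_iso_stop=500.0)

    def series(self, p_delta, p_theta=None, dur=600.0):
        grid = make_grid(dur, 20.0, 0.0)
        n = len(grid.centers)
        pd_ = np.asarray(p_delta, dtype=float)
        pt = np.full(n, 0.5) if p_theta is None else np.asarray(p_theta, dtype=float)
        return PowerRatioSeries(grid=grid, p_theta=pt, p_delta=pd_)

    def test_short_excursion_not_prominent(self):
        grid = make_grid(600.0, 20.0, 0.0)
        n = len(grid.centers)
        pd_ = np.full(n, 0.05)
        # 40 s above threshold (2 windows) < 1 min persistence
        i0 = np.argmin(np.abs(grid.centers - 200.0))
        pd_[i0 : i0 + 2] = 0.5
        res = band_prominence_times(self.series(pd_), self.ANN)
        assert res.tau_delta_app is None

    def test_sustained_appearance_and_dampening(self):
        grid = make_grid(600.0, 20.0, 0.0)
        c = grid.centers
        pd_ = np.where((c >= 200) & (c < 400), 0.5, 0.05)
        res = band_prominence_times(self.series(pd_), self.ANN)
        assert res.tau_delta_app == pytest.approx(110.0, abs=20.0)  # 210 abs
        assert res.tau_delta_disp == pytest.approx(310.0, abs=20.0)  # 410 abs

    def test_dampening_requires_appearance(self):
        res = band_prominence_times(self.series(np.full(30, 0.05)), self.ANN)
        assert res.tau_delta_app is None and res.tau_delta_disp is None

    def test_scenario_times_match_truth(self, deep_bundle):
        prom = deep_bundle.result.prominence
        true = deep_bundle.truth.true_events
        assert prom.tau_delta_app == pytest.approx(true.tau_delta_app, abs=20.0)
        assert prom.tau_theta_disp == pytest.approx(true.tau_theta_disp, abs=20.0)
        assert prom.tau_delta_disp == pytest.approx(true.tau_delta_disp, abs=20.0)
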