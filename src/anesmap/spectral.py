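"""Sliding-window spectral decomposition and rhythm tracking.

The power spectral density of each 60 s window (30 s step) is separated into

* an aperiodic component ``a / (c + f^p)`` -- the broadband 1/f-like decay,
  with an offset ``c`` that keeps the model finite at f = 0 and markedly
  reduces the low-frequency fit error compared to a pure power law -- and
* an oscillatory residual, parameterized by at most one Gaussian per band
  (theta and delta), each with amplitude ``b``, center ``f`` and width
  ``sigma``.

The aperiodic estimate comes from IRASA (irregular-resampling auto-spectral
analysis): the window is resampled by factor pairs ``(h, 1/h)`` for
h = 1.1 ... 1.9; a genuine oscillation moves to ``f/h`` (resp. ``f*h``) in
the resampled spectra while a self-similar 1/f background keeps its shape,
so the pointwise median over the geometric means of each pair leaves only
the aperiodic part.  Consecutive per-window Gaussians are then linearly
interpolated into continuous rhythm tracks, from which the theta
center-frequency decay after induction is timed and its slope measured.

Band power ratios (theta and delta power relative to the < 20 Hz signal) are
computed directly on the filtered EEG, without the spectral decomposition,
on 20 s non-overlapping windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import optimize, signal as sps

from .params import SpectralParams
from .signal_io import (
    Recording,
    WindowGrid,
    bandpass,
    lowpass,
    make_grid,
    window_masked_fraction,
    window_mean_square,
)

__all__ = [
    "AperiodicFit",
    "GaussianComponent",
    "SpectralFrame",
    "RhythmTrack",
    "PowerRatioSeries",
    "ProminenceResult",
    "ThetaDecayResult",
    "welch_psd",
    "irasa_aperiodic",
    "fit_aperiodic",
    "fit_oscillatory",
    "spectral_frames",
    "track_rhythms",
    "theta_decay",
    "power_ratios",
    "band_prominence_times",
]


@dataclass(frozen=True)
class AperiodicFit:
    """Fitted aperiodic model ``a / (c + f^p)`` with log-log residual RSS."""

    a: float
    c: float
    p: float
    rss: float

    def __call__(self, f: np.ndarray) -> np.ndarray:
        return self.a / (self.c + np.asarray(f, dtype=float) ** self.p)


@dataclass(frozen=True)
class GaussianComponent:
    """One oscillatory peak: amplitude ``b`` (PSD units), center ``f`` (Hz),
    width ``sigma`` (Hz), and the band it was assigned to."""

    b: float
    f: float
    sigma: float
    band: str = "none"

    @property
    def area(self) -> float:
        return self.b * self.sigma


@dataclass(frozen=True)
class SpectralFrame:
    """Per-window decomposition: aperiodic fit plus <= 1 Gaussian per band."""

    center_s: float
    aperiodic: Optional[AperiodicFit]
    theta: Optional[GaussianComponent]
    delta: Optional[GaussianComponent]
    valid: bool = True


@dataclass
class RhythmTrack:
    """Piecewise-linear center-frequency / width track of one band.

    ``runs`` is a list of ``(t, f, sigma)`` knot arrays, one per valid
    interval (consecutive window detections); isolated single-window
    detections are not part of any run.  The envelopes are
    ``up = f + sigma`` and ``low = f - sigma``.
    """

    band: str
    runs: List[Tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=list)

    @property
    def valid_intervals(self) -> List[Tuple[float, float]]:
        return [(float(t[0]), float(t[-1])) for t, _, _ in self.runs]

    def _interp(self, t, idx: int):
        scalar = np.ndim(t) == 0
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.full(t_arr.shape, np.nan, dtype=float)
        for kt, kf, ks in self.runs:
            inside = (t_arr >= kt[0]) & (t_arr <= kt[-1])
            vals = (kf, ks)[idx]
            out[inside] = np.interp(t_arr[inside], kt, vals)
        return float(out[0]) if scalar else out

    def f_at(self, t) -> np.ndarray:
        return self._interp(t, 0)

    def sigma_at(self, t) -> np.ndarray:
        return self._interp(t, 1)

    def up(self, t) -> np.ndarray:
        return self.f_at(t) + self.sigma_at(t)

    def low(self, t) -> np.ndarray:
        return self.f_at(t) - self.sigma_at(t)


# ---------------------------------------------------------------------------
# PSD estimation


def welch_psd(
    x: np.ndarray, fs: float, params: SpectralParams = SpectralParams()
) -> Tuple[np.ndarray, np.ndarray]:
    """Welch PSD (5 s Hann sub-windows, 50% overlap) restricted to the
    0.2-15 Hz analysis range; frequency resolution 0.2 Hz."""
    x = np.asarray(x, dtype=float)
    nper = int(round(params.welch_subwindow_s * fs))
    if x.size < nper:
        raise ValueError(
            f"window of {x.size / fs:.1f} s is shorter than the "
            f"{params.welch_subwindow_s} s Welch sub-window"
        )
    f, p = sps.welch(x, fs=fs, window="hann", nperseg=nper, noverlap=nper // 2)
    sel = (f >= params.fmin - 1e-9) & (f <= params.fmax + 1e-9)
    return f[sel], p[sel]


def _h_factors(params: SpectralParams) -> List[Tuple[int, int]]:
    """Resampling factors as reduced rationals (h is a multiple of 0.05,
    hence exactly k/20)."""
    out = []
    n = int(round((params.irasa_hmax - params.irasa_hmin) / params.irasa_hstep)) + 1
    for i in range(n):
        h = params.irasa_hmin + i * params.irasa_hstep
        up = int(round(h * 20))
        g = math.gcd(up, 20)
        out.append((up // g, 20 // g))
    return out


def irasa_aperiodic(
    x: np.ndarray, fs: float, params: SpectralParams = SpectralParams()
) -> Tuple[np.ndarray, np.ndarray]:
    """IRASA estimate of the aperiodic PSD on the 0.2-15 Hz grid.

    For each factor pair the signal is polyphase-resampled up and down; the
    two PSDs (computed at the nominal rate, so oscillations land at ``f/h``
    and ``f*h``) are combined by geometric mean, which cancels the amplitude
    scaling of a self-similar background exactly.  The pointwise median over
    all factors is the aperiodic estimate.
    """
    x = np.asarray(x, dtype=float)
    freqs, _ = welch_psd(x, fs, params)
    gms = []
    for up, down in _h_factors(params):
        x_up = sps.resample_poly(x, up, down)
        x_dn = sps.resample_poly(x, down, up)
        _, p_up = welch_psd(x_up, fs, params)
        _, p_dn = welch_psd(x_dn, fs, params)
        gms.append(np.sqrt(p_up * p_dn))
    return freqs, np.median(np.asarray(gms), axis=0)


# ---------------------------------------------------------------------------
# Aperiodic fit


class FitFailure(RuntimeError):
    """Nonlinear fit did not converge after bounded restarts."""


def fit_aperiodic(
    freqs: np.ndarray, psd: np.ndarray, params: SpectralParams = SpectralParams()
) -> AperiodicFit:
    """Robust least-squares fit of ``log(a / (c + f^p))`` to ``log PSD``.

    Constraints: a > 0, c >= 0, p >= 0.  After an initial fit from several
    starting points, the fit is repeated a few times on the points with the
    smallest log-residuals (``fit_keep_frac`` of the grid): residual
    oscillatory peaks that survive the IRASA median are strictly positive
    outliers, so the clipping removes their pull on the exponent without
    biasing the clean-spectrum fit.  The reported RSS is evaluated on the
    full grid.
    """
    fit = _fit_aperiodic_once(freqs, psd)
    f_all = np.asarray(freqs, dtype=float)
    p_all = np.asarray(psd, dtype=float)
    good = p_all > 0
    for _ in range(params.fit_clip_iters):
        resid = np.log(p_all[good]) - np.log(fit(f_all[good]))
        keep = resid <= np.quantile(resid, params.fit_keep_frac)
        if keep.sum() < 5:
            break
        fit = _fit_aperiodic_once(f_all[good][keep], p_all[good][keep])
    rss = float(np.sum((np.log(p_all[good]) - np.log(fit(f_all[good]))) ** 2))
    return AperiodicFit(a=fit.a, c=fit.c, p=fit.p, rss=rss)


def _fit_aperiodic_once(freqs: np.ndarray, psd: np.ndarray) -> AperiodicFit:
    """Single bounded nonlinear fit with a few restarts."""
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    good = psd > 0
    if good.sum() < 5:
        raise FitFailure("PSD not strictly positive on enough of the grid")
    f, y = freqs[good], np.log(psd[good])

    def residual(theta: np.ndarray) -> np.ndarray:
        log_a, c, p = theta
        return log_a - np.log(c + f**p) - y

    hi = f >= 1.0
    if hi.sum() >= 2:
        slope = np.polyfit(np.log(f[hi]), y[hi], 1)[0]
    else:
        slope = -1.0
    p0 = float(np.clip(-slope, 0.0, 8.0))
    best = None
    for c0, pp0 in ((0.1, p0), (0.5, 2.0), (0.01, 1.0)):
        la0 = float(np.interp(1.0, f, y) + np.log(c0 + 1.0))
        try:
            res = optimize.least_squares(
                residual,
                x0=[la0, c0, pp0],
                bounds=([-60.0, 0.0, 0.0], [60.0, 1e3, 10.0]),
                max_nfev=2000,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitFailure("aperiodic fit failed from every starting point")
    log_a, c, p = best.x
    return AperiodicFit(a=float(np.exp(log_a)), c=float(c), p=float(p), rss=float(2 * best.cost))


# ---------------------------------------------------------------------------
# Oscillatory fit


def _gauss_sum(f: np.ndarray, theta: np.ndarray) -> np.ndarray:
    out = np.zeros_like(f)
    for b, fc, s in theta.reshape(-1, 3):
        out += b * np.exp(-((f - fc) ** 2) / (2 * s**2))
    return out


def fit_oscillatory(
    freqs: np.ndarray,
    raw_psd: np.ndarray,
    aperiodic: AperiodicFit,
    params: SpectralParams = SpectralParams(),
) -> List[GaussianComponent]:
    """Fit Gaussians to the oscillatory residual and select band components.

    The residual (raw PSD minus the aperiodic model, negative values clipped
    to zero) is fitted on 1-15 Hz with up to four Gaussians seeded at local
    maxima of prominence >= std(residual).  Components with sigma outside
    [0.2, 2] Hz or amplitude <= std(residual) are pruned.  At most one
    component is kept per band (theta 4-10 Hz, delta 2-4 Hz), chosen by
    largest area ``b * sigma``; exact area ties go to the component closest
    to the band median frequency (7.5 / 3 Hz), then to the lower frequency.
    """
    freqs = np.asarray(freqs, dtype=float)
    resid = np.asarray(raw_psd, dtype=float) - aperiodic(freqs)
    sel = freqs >= params.osc_fmin
    f, r = freqs[sel], np.clip(resid[sel], 0.0, None)
    sd = float(np.std(r))
    if sd <= 0:
        return []
    peaks, _ = sps.find_peaks(r, prominence=sd)
    if peaks.size == 0:
        return []
    peaks = peaks[np.argsort(r[peaks])[::-1]][: params.max_components]

    lo_s, hi_s = params.sigma_bounds
    x0, lo, hi = [], [], []
    for pk in sorted(peaks):
        x0 += [r[pk], f[pk], 0.5]
        lo += [0.0, params.osc_fmin, lo_s]
        hi += [np.inf, params.fmax, hi_s]
    try:
        res = optimize.least_squares(
            lambda th: _gauss_sum(f, th) - r, x0=x0, bounds=(lo, hi), max_nfev=2000
        )
        fitted = res.x.reshape(-1, 3)
    except Exception:
        fitted = np.asarray(x0, dtype=float).reshape(-1, 3)

    comps = []
    s_lo, s_hi = params.sigma_prune
    for b, fc, s in fitted:
        if s < s_lo or s > s_hi or b <= sd:
            continue
        t1, t2 = params.theta_membership
        d1, d2 = params.delta_membership
        if t1 <= fc <= t2:
            band = "theta"
        elif d1 <= fc < d2:
            band = "delta"
        else:
            band = "none"
        comps.append(GaussianComponent(b=float(b), f=float(fc), sigma=float(s), band=band))

    selected: List[GaussianComponent] = []
    for band, median in (("theta", params.theta_median_hz), ("delta", params.delta_median_hz)):
        members = [c for c in comps if c.band == band]
        if members:
            members.sort(key=lambda c: (-c.area, abs(c.f - median), c.f))
            selected.append(members[0])
    selected += [c for c in comps if c.band == "none"]
    return selected


# ---------------------------------------------------------------------------
# Sliding-window frames and tracking


def spectral_frames(
    rec: Recording,
    params: SpectralParams = SpectralParams(),
    max_masked: float = 0.5,
) -> Tuple[WindowGrid, List[SpectralFrame]]:
    """Run the full per-window decomposition over the recording.

    Windows that are mostly artifact-masked, or whose aperiodic fit fails,
    produce an invalid frame (treated as missing downstream).
    """
    grid = make_grid(rec.duration_s, params.window_s, params.window_s - params.step_s)
    masked = window_masked_fraction(rec, grid)
    frames: List[SpectralFrame] = []
    for k, sl in enumerate(grid.sample_slices(rec.fs)):
        center = float(grid.centers[k])
        if masked[k] > max_masked:
            frames.append(SpectralFrame(center, None, None, None, valid=False))
            continue
        x = rec.eeg[sl]
        try:
            freqs, raw = welch_psd(x, rec.fs, params)
            _, psd_m = irasa_aperiodic(x, rec.fs, params)
            ap = fit_aperiodic(freqs, psd_m, params)
            comps = fit_oscillatory(freqs, raw, ap, params)
        except (FitFailure, ValueError):
            frames.append(SpectralFrame(center, None, None, None, valid=False))
            continue
        theta = next((c for c in comps if c.band == "theta"), None)
        delta = next((c for c in comps if c.band == "delta"), None)
        frames.append(SpectralFrame(center, ap, theta, delta, valid=True))
    return grid, frames


def track_rhythms(frames: List[SpectralFrame]) -> Dict[str, RhythmTrack]:
    """Interpolate per-window Gaussians into continuous per-band tracks.

    Detections in consecutive windows are joined by straight lines (center
    frequency and width separately).  A detection whose neighbors on both
    sides are empty is considered not significant and is dropped, so every
    run spans at least two window centers.
    """
    tracks: Dict[str, RhythmTrack] = {}
    for band in ("theta", "delta"):
        det = [(fr.center_s, getattr(fr, band)) for fr in frames]
        present = [c is not None for _, c in det]
        keep = []
        n = len(det)
        for i in range(n):
            if not present[i]:
                keep.append(False)
                continue
            left = present[i - 1] if i > 0 else False
            right = present[i + 1] if i < n - 1 else False
            keep.append(left or right)
        track = RhythmTrack(band=band)
        i = 0
        while i < n:
            if not keep[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and keep[j + 1]:
                j += 1
            ts = np.array([det[k][0] for k in range(i, j + 1)])
            fs_ = np.array([det[k][1].f for k in range(i, j + 1)])
            ss = np.array([det[k][1].sigma for k in range(i, j + 1)])
            track.runs.append((ts, fs_, ss))
            i = j + 1
        tracks[band] = track
    return tracks


@dataclass(frozen=True)
class ThetaDecayResult:
    """Theta decay onset (delay from induction, s) and slope (Hz/min)."""

    tau_decay: Optional[float]
    slope_hz_per_min: Optional[float]


def theta_decay(
    track: RhythmTrack,
    annotations,
    frame_centers: np.ndarray,
    params: SpectralParams = SpectralParams(),
) -> ThetaDecayResult:
    """Time the post-induction decay of the theta center frequency.

    The decay onset is the first frame center ``t`` after isoflurane onset
    such that every tracked ``f_theta`` value over the next 5 minutes stays
    strictly below ``f_theta(t)`` (evaluated on the frame grid; a candidate
    whose horizon extends beyond the recording, or sees no tracked value at
    all, is not declared).  The slope is the least-squares slope of
    ``f_theta`` over the following 2 minutes, reported in Hz/min and
    requiring at least three tracked frames.
    """
    iso = annotations.tau_iso_start
    centers = np.asarray(frame_centers, dtype=float)
    fvals = track.f_at(centers)
    tau_abs = None
    for i, c in enumerate(centers):
        if c <= iso or np.isnan(fvals[i]):
            continue
        if c + params.decay_horizon_s > centers[-1] + 1e-9:
            break
        horizon = (centers > c) & (centers <= c + params.decay_horizon_s)
        later = fvals[horizon]
        later = later[~np.isnan(later)]
        if later.size and np.all(later < fvals[i]):
            tau_abs = float(c)
            break
    if tau_abs is None:
        return ThetaDecayResult(None, None)
    win = (centers >= tau_abs) & (centers <= tau_abs + params.slope_fit_s)
    t_fit, f_fit = centers[win], fvals[win]
    ok = ~np.isnan(f_fit)
    if ok.sum() < params.slope_min_points:
        return ThetaDecayResult(float(tau_abs - iso), None)
    slope = float(np.polyfit(t_fit[ok], f_fit[ok], 1)[0]) * 60.0
    return ThetaDecayResult(float(tau_abs - iso), slope)


# ---------------------------------------------------------------------------
# Band power ratios (no spectral decomposition)


@dataclass(frozen=True)
class PowerRatioSeries:
    """Theta/delta power relative to the < 20 Hz signal per 20 s window."""

    grid: WindowGrid
    p_theta: np.ndarray
    p_delta: np.ndarray


@dataclass(frozen=True)
class ProminenceResult:
    """Per-window prominence flags (after the 1 min persistence rule) and
    the derived appearance/dampening delays (relative to induction)."""

    grid: WindowGrid
    theta_prominent: np.ndarray
    delta_prominent: np.ndarray
    tau_delta_app: Optional[float]
    tau_theta_disp: Optional[float]
    tau_delta_disp: Optional[float]


def power_ratios(rec: Recording, params: SpectralParams = SpectralParams()) -> PowerRatioSeries:
    """Band power ratios ``P_band = p_band / p_<20Hz`` on 20 s windows.

    Computed directly on the band-passed raw EEG.  Windows that are mostly
    masked, or whose low-passed power vanishes, are missing (NaN).
    """
    if rec.fs <= 2 * params.lowpass_hz:
        raise ValueError("sampling rate too low for the 20 Hz reference band")
    grid = make_grid(rec.duration_s, params.ratio_window_s, params.ratio_overlap_s)
    s20 = lowpass(rec.eeg, params.lowpass_hz, rec.fs)
    sth = bandpass(rec.eeg, *params.theta_band, rec.fs)
    sde = bandpass(rec.eeg, *params.delta_band, rec.fs)
    p20 = window_mean_square(s20, rec, grid)
    pth = window_mean_square(sth, rec, grid)
    pde = window_mean_square(sde, rec, grid)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_th = np.where(p20 > 0, pth / p20, np.nan)
        r_de = np.where(p20 > 0, pde / p20, np.nan)
    return PowerRatioSeries(grid=grid, p_theta=r_th, p_delta=r_de)


def _sustained(flags: np.ndarray, k: int) -> np.ndarray:
    """``out[i]`` true iff ``flags[i : i + k + 1]`` all true and in range."""
    n = flags.size
    out = np.zeros(n, dtype=bool)
    for i in range(n - k):
        if flags[i : i + k + 1].all():
            out[i] = True
    return out


def band_prominence_times(
    ratios: PowerRatioSeries,
    annotations,
    params: SpectralParams = SpectralParams(),
) -> ProminenceResult:
    """Appearance / dampening times of the theta and delta rhythms.

    A rhythm is prominent from the first window where its power ratio stays
    above threshold (0.1 theta / 0.15 delta) for a full minute, and dampened
    from the first window where it stays below for a full minute.  Theta
    starts prominent (it precedes induction), delta starts absent.  The
    delta dampening time is only searched after the delta appearance.
    Missing windows break every run.  Delays are relative to induction.
    """
    iso = annotations.tau_iso_start
    centers = ratios.grid.centers
    step = ratios.grid.step_s
    k = int(round(params.prominence_persist_s / step))

    def flags_and_times(p: np.ndarray, thr: float, initial: bool):
        raw_on = np.where(np.isnan(p), False, p > thr)
        raw_off = np.where(np.isnan(p), False, p < thr)
        sus_on = _sustained(raw_on, k)
        sus_off = _sustained(raw_off, k)
        flags = np.zeros(p.size, dtype=bool)
        cur = initial
        for i in range(p.size):
            if cur and sus_off[i]:
                cur = False
            elif not cur and sus_on[i]:
                cur = True
            flags[i] = cur
        return flags, sus_on, sus_off

    th_flags, _, th_sus_off = flags_and_times(ratios.p_theta, params.t_theta, True)
    de_flags, de_sus_on, de_sus_off = flags_and_times(ratios.p_delta, params.t_delta, False)

    def first_time(sus: np.ndarray, t_min: float) -> Optional[float]:
        idx = np.flatnonzero(sus & (centers >= t_min))
        return float(centers[idx[0]]) if idx.size else None

    t_de_app = first_time(de_sus_on, iso)
    t_th_disp = first_time(th_sus_off, iso)
    t_de_disp = None if t_de_app is None else first_time(de_sus_off, t_de_app)
    rel = lambda t: None if t is None else float(t - iso)
    return ProminenceResult(
        grid=ratios.grid,
        theta_prominent=th_flags,
        delta_prominent=de_flags,
        tau_delta_app=rel(t_de_app),
        tau_theta_disp=rel(t_th_disp),
        tau_delta_disp=rel(t_de_disp),
    )
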