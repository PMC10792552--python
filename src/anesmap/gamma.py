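"""Gamma-rebound detection during recovery from anesthesia.

After deep anesthesia with substantial iso-electric suppression, a sustained
narrow-band ~60 Hz activity can appear once isoflurane is stopped.  It is
detected on the 50-70 Hz band power computed in 0.2 s windows: the rebound
threshold is three times the RMS of that power series over the
pre-induction baseline, and a rebound is declared when the power stays
above threshold for at least two minutes during recovery (short sub-second
dips are tolerated: the rebound is a train of bursts, not a continuous
oscillation).  The rebound magnitude is the area under the power curve from
isoflurane cessation to the end of the recording.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .params import GammaParams
from .segments import bool_runs, merge_close
from .signal_io import Recording, WindowGrid, bandpass, make_grid, window_mean_square

__all__ = ["GammaResult", "gamma_power_series", "detect_gamma_rebound", "gamma_area", "analyze_gamma"]


@dataclass(frozen=True)
class GammaResult:
    """Gamma power series, threshold, rebound onset and area.

    ``tau_gamma`` is the rebound onset in absolute recording time (None if
    no rebound); ``rebound_interval`` is the sustained supra-threshold run
    that triggered the detection; ``a_gamma`` the area (uV^2 s) under the
    power curve over the recovery period.
    """

    grid: WindowGrid
    p_gamma: np.ndarray
    threshold: float
    tau_gamma: Optional[float]
    rebound_interval: Optional[Tuple[float, float]]
    a_gamma: float


def gamma_power_series(
    rec: Recording, params: GammaParams = GammaParams()
) -> Tuple[WindowGrid, np.ndarray]:
    """50-70 Hz band power (mean squared amplitude, uV^2) per 0.2 s window."""
    f1, f2 = params.band
    if rec.fs <= 2 * f2:
        raise ValueError(f"sampling rate {rec.fs} Hz too low for the {f1}-{f2} Hz band")
    filt = bandpass(rec.eeg, f1, f2, rec.fs)
    grid = make_grid(rec.duration_s, params.window_s, 0.0)
    power = window_mean_square(filt, rec, grid)
    return grid, power


def detect_gamma_rebound(
    grid: WindowGrid,
    p_gamma: np.ndarray,
    annotations,
    params: GammaParams = GammaParams(),
) -> Tuple[Optional[float], Optional[Tuple[float, float]], float]:
    """Find the first sustained supra-threshold gamma run during recovery.

    Returns ``(tau_gamma, run_interval, threshold)``.  The threshold is
    ``3 x RMS`` of the baseline (pre-induction) power series.  Runs above
    threshold after isoflurane cessation are merged across gaps shorter
    than ``gap_tolerance_s``; the first merged run lasting at least
    ``persist_s`` is the rebound.
    """
    if annotations is None:
        raise ValueError("gamma detection requires isoflurane start/stop annotations")
    iso_start, iso_stop = annotations.tau_iso_start, annotations.tau_iso_stop
    centers = grid.centers
    base = p_gamma[(centers < iso_start) & ~np.isnan(p_gamma)]
    if base.size == 0:
        raise ValueError("empty pre-induction baseline for the gamma threshold")
    threshold = params.threshold_factor * float(np.sqrt(np.mean(np.square(base))))

    recovery = centers > iso_stop
    above = np.where(np.isnan(p_gamma), False, p_gamma > threshold) & recovery
    runs = bool_runs(above)
    if not runs.size:
        return None, None, threshold
    half = grid.width_s / 2.0
    run_times = np.column_stack(
        [centers[runs[:, 0]] - half, centers[runs[:, 1] - 1] + half]
    )
    run_times = merge_close(run_times, params.gap_tolerance_s)
    for s, e in run_times:
        if e - s >= params.persist_s:
            return float(s), (float(s), float(e)), threshold
    return None, None, threshold


def gamma_area(
    grid: WindowGrid,
    p_gamma: np.ndarray,
    annotations,
) -> float:
    """Trapezoidal area under the gamma power curve over the recovery
    period (isoflurane stop to end of recording), in uV^2 s."""
    sel = grid.centers >= annotations.tau_iso_stop
    t = grid.centers[sel]
    p = p_gamma[sel]
    ok = ~np.isnan(p)
    if ok.sum() < 2:
        return 0.0
    return float(np.trapezoid(p[ok], t[ok]))


def analyze_gamma(rec: Recording, params: GammaParams = GammaParams()) -> GammaResult:
    """Full gamma analysis of one recording."""
    grid, power = gamma_power_series(rec, params)
    tau, interval, thr = detect_gamma_rebound(grid, power, rec.annotations, params)
    area = gamma_area(grid, power, rec.annotations)
    return GammaResult(
        grid=grid,
        p_gamma=power,
        threshold=thr,
        tau_gamma=tau,
        rebound_interval=interval,
        a_gamma=area,
    )
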