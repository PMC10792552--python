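"""Segmentation of iso-electric and band suppressions.

Iso-electric suppressions (IES) are epochs where the EEG amplitude stays
below an adaptive threshold ``r_ies * RMS_EEG`` for at least one second
(runs below threshold shorter than that are ignored; detections separated by
less than half a second are merged).  Theta- and delta-suppressions are the
same detector applied to the 5-10 Hz / 2.5-4.5 Hz band-passed signal at
``0.2 * RMS_EEG``, with IES intervals subtracted so the three labels are
disjoint.  Suppression ratios (the fraction of a 20 s sliding window spent
in suppression) and the derived timestamps -- delay to first IES, cumulative
IES duration, and the strong-IES onset -- are computed here as well.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from . import segments as seg
from .params import SuppressionParams
from .signal_io import Recording, WindowGrid, bandpass, rms, window_masked_fraction

__all__ = [
    "SegmentList",
    "RatioSeries",
    "IesSummary",
    "detect_suppressions",
    "detect_ies",
    "detect_band_suppressions",
    "suppression_ratios",
    "ies_summary",
    "sweep_ies_threshold",
    "first_sustained",
]


@dataclass(frozen=True)
class SegmentList:
    """Labeled, sorted, disjoint half-open segments (seconds)."""

    label: str
    segments: np.ndarray  # (n, 2)

    @property
    def total_duration(self) -> float:
        return seg.total_duration(self.segments)

    def __len__(self) -> int:
        return len(self.segments)


@dataclass(frozen=True)
class RatioSeries:
    """Suppression ratios on a sliding-window grid (NaN = missing)."""

    grid: WindowGrid
    ies_ratio: np.ndarray
    theta_ratio: np.ndarray
    delta_ratio: np.ndarray


@dataclass(frozen=True)
class IesSummary:
    """Headline IES quantities of one recording.

    ``tau_ies1`` and ``tau_s`` are delays from isoflurane onset (None when
    the event never happens); ``delta_ies`` is the cumulative IES duration.
    """

    tau_ies1: Optional[float]
    delta_ies: float
    tau_s: Optional[float]


def detect_suppressions(
    signal: np.ndarray,
    fs: float,
    threshold: float,
    min_dur_s: float = 1.0,
    merge_gap_s: float = 0.5,
    mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Detect runs where ``|signal| < threshold``.

    Maximal sub-threshold runs lasting at least ``min_dur_s`` are kept, then
    detections separated by a gap shorter than ``merge_gap_s`` are merged.
    Masked samples are never counted as suppression (they interrupt runs).
    Returns an ``(n, 2)`` array of ``[start_s, end_s)`` segments.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("empty signal")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    below = np.abs(signal) < threshold
    if mask is not None:
        below &= ~np.asarray(mask, dtype=bool)
    runs = seg.bool_runs(below).astype(float) / fs
    runs = seg.filter_min_duration(runs, min_dur_s)
    return seg.merge_close(runs, merge_gap_s)


def ies_threshold(rec: Recording, params: SuppressionParams = SuppressionParams()) -> float:
    """Adaptive IES threshold ``r_ies * RMS_EEG`` with a small absolute
    floor guarding all-flat recordings (RMS ~ 0)."""
    if params.rms_mode == "baseline" and rec.annotations is not None:
        n0 = int(rec.annotations.tau_iso_start * rec.fs)
        base = rec.eeg[:n0] if n0 > 0 else rec.eeg
        base_mask = rec.artifact_mask[: base.size]
        r = rms(base, base_mask)
    else:
        r = rms(rec.eeg, rec.artifact_mask)
    return max(params.r_ies * r, params.threshold_floor_uv)


def detect_ies(rec: Recording, params: SuppressionParams = SuppressionParams()) -> SegmentList:
    """IES segmentation of the raw EEG at threshold ``r_ies * RMS_EEG``."""
    thr = ies_threshold(rec, params)
    segs = detect_suppressions(
        rec.eeg, rec.fs, thr, params.min_dur_s, params.merge_gap_s, rec.artifact_mask
    )
    return SegmentList("ies", segs)


def detect_band_suppressions(
    rec: Recording,
    band: str,
    ies: SegmentList,
    params: SuppressionParams = SuppressionParams(),
) -> SegmentList:
    """Theta/delta suppression: the band-passed EEG below ``band_thr * RMS_EEG``,
    with IES intervals subtracted and the minimum-duration rule re-applied."""
    if band == "theta":
        f1, f2 = params.theta_band
    elif band == "delta":
        f1, f2 = params.delta_band
    else:
        raise ValueError(f"band must be 'theta' or 'delta', got {band!r}")
    filt = bandpass(rec.eeg, f1, f2, rec.fs)
    thr = max(params.band_thr * rms(rec.eeg, rec.artifact_mask), params.threshold_floor_uv)
    segs = detect_suppressions(
        filt, rec.fs, thr, params.min_dur_s, params.merge_gap_s, rec.artifact_mask
    )
    segs = seg.difference(segs, ies.segments)
    segs = seg.filter_min_duration(segs, params.min_dur_s)
    return SegmentList(f"{band}_suppression", segs)


def suppression_ratios(
    segments_by_label: Dict[str, np.ndarray],
    grid: WindowGrid,
    rec: Optional[Recording] = None,
    max_masked: float = 0.5,
) -> RatioSeries:
    """Fraction of each sliding window covered by each suppression label.

    Windows with more than ``max_masked`` of their samples artifact-masked
    are reported missing (NaN) when a recording is supplied.
    """
    missing = None
    if rec is not None:
        missing = window_masked_fraction(rec, grid) > max_masked

    def series(key: str) -> np.ndarray:
        segs = segments_by_label.get(key, np.empty((0, 2)))
        out = np.array(
            [seg.overlap_duration(segs, s, e) / grid.width_s for s, e in grid.bounds()]
        )
        if missing is not None:
            out[missing] = np.nan
        return out

    return RatioSeries(
        grid=grid,
        ies_ratio=series("ies"),
        theta_ratio=series("theta"),
        delta_ratio=series("delta"),
    )


def first_sustained(
    centers: np.ndarray,
    ok: np.ndarray,
    horizon_s: float,
    t_min: float = -np.inf,
) -> Optional[float]:
    """First grid center ``t >= t_min`` such that ``ok`` holds on every
    window center in ``[t, t + horizon_s]``.

    The horizon must fit inside the grid (a condition that cannot be
    verified against the full horizon near the end of the recording is not
    declared).  Missing values must already be False in ``ok``.
    """
    centers = np.asarray(centers, dtype=float)
    ok = np.asarray(ok, dtype=bool)
    if centers.size == 0:
        return None
    step = centers[1] - centers[0] if centers.size > 1 else horizon_s
    k = int(round(horizon_s / step))
    for i, c in enumerate(centers):
        if c < t_min or i + k >= centers.size:
            continue
        if ok[i : i + k + 1].all():
            return float(c)
    return None


def ies_summary(
    ies: SegmentList,
    ratios: RatioSeries,
    annotations,
    params: SuppressionParams = SuppressionParams(),
) -> IesSummary:
    """Delay to first IES, cumulative IES duration, and strong-IES onset.

    The strong-IES time is the first window center (at or after isoflurane
    onset) from which the IES ratio exceeds ``strong_thr`` on every window
    over the next ``strong_persist_s`` seconds; missing windows break the
    run.  Both delays are relative to isoflurane onset.
    """
    iso = annotations.tau_iso_start
    tau_ies1 = float(ies.segments[0, 0] - iso) if len(ies) else None
    ok = np.where(np.isnan(ratios.ies_ratio), False, ratios.ies_ratio > params.strong_thr)
    t = first_sustained(ratios.grid.centers, ok, params.strong_persist_s, t_min=iso)
    tau_s = None if t is None else float(t - iso)
    return IesSummary(tau_ies1=tau_ies1, delta_ies=ies.total_duration, tau_s=tau_s)


def sweep_ies_threshold(
    rec: Recording,
    r_values: np.ndarray,
    params: SuppressionParams = SuppressionParams(),
) -> np.ndarray:
    """Total detected IES duration as a function of the relative threshold.

    Returns an ``(n, 2)`` array of ``(r, total_duration_s)`` rows.  The
    curve is non-decreasing in ``r``; a plateau around the operating point
    indicates a robust threshold choice (the detected duration is then
    insensitive to the exact value of ``r``).
    """
    r_values = np.asarray(r_values, dtype=float)
    base = rms(rec.eeg, rec.artifact_mask)
    out = np.empty((r_values.size, 2))
    for i, r in enumerate(r_values):
        thr = max(r * base, params.threshold_floor_uv) if r > 0 else 0.0
        if thr <= 0:
            dur = 0.0
        else:
            segs = detect_suppressions(
                rec.eeg, rec.fs, thr, params.min_dur_s, params.merge_gap_s, rec.artifact_mask
            )
            dur = seg.total_duration(segs)
        out[i] = (r, dur)
    return out
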