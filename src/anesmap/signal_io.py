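"""Recording container, file I/O, artifact masking, filtering and windowing.

A :class:`Recording` holds a single-channel EEG trace (microvolts), an
optional EMG channel at the same sampling rate, protocol annotations
(isoflurane start/stop, optional loss/return-of-movement marks) and a boolean
artifact mask.  Everything downstream (suppression segmentation, spectral
decomposition, gamma detection) consumes this container.

Supported on-disk formats:

* plain columnar UTF-8 text ``time_s  eeg_uV  [emg_uV]`` (uniform sampling
  required, rate inferred from the time column);
* 16-bit EDF, read through :mod:`mne` and written by a minimal EDF writer
  (integer-second recordings, physical unit uV);
* annotations as a JSON object
  ``{"tau_iso_start": s, "tau_iso_stop": s, "tau_lom": s|null, "tau_rom": s|null}``.

Time convention: seconds from recording start; intervals are half-open
``[start, end)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import signal as sps

from .params import ArtifactParams
from .segments import bool_runs

__all__ = [
    "Annotations",
    "Recording",
    "WindowGrid",
    "make_grid",
    "bandpass",
    "lowpass",
    "rms",
    "mask_artifacts",
    "read_recording",
    "write_text",
    "write_edf",
    "load_annotations",
    "save_annotations",
]


class FormatError(ValueError):
    """Raised when an input file does not parse as a valid recording."""


@dataclass(frozen=True)
class Annotations:
    """Protocol time marks, in seconds from recording start."""

    tau_iso_start: float
    tau_iso_stop: float
    tau_lom: Optional[float] = None
    tau_rom: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "tau_iso_start": self.tau_iso_start,
            "tau_iso_stop": self.tau_iso_stop,
            "tau_lom": self.tau_lom,
            "tau_rom": self.tau_rom,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Annotations":
        return cls(
            tau_iso_start=float(d["tau_iso_start"]),
            tau_iso_stop=float(d["tau_iso_stop"]),
            tau_lom=None if d.get("tau_lom") is None else float(d["tau_lom"]),
            tau_rom=None if d.get("tau_rom") is None else float(d["tau_rom"]),
        )


@dataclass
class Recording:
    """EEG (+ optional EMG) recording in microvolts.

    Invariants: all channels share ``fs`` and length; the artifact mask has
    the same length as the EEG; annotation times lie inside the recording.
    """

    eeg: np.ndarray
    fs: float
    emg: Optional[np.ndarray] = None
    annotations: Optional[Annotations] = None
    artifact_mask: Optional[np.ndarray] = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        if self.eeg.ndim != 1 or self.eeg.size == 0:
            raise ValueError("eeg must be a non-empty 1-D array")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.emg is not None:
            self.emg = np.asarray(self.emg, dtype=float)
            if self.emg.shape != self.eeg.shape:
                raise FormatError("EEG and EMG lengths differ")
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(self.eeg.shape, dtype=bool)
        else:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
            if self.artifact_mask.shape != self.eeg.shape:
                raise ValueError("mask length must equal signal length")
        if self.annotations is not None:
            d = self.duration_s
            a = self.annotations
            if not (0 <= a.tau_iso_start < a.tau_iso_stop <= d + 1e-9):
                raise ValueError("annotation times must lie inside the recording")

    @property
    def n_samples(self) -> int:
        return int(self.eeg.size)

    @property
    def duration_s(self) -> float:
        return self.eeg.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.eeg.size) / self.fs


@dataclass(frozen=True)
class WindowGrid:
    """Sliding-window grid: centers ``t`` with each ``[t - w/2, t + w/2)``
    fully inside the recording; consecutive centers differ by
    ``width_s - overlap_s``."""

    width_s: float
    overlap_s: float
    centers: np.ndarray

    @property
    def step_s(self) -> float:
        return self.width_s - self.overlap_s

    def bounds(self) -> np.ndarray:
        """(n, 2) array of window ``[start, end)`` times."""
        half = self.width_s / 2.0
        return np.column_stack([self.centers - half, self.centers + half])

    def sample_slices(self, fs: float) -> list:
        out = []
        for s, e in self.bounds():
            out.append(slice(int(round(s * fs)), int(round(e * fs))))
        return out


def make_grid(duration_s: float, width_s: float, overlap_s: float = 0.0) -> WindowGrid:
    """Build the sliding-window grid used by every windowed statistic.

    Centers start at ``width_s / 2`` and step by ``width_s - overlap_s``;
    only windows fully inside ``[0, duration_s)`` are kept (no partial
    tail windows).
    """
    if not (0 <= overlap_s < width_s):
        raise ValueError("need 0 <= overlap_s < width_s")
    if width_s > duration_s:
        raise ValueError("window width exceeds recording duration")
    step = width_s - overlap_s
    n = int(np.floor((duration_s - width_s) / step + 1e-9)) + 1
    centers = width_s / 2.0 + step * np.arange(n)
    return WindowGrid(width_s=width_s, overlap_s=overlap_s, centers=centers)


# ---------------------------------------------------------------------------
# Filtering and basic statistics


def bandpass(x: np.ndarray, f1: float, f2: float, fs: float) -> np.ndarray:
    """Zero-phase Butterworth band-pass, order 1 applied forward-backward
    (effective order 4).  Preserves the phase of in-band sinusoids."""
    if not (0 < f1 < f2 < fs / 2):
        raise ValueError(f"invalid band ({f1}, {f2}) for fs={fs}")
    sos = sps.butter(1, [f1, f2], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def lowpass(x: np.ndarray, fc: float, fs: float) -> np.ndarray:
    """Zero-phase Butterworth low-pass (order 1 forward-backward)."""
    if not (0 < fc < fs / 2):
        raise ValueError(f"invalid cutoff {fc} for fs={fs}")
    sos = sps.butter(1, fc, btype="lowpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def rms(x: np.ndarray, mask: Optional[np.ndarray] = None) -> float:
    """Root mean square of the unmasked samples (mask True = excluded)."""
    x = np.asarray(x, dtype=float)
    if mask is not None:
        x = x[~np.asarray(mask, dtype=bool)]
    if x.size == 0:
        raise ValueError("all samples are masked; RMS undefined")
    return float(np.sqrt(np.mean(np.square(x))))


# ---------------------------------------------------------------------------
# Artifact masking


def mask_artifacts(
    rec: Recording,
    low_thr: float | None = None,
    high_thr: float | None = None,
    flat_min_s: float | None = None,
    params: ArtifactParams = ArtifactParams(),
) -> Recording:
    """Return a copy of ``rec`` with artifact samples masked.

    Two rules are applied and OR-ed into the mask:

    1. *Dropout flat-lines*: runs of exactly-equal consecutive samples lasting
       at least ``flat_min_s`` (hardware dropouts typically read constant 0).
    2. *High-amplitude hysteresis*: every connected excursion of ``|eeg|``
       above ``low_thr`` that touches ``high_thr`` is masked in full, so a
       large artifact is removed down to where the signal genuinely returns
       to baseline.
    """
    low_thr = params.low_thr_uv if low_thr is None else low_thr
    high_thr = params.high_thr_uv if high_thr is None else high_thr
    flat_min_s = params.flat_min_s if flat_min_s is None else flat_min_s
    if not (0 < low_thr < high_thr):
        raise ValueError("need 0 < low_thr < high_thr")

    x = rec.eeg
    mask = rec.artifact_mask.copy()

    # Rule 1: constant runs >= flat_min_s.
    eq = np.r_[False, np.diff(x) == 0.0]
    for i0, i1 in bool_runs(eq):
        # eq[i] marks sample i equal to its predecessor; the constant run of
        # samples is [i0 - 1, i1).
        if (i1 - (i0 - 1)) >= flat_min_s * rec.fs:
            mask[i0 - 1 : i1] = True

    # Rule 2: hysteresis thresholding on |x|.
    absx = np.abs(x)
    weak = absx > low_thr
    strong = absx >= high_thr
    if strong.any():
        cs = np.concatenate([[0], np.cumsum(strong)])
        for i0, i1 in bool_runs(weak):
            if cs[i1] - cs[i0] > 0:
                mask[i0:i1] = True

    return replace(rec, artifact_mask=mask)


# ---------------------------------------------------------------------------
# File I/O


def write_text(rec: Recording, path: str | Path) -> Path:
    """Write ``time_s  eeg_uV  [emg_uV]`` columns."""
    path = Path(path)
    cols = [rec.times, rec.eeg]
    header = "time_s eeg_uV"
    if rec.emg is not None:
        cols.append(rec.emg)
        header += " emg_uV"
    np.savetxt(path, np.column_stack(cols), fmt="%.6f", header=header)
    return path


def _read_text(path: Path) -> Recording:
    try:
        data = np.loadtxt(path)
    except Exception as exc:  # pragma: no cover - message path
        raise FormatError(f"could not parse columnar text {path}: {exc}") from exc
    if data.ndim != 2 or data.shape[1] not in (2, 3):
        raise FormatError(f"{path}: expected 2 or 3 columns (time, eeg[, emg])")
    t = data[:, 0]
    if t.size < 2:
        raise FormatError(f"{path}: need at least two samples to infer fs")
    dt = np.diff(t)
    dt0 = float(np.median(dt))
    if dt0 <= 0:
        raise FormatError(f"{path}: non-increasing time column")
    bad = np.flatnonzero(np.abs(dt - dt0) > 1e-4 * dt0)
    if bad.size:
        raise FormatError(
            f"{path}: irregular sampling at row {int(bad[0]) + 1} "
            f"(dt={dt[bad[0]]:.6g}, expected {dt0:.6g})"
        )
    emg = data[:, 2] if data.shape[1] == 3 else None
    return Recording(eeg=data[:, 1], emg=emg, fs=1.0 / dt0)


# EDF: 256-byte fixed header + 256 bytes per signal, then 1 s data records of
# little-endian int16 samples scaled between the physical and digital ranges.

def write_edf(rec: Recording, path: str | Path) -> Path:
    """Write a minimal 16-bit EDF file (1 s records, physical unit uV).

    The recording is truncated to an integer number of seconds (our bundled
    scenarios are integer-second by construction).
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_rec = rec.n_samples // fs
    if n_rec < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    chans = [("EEG", rec.eeg)]
    if rec.emg is not None:
        chans.append(("EMG", rec.emg))
    ns = len(chans)

    def pad(s: str, n: int) -> bytes:
        return s[:n].ljust(n).encode("ascii")

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),  # patient id
            pad("Startdate X X X X", 80),  # recording id
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * (1 + ns)), 8),
            pad("", 44),
            pad(str(n_rec), 8),
            pad("1", 8),  # record duration (s)
            pad(str(ns), 4),
        ]
    )

    phys_max = [max(1.0, float(np.max(np.abs(x[: n_rec * fs])))) for _, x in chans]
    sig_header = b"".join(
        [pad(lbl, 16) for lbl, _ in chans]
        + [pad("", 80)] * ns  # transducer
        + [pad("uV", 8)] * ns
        + [pad(f"{-pm:.6g}", 8) for pm in phys_max]
        + [pad(f"{pm:.6g}", 8) for pm in phys_max]
        + [pad("-32767", 8)] * ns
        + [pad("32767", 8)] * ns
        + [pad("", 80)] * ns  # prefiltering
        + [pad(str(fs), 8)] * ns
        + [pad("", 32)] * ns
    )

    digital = []
    for (_, x), pm in zip(chans, phys_max):
        d = np.clip(np.round(x[: n_rec * fs] / pm * 32767.0), -32767, 32767)
        digital.append(d.astype("<i2").reshape(n_rec, fs))

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_rec):
            for d in digital:
                fh.write(d[r].tobytes())
    return path


def _read_edf(path: Path) -> Recording:
    import mne  # deferred: mne import is heavy

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise FormatError(f"unreadable EDF file {path}: {exc}") from exc
    fs = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # mne loads EDF uV channels as volts
    names = [n.upper() for n in raw.ch_names]
    eeg_idx = names.index("EEG") if "EEG" in names else 0
    emg_idx = names.index("EMG") if "EMG" in names else None
    emg = data[emg_idx] if emg_idx is not None else None
    return Recording(eeg=data[eeg_idx], emg=emg, fs=fs)


def read_recording(
    path: str | Path,
    fmt: Optional[str] = None,
    annotations: Optional[Annotations] = None,
) -> Recording:
    """Load a recording from EDF or columnar text.

    ``fmt`` is ``"edf"`` or ``"text"``; when omitted it is inferred from the
    file extension.  The artifact mask is initialized to all-false.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "text"
    if fmt == "edf":
        rec = _read_edf(path)
    elif fmt == "text":
        rec = _read_text(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if annotations is not None:
        rec = replace(rec, annotations=annotations)
    return rec


def load_annotations(path: str | Path) -> Annotations:
    with open(path) as fh:
        return Annotations.from_dict(json.load(fh))


def save_annotations(ann: Annotations, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(ann.to_dict(), fh, indent=1)
    return path


# ---------------------------------------------------------------------------
# Windowed statistics with missing-value support


def window_masked_fraction(rec: Recording, grid: WindowGrid) -> np.ndarray:
    """Fraction of masked samples per grid window."""
    out = np.empty(len(grid.centers))
    for k, sl in enumerate(grid.sample_slices(rec.fs)):
        m = rec.artifact_mask[sl]
        out[k] = m.mean() if m.size else 1.0
    return out


def window_mean_square(
    x: np.ndarray,
    rec: Recording,
    grid: WindowGrid,
    max_masked: float = 0.5,
) -> np.ndarray:
    """Mean square of ``x`` per window, NaN where more than ``max_masked`` of
    the window is artifact-masked; masked samples are excluded elsewhere."""
    out = np.full(len(grid.centers), np.nan)
    for k, sl in enumerate(grid.sample_slices(rec.fs)):
        m = rec.artifact_mask[sl]
        if m.size == 0 or m.mean() > max_masked:
            continue
        vals = x[sl][~m]
        if vals.size:
            out[k] = float(np.mean(np.square(vals)))
    return out
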