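"""Seeded synthetic EEG/EMG generator with known ground truth.

The generator emulates the phenomenology of isoflurane anesthesia in mouse
cortical EEG so that every detector in the package can be validated against
planted truth:

* a 1/f-decaying aperiodic background with power spectral density
  ``a / (c + f^p)``, synthesized by shaping white Gaussian noise in the
  frequency domain (exact expected PSD, no filter-design error);
* narrow-band rhythms (theta ~8 Hz, delta ~3 Hz) realized as slowly
  frequency-modulated sinusoids whose instantaneous frequency follows a
  constant or linearly decaying trajectory with Gaussian spread ``sigma``;
* iso-electric suppressions planted as near-flat epochs (the signal is
  scaled to a small residual, 2% by default, rather than exactly zero so
  detectors face realistic traces);
* a ~60 Hz gamma burst train during recovery;
* an EMG channel, active outside the loss/return-of-movement interval and
  nearly flat inside it.

A scenario is an ordered list of stages tiling the recording; stages are
crossfaded over one second to avoid spectral edge artifacts, while the
ground truth refers to the nominal stage boundaries.  Everything is
deterministic under the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import signal as sps

from .events import EventTimestamps
from .signal_io import Annotations, Recording

__all__ = [
    "RhythmSpec",
    "GammaSpec",
    "StageSpec",
    "ScenarioConfig",
    "GroundTruth",
    "generate_aperiodic",
    "generate_oscillation",
    "assemble_recording",
    "deep_scenario",
    "light_scenario",
    "scenario_from_dict",
]

IES_RESIDUAL = 0.02  # flat epochs keep 2% of the local amplitude
CROSSFADE_S = 1.0  # raised-cosine stage crossfade (total width)
IES_RAMP_S = 0.05  # on/off ramps of planted flat epochs
EMG_FLAT_FACTOR = 0.05


@dataclass(frozen=True)
class RhythmSpec:
    """A planted narrow-band rhythm.

    The center frequency moves linearly from ``f_start`` to ``f_end``
    across the stage (constant when equal); ``sigma`` is the Gaussian
    spectral width (Hz) realized by slow frequency modulation.
    """

    amplitude: float
    f_start: float
    f_end: Optional[float] = None
    sigma: float = 0.5

    @property
    def f_stop(self) -> float:
        return self.f_start if self.f_end is None else self.f_end


@dataclass(frozen=True)
class GammaSpec:
    """A planted gamma burst train (bursts of a narrow-band ~60 Hz rhythm)."""

    amplitude: float
    center_hz: float = 60.0
    sigma: float = 1.0
    start_offset_s: float = 5.0
    duration_s: Optional[float] = None
    burst_on_s: float = 0.7
    burst_off_s: float = 0.25


@dataclass(frozen=True)
class StageSpec:
    """One scenario stage over the half-open interval [start_s, end_s)."""

    start_s: float
    end_s: float
    aperiodic: Tuple[float, float, float] = (200.0, 0.5, 2.0)  # (a, c, p)
    theta: Optional[RhythmSpec] = None
    delta: Optional[RhythmSpec] = None
    ies_fraction: float = 0.0
    gamma: Optional[GammaSpec] = None
    emg_active: bool = True

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class ScenarioConfig:
    """Full scenario: protocol times, stage list and RNG seed."""

    fs: float
    duration_s: float
    tau_iso_start: float
    tau_iso_stop: float
    stages: Tuple[StageSpec, ...]
    seed: int = 0
    tau_lom: Optional[float] = None
    tau_rom: Optional[float] = None
    ies_on_s: float = 7.0  # planted flat-epoch length inside IES stages

    def validate(self) -> None:
        if not (0 <= self.tau_iso_start < self.tau_iso_stop <= self.duration_s):
            raise ValueError("need 0 <= tau_iso_start < tau_iso_stop <= duration_s")
        if not self.stages:
            raise ValueError("scenario needs at least one stage")
        cur = 0.0
        for st in self.stages:
            if abs(st.start_s - cur) > 1e-9 or st.end_s <= st.start_s:
                raise ValueError("stages must tile [0, duration_s) without gaps or overlap")
            cur = st.end_s
            for r in (st.theta, st.delta):
                if r is not None:
                    lo, hi = sorted((r.f_start, r.f_stop))
                    if not (0 < lo and hi < self.fs / 2):
                        raise ValueError("rhythm trajectory must stay inside (0, fs/2)")
            if not (0.0 <= st.ies_fraction <= 1.0):
                raise ValueError("ies_fraction must lie in [0, 1]")
        if abs(cur - self.duration_s) > 1e-9:
            raise ValueError("stages must tile the full duration")


@dataclass
class GroundTruth:
    """Everything that was planted, for validating the detectors.

    ``planted_ies`` are the nominal flat intervals; ``planted_rhythms``
    maps band -> list of (start, end, f_start, f_end, sigma) tuples;
    ``true_events`` mirrors the event table (delays from induction);
    ``true_gamma_area`` is the expected area under the 50-70 Hz power
    curve over the recovery period (burst power plus aperiodic background).
    """

    planted_ies: np.ndarray
    planted_rhythms: Dict[str, List[Tuple[float, float, float, float, float]]]
    true_events: EventTimestamps
    true_gamma_area: float
    gamma_bursts: np.ndarray
    emg_lom_rom: Tuple[Optional[float], Optional[float]]

    def to_dict(self) -> dict:
        return {
            "planted_ies": self.planted_ies.tolist(),
            "planted_rhythms": {
                k: [list(t) for t in v] for k, v in self.planted_rhythms.items()
            },
            "true_events": self.true_events.to_dict(),
            "true_gamma_area": self.true_gamma_area,
            "gamma_bursts": self.gamma_bursts.tolist(),
            "emg_lom_rom": list(self.emg_lom_rom),
        }


# ---------------------------------------------------------------------------
# Elementary generators


def generate_aperiodic(
    a: float, c: float, p: float, duration_s: float, fs: float, seed=None
) -> np.ndarray:
    """Zero-mean Gaussian signal with expected one-sided PSD ``a/(c+f^p)``
    (uV^2/Hz), synthesized by frequency-domain shaping of white noise."""
    if a <= 0 or c < 0 or p < 0:
        raise ValueError("need a > 0, c >= 0, p >= 0")
    if fs <= 0 or duration_s < 1.0 / fs:
        raise ValueError("need fs > 0 and duration of at least one sample")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    with np.errstate(divide="ignore"):
        psd = a / (c + freqs**p)
    psd[~np.isfinite(psd)] = 0.0  # c = 0, f = 0
    mag = np.sqrt(psd * fs * n / 2.0)
    z = (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)) / np.sqrt(2.0)
    spec = mag * z
    spec[0] = 0.0  # zero mean
    if n % 2 == 0:
        spec[-1] = spec[-1].real
    return np.fft.irfft(spec, n=n)


def generate_oscillation(
    amplitude: float,
    f_start: float,
    f_end: Optional[float],
    sigma: float,
    duration_s: float,
    fs: float,
    seed=None,
) -> np.ndarray:
    """Narrow-band rhythm: amplitude-``A`` sinusoid whose instantaneous
    frequency follows the linear trajectory plus slow Gaussian jitter of
    standard deviation ``sigma`` (giving a ~Gaussian spectral peak of that
    width).  Zero amplitude returns the zero signal."""
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if fs <= 0 or duration_s < 1.0 / fs:
        raise ValueError("need fs > 0 and duration of at least one sample")
    f_end = f_start if f_end is None else f_end
    lo, hi = sorted((f_start, f_end))
    if not (0 < lo and hi < fs / 2):
        raise ValueError("frequency trajectory must stay inside (0, fs/2)")
    n = int(round(duration_s * fs))
    if amplitude == 0:
        return np.zeros(n)
    rng = np.random.default_rng(seed)
    f_nom = np.linspace(f_start, f_end, n, endpoint=False)
    if sigma > 0:
        sos = sps.butter(2, 0.5, btype="lowpass", fs=fs, output="sos")
        jitter = sps.sosfilt(sos, rng.standard_normal(n))
        sd = jitter.std()
        jitter = jitter / sd * sigma if sd > 0 else jitter * 0.0
    else:
        jitter = np.zeros(n)
    f_inst = np.clip(f_nom + jitter, 0.05, 0.49 * fs)
    phase = 2 * np.pi * np.cumsum(f_inst) / fs + rng.uniform(0, 2 * np.pi)
    return amplitude * np.cos(phase)


def _band_integral(a: float, c: float, p: float, f1: float, f2: float) -> float:
    f = np.linspace(f1, f2, 512)
    return float(np.trapezoid(a / (c + f**p), f))


def _ies_pattern(stage: StageSpec, on_s: float) -> np.ndarray:
    """Nominal flat intervals realizing the stage's IES fraction: epochs of
    ``on_s`` seconds separated by gaps sized from the target fraction."""
    f = stage.ies_fraction
    if f <= 0:
        return np.empty((0, 2))
    if f >= 1:
        return np.array([[stage.start_s, stage.end_s]])
    off = on_s * (1.0 - f) / f
    out = []
    t = stage.start_s
    while t < stage.end_s - 1.0:
        e = min(t + on_s, stage.end_s)
        if e - t >= 1.0:
            out.append((t, e))
        t += on_s + off
    return np.asarray(out)


def _gamma_bursts(stage: StageSpec) -> np.ndarray:
    g = stage.gamma
    if g is None:
        return np.empty((0, 2))
    start = stage.start_s + g.start_offset_s
    dur = g.duration_s if g.duration_s is not None else (stage.end_s - start)
    stop = min(start + dur, stage.end_s)
    out = []
    t = start
    while t < stop:
        e = min(t + g.burst_on_s, stop)
        if e > t:
            out.append((t, e))
        t += g.burst_on_s + g.burst_off_s
    return np.asarray(out)


def _envelope(n: int, fs: float, t_offset: float, intervals: np.ndarray,
              depth: float, ramp_s: float) -> np.ndarray:
    """Multiplicative envelope dipping to ``depth`` inside each interval,
    with raised-cosine ramps of ``ramp_s`` at the edges."""
    env = np.ones(n)
    if not len(intervals):
        return env
    t = t_offset + np.arange(n) / fs
    for s, e in intervals:
        dip = np.zeros(n)
        core = (t >= s + ramp_s) & (t < e - ramp_s)
        dip[core] = 1.0
        up = (t >= s) & (t < s + ramp_s)
        dip[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - s) / ramp_s))
        dn = (t >= e - ramp_s) & (t < e)
        dip[dn] = 0.5 * (1 + np.cos(np.pi * (t[dn] - (e - ramp_s)) / ramp_s))
        env = np.minimum(env, 1.0 - (1.0 - depth) * dip)
    return env


def _true_events(config: ScenarioConfig, planted_ies: np.ndarray,
                 gamma_bursts: np.ndarray) -> EventTimestamps:
    iso = config.tau_iso_start
    stages = config.stages
    theta_decay = delta_app = theta_disp = delta_disp = tau_s = None
    for st in stages:
        if st.start_s < iso:
            continue
        if theta_decay is None and st.theta is not None and st.theta.f_stop < st.theta.f_start:
            theta_decay = st.start_s - iso
        if delta_app is None and st.delta is not None:
            delta_app = st.start_s - iso
        if tau_s is None and st.ies_fraction > 0.25:
            tau_s = st.start_s - iso
    for prev, cur in zip(stages[:-1], stages[1:]):
        if cur.start_s < iso:
            continue
        if theta_disp is None and prev.theta is not None and cur.theta is None:
            theta_disp = cur.start_s - iso
        if (
            delta_disp is None
            and delta_app is not None
            and cur.start_s - iso >= delta_app
            and prev.delta is not None
            and cur.delta is None
        ):
            delta_disp = cur.start_s - iso
    tau_ies1 = float(planted_ies[0, 0] - iso) if len(planted_ies) else None
    tau_gamma = float(gamma_bursts[0, 0] - iso) if len(gamma_bursts) else None
    rel = lambda t: None if t is None else float(t - iso)
    return EventTimestamps(
        tau_start_rec=0.0,
        tau_iso_start=iso,
        tau_iso_stop=config.tau_iso_stop,
        tau_rec_stop=config.duration_s,
        tau_theta_decay=theta_decay,
        tau_delta_app=delta_app,
        tau_theta_disp=theta_disp,
        tau_delta_disp=delta_disp,
        tau_ies1=tau_ies1,
        tau_s=tau_s,
        tau_gamma=tau_gamma,
        tau_lom=rel(config.tau_lom),
        tau_rom=rel(config.tau_rom),
    )


def assemble_recording(config: ScenarioConfig) -> Tuple[Recording, GroundTruth]:
    """Synthesize the EEG/EMG recording and its ground truth.

    The EEG is the stagewise sum of aperiodic background and planted
    rhythms, crossfaded across stage boundaries; flat epochs and gamma
    bursts are applied as multiplicative envelopes.  Deterministic under
    ``config.seed``.
    """
    config.validate()
    fs = config.fs
    n = int(round(config.duration_s * fs))
    root = np.random.SeedSequence(config.seed)
    stage_seeds = root.spawn(len(config.stages) + 1)
    eeg = np.zeros(n)
    half_fade = CROSSFADE_S / 2.0
    planted_ies: List[np.ndarray] = []
    rhythms: Dict[str, List[Tuple[float, float, float, float, float]]] = {
        "theta": [],
        "delta": [],
    }
    gamma_bursts = np.empty((0, 2))
    gamma_background = 0.0

    for k, st in enumerate(config.stages):
        sub = stage_seeds[k].spawn(4)
        ext_s = max(0.0, st.start_s - half_fade)
        ext_e = min(config.duration_s, st.end_s + half_fade)
        i0, i1 = int(round(ext_s * fs)), int(round(ext_e * fs))
        ns = i1 - i0
        dur = ns / fs
        a, c, p = st.aperiodic
        x = generate_aperiodic(a, c, p, dur, fs, sub[0])

        # Rhythms follow the stage's nominal trajectory; on the extended
        # interval the trajectory is extrapolated linearly (a crossfade-wide
        # sliver, irrelevant to the planted truth).
        for band, spec, ss in (("theta", st.theta, sub[1]), ("delta", st.delta, sub[2])):
            if spec is None:
                continue
            slope = (spec.f_stop - spec.f_start) / st.duration_s
            f0 = spec.f_start + slope * (ext_s - st.start_s)
            f1 = spec.f_start + slope * (ext_e - st.start_s)
            lo, hi = sorted((f0, f1))
            f0, f1 = max(lo, 0.1), min(hi, 0.49 * fs)
            if slope < 0:
                f0, f1 = f1, f0
            x = x + generate_oscillation(spec.amplitude, f0, f1, spec.sigma, dur, fs, ss)
            rhythms[band].append(
                (st.start_s, st.end_s, spec.f_start, spec.f_stop, spec.sigma)
            )

        if st.gamma is not None:
            bursts = _gamma_bursts(st)
            gamma_bursts = bursts
            g = st.gamma
            tone = generate_oscillation(g.amplitude, g.center_hz, g.center_hz, g.sigma, dur, fs, sub[3])
            on_env = 1.0 - _envelope(ns, fs, ext_s, bursts, 0.0, IES_RAMP_S)
            x = x + tone * on_env
            gamma_background = _band_integral(a, c, p, 50.0, 70.0)

        ies = _ies_pattern(st, config.ies_on_s)
        if len(ies):
            planted_ies.append(ies)
            x = x * _envelope(ns, fs, ext_s, ies, IES_RESIDUAL, IES_RAMP_S)

        # Partition-of-unity crossfade weight.
        t = ext_s + np.arange(ns) / fs
        w = np.ones(ns)
        if st.start_s > 0:
            up = (t >= st.start_s - half_fade) & (t < st.start_s + half_fade)
            w[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - (st.start_s - half_fade)) / CROSSFADE_S))
            w[t < st.start_s - half_fade] = 0.0
        if st.end_s < config.duration_s:
            dn = (t >= st.end_s - half_fade) & (t < st.end_s + half_fade)
            w[dn] = np.minimum(
                w[dn],
                0.5 * (1 + np.cos(np.pi * (t[dn] - (st.end_s - half_fade)) / CROSSFADE_S)),
            )
            w[t >= st.end_s + half_fade] = 0.0
        eeg[i0:i1] += w * x

    planted = np.vstack(planted_ies) if planted_ies else np.empty((0, 2))

    # EMG: band-limited 20-200 Hz noise, nearly flat between LOM and ROM.
    emg_rng = np.random.default_rng(stage_seeds[-1])
    emg = emg_rng.standard_normal(n)
    sos = sps.butter(2, [20.0, 200.0], btype="bandpass", fs=fs, output="sos")
    emg = sps.sosfiltfilt(sos, emg)
    emg = emg / emg.std() * 150.0
    if config.tau_lom is not None and config.tau_rom is not None:
        flat = _envelope(
            n, fs, 0.0, np.array([[config.tau_lom, config.tau_rom]]), EMG_FLAT_FACTOR, 0.5
        )
        emg = emg * flat

    true_area = 0.0
    if len(gamma_bursts):
        g_stage = next(st for st in config.stages if st.gamma is not None)
        # Effective squared-envelope time per burst: the cosine on/off ramps
        # carry 3/8 of a rectangle's power, so each burst contributes
        # duration - 1.25 * ramp.
        on = float(np.sum(gamma_bursts[:, 1] - gamma_bursts[:, 0]))
        on -= len(gamma_bursts) * 1.25 * IES_RAMP_S
        recovery = config.duration_s - config.tau_iso_stop
        true_area = on * g_stage.gamma.amplitude**2 / 2.0 + gamma_background * recovery

    ann = Annotations(
        tau_iso_start=config.tau_iso_start,
        tau_iso_stop=config.tau_iso_stop,
        tau_lom=config.tau_lom,
        tau_rom=config.tau_rom,
    )
    rec = Recording(eeg=eeg, emg=emg, fs=fs, annotations=ann)
    truth = GroundTruth(
        planted_ies=planted,
        planted_rhythms=rhythms,
        true_events=_true_events(config, planted, gamma_bursts),
        true_gamma_area=true_area,
        gamma_bursts=gamma_bursts,
        emg_lom_rom=(config.tau_lom, config.tau_rom),
    )
    return rec, truth


# ---------------------------------------------------------------------------
# Bundled scenarios


def deep_scenario(seed: int = 7) -> ScenarioConfig:
    """Deep-anesthesia scenario: 20 min at 500 Hz, isoflurane from 3 min to
    16 min, theta decay then delta dominance, dampening of both bands, a
    strong burst-suppression phase (half the time iso-electric) and a gamma
    rebound with return of movement during recovery."""
    ap = (200.0, 0.5, 2.0)
    theta = lambda f0, f1=None: RhythmSpec(amplitude=20.0, f_start=f0, f_end=f1, sigma=0.5)
    delta = RhythmSpec(amplitude=25.0, f_start=3.0, sigma=0.5)
    stages = (
        StageSpec(0.0, 190.0, ap, theta=theta(8.0)),
        StageSpec(190.0, 310.0, ap, theta=theta(8.0, 6.0)),
        StageSpec(310.0, 480.0, ap, theta=theta(6.0), delta=delta),
        StageSpec(480.0, 600.0, ap, delta=delta, emg_active=False),
        StageSpec(600.0, 690.0, ap, emg_active=False),
        StageSpec(690.0, 960.0, ap, ies_fraction=0.5, emg_active=False),
        StageSpec(960.0, 1200.0, ap, theta=theta(8.0),
                  gamma=GammaSpec(amplitude=12.0, start_offset_s=5.0, duration_s=185.0)),
    )
    return ScenarioConfig(
        fs=500.0,
        duration_s=1200.0,
        tau_iso_start=180.0,
        tau_iso_stop=960.0,
        stages=stages,
        seed=seed,
        tau_lom=480.0,
        tau_rom=960.0,
    )


def light_scenario(seed: int = 11) -> ScenarioConfig:
    """Light-anesthesia scenario: same induction sequence but delta stays
    prominent until isoflurane stops; no iso-electric suppression and no
    gamma rebound."""
    ap = (200.0, 0.5, 2.0)
    theta = lambda f0, f1=None: RhythmSpec(amplitude=20.0, f_start=f0, f_end=f1, sigma=0.5)
    delta = RhythmSpec(amplitude=25.0, f_start=3.0, sigma=0.5)
    stages = (
        StageSpec(0.0, 190.0, ap, theta=theta(8.0)),
        StageSpec(190.0, 310.0, ap, theta=theta(8.0, 6.0)),
        StageSpec(310.0, 480.0, ap, theta=theta(6.0), delta=delta),
        StageSpec(480.0, 960.0, ap, delta=delta, emg_active=False),
        StageSpec(960.0, 1200.0, ap, theta=theta(8.0)),
    )
    return ScenarioConfig(
        fs=500.0,
        duration_s=1200.0,
        tau_iso_start=180.0,
        tau_iso_stop=960.0,
        stages=stages,
        seed=seed,
        tau_lom=480.0,
        tau_rom=960.0,
    )


def scenario_from_dict(d: dict) -> ScenarioConfig:
    """Build a scenario from a plain dict (parsed YAML/JSON)."""

    def rhythm(r):
        return None if r is None else RhythmSpec(**r)

    stages = tuple(
        StageSpec(
            start_s=s["start_s"],
            end_s=s["end_s"],
            aperiodic=tuple(s.get("aperiodic", (200.0, 0.5, 2.0))),
            theta=rhythm(s.get("theta")),
            delta=rhythm(s.get("delta")),
            ies_fraction=s.get("ies_fraction", 0.0),
            gamma=None if s.get("gamma") is None else GammaSpec(**s["gamma"]),
            emg_active=s.get("emg_active", True),
        )
        for s in d["stages"]
    )
    return ScenarioConfig(
        fs=d["fs"],
        duration_s=d["duration_s"],
        tau_iso_start=d["tau_iso_start"],
        tau_iso_stop=d["tau_iso_stop"],
        stages=stages,
        seed=d.get("seed", 0),
        tau_lom=d.get("tau_lom"),
        tau_rom=d.get("tau_rom"),
    )


def synthetic_cohort(
    n_subjects: int = 12,
    recordings_per_subject: int = 2,
    seed: int = 0,
    separable: bool = True,
):
    """Synthetic event-delay cohort table for the classifier.

    Half the subjects are IES sensitive (cumulative IES > 30 s, early first
    IES); the other half never reach IES (``tau_ies1`` absent).  With
    ``separable`` the first-IES delay perfectly separates the classes;
    the other delay columns overlap between classes.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        positive = s < n_subjects // 2
        for r in range(recordings_per_subject):
            delta_ies = rng.uniform(60, 250) if positive else rng.uniform(0, 20)
            # sensitive recordings reach IES early; insensitive ones never do
            tau_ies1 = rng.uniform(10, 120) if positive else np.nan
            if not separable:
                tau_ies1 = rng.uniform(10, 500)
            rows.append(
                {
                    "recording_id": f"rec{s:02d}_{r}",
                    "subject_id": f"subject{s:02d}",
                    "protocol": "incremented" if positive else "1pc",
                    "delta_ies_s": delta_ies,
                    "tau_theta_decay_s": rng.uniform(10, 120),
                    "tau_delta_app_s": rng.uniform(60, 300),
                    "tau_theta_disp_s": rng.uniform(200, 500),
                    "tau_delta_disp_s": rng.uniform(300, 700),
                    "tau_ies1_s": tau_ies1,
                }
            )
    return pd.DataFrame(rows)
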