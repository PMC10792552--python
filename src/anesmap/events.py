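"""Event-chain assembly, ordering validation and anesthesia state labeling.

Across recordings the EEG events of isoflurane anesthesia appear in a fixed
temporal order: induction, theta center-frequency decay, delta appearance,
theta dampening, delta dampening, strong iso-electric suppression, gamma
rebound.  This module collects the per-recording event timestamps computed
upstream, checks that ordering (with a one-window tolerance, since the
events are quantized on 10-30 s grids), and labels every 20 s window with
an anesthesia state from the state chart:

    Awake -> ThetaDecay -> ProminentDeltaTheta -> ProminentDelta
          -> {PreIES | LightIES | Movement}
    PreIES/LightIES -> StrongIES -> GammaReboundMovement -> Movement

States are decided by a pure cascade over the per-window flags (band
prominence, IES ratio, gamma activity, movement annotations).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .signal_io import Annotations, WindowGrid

__all__ = [
    "EventTimestamps",
    "StateLabelSeries",
    "CHAIN_ORDER",
    "STATES",
    "STATE_EDGES",
    "extract_event_chain",
    "validate_order",
    "label_states",
    "is_valid_state_path",
    "emg_movement_times",
]


# The ordered chain of post-induction events (delays from induction).
CHAIN_ORDER: Tuple[str, ...] = (
    "tau_theta_decay",
    "tau_delta_app",
    "tau_theta_disp",
    "tau_delta_disp",
    "tau_s",
    "tau_gamma",
)


@dataclass(frozen=True)
class EventTimestamps:
    """Timestamps of the EEG/EMG time-frequency events of one recording.

    The four protocol times are absolute (seconds from recording start);
    every other field is a delay from isoflurane onset, with ``None``
    meaning the event never occurred.
    """

    tau_start_rec: float
    tau_iso_start: float
    tau_iso_stop: float
    tau_rec_stop: float
    tau_theta_decay: Optional[float] = None
    tau_delta_app: Optional[float] = None
    tau_theta_disp: Optional[float] = None
    tau_delta_disp: Optional[float] = None
    tau_ies1: Optional[float] = None
    tau_s: Optional[float] = None
    tau_gamma: Optional[float] = None
    tau_lom: Optional[float] = None
    tau_rom: Optional[float] = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "EventTimestamps":
        return cls(**{k: d.get(k) for k in cls.__dataclass_fields__})

    def chain_events(self) -> List[Tuple[str, float]]:
        """Present events of the ordered chain, as (name, delay) pairs."""
        out = []
        for name in CHAIN_ORDER:
            v = getattr(self, name)
            if v is not None:
                out.append((name, float(v)))
        return out


def extract_event_chain(
    annotations: Annotations,
    duration_s: float,
    ies_summary,
    prominence,
    theta_decay_result,
    gamma_result=None,
) -> EventTimestamps:
    """Assemble the full event table from the upstream module results.

    ``ies_summary``, ``prominence`` and ``theta_decay_result`` are the
    outputs of the suppression / spectral modules; ``gamma_result`` the
    gamma analysis (optional).  Absent events stay ``None``.
    """
    iso = annotations.tau_iso_start
    tau_gamma = None
    if gamma_result is not None and gamma_result.tau_gamma is not None:
        tau_gamma = float(gamma_result.tau_gamma - iso)
    rel = lambda t: None if t is None else float(t - iso)
    return EventTimestamps(
        tau_start_rec=0.0,
        tau_iso_start=annotations.tau_iso_start,
        tau_iso_stop=annotations.tau_iso_stop,
        tau_rec_stop=float(duration_s),
        tau_theta_decay=theta_decay_result.tau_decay,
        tau_delta_app=prominence.tau_delta_app,
        tau_theta_disp=prominence.tau_theta_disp,
        tau_delta_disp=prominence.tau_delta_disp,
        tau_ies1=ies_summary.tau_ies1,
        tau_s=ies_summary.tau_s,
        tau_gamma=tau_gamma,
        tau_lom=rel(annotations.tau_lom),
        tau_rom=rel(annotations.tau_rom),
    )


def validate_order(events: EventTimestamps, tolerance_s: float = 20.0) -> List[Tuple[str, str]]:
    """Check the chain ordering among the events that are present.

    Returns the list of violated adjacent pairs; an empty list means the
    chain is ordered.  Because the event times are quantized on different
    window grids (10-30 s), strictness is checked with ``tolerance_s``
    slack: the pair ``(u, v)`` is violated when ``v <= u - tolerance_s``.
    Absent events are skipped.  The chain starts at induction (delay 0).
    """
    chain = [("tau_iso_start", 0.0)] + events.chain_events()
    violations = []
    for (name_u, u), (name_v, v) in zip(chain[:-1], chain[1:]):
        if v <= u - tolerance_s:
            violations.append((name_u, name_v))
    return violations


# ---------------------------------------------------------------------------
# State chart


STATES: Tuple[str, ...] = (
    "Awake",
    "ThetaDecay",
    "ProminentDeltaTheta",
    "ProminentDelta",
    "PreIES",
    "LightIES",
    "StrongIES",
    "Movement",
    "GammaReboundMovement",
)

# Directed edges of the state chart (self-loops are always allowed).
STATE_EDGES = frozenset(
    {
        ("Awake", "ThetaDecay"),
        ("ThetaDecay", "ProminentDeltaTheta"),
        ("ProminentDeltaTheta", "ProminentDelta"),
        ("ProminentDelta", "PreIES"),
        ("ProminentDelta", "LightIES"),
        ("ProminentDelta", "Movement"),
        ("PreIES", "LightIES"),
        ("LightIES", "PreIES"),
        ("PreIES", "StrongIES"),
        ("LightIES", "StrongIES"),
        ("PreIES", "Movement"),
        ("LightIES", "Movement"),
        ("StrongIES", "GammaReboundMovement"),
        ("StrongIES", "Movement"),
        ("Movement", "GammaReboundMovement"),
        ("GammaReboundMovement", "Movement"),
    }
)


@dataclass(frozen=True)
class StateLabelSeries:
    """One anesthesia state per window (None where flags are missing)."""

    grid: WindowGrid
    states: List[Optional[str]]
    theta_prominent: np.ndarray
    delta_prominent: np.ndarray
    ies_ratio: np.ndarray

    def path(self) -> List[str]:
        """Sequence of visited states with consecutive repeats collapsed."""
        out: List[str] = []
        for s in self.states:
            if s is not None and (not out or out[-1] != s):
                out.append(s)
        return out


def label_states(
    grid: WindowGrid,
    theta_prominent: np.ndarray,
    delta_prominent: np.ndarray,
    ies_ratio: np.ndarray,
    annotations: Annotations,
    events: EventTimestamps,
    gamma_interval: Optional[Tuple[float, float]] = None,
    strong_thr: float = 0.25,
) -> StateLabelSeries:
    """Label every window with a state-chart state.

    Decision cascade per window (first match wins): pre-induction windows
    are Awake; windows after the return of movement are Movement, or
    GammaReboundMovement while the detected gamma rebound covers most of
    the window; IES ratio above the strong threshold gives StrongIES; a
    little IES with delta prominent but theta dampened gives LightIES; both
    rhythms prominent gives ProminentDeltaTheta; delta alone
    ProminentDelta; theta alone is ThetaDecay once the theta decay has
    started (Awake before); neither rhythm gives PreIES.  Windows with a
    missing IES ratio get no state.
    """
    iso = annotations.tau_iso_start
    tau_rom_abs = annotations.tau_rom
    states: List[Optional[str]] = []
    for i, t in enumerate(grid.centers):
        th = bool(theta_prominent[i])
        de = bool(delta_prominent[i])
        r = ies_ratio[i]
        if np.isnan(r):
            states.append(None)
            continue
        if t < iso:
            states.append("Awake")
        elif tau_rom_abs is not None and t >= tau_rom_abs:
            gamma_on = False
            if gamma_interval is not None:
                s, e = gamma_interval
                lo, hi = t - grid.width_s / 2, t + grid.width_s / 2
                gamma_on = (min(hi, e) - max(lo, s)) > 0.5 * grid.width_s
            states.append("GammaReboundMovement" if gamma_on else "Movement")
        elif r > strong_thr:
            states.append("StrongIES")
        elif r > 0 and de and not th:
            states.append("LightIES")
        elif th and de:
            states.append("ProminentDeltaTheta")
        elif de:
            states.append("ProminentDelta")
        elif th:
            decayed = (
                events.tau_theta_decay is not None
                and (t - iso) >= events.tau_theta_decay
            )
            states.append("ThetaDecay" if decayed else "Awake")
        else:
            states.append("PreIES")
    return StateLabelSeries(
        grid=grid,
        states=states,
        theta_prominent=np.asarray(theta_prominent, dtype=bool),
        delta_prominent=np.asarray(delta_prominent, dtype=bool),
        ies_ratio=np.asarray(ies_ratio, dtype=float),
    )


def is_valid_state_path(states: Sequence[Optional[str]]) -> bool:
    """True when every transition between consecutive labeled windows is an
    edge of the state chart (or a self-loop)."""
    prev = None
    for s in states:
        if s is None:
            continue
        if prev is not None and s != prev and (prev, s) not in STATE_EDGES:
            return False
        prev = s
    return True


def emg_movement_times(
    emg: np.ndarray,
    fs: float,
    window_s: float = 1.0,
    rel_threshold: float = 0.5,
) -> Tuple[Optional[float], Optional[float]]:
    """Heuristic loss/return-of-movement marks from the EMG envelope.

    Movement marks are normally protocol annotations identified on the EMG
    trace; this convenience detector thresholds the windowed EMG RMS at
    ``rel_threshold`` times its overall RMS and reports the first sustained
    low run (loss of movement) and the subsequent return to activity.  It
    is plumbing for unannotated data, not a validated method.
    """
    emg = np.asarray(emg, dtype=float)
    n = int(window_s * fs)
    if n < 1 or emg.size < 2 * n:
        return None, None
    m = emg[: emg.size // n * n].reshape(-1, n)
    env = np.sqrt(np.mean(np.square(m), axis=1))
    thr = rel_threshold * np.sqrt(np.mean(np.square(emg)))
    low = env < thr
    lom = rom = None
    for i, flag in enumerate(low):
        if lom is None and flag:
            lom = i * window_s
        elif lom is not None and not flag:
            rom = i * window_s
            break
    return lom, rom
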