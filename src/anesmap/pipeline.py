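"""End-to-end orchestration: preprocess -> suppress -> spectral -> gamma ->
events -> states, with optional on-disk outputs and a manifest.

``run_pipeline`` is the single entry point used by the CLI, the examples
and the acceptance script; it is deterministic for a fixed recording and
parameter set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

import pandas as pd

from . import __version__
from .events import EventTimestamps, StateLabelSeries, extract_event_chain, label_states, validate_order
from .gamma import GammaResult, analyze_gamma
from .params import DEFAULT_PARAMS, PipelineParams
from .signal_io import Recording, make_grid, mask_artifacts, rms
from .spectral import (
    PowerRatioSeries,
    ProminenceResult,
    ThetaDecayResult,
    band_prominence_times,
    power_ratios,
    spectral_frames,
    theta_decay,
    track_rhythms,
)
from .suppression import (
    IesSummary,
    RatioSeries,
    SegmentList,
    detect_band_suppressions,
    detect_ies,
    ies_summary,
    suppression_ratios,
)

__all__ = ["PipelineResult", "run_pipeline", "write_outputs"]


class StageFailure(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineResult:
    """Bundle of every stage output for one recording."""

    params: PipelineParams
    rms_eeg: float
    ies: SegmentList
    theta_suppression: SegmentList
    delta_suppression: SegmentList
    ratios: RatioSeries
    ies_sum: IesSummary
    power: PowerRatioSeries
    prominence: ProminenceResult
    frames: list
    frame_grid: object
    tracks: dict
    theta: ThetaDecayResult
    gamma: Optional[GammaResult]
    events: EventTimestamps
    order_violations: list
    states: StateLabelSeries

    def report(self) -> str:
        ev = self.events
        lines = [
            "anesthesia-state mapping report",
            f"  recording RMS: {self.rms_eeg:.2f} uV",
            f"  IES segments: {len(self.ies)} "
            f"(cumulative {self.ies_sum.delta_ies:.1f} s)",
            "  event delays from induction (s):",
        ]
        for name in (
            "tau_theta_decay",
            "tau_delta_app",
            "tau_theta_disp",
            "tau_delta_disp",
            "tau_ies1",
            "tau_s",
            "tau_gamma",
        ):
            v = getattr(ev, name)
            lines.append(f"    {name}: {'absent' if v is None else f'{v:.1f}'}")
        lines.append(
            "  event chain: "
            + ("ordered" if not self.order_violations else f"violations {self.order_violations}")
        )
        lines.append("  state path: " + " -> ".join(self.states.path()))
        return "\n".join(lines)


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **k):
            try:
                return fn(*a, **k)
            except Exception as exc:
                raise StageFailure(f"pipeline stage {name} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(rec: Recording, params: PipelineParams = DEFAULT_PARAMS) -> PipelineResult:
    """Run the full analysis on a recording with annotations."""
    if rec.annotations is None:
        raise ValueError("run_pipeline requires protocol annotations")
    rec = mask_artifacts(rec, params=params.artifacts)
    sp = params.suppression

    rms_eeg = rms(rec.eeg, rec.artifact_mask)
    ies = _stage("suppression.detect_ies")(detect_ies)(rec, sp)
    th_s = _stage("suppression.detect_band_suppressions")(detect_band_suppressions)(
        rec, "theta", ies, sp
    )
    de_s = _stage("suppression.detect_band_suppressions")(detect_band_suppressions)(
        rec, "delta", ies, sp
    )
    grid_r = make_grid(rec.duration_s, sp.ratio_window_s, sp.ratio_overlap_s)
    ratios = suppression_ratios(
        {"ies": ies.segments, "theta": th_s.segments, "delta": de_s.segments}, grid_r, rec
    )
    ies_sum = ies_summary(ies, ratios, rec.annotations, sp)

    power = _stage("spectral.power_ratios")(power_ratios)(rec, params.spectral)
    prom = band_prominence_times(power, rec.annotations, params.spectral)
    frame_grid, frames = _stage("spectral.frames")(spectral_frames)(rec, params.spectral)
    tracks = track_rhythms(frames)
    th_decay = theta_decay(tracks["theta"], rec.annotations, frame_grid.centers, params.spectral)

    gamma_res = None
    if rec.fs > 2 * params.gamma.band[1]:
        gamma_res = _stage("gamma.analyze")(analyze_gamma)(rec, params.gamma)

    events = extract_event_chain(
        rec.annotations, rec.duration_s, ies_sum, prom, th_decay, gamma_res
    )
    violations = validate_order(events, params.order_tolerance_s)

    state_ratios = suppression_ratios({"ies": ies.segments}, power.grid, rec)
    states = label_states(
        power.grid,
        prom.theta_prominent,
        prom.delta_prominent,
        state_ratios.ies_ratio,
        rec.annotations,
        events,
        gamma_interval=None if gamma_res is None else gamma_res.rebound_interval,
        strong_thr=sp.strong_thr,
    )

    return PipelineResult(
        params=params,
        rms_eeg=rms_eeg,
        ies=ies,
        theta_suppression=th_s,
        delta_suppression=de_s,
        ratios=ratios,
        ies_sum=ies_sum,
        power=power,
        prominence=prom,
        frames=frames,
        frame_grid=frame_grid,
        tracks=tracks,
        theta=th_decay,
        gamma=gamma_res,
        events=events,
        order_violations=violations,
        states=states,
    )


def write_outputs(result: PipelineResult, out_dir: str | Path, seed: Optional[int] = None) -> Path:
    """Write every stage output plus a manifest to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for sl in (result.ies, result.theta_suppression, result.delta_suppression):
        for s, e in sl.segments:
            rows.append({"label": sl.label, "start_s": s, "end_s": e})
    pd.DataFrame(rows, columns=["label", "start_s", "end_s"]).to_csv(
        out / "segments.csv", index=False
    )

    pd.DataFrame(
        {
            "center_s": result.ratios.grid.centers,
            "ies_ratio": result.ratios.ies_ratio,
            "theta_ratio": result.ratios.theta_ratio,
            "delta_ratio": result.ratios.delta_ratio,
        }
    ).to_csv(out / "ratios.csv", index=False)

    pd.DataFrame(
        {
            "center_s": result.power.grid.centers,
            "p_theta": result.power.p_theta,
            "p_delta": result.power.p_delta,
        }
    ).to_csv(out / "power_ratios.csv", index=False)

    frows = []
    for fr in result.frames:
        row: Dict = {"center_s": fr.center_s}
        if fr.valid and fr.aperiodic is not None:
            row.update(a=fr.aperiodic.a, c=fr.aperiodic.c, p=fr.aperiodic.p, rss=fr.aperiodic.rss)
        for band in ("theta", "delta"):
            comp = getattr(fr, band)
            if comp is not None:
                row[f"{band}_b"] = comp.b
                row[f"{band}_f"] = comp.f
                row[f"{band}_sigma"] = comp.sigma
        frows.append(row)
    pd.DataFrame(frows).to_csv(out / "frames.csv", index=False)

    tracks_json = {
        band: [
            {"interval": [float(t[0]), float(t[-1])],
             "knots": [[float(a), float(b), float(c)] for a, b, c in zip(t, f, s)]}
            for t, f, s in tr.runs
        ]
        for band, tr in result.tracks.items()
    }
    (out / "tracks.json").write_text(json.dumps(tracks_json, indent=1))

    (out / "events.json").write_text(json.dumps(result.events.to_dict(), indent=1))

    pd.DataFrame(
        {"center_s": result.states.grid.centers, "state": result.states.states}
    ).to_csv(out / "states.csv", index=False)

    if result.gamma is not None:
        g = result.gamma
        (out / "gamma.json").write_text(
            json.dumps(
                {
                    "tau_gamma": g.tau_gamma,
                    "threshold": g.threshold,
                    "a_gamma": g.a_gamma,
                    "rebound_interval": g.rebound_interval,
                },
                indent=1,
            )
        )

    manifest = {
        "anesmap_version": __version__,
        "config_hash": result.params.config_hash(),
        "seed": seed,
        "params": result.params.to_dict(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out / "report.txt").write_text(result.report() + "\n")
    return out
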