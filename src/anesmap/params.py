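"""Default analysis parameters.

All thresholds and window sizes used across the pipeline live here so that a
single :class:`PipelineParams` instance fully determines the analysis.  The
defaults are the standard operating point of the method: a relative
iso-electric-suppression (IES) threshold of 0.7 x the recording RMS, band
suppression thresholds at 0.2 x RMS, 20 s ratio windows, 60 s spectral
windows with a 30 s step, and prominence thresholds of 0.1 (theta) and
0.15 (delta) on the band power ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple

import hashlib
import json


@dataclass(frozen=True)
class SuppressionParams:
    """Parameters of IES / band-suppression segmentation.

    ``r_ies`` scales the recording RMS into the IES amplitude threshold;
    ``band_thr`` does the same for the band-passed theta/delta signals.
    Runs shorter than ``min_dur_s`` are discarded and detections separated
    by less than ``merge_gap_s`` are merged.  ``strong_thr`` and
    ``strong_persist_s`` define the entry into "strong IES": the IES ratio
    must exceed the threshold on every window over the persistence horizon.
    """

    r_ies: float = 0.7
    band_thr: float = 0.2
    min_dur_s: float = 1.0
    merge_gap_s: float = 0.5
    theta_band: Tuple[float, float] = (5.0, 10.0)
    delta_band: Tuple[float, float] = (2.5, 4.5)
    ratio_window_s: float = 20.0
    ratio_overlap_s: float = 10.0
    strong_thr: float = 0.25
    strong_persist_s: float = 40.0
    # Amplitude floor (uV) guarding the degenerate all-flat recording whose
    # RMS is ~0 and would otherwise produce a zero threshold.
    threshold_floor_uv: float = 0.01
    # RMS estimated on the whole recording ("offline") or on the
    # pre-induction baseline only ("baseline").
    rms_mode: str = "offline"


@dataclass(frozen=True)
class SpectralParams:
    """Parameters of the sliding-window spectral decomposition."""

    window_s: float = 60.0
    step_s: float = 30.0
    welch_subwindow_s: float = 5.0
    fmin: float = 0.2
    fmax: float = 15.0
    irasa_hmin: float = 1.1
    irasa_hmax: float = 1.9
    irasa_hstep: float = 0.05
    osc_fmin: float = 1.0
    # Robust aperiodic fit: after an initial fit, points with the largest
    # positive log-residuals (oscillatory peak residue is one-sided) are
    # dropped and the fit repeated.
    fit_keep_frac: float = 0.6
    fit_clip_iters: int = 3
    sigma_bounds: Tuple[float, float] = (0.1, 3.0)
    sigma_prune: Tuple[float, float] = (0.2, 2.0)
    max_components: int = 4
    # Band membership for selecting at most one Gaussian per band, and the
    # median frequency used to break exact-area ties.
    theta_membership: Tuple[float, float] = (4.0, 10.0)
    delta_membership: Tuple[float, float] = (2.0, 4.0)
    theta_median_hz: float = 7.5
    delta_median_hz: float = 3.0
    # Power ratios (computed on the raw signal, no decomposition).
    ratio_window_s: float = 20.0
    ratio_overlap_s: float = 0.0
    lowpass_hz: float = 20.0
    theta_band: Tuple[float, float] = (5.0, 10.0)
    delta_band: Tuple[float, float] = (2.5, 4.5)
    t_theta: float = 0.1
    t_delta: float = 0.15
    prominence_persist_s: float = 60.0
    # Theta-decay detection (strict decrease over the horizon) and slope fit.
    decay_horizon_s: float = 300.0
    slope_fit_s: float = 120.0
    slope_min_points: int = 3


@dataclass(frozen=True)
class GammaParams:
    """Parameters of gamma-rebound detection during recovery."""

    band: Tuple[float, float] = (50.0, 70.0)
    window_s: float = 0.2
    threshold_factor: float = 3.0
    persist_s: float = 120.0
    gap_tolerance_s: float = 1.0


@dataclass(frozen=True)
class ClassifyParams:
    """Logistic-regression settings for IES-sensitivity prediction."""

    ies_sensitive_thr_s: float = 30.0
    C: float = 1.0
    n_folds: int = 4
    tol: float = 1e-6
    max_iter: int = 1000
    norm_scale_s: float = 100.0
    norm_offset_s: float = 0.1


@dataclass(frozen=True)
class ArtifactParams:
    """Artifact masking: flat-line dropouts and hysteresis high-amplitude."""

    low_thr_uv: float = 0.08
    high_thr_uv: float = 1200.0
    flat_min_s: float = 0.5
    masked_window_fraction: float = 0.5


@dataclass(frozen=True)
class PipelineParams:
    """Bundle of every stage's parameters (single source of defaults)."""

    artifacts: ArtifactParams = field(default_factory=ArtifactParams)
    suppression: SuppressionParams = field(default_factory=SuppressionParams)
    spectral: SpectralParams = field(default_factory=SpectralParams)
    gamma: GammaParams = field(default_factory=GammaParams)
    classify: ClassifyParams = field(default_factory=ClassifyParams)
    # Tolerance (s) used when checking the strict event ordering; event times
    # are quantized on 10-30 s grids so exact strictness is not meaningful.
    order_tolerance_s: float = 20.0

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Stable hash of the effective configuration (for manifests)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


DEFAULT_PARAMS = PipelineParams()
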