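# Methods

This note documents the models, algorithms and design choices behind
`anesmap`, and what the synthetic validation does and does not establish.

## Signal model and preprocessing

A recording is a single cortical EEG channel in microvolts at sampling rate
f_s (500 Hz in all bundled scenarios), with optional EMG, protocol
annotations (isoflurane start/stop, optional loss/return of movement), and
a boolean artifact mask.  Times are seconds from recording start; all
intervals are half-open `[start, end)`, which makes adjacency and duration
arithmetic exact.

Artifact masking applies two independent rules whose union forms the mask:
(1) runs of exactly-equal consecutive samples lasting ≥ 0.5 s are treated
as hardware dropouts (real dropouts read constant, usually 0; the 0.5 s
minimum keeps chance sample equality from masking good data); (2)
hysteresis thresholding with a low threshold of 0.08 µV and a high
threshold of 1200 µV — every connected excursion of |S| above the low
threshold that touches the high threshold is masked in full, so a large
transient is removed down to its true return to baseline.  Windowed
statistics treat a window as missing when more than half of it is masked,
and otherwise use unmasked samples only.

Filtering is a Butterworth band-pass of order 1 applied forward–backward
(zero phase, effective order 4).  These are deliberately soft filters:
gain is 1 only at the band's geometric center, so for example a pure 3 Hz
tone yields a delta power ratio around 0.8 rather than 1.  Tests and
thresholds account for this; the prominence thresholds (0.1 / 0.15) are
far from those gains, so band logic is unaffected.

## Suppression segmentation

"Amplitude below threshold" is operationalized pointwise as |S(t)| < T
(rather than via a Hilbert envelope), because the ≥ 1 s duration rule makes
half-cycle zero-crossing dips irrelevant — a sinusoid above threshold never
produces a 1 s sub-threshold run.  Detection order matters: runs ≥ 1 s are
identified first, and only then are detections separated by < 0.5 s merged.
Merging before the duration filter would chain the ~20 ms zero-crossing
dips of any ordinary oscillation into one spurious suppression, so the
merge must act on detections, not raw runs.

The IES threshold is adaptive, `T_IES = 0.7 · RMS_EEG`, with the RMS taken
over the whole unmasked recording (a baseline-only mode using the
pre-induction interval is available for on-line use).  An absolute floor of
0.01 µV guards degenerate all-flat recordings whose RMS is ~0.  A threshold
sweep utility reports detected IES duration as a function of the relative
threshold; the curve is provably non-decreasing, and a plateau around the
operating point indicates the detection is insensitive to the exact value.

Band suppressions subtract IES intervals exactly (interval difference) and
re-apply the minimum-duration rule, so the three labels are disjoint by
construction.

The strong-IES onset τ_S is the first ratio-window center t at or after
induction such that IESSR > 0.25 on every window in [t, t + 40 s]; missing
windows break the run, and a candidate whose 40 s horizon extends beyond
the grid is not declared.  The same "sustained predicate on a window grid"
helper implements the 1-minute band prominence/dampening rules.

## Spectral decomposition

Each 60 s window (30 s step) is processed as follows.

1. Welch PSD with 5 s Hann sub-windows and 50% overlap (0.2 Hz
   resolution), kept on 0.2–15 Hz.  The 50% overlap is a standard variance
   reduction; only the sub-window length is essential to the grid.
2. IRASA: for factors h = 1.1 … 1.9 in steps of 0.05 (all exactly rational,
   k/20, so polyphase resampling is drift-free), the signal is resampled up
   and down and both PSDs are computed at the nominal rate.  Time
   stretching moves an oscillation at f₀ to f₀/h (resp. f₀·h) while a
   self-similar 1/f background keeps its shape up to an amplitude factor
   that the geometric mean of each (h, 1/h) pair cancels exactly.  The
   pointwise median over the 17 pairs is the aperiodic estimate.
3. The aperiodic model `a/(c + f^p)` is fitted to the median PSD in
   log–log by bounded nonlinear least squares (a > 0, c ≥ 0, p ≥ 0,
   multiple starts).  The offset c keeps the model finite at f → 0 and is
   what lets the fit extend to 0.2 Hz.  The fit is robust: after the
   initial pass, the 40% of grid points with the largest log-residuals are
   dropped and the fit repeated (three iterations).  Residual oscillatory
   structure that survives the IRASA median — the shifted-peak tails of a
   strong narrow rhythm land inside 4–15 Hz for these factors — is strictly
   positive, so one-sided clipping removes its pull on the exponent while
   an uncontaminated spectrum is refitted on a clean subset and unbiased.
   On noiseless model curves the fit recovers (a, c, p) to machine
   precision; on synthetic 1/f signals the exponent is recovered to ±0.05,
   and adding a realistic theta rhythm (peak ~50× the local background)
   moves it by ≲ 0.15.
4. The oscillatory residual (raw PSD minus the aperiodic model, negatives
   clipped to 0) is fitted on 1–15 Hz with up to four Gaussians seeded at
   local maxima of prominence ≥ std(residual), with bounds f ∈ [1, 15],
   σ ∈ [0.1, 3].  Components with σ < 0.2 or σ > 2 Hz, or amplitude
   b ≤ std(residual), are pruned.  At most one component is kept per band —
   theta membership 4–10 Hz, delta 2–4 Hz (a component at exactly 4 Hz
   counts as theta) — chosen by largest area b·σ; an exact area tie goes to
   the component closest to the band median (7.5 / 3 Hz), then to the lower
   frequency, making selection fully deterministic.

Rhythm tracking joins detections in consecutive frames by straight lines in
center frequency and width; a detection with empty neighbors on both sides
is considered not significant and dropped, so every track run spans at
least two frame centers.  The envelopes up = f + σ and low = f − σ differ
by exactly 2σ wherever the track is defined.

The theta-decay onset is the first frame center t after induction whose
tracked f_θ strictly exceeds every tracked value in the following 5 min
(evaluated on the frame grid; frames without a theta detection are skipped,
a candidate seeing no detection at all in its horizon is not declared, and
the horizon must fit inside the recording).  The slope is the least-squares
slope of f_θ over [τ_θdecay, τ_θdecay + 2 min], needing ≥ 3 tracked frames,
reported in Hz/min.  Because the first fitted frames straddle the decay
onset and the last may reach the post-decay plateau, a planted −1 Hz/min
ramp is recovered as roughly −0.75 to −0.9 Hz/min; this quantization bias
is inherent to the 60 s window and documented rather than corrected.

## Gamma rebound

The 50–70 Hz power is computed on 0.2 s non-overlapping windows.  The
threshold is 3 × the RMS of that power series over the pre-induction
baseline (the RMS is of the power values themselves, not of the filtered
signal).  During recovery (t > τ_Isostop), supra-threshold runs separated
by gaps < 1 s are merged — the rebound is a burst train, so strict
pointwise persistence would never trigger — and the first merged run
lasting ≥ 2 min defines the rebound onset.  The rebound magnitude A_γ is
the trapezoidal integral of the power series from isoflurane cessation to
the end of the recording.

## Events and states

The event chain collects, per recording, the delays from induction of:
theta decay, delta appearance, theta dampening, delta dampening, first IES,
strong IES, and gamma rebound, plus movement marks.  Ordering is checked on
adjacent present events with a one-window (20 s) tolerance, because the
events are quantized on different grids (10, 20 and 30 s); absent events
are skipped.

State labeling is a pure cascade per 20 s window: pre-induction windows are
Awake; windows after the return of movement are Movement, or
γ-rebound + Movement while the detected rebound covers more than half the
window; IESSR > 0.25 gives Strong IES; a little IES (0 < IESSR ≤ 0.25) with
delta prominent but theta dampened gives Light IES; both rhythms prominent
give Prominent δ&θ, delta alone Prominent δ; theta alone is θ-decay once
the decay has started (Awake before); windows with neither rhythm — with or
without a little IES — fall to Pre-IES.  Prominence flags carry the
1-minute persistence rule as hysteresis (theta starts prominent, delta
absent), which prevents single-window flicker and makes the realized state
sequence a walk on the chart's edge set.  Movement takes precedence over
spectral states after the return of movement; that resolution, like the
rule that θ-decay ends when delta appears, is a design choice where
window-level rules were genuinely open.

Loss/return of movement are protocol annotations; a windowed-EMG-RMS
threshold detector is provided as a convenience for unannotated data and is
explicitly a heuristic, not a validated method.

## Sensitivity classification

The positive class is cumulative IES duration strictly above 30 s — the
regime in which the gamma rebound appears.  Delays map through
τ* = ln(1 + 100/(delay + 0.1)) (natural log; the 0.1 s offset bounds the
transform at zero delay, ln 1001 ≈ 6.9088); an event that never occurred
maps to 0, the infinite-delay limit.  The model is logistic regression with
l2 penalty and C = 1 (lbfgs, tol 1e−6, max 1000 iterations), evaluated by
stratified group 4-fold cross-validation: recordings of one subject never
split across folds, and validation folds keep the cohort's class balance to
within one recording.  ROC-AUC is reported pooled over out-of-fold
predictions (primary) and per fold.  Pooling concatenates probabilities
from differently calibrated fold models; with an uninformative feature this
pushes the pooled AUC systematically below 0.5 (per-fold AUCs are exactly
0.5 there), which is why both aggregations are reported.

## Synthetic data: what it emulates and what it does not

The generator composes each recording from stages that tile the duration:

- 1/f background synthesized by frequency-domain shaping: rfft-bin
  amplitudes √(S(f)·f_s·n/2) with S(f) = a/(c + f^p) and complex Gaussian
  phases, giving the exact expected PSD with no filter-design error.
  Defaults a = 200 µV²·Hz, c = 0.5, p = 2 put the background RMS near
  21 µV, a plausible cortical screw-electrode scale chosen for detector
  testability (no amplitude calibration exists for this preparation).
- Rhythms as constant-amplitude sinusoids whose instantaneous frequency
  follows the stage's linear trajectory plus slow (< 0.5 Hz) Gaussian
  jitter of standard deviation σ, yielding an approximately Gaussian
  spectral peak of width σ.  Theta: amplitude 20 µV at 8 Hz (decaying to
  6 Hz over 2 min after induction, i.e. −1 Hz/min); delta: 25 µV at 3 Hz;
  both σ = 0.5 Hz.  These amplitudes give power ratios around 0.35–0.46
  when present and below 0.08 when absent — prominent but not caricatured.
- Iso-electric epochs as multiplicative envelopes dipping to 2% of the
  local amplitude (near-flat, not exactly zero, so detectors face realistic
  traces) with 50 ms cosine ramps; inside a burst-suppression stage, 7 s
  flat epochs alternate with gaps sized to hit the stage's IES fraction
  (0.5 in the deep scenario, i.e. IESSR ≈ 0.35–1 per 20 s window).
- A gamma burst train at 60 Hz (σ = 1 Hz, amplitude 12 µV, 0.7 s bursts
  with 0.25 s gaps) starting 5 s after isoflurane cessation, and an EMG of
  20–200 Hz noise at 150 µV RMS, scaled to 5% between LOM and ROM.
- Stages are crossfaded over 1 s by raised-cosine partition-of-unity
  weights; ground truth refers to the nominal boundaries.  The planted
  gamma area accounts for the envelope shape exactly (each burst carries
  duration − 1.25 × ramp of squared-envelope time) plus the aperiodic
  background's 50–70 Hz band power over the recovery.

Two bundled scenarios fix the study conditions: **deep** (20 min, induction
at 3 min, cessation at 16 min; theta decay → δ&θ → δ only → neither →
burst suppression at IES fraction 0.5 → recovery with gamma and returning
theta) and **light** (delta persists until cessation, no IES, no gamma).

What passing on these scenarios shows: the detectors recover planted
structure through the full pipeline — thresholds, persistence rules, grid
quantization, fits — at realistic signal-to-background contrasts, with
every event landing within one analysis window across seeds.  What it does
not show: robustness to real-world artifacts beyond the masked classes
(chewing, electrode pops mid-amplitude), non-Gaussian or non-stationary
backgrounds, rhythms with harmonic structure, EMG bleed into the gamma
band, or inter-animal variability in absolute amplitude; conclusions about
real recordings require the thresholds (especially r_IES = 0.7 and the
prominence thresholds) to be revalidated per preparation.

## Numerical choices and degenerate inputs

- Welch sub-window 5 s, Hann, 50% overlap; IRASA factors exactly rational.
- Aperiodic fit bounds: log a ∈ [−60, 60], c ∈ [0, 1000], p ∈ [0, 10];
  restarts from three initializations; a window whose fit fails is treated
  as missing rather than aborting the run.
- Gaussian fit: joint bounded least squares over ≤ 4 seeded components;
  on failure the per-peak seeds are used so pruning still applies.
- All-flat recordings: the absolute threshold floor (0.01 µV) yields one
  full-recording IES segment instead of a zero threshold.
- Ratio denominators of 0 (zero signal in a window) give missing values,
  never division errors.
- Event searches whose persistence horizon does not fit inside the grid do
  not declare the event (no partial-horizon declarations at recording end).

## Problem sizes

The bundled scenarios are 20 min at 500 Hz (600 k samples); exponent-
recovery checks use 10 min signals over several seeds; the classifier
cohort is 24 recordings from 12 subjects with 20 label permutations for
the chance-level check.  These sizes exercise every code path of the
method while keeping the full validation suite fast enough to run on every
change.
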