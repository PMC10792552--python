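"""Separate the EEG spectrum into 1/f background and tracked rhythms.

Synthesizes five minutes of 1/f background (exponent p = 2) plus an 8 Hz
theta rhythm, then runs the sliding-window IRASA decomposition: each 60 s
window yields an aperiodic fit a/(c + f^p) and at most one Gaussian per
band, and consecutive detections are interpolated into continuous rhythm
tracks.  Prints the recovered exponent and theta parameters.
"""

import numpy as np

from anesmap import Recording, generate_aperiodic, generate_oscillation
from anesmap.spectral import spectral_frames, track_rhythms

fs = 500.0
background = generate_aperiodic(a=1.0, c=0.1, p=2.0, duration_s=300, fs=fs, seed=3)
theta = generate_oscillation(1.0, 8.0, None, 0.5, 300, fs, seed=4)
rec = Recording(eeg=background + theta, fs=fs)

grid, frames = spectral_frames(rec)
valid = [fr for fr in frames if fr.valid]
exponents = [fr.aperiodic.p for fr in valid]
thetas = [fr.theta for fr in valid if fr.theta is not None]

print(f"{len(valid)} windows decomposed")
print(f"recovered 1/f exponent: median {np.median(exponents):.2f} (generated 2.0)")
print(f"theta detected in {len(thetas)}/{len(valid)} windows; "
      f"center {np.median([t.f for t in thetas]):.2f} Hz (planted 8.0), "
      f"width {np.median([t.sigma for t in thetas]):.2f} Hz (planted 0.5)")

tracks = track_rhythms(frames)
theta_track = tracks["theta"]
print(f"theta track spans {theta_track.valid_intervals}")
print("\nThe IRASA median removes the oscillatory peak before the 1/f fit,")
print("so the exponent is recovered without bias from the rhythm, while the")
print("clipped residual yields the rhythm's own parameters.")
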