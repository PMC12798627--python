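"""Generate one guided-breathwork session and inspect its ground truth.

The simulator renders a 10-minute four-channel recording (ECG, EDA, EMG,
respiration) with a 60 s free-breathing lead-in followed by 4-7-8 pacing
(inhale 4 s, hold 7 s, exhale 8 s), and returns every event it rendered.
"""

import numpy as np

from physiopipe import SimulationConfig, simulate_session

cfg = SimulationConfig(seed=1, protocol="breathwork_478")
rec, truth = simulate_session(cfg, participant_id="demo", tech="MindGym")

print("channels:", {m: f"{ch.n} samples @ {ch.fs:g} Hz" for m, ch in rec.channels.items()})
print("markers:", rec.markers)
print("true inhalation onsets (first 6):", truth.inhalation_onsets_s[:6])
print("true R-peak count:", truth.r_peaks_s.size)
print("true breath rate per 2-min window (bpm):", truth.breath_rate_per_window())

# The first window mixes the 15 bpm lead-in with 19 s cycles; later windows
# sit near 60/19 ~ 3.2 bpm -- the paced-breathing signature downstream
# stages must recover.
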