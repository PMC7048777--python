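"""Simulate a voltage-clamp recording and detect its sPSC events.

Builds a 60 s synthetic trace (1 Hz Poisson events, ~20 pA median amplitude,
2 pA noise), runs threshold detection, and compares against the generator's
ground truth.  Printed: true vs detected event counts, the mean amplitude and
interevent interval, and the one-minute highest-activity window.
"""

import numpy as np

from ephysq import (
    DetectionConfig,
    SimConfig,
    detect_events,
    select_highest_activity_window,
    simulate_spsc_trace,
)

cfg = SimConfig(duration_s=60.0, event_rate_hz=1.0, noise_sd_pa=2.0, seed=42)
trace, truth = simulate_spsc_trace(cfg)
events = detect_events(trace, DetectionConfig())
window, start = select_highest_activity_window(events, trace.duration_s, 60.0)

print(f"ground truth: {len(truth)} events; detected: {len(events)}")
print(f"mean amplitude: {events.amplitude_pa.mean():.1f} pA "
      f"(true median target ~20 pA)")
print(f"mean interevent interval: {events.iei_s.mean():.2f} s "
      f"(1 Hz rate -> ~1 s)")
print(f"highest-activity window starts at {start:.0f} s "
      f"with {len(window)} events")
# Detected counts track the Poisson ground truth; amplitudes and IEIs are the
# inputs to the group comparisons in the other examples.
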