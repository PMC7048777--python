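"""Peak-aligned averaging and biexponential decay fitting.

Detects events in a noisy synthetic trace, averages them aligned on their
peaks, and fits A1*exp(-t/tau1) + A2*exp(-t/tau2) to the decay, summarised
by the amplitude-weighted time constant.
"""

import numpy as np

from ephysq import (
    SimConfig,
    average_events,
    detect_events,
    fit_biexponential,
    make_biexp_waveform,
    simulate_spsc_trace,
)

cfg = SimConfig(duration_s=120.0, event_rate_hz=1.0, noise_sd_pa=2.0, seed=3)
trace, _ = simulate_spsc_trace(cfg)
events = detect_events(trace)
avg = average_events(trace, events, pre_ms=5, post_ms=80)
fit = fit_biexponential(avg.waveform, trace.fs_hz)

# reference: the same fit applied to the noise-free generator waveform
# (its finite rise phase makes the realised decay slower than the raw
# tau1/tau2 mixture would suggest)
ideal = make_biexp_waveform(cfg.rise_tau_ms, cfg.tau1_ms, cfg.tau2_ms,
                            cfg.frac_fast, cfg.fs_hz)
ref = fit_biexponential(-ideal, cfg.fs_hz)

print(f"averaged {avg.n_events} events ({avg.n_dropped} at boundaries dropped)")
print(f"fit: A1={fit.A1:.1f} pA tau1={fit.tau1_ms:.2f} ms, "
      f"A2={fit.A2:.1f} pA tau2={fit.tau2_ms:.2f} ms "
      f"(converged={fit.converged})")
print(f"weighted tau = {fit.tau_weighted_ms:.2f} ms; "
      f"noise-free waveform gives {ref.tau_weighted_ms:.2f} ms")
# The weighted tau is the single per-cell decay number used when comparing
# groups (e.g. 8.72 +- 0.89 ms vs 8.01 +- 1.06 ms in the worked ANOVA
# example); the small excess over the noise-free reference comes from
# overlapping neighbouring events in the averaging windows.
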