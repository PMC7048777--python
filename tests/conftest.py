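import numpy as np
import pytest

from ephysq import SimConfig, Trace, make_biexp_waveform, simulate_spsc_trace


@pytest.fixture
def fs() -> float:
    return 5000.0


def build_trace_with_events(times_s, amps_pa, duration_s, fs_hz=5000.0,
                            noise_sd=0.0, seed=0, event_sign=-1,
                            rise_tau_ms=0.5, tau1_ms=2.0, tau2_ms=20.0,
                            frac_fast=0.63):
    """Deterministic trace with events at chosen onsets; returns
    (Trace, peak_times, amps)."""
    w = make_biexp_waveform(rise_tau_ms, tau1_ms, tau2_ms, frac_fast, fs_hz)
    peak_off = int(np.argmax(w))
    n = int(round(duration_s * fs_hz))
    x = np.zeros(n)
    peaks = []
    for t0, a in zip(times_s, amps_pa):
        i = int(round(t0 * fs_hz))
        seg = w[: n - i]
        x[i : i + seg.size] += event_sign * a * seg
        peaks.append((i + peak_off) / fs_hz)
    if noise_sd > 0:
        x += np.random.default_rng(seed).normal(0, noise_sd, n)
    tr = Trace(samples=x, fs_hz=fs_hz, units="pA", modality="voltage_clamp")
    return tr, np.asarray(peaks), np.asarray(amps_pa, dtype=float)


def separated_noise_free_fixtures(n_traces=5, min_gap_s=0.25):
    """Noise-free Poisson recordings whose events are all well separated.

    Scans seeds in order and keeps records with no two ground-truth events
    closer than ``min_gap_s`` — the regime where detection must be exact.
    """
    out = []
    seed = 0
    while len(out) < n_traces and seed < 200:
        cfg = SimConfig(duration_s=20.0, event_rate_hz=0.4, noise_sd_pa=0.0,
                        seed=seed)
        trace, truth = simulate_spsc_trace(cfg)
        gaps = np.diff(truth.event_times_s)
        if len(truth) >= 3 and (gaps.size == 0 or gaps.min() > min_gap_s):
            out.append((trace, truth))
        seed += 1
    assert len(out) == n_traces
    return out
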