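"""Synthetic patch-clamp trace generation with known ground truth.

Emulates whole-cell recordings from cultured hippocampal neurons: spontaneous
postsynaptic currents (sPSCs) appear as transient deflections on a noisy
baseline under voltage clamp at -70 mV, and current-step protocols elicit
trains of action potentials under current clamp.  Events arrive as a
homogeneous Poisson process; each event is a biexponential-decay waveform
with a brief exponential rise, scaled by a log-normal amplitude; events
superpose linearly and ride on Gaussian instrument noise.  Every simulated
trace carries its ground truth (event peak times and amplitudes, or spike
counts) so detection and kinetics code can be validated exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .events import Trace

__all__ = [
    "SimConfig",
    "GroundTruth",
    "StepProtocol",
    "make_biexp_waveform",
    "simulate_spsc_trace",
    "simulate_step_protocol",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters for one synthetic voltage-clamp sPSC recording.

    Amplitudes are log-normal: ``amp_mu``/``amp_sigma`` parameterise the log,
    so the median amplitude is ``exp(amp_mu)`` pA (default ~20 pA).  Kinetic
    defaults (tau1=2 ms, tau2=20 ms, frac_fast=0.63) give an
    amplitude-weighted decay constant of ~8.7 ms, the scale typical of mixed
    sPSCs in hippocampal cultures.  Inward currents at a -70 mV holding
    potential are negative deflections (``event_sign=-1``).
    """

    duration_s: float = 60.0
    fs_hz: float = 5000.0
    event_rate_hz: float = 1.0
    amp_mu: float = math.log(20.0)
    amp_sigma: float = 0.4
    rise_tau_ms: float = 0.5
    tau1_ms: float = 2.0
    tau2_ms: float = 20.0
    frac_fast: float = 0.63
    noise_sd_pa: float = 2.0
    event_sign: int = -1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.event_rate_hz < 0:
            raise ValueError("event_rate_hz must be >= 0")
        if self.tau1_ms <= 0 or self.tau2_ms <= 0:
            raise ValueError("decay time constants must be positive")
        if self.rise_tau_ms < 0:
            raise ValueError("rise_tau_ms must be >= 0")
        if not 0.0 <= self.frac_fast <= 1.0:
            raise ValueError("frac_fast must lie in [0, 1]")
        if self.noise_sd_pa < 0:
            raise ValueError("noise_sd_pa must be >= 0")
        if self.event_sign not in (-1, 1):
            raise ValueError("event_sign must be -1 (inward) or +1 (outward)")


@dataclass(frozen=True)
class GroundTruth:
    """True event peak times (s) and positive peak amplitudes (pA)."""

    event_times_s: np.ndarray
    event_amps_pa: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.event_times_s, dtype=float)
        a = np.asarray(self.event_amps_pa, dtype=float)
        if t.shape != a.shape or t.ndim != 1:
            raise ValueError("times and amplitudes must be 1-D and equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("event times must be strictly ascending")
        if np.any(a <= 0):
            raise ValueError("amplitudes must be positive magnitudes")
        object.__setattr__(self, "event_times_s", t)
        object.__setattr__(self, "event_amps_pa", a)

    def __len__(self) -> int:
        return self.event_times_s.size


@dataclass(frozen=True)
class StepProtocol:
    """Current-clamp step protocol with a known spike-count schedule.

    ``spike_counts[i]`` is the number of stereotyped action potentials to
    place in the step window of sweep ``i``; the injected current for sweep
    ``i`` is ``(i + 1) * step_increment_pa``.
    """

    spike_counts: tuple[int, ...]
    step_increment_pa: float = 50.0
    step_duration_ms: float = 500.0
    baseline_mv: float = -65.0
    pre_ms: float = 100.0
    post_ms: float = 100.0
    fs_hz: float = 5000.0
    noise_sd_mv: float = 0.3

    def __post_init__(self) -> None:
        if self.step_increment_pa <= 0:
            raise ValueError("step_increment_pa must be positive")
        if len(self.spike_counts) < 1:
            raise ValueError("need at least one step")
        if any(c < 0 for c in self.spike_counts):
            raise ValueError("spike counts must be >= 0")
        if self.step_duration_ms <= 0 or self.fs_hz <= 0:
            raise ValueError("step_duration_ms and fs_hz must be positive")

    @property
    def n_steps(self) -> int:
        return len(self.spike_counts)

    @property
    def step_currents_pa(self) -> np.ndarray:
        return self.step_increment_pa * np.arange(1, self.n_steps + 1)


def make_biexp_waveform(
    rise_tau_ms: float,
    tau1_ms: float,
    tau2_ms: float,
    frac_fast: float,
    fs_hz: float,
    window_ms: float | None = None,
) -> np.ndarray:
    """Sampled unit-peak synaptic waveform.

    Shape: ``(1 - exp(-t/rise_tau)) * (f*exp(-t/tau1) + (1-f)*exp(-t/tau2))``
    normalised so its maximum is exactly 1.  ``rise_tau_ms=0`` gives an
    instantaneous rise (pure biexponential decay).  ``window_ms`` defaults to
    a length at which the tail has decayed below 0.1% of the peak; an
    explicit window must still let the tail fall below 1% of the peak.
    """
    if tau1_ms <= 0 or tau2_ms <= 0:
        raise ValueError("decay time constants must be positive")
    if rise_tau_ms < 0:
        raise ValueError("rise_tau_ms must be >= 0")
    if not 0.0 <= frac_fast <= 1.0:
        raise ValueError("frac_fast must lie in [0, 1]")
    if fs_hz <= 0:
        raise ValueError("fs_hz must be positive")
    if window_ms is None:
        window_ms = max(tau1_ms, tau2_ms) * math.log(1000.0) + 8.0 * rise_tau_ms
    n = int(round(window_ms / 1000.0 * fs_hz))
    if n < 2:
        raise ValueError("window_ms too short for the sampling rate")
    t = np.arange(n) / fs_hz * 1000.0  # ms
    decay = frac_fast * np.exp(-t / tau1_ms) + (1.0 - frac_fast) * np.exp(-t / tau2_ms)
    if rise_tau_ms > 0:
        w = (1.0 - np.exp(-t / rise_tau_ms)) * decay
    else:
        w = decay
    peak = w.max()
    if peak <= 0:
        raise ValueError("degenerate waveform")
    w = w / peak
    if w[-1] > 0.01:
        raise ValueError(
            f"window_ms={window_ms} too short: tail at {w[-1]:.3f} of peak (>1%)"
        )
    return w


def simulate_spsc_trace(config: SimConfig) -> tuple[Trace, GroundTruth]:
    """Simulate one voltage-clamp trace; returns the trace and its truth.

    Event count is Poisson(rate * duration); onsets are uniform on the
    record; each event adds ``event_sign * amp * waveform`` starting at its
    onset sample (linear superposition, no refractoriness).  Ground-truth
    times are the event *peak* times — onset plus the waveform's rise delay —
    since peaks are what detection localises and aligns on.
    """
    rng = np.random.default_rng(config.seed)
    n_samples = int(round(config.duration_s * config.fs_hz))
    samples = np.zeros(n_samples)

    w = make_biexp_waveform(
        config.rise_tau_ms, config.tau1_ms, config.tau2_ms,
        config.frac_fast, config.fs_hz,
    )
    peak_offset = int(np.argmax(w))

    n_events = rng.poisson(config.event_rate_hz * config.duration_s)
    onsets = np.sort(rng.uniform(0.0, config.duration_s, size=n_events))
    amps = rng.lognormal(config.amp_mu, config.amp_sigma, size=n_events)

    kept_t, kept_a = [], []
    for t0, amp in zip(onsets, amps):
        i0 = int(round(t0 * config.fs_hz))
        if i0 + peak_offset >= n_samples:
            continue  # peak would fall off the record
        seg = w[: n_samples - i0]
        samples[i0 : i0 + seg.size] += config.event_sign * amp * seg
        kept_t.append((i0 + peak_offset) / config.fs_hz)
        kept_a.append(amp)

    if config.noise_sd_pa > 0:
        samples += rng.normal(0.0, config.noise_sd_pa, size=n_samples)

    # same-sample collisions would break strict ascent; nudge is not needed at
    # realistic rates, so collapse duplicates keeping the larger event
    times = np.asarray(kept_t)
    amps_out = np.asarray(kept_a)
    if times.size > 1:
        order = np.argsort(times, kind="stable")
        times, amps_out = times[order], amps_out[order]
        keep = np.ones(times.size, dtype=bool)
        for i in range(1, times.size):
            if times[i] <= times[i - 1]:
                if amps_out[i] > amps_out[i - 1]:
                    keep[i - 1] = False
                else:
                    keep[i] = False
        times, amps_out = times[keep], amps_out[keep]

    trace = Trace(samples=samples, fs_hz=config.fs_hz, units="pA",
                  modality="voltage_clamp")
    return trace, GroundTruth(event_times_s=times, event_amps_pa=amps_out)


def _spike_shape(fs_hz: float, peak_mv_above_zero: float = 25.0,
                 half_width_ms: float = 0.6) -> np.ndarray:
    """Stereotyped action-potential bump (mV above baseline), Gaussian shape."""
    sd_ms = half_width_ms / 2.355  # FWHM -> sd
    half_n = int(round(4 * sd_ms / 1000.0 * fs_hz))
    t = np.arange(-half_n, half_n + 1) / fs_hz * 1000.0
    return peak_mv_above_zero * np.exp(-0.5 * (t / sd_ms) ** 2)


def simulate_step_protocol(
    protocol: StepProtocol, seed: int = 0
) -> tuple[list[Trace], np.ndarray]:
    """Simulate the current-clamp sweeps of a step protocol.

    Each sweep holds ``baseline_mv`` throughout; during the step window the
    requested number of stereotyped spikes is placed at evenly spaced times,
    each crossing 0 mV (peaks ~+25 mV relative to 0).  Returns the sweeps and
    the ground-truth spike counts (one per sweep).
    """
    rng = np.random.default_rng(seed)
    fs = protocol.fs_hz
    n_pre = int(round(protocol.pre_ms / 1000.0 * fs))
    n_step = int(round(protocol.step_duration_ms / 1000.0 * fs))
    n_post = int(round(protocol.post_ms / 1000.0 * fs))
    n_total = n_pre + n_step + n_post

    # spike bump lifting the membrane from baseline to above 0 mV
    bump = _spike_shape(fs) + (0.0 - protocol.baseline_mv)
    half = bump.size // 2

    traces: list[Trace] = []
    for count in protocol.spike_counts:
        v = np.full(n_total, protocol.baseline_mv)
        if count > 0:
            centers = n_pre + ((np.arange(count) + 0.5) / count * n_step).astype(int)
            for c in centers:
                lo, hi = max(0, c - half), min(n_total, c + half + 1)
                v[lo:hi] = protocol.baseline_mv + bump[lo - (c - half) : hi - (c - half)]
        if protocol.noise_sd_mv > 0:
            v = v + rng.normal(0.0, protocol.noise_sd_mv, size=n_total)
        traces.append(Trace(samples=v, fs_hz=fs, units="mV",
                            modality="current_clamp"))
    return traces, np.asarray(protocol.spike_counts, dtype=int)
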