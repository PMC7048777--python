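"""Spontaneous postsynaptic current detection and action-potential analysis.

Detection replaces a commercial mini-event detector with a transparent,
parameter-sparse pipeline: rolling-median baseline subtraction, robust noise
estimation (1.4826 * MAD), threshold crossing on a lightly smoothed residual
with hysteresis re-arming, peak localisation on the raw residual, and
refractory merging that keeps the larger of two close events.  Event times
are peak times.  The module also selects the one-minute window with the most
activity, builds peak-aligned average event waveforms (per cell, then per
group), and counts/measures action potentials in current-step sweeps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Trace",
    "DetectionConfig",
    "EventTable",
    "ApResult",
    "EventAverage",
    "detect_events",
    "compute_ieis",
    "select_highest_activity_window",
    "average_events",
    "average_of_cell_averages",
    "count_action_potentials",
    "analyze_step_protocol",
]


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled recording (current in pA or voltage in mV)."""

    samples: np.ndarray
    fs_hz: float
    units: str  # "pA" | "mV"
    modality: str  # "voltage_clamp" | "current_clamp"

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 1 or s.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.units not in ("pA", "mV"):
            raise ValueError("units must be 'pA' or 'mV'")
        if self.modality not in ("voltage_clamp", "current_clamp"):
            raise ValueError("modality must be voltage_clamp or current_clamp")
        object.__setattr__(self, "samples", s)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs_hz


@dataclass(frozen=True)
class DetectionConfig:
    """Threshold-detector parameters.

    ``threshold_k`` is in multiples of the robust noise SD.  ``noise_floor``
    (trace units) keeps the threshold positive on noise-free synthetic input,
    where the MAD estimate is exactly zero.  ``smooth_ms`` is the moving-
    average width applied to the residual for crossing logic only; peak time
    and amplitude are refined on the unsmoothed residual.
    """

    threshold_k: float = 4.0
    baseline_window_ms: float = 200.0
    peak_search_ms: float = 10.0
    refractory_ms: float = 5.0
    event_sign: int = -1
    smooth_ms: float = 1.0
    noise_floor: float = 0.01

    def __post_init__(self) -> None:
        if self.threshold_k <= 0:
            raise ValueError("threshold_k must be positive")
        if min(self.baseline_window_ms, self.peak_search_ms,
               self.refractory_ms) <= 0:
            raise ValueError("all windows must be positive")
        if self.event_sign not in (-1, 1):
            raise ValueError("event_sign must be -1 or +1")


@dataclass(frozen=True)
class EventTable:
    """Detected events: peak times (s), amplitudes (pA), interevent intervals."""

    event_time_s: np.ndarray
    amplitude_pa: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.event_time_s, dtype=float)
        a = np.asarray(self.amplitude_pa, dtype=float)
        if t.shape != a.shape or t.ndim != 1:
            raise ValueError("times and amplitudes must be 1-D, equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("event times must be strictly ascending")
        if np.any(a <= 0):
            raise ValueError("amplitudes must be positive")
        object.__setattr__(self, "event_time_s", t)
        object.__setattr__(self, "amplitude_pa", a)

    def __len__(self) -> int:
        return self.event_time_s.size

    @property
    def iei_s(self) -> np.ndarray:
        return compute_ieis(self.event_time_s)

    def to_frame(self) -> pd.DataFrame:
        iei = np.concatenate([[np.nan], self.iei_s]) if len(self) else np.array([])
        return pd.DataFrame(
            {"event_time_s": self.event_time_s,
             "amplitude_pa": self.amplitude_pa,
             "iei_s": iei}
        )


@dataclass(frozen=True)
class ApResult:
    """Action-potential counts and amplitudes for one or more sweeps."""

    step_current_pa: np.ndarray  # one entry per sweep
    spike_count: np.ndarray
    spike_amplitude_mv: tuple[np.ndarray, ...]  # per-sweep arrays
    baseline_mv: np.ndarray


@dataclass(frozen=True)
class EventAverage:
    """Peak-aligned mean event waveform for one cell."""

    waveform: np.ndarray
    pre_samples: int  # index of the alignment (peak) sample
    fs_hz: float
    n_events: int
    n_dropped: int


def _rolling_median(x: np.ndarray, window: int) -> np.ndarray:
    w = max(3, window | 1)  # odd, >= 3
    return (
        pd.Series(x).rolling(w, center=True, min_periods=1).median().to_numpy()
    )


def detect_events(trace: Trace, cfg: DetectionConfig | None = None) -> EventTable:
    """Detect sPSC-like events in a voltage-clamp current trace.

    Pipeline: rolling-median baseline (``baseline_window_ms``) -> residual ->
    robust noise SD (1.4826 * MAD) -> moving-average smoothing of
    ``event_sign * residual`` -> upward threshold crossings at
    ``threshold_k * sigma`` with hysteresis (a new event requires the smoothed
    signal to have fallen below half-threshold since the previous one) ->
    peak within ``peak_search_ms`` of the crossing, refined on the raw
    residual -> refractory merging keeping the larger event.
    """
    cfg = cfg or DetectionConfig()
    if trace.modality != "voltage_clamp":
        raise ValueError("event detection requires a voltage_clamp trace")
    n = trace.samples.size
    w_base = int(round(cfg.baseline_window_ms / 1000.0 * trace.fs_hz))
    if n <= w_base:
        raise ValueError("trace shorter than the baseline window")

    baseline = _rolling_median(trace.samples, w_base)
    residual = trace.samples - baseline
    sigma = 1.4826 * np.median(np.abs(residual - np.median(residual)))
    thr = max(cfg.threshold_k * sigma, cfg.noise_floor)
    rearm = 0.5 * thr

    s = cfg.event_sign * residual
    w_sm = max(1, int(round(cfg.smooth_ms / 1000.0 * trace.fs_hz)))
    s_f = np.convolve(s, np.ones(w_sm) / w_sm, mode="same") if w_sm > 1 else s

    above = s_f > thr
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        crossings = np.concatenate([[0], crossings])
    below_rearm = np.flatnonzero(s_f < rearm)

    w_peak = max(1, int(round(cfg.peak_search_ms / 1000.0 * trace.fs_hz)))
    half_sm = w_sm // 2 + 1
    cand_t, cand_a = [], []
    last_accept = -1
    for c in crossings:
        if last_accept >= 0:
            # hysteresis: require a dip below the re-arm level in between
            j = np.searchsorted(below_rearm, last_accept)
            if j >= below_rearm.size or below_rearm[j] >= c:
                continue
        p_sm = c + int(np.argmax(s_f[c : c + w_peak]))
        lo, hi = max(0, p_sm - half_sm), min(n, p_sm + half_sm + 1)
        p = lo + int(np.argmax(s[lo:hi]))
        cand_t.append(p)
        cand_a.append(s[p])
        last_accept = c

    if not cand_t:
        return EventTable(np.array([]), np.array([]))

    # refractory merge: keep the larger of events closer than refractory_ms
    refr = cfg.refractory_ms / 1000.0 * trace.fs_hz
    idx = np.asarray(cand_t)
    amp = np.asarray(cand_a)
    order = np.argsort(idx, kind="stable")
    idx, amp = idx[order], amp[order]
    kept_i: list[int] = []
    kept_a: list[float] = []
    for i, a in zip(idx, amp):
        if kept_i and i - kept_i[-1] < refr:
            if a > kept_a[-1]:
                kept_i[-1], kept_a[-1] = i, a
        else:
            kept_i.append(int(i))
            kept_a.append(float(a))
    times = np.asarray(kept_i) / trace.fs_hz
    return EventTable(event_time_s=times, amplitude_pa=np.asarray(kept_a))


def compute_ieis(event_times: np.ndarray) -> np.ndarray:
    """Interevent intervals (s); empty for fewer than two events."""
    t = np.asarray(event_times, dtype=float)
    if t.size < 2:
        return np.array([])
    d = np.diff(t)
    if np.any(d <= 0):
        raise ValueError("event times must be strictly ascending")
    return d


def select_highest_activity_window(
    events: EventTable, trace_duration_s: float, window_s: float = 60.0
) -> tuple[EventTable, float]:
    """Restrict events to the length-``window_s`` window with the most events.

    Candidate windows are anchored at each event time (clamped so the window
    fits in the record) plus the start of the record; ties go to the earliest
    window start.  Returns the restricted table and the window start time.
    """
    if window_s > trace_duration_s:
        raise ValueError("window_s exceeds the trace duration")
    t = events.event_time_s
    if t.size == 0:
        return events, 0.0
    starts = np.unique(np.concatenate([[0.0], np.minimum(t, trace_duration_s - window_s)]))
    counts = np.searchsorted(t, starts + window_s, side="right") - np.searchsorted(
        t, starts, side="left"
    )
    best = int(np.argmax(counts))  # argmax takes the first (earliest) maximum
    t0 = float(starts[best])
    mask = (t >= t0) & (t <= t0 + window_s)
    return (
        EventTable(event_time_s=t[mask], amplitude_pa=events.amplitude_pa[mask]),
        t0,
    )


def average_events(
    trace: Trace, events: EventTable, pre_ms: float = 5.0, post_ms: float = 50.0
) -> EventAverage:
    """Peak-aligned mean waveform across a cell's detected events.

    Each event contributes the trace segment from ``pre_ms`` before to
    ``post_ms`` after its peak sample; events whose window leaves the record
    are dropped (logged).  The alignment index of the output is
    ``pre_samples``.
    """
    if len(events) == 0:
        raise ValueError("no events to average")
    n_pre = int(round(pre_ms / 1000.0 * trace.fs_hz))
    n_post = int(round(post_ms / 1000.0 * trace.fs_hz))
    n = trace.samples.size
    segs = []
    dropped = 0
    for t in events.event_time_s:
        i = int(round(t * trace.fs_hz))
        if i - n_pre < 0 or i + n_post >= n:
            dropped += 1
            continue
        segs.append(trace.samples[i - n_pre : i + n_post + 1])
    if dropped:
        logger.info("average_events: dropped %d boundary events", dropped)
    if not segs:
        raise ValueError("no events with a full averaging window")
    wf = np.mean(np.stack(segs), axis=0)
    return EventAverage(waveform=wf, pre_samples=n_pre, fs_hz=trace.fs_hz,
                        n_events=len(segs), n_dropped=dropped)


def average_of_cell_averages(waveforms: list[np.ndarray]) -> np.ndarray:
    """Grand mean of per-cell average waveforms (one trace per group)."""
    if not waveforms:
        raise ValueError("no waveforms")
    lengths = {np.asarray(w).size for w in waveforms}
    if len(lengths) != 1:
        raise ValueError(f"waveform lengths differ: {sorted(lengths)}")
    return np.mean(np.stack([np.asarray(w, dtype=float) for w in waveforms]), axis=0)


def count_action_potentials(
    trace: Trace,
    ap_threshold_mv: float = 0.0,
    min_separation_ms: float = 1.0,
    rearm_mv: float = 10.0,
    baseline_ms: float = 50.0,
    step_current_pa: float = np.nan,
) -> ApResult:
    """Count APs in one current-clamp sweep and measure their amplitudes.

    Spikes are upward crossings of ``ap_threshold_mv`` separated by at least
    ``min_separation_ms``, with hysteresis: a new spike requires the voltage
    to have repolarised below ``ap_threshold_mv - rearm_mv`` since the
    previous one (noise flickers near threshold do not double-count).  The
    amplitude of a spike is its peak voltage minus the pre-step baseline
    (median of the first ``baseline_ms``).
    """
    if trace.modality != "current_clamp":
        raise ValueError("AP counting requires a current_clamp trace")
    v = trace.samples
    n_base = max(1, int(round(baseline_ms / 1000.0 * trace.fs_hz)))
    baseline = float(np.median(v[:n_base]))

    above = v > ap_threshold_mv
    ups = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    below_rearm = np.flatnonzero(v < ap_threshold_mv - rearm_mv)
    min_sep = min_separation_ms / 1000.0 * trace.fs_hz
    spikes: list[int] = []
    for u in ups:
        if spikes:
            if u - spikes[-1] < min_sep:
                continue
            j = np.searchsorted(below_rearm, spikes[-1])
            if j >= below_rearm.size or below_rearm[j] >= u:
                continue  # never repolarised: same spike
        spikes.append(int(u))
    amps = []
    for k, u in enumerate(spikes):
        end = spikes[k + 1] if k + 1 < len(spikes) else v.size
        amps.append(float(np.max(v[u:end]) - baseline))
    return ApResult(
        step_current_pa=np.array([step_current_pa]),
        spike_count=np.array([len(spikes)]),
        spike_amplitude_mv=(np.asarray(amps),),
        baseline_mv=np.array([baseline]),
    )


def analyze_step_protocol(
    traces: list[Trace], step_currents_pa: np.ndarray, **kwargs
) -> ApResult:
    """Apply :func:`count_action_potentials` to every sweep of a protocol."""
    if len(traces) != len(step_currents_pa):
        raise ValueError("one step current per sweep required")
    singles = [
        count_action_potentials(tr, step_current_pa=c, **kwargs)
        for tr, c in zip(traces, step_currents_pa)
    ]
    return ApResult(
        step_current_pa=np.asarray(step_currents_pa, dtype=float),
        spike_count=np.concatenate([r.spike_count for r in singles]),
        spike_amplitude_mv=tuple(r.spike_amplitude_mv[0] for r in singles),
        baseline_mv=np.concatenate([r.baseline_mv for r in singles]),
    )
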