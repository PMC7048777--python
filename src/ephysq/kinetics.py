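"""Biexponential decay fitting for averaged synaptic-current waveforms.

The falling phase of an averaged event is modelled as
``y(t) = A1 * exp(-t/tau1) + A2 * exp(-t/tau2)`` starting at the peak, and
summarised by the amplitude-weighted time constant
``tau_w = (A1*tau1 + A2*tau2) / (A1 + A2)``, the single per-cell decay
number used for group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["DecayFit", "fit_biexponential", "weighted_tau"]


@dataclass(frozen=True)
class DecayFit:
    """Canonicalised biexponential fit: ``tau1_ms <= tau2_ms``; amplitudes
    are magnitudes (pA) of the respective components."""

    A1: float
    tau1_ms: float
    A2: float
    tau2_ms: float
    tau_weighted_ms: float
    rss: float
    converged: bool
    sign: int = -1  # polarity of the original waveform peak


def weighted_tau(fit: DecayFit) -> float:
    """Amplitude-weighted decay constant (ms); in [tau1, tau2] for A >= 0."""
    denom = fit.A1 + fit.A2
    if denom == 0:
        raise ValueError("weighted tau undefined: A1 + A2 == 0")
    return (fit.A1 * fit.tau1_ms + fit.A2 * fit.tau2_ms) / denom


def _canonical(A1, t1, A2, t2):
    return (A1, t1, A2, t2) if t1 <= t2 else (A2, t2, A1, t1)


def _tail_slope_init(t_ms: np.ndarray, y: np.ndarray) -> float:
    """tau2 seed from a log-linear fit of the last third of the decay."""
    k = max(4, y.size // 3)
    tt, yy = t_ms[-k:], y[-k:]
    pos = yy > 0
    if pos.sum() < 3:
        return max(t_ms[-1] / 3.0, 1e-3)
    slope, _ = np.polyfit(tt[pos], np.log(yy[pos]), 1)
    if slope >= -1e-12:
        return max(t_ms[-1] / 3.0, 1e-3)
    return float(np.clip(-1.0 / slope, 1e-3, 10.0 * t_ms[-1]))


def _amps_given_taus(t_ms, y, t1, t2):
    basis = np.column_stack([np.exp(-t_ms / t1), np.exp(-t_ms / t2)])
    coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
    return coef


def fit_biexponential(
    waveform: np.ndarray,
    fs_hz: float,
    fit_start: int | None = None,
    include_offset: bool = False,
    max_restarts: int = 5,
) -> DecayFit:
    """Least-squares biexponential fit of the decay phase of ``waveform``.

    The fit runs on the magnitude of the segment from the peak (largest
    absolute sample, or ``fit_start``) to the end.  Initialisation: tau2 from
    a log-linear fit of the tail, tau1 = tau2/5, amplitudes by linear least
    squares given the taus; up to ``max_restarts`` deterministic jittered
    restarts if the optimiser fails to converge.  A degenerate input (flat or
    all-zero decay) returns ``converged=False`` rather than raising.
    """
    w = np.asarray(waveform, dtype=float)
    if w.ndim != 1 or w.size < 3:
        raise ValueError("waveform must be 1-D with at least 3 samples")
    if fs_hz <= 0:
        raise ValueError("fs_hz must be positive")
    peak = int(np.argmax(np.abs(w))) if fit_start is None else int(fit_start)
    decay = w[peak:]
    if decay.size < 20:
        raise ValueError("need at least 20 samples after the peak")
    sign = -1 if w[peak] < 0 else 1
    y = sign * decay
    t_ms = np.arange(y.size) / fs_hz * 1000.0

    bad = DecayFit(np.nan, np.nan, np.nan, np.nan, np.nan,
                   rss=float(np.sum(y**2)), converged=False, sign=sign)
    if y[0] <= 0 or np.allclose(y, 0):
        return bad

    def model(p, t):
        A1, t1, A2, t2 = p[:4]
        return A1 * np.exp(-t / t1) + A2 * np.exp(-t / t2) + (p[4] if include_offset else 0.0)

    def resid(p):
        return model(p, t_ms) - y

    tau2_0 = _tail_slope_init(t_ms, y)
    rng = np.random.default_rng(0)  # deterministic restart jitter
    best = None
    for attempt in range(max_restarts + 1):
        jit = rng.lognormal(0.0, 0.3, size=2) if attempt else np.ones(2)
        t2 = tau2_0 * jit[0]
        t1 = max(t2 / 5.0 * jit[1], 1e-4)
        A1, A2 = _amps_given_taus(t_ms, y, t1, t2)
        p0 = [A1, t1, A2, t2] + ([0.0] if include_offset else [])
        lb = [-np.inf, 1e-6, -np.inf, 1e-6] + ([-np.inf] if include_offset else [])
        ub = [np.inf] * len(p0)
        try:
            res = least_squares(resid, p0, bounds=(lb, ub), method="trf",
                                max_nfev=2000)
        except Exception:
            continue
        rss = float(2 * res.cost)
        if best is None or rss < best[1]:
            best = (res, rss)
        if res.success and rss <= (best[1] if best else np.inf):
            if _fit_is_sane(res.x, y):
                break
    if best is None:
        return bad
    res, rss = best
    A1, t1, A2, t2 = res.x[:4]
    A1, t1, A2, t2 = _canonical(A1, t1, A2, t2)
    converged = bool(res.success) and _fit_is_sane(res.x, y)
    tw = np.nan
    if A1 + A2 != 0:
        tw = (A1 * t1 + A2 * t2) / (A1 + A2)
    return DecayFit(A1=float(A1), tau1_ms=float(t1), A2=float(A2),
                    tau2_ms=float(t2), tau_weighted_ms=float(tw),
                    rss=rss, converged=converged, sign=sign)


def _fit_is_sane(p, y) -> bool:
    A1, t1, A2, t2 = p[:4]
    if not np.all(np.isfinite(p)):
        return False
    if t1 <= 0 or t2 <= 0:
        return False
    return abs(A1 + A2) > 1e-12 * max(1.0, float(np.max(np.abs(y))))
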