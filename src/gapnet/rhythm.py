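"""Oscillation detection and population statistics.

Covers the slow-rhythm analyses applied to membrane voltage and calcium
traces: action-potential removal, UP-onset (cycle) detection with a Schmitt
trigger, per-cell frequency and regularity (CV) statistics, autocorrelograms,
zero-lag pairwise synchrony, relative fluorescence (dF/F0) and a coarse
activity-state classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .trace import Trace

__all__ = [
    "OscillationStats", "SyncMatrix", "despike", "detect_cycles",
    "oscillation_stats", "autocorrelogram", "pairwise_sync", "dff",
    "classify_activity",
]


@dataclass
class OscillationStats:
    """Cycle statistics of one oscillating trace.

    ``cv_freq`` is the coefficient of variation of per-cycle frequencies
    (population SD / mean, in %); ``amplitude`` is the mean per-cycle
    peak-to-nadir excursion; ``nadir`` the mean per-cycle minimum.
    """

    cycle_times: np.ndarray      # UP-onset times (s)
    mean_freq: float             # Hz
    cv_freq: float               # %
    amplitude: float             # mV
    nadir: float                 # mV
    sufficient: bool = True      # False when < 3 cycles were found


@dataclass
class SyncMatrix:
    """Pairwise zero-lag synchrony of a set of traces."""

    r0: np.ndarray               # zero-lag correlation, symmetric, diag 1
    lagmax: np.ndarray           # lag (s) of the correlogram peak, |lag|<=5 s

    def mean_offdiag(self) -> float:
        n = self.r0.shape[0]
        mask = ~np.eye(n, dtype=bool)
        return float(np.mean(self.r0[mask]))


def despike(V: Trace, *, window_s: float = 0.05,
            f_cut: float = 2.0) -> Trace:
    """Remove action-potential transients, keeping the sub-Hz envelope.

    A running median (default 50 ms) suppresses brief spikes, followed by a
    zero-phase 2 Hz low-pass (4th-order Butterworth) that removes residual
    fast structure.  Slow components (<~0.5 Hz) pass essentially unchanged.
    """
    if V.dt > 1e-3 + 1e-12:
        raise ValueError("despike expects dt <= 1 ms")
    k = max(1, int(round(window_s / V.dt)))
    if k % 2 == 0:
        k += 1
    med = ndimage.median_filter(V.data, size=k, mode="nearest")
    nyq = 0.5 / V.dt
    sos = signal.butter(4, f_cut / nyq, output="sos")
    out = signal.sosfiltfilt(sos, med)
    return Trace(out, V.dt, V.unit, V.kind, dict(V.meta))


def detect_cycles(V: Trace, hysteresis: float | None = None) -> np.ndarray:
    """UP-onset times via a Schmitt trigger on a despiked trace.

    The midrange is the mean of the 5th and 95th percentiles; an UP onset is
    an upward crossing of ``midrange + hysteresis/2`` that follows a downward
    crossing of ``midrange - hysteresis/2``.  With ``hysteresis=None`` the
    band defaults to 30 % of the 5th-95th percentile span.  Returns an empty
    array for flat traces.
    """
    x = V.data
    p5, p95 = np.percentile(x, [5.0, 95.0])
    span = p95 - p5
    if span <= 1e-9:
        return np.zeros(0)
    if hysteresis is None:
        hysteresis = 0.3 * span
    mid = 0.5 * (p5 + p95)
    hi = mid + 0.5 * hysteresis
    lo = mid - 0.5 * hysteresis
    # vectorized hysteresis state machine: -1 below lo, +1 at/above hi,
    # previous state carried forward in between
    marks = np.zeros(x.size, dtype=np.int8)
    marks[x >= hi] = 1
    marks[x < lo] = -1
    idx = np.flatnonzero(marks)
    if idx.size == 0:
        return np.zeros(0)
    state = np.zeros(x.size, dtype=np.int8)
    state[idx] = marks[idx]
    # forward-fill; samples before the first mark inherit it retroactively as
    # "unarmed" unless the trace starts below lo
    fill = np.maximum.accumulate(np.where(marks != 0,
                                          np.arange(x.size), -1))
    state = np.where(fill >= 0, marks[np.maximum(fill, 0)],
                     -1 if x[0] < lo else 0)
    ups = np.flatnonzero((state[1:] == 1) & (state[:-1] == -1)) + 1
    onsets = []
    for k in ups:
        if x[k] > x[k - 1]:
            frac = (hi - x[k - 1]) / (x[k] - x[k - 1])
            frac = min(max(frac, 0.0), 1.0)
        else:
            frac = 0.0
        onsets.append((k - 1 + frac) * V.dt)
    return np.asarray(onsets)


def oscillation_stats(V: Trace, hysteresis: float | None = None
                      ) -> OscillationStats:
    """Per-cycle frequency, CV, amplitude and nadir of one trace.

    Requires at least three detected UP onsets; otherwise returns a result
    flagged ``sufficient=False`` with NaN statistics.
    """
    onsets = detect_cycles(V, hysteresis)
    if onsets.size < 3:
        return OscillationStats(onsets, float("nan"), float("nan"),
                                float("nan"), float("nan"), sufficient=False)
    freqs = 1.0 / np.diff(onsets)
    mean_freq = float(np.mean(freqs))
    cv = float(np.std(freqs) / mean_freq * 100.0)
    amps, nadirs = [], []
    idx = np.round(onsets / V.dt).astype(int)
    for a, b in zip(idx[:-1], idx[1:]):
        seg = V.data[a:b]
        amps.append(seg.max() - seg.min())
        nadirs.append(seg.min())
    return OscillationStats(onsets, mean_freq, cv, float(np.mean(amps)),
                            float(np.mean(nadirs)))


def autocorrelogram(V: Trace, max_lag: float = 20.0):
    """Biased normalized autocorrelation, ``r(0) = 1``.

    Returns ``(lags, r)`` with lags in seconds spanning ``[-max_lag,
    max_lag]``.
    """
    x = V.data - V.data.mean()
    var = np.dot(x, x)
    if var <= 1e-15:
        raise ValueError("autocorrelogram of a zero-variance trace")
    m = min(int(round(max_lag / V.dt)), x.size - 1)
    full = signal.correlate(x, x, mode="full", method="fft") / var
    mididx = x.size - 1
    r = full[mididx - m: mididx + m + 1]
    lags = np.arange(-m, m + 1) * V.dt
    return lags, r


def pairwise_sync(traces, max_lag: float = 5.0) -> SyncMatrix:
    """Zero-lag correlation matrix and correlogram-peak lags of a trace set.

    Accepts a :class:`~gapnet.synthetic_models.TraceSet` or a list of
    voltage/fluorescence traces sharing one ``dt``.  Voltage traces sampled
    at <= 1 ms are despiked first; each trace is then z-scored and the
    normalized cross-correlation evaluated.  Zero-variance traces raise.
    """
    trs = list(traces.voltages) if hasattr(traces, "voltages") else list(traces)
    if len(trs) < 2:
        raise ValueError("pairwise_sync needs at least two traces")
    dt = trs[0].dt
    if any(abs(tr.dt - dt) > 1e-12 for tr in trs):
        raise ValueError("traces must share a common dt")
    prepped = []
    for tr in trs:
        x = tr
        if tr.kind == "V" and tr.dt <= 1e-3 + 1e-12:
            x = despike(tr)
        d = x.data - x.data.mean()
        sd = d.std()
        if sd <= 1e-12:
            raise ValueError("zero-variance trace in pairwise_sync")
        prepped.append(d / sd)
    n = len(prepped)
    npts = prepped[0].size
    m = min(int(round(max_lag / dt)), npts - 1)
    r0 = np.eye(n)
    lagmax = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            full = signal.correlate(prepped[i], prepped[j], mode="full",
                                    method="fft") / npts
            mididx = npts - 1
            r0[i, j] = r0[j, i] = full[mididx]
            seg = full[mididx - m: mididx + m + 1]
            lag = (np.argmax(seg) - m) * dt
            lagmax[i, j] = lag
            lagmax[j, i] = -lag
    return SyncMatrix(r0, lagmax)


def dff(F: Trace, baseline_quantile: float = 0.10) -> Trace:
    """Relative fluorescence change (F - F0)/F0.

    F0 is the given quantile of the trace (default 10th percentile), i.e.
    the baseline fluorescence over the period of lowest activity.
    """
    if np.any(F.data <= 0):
        raise ValueError("fluorescence must be strictly positive")
    f0 = float(np.quantile(F.data, baseline_quantile))
    if f0 <= 0:
        raise ValueError("non-positive baseline fluorescence")
    out = (F.data - f0) / f0
    return Trace(out, F.dt, "dF/F0", "F", dict(F.meta))


def classify_activity(V: Trace, spike_thresh: float = -20.0) -> str:
    """Coarse state of a raw voltage trace.

    ``silent`` when fewer than three cycles are detected on the despiked
    trace; otherwise ``suprathreshold_oscillating`` if any raw sample crosses
    ``spike_thresh`` (default -20 mV), else ``subthreshold_oscillating``.
    """
    base = despike(V) if V.dt <= 1e-3 + 1e-12 else V
    onsets = detect_cycles(base)
    if onsets.size < 3:
        return "silent"
    if np.any(V.data >= spike_thresh):
        return "suprathreshold_oscillating"
    return "subthreshold_oscillating"
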