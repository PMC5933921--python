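"""Impedance profiles, resonance extraction, entrainment scoring and
pre-/post-junctional (transfer) resonance.

The impedance profile of a (voltage, current) trace pair is the ratio of
discrete Fourier transforms ``Z(f) = V~(f) / I~(f)`` restricted to an
analysis band, with the magnitude optionally smoothed by a Gaussian kernel
in log-frequency.  The resonance (preferred) frequency is the frequency of
the smoothed-magnitude maximum; a profile whose peak does not exceed the
band edges by a minimum quality ratio is flagged as non-resonant rather than
yielding an arbitrary peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .trace import Trace
from . import rhythm

__all__ = ["ImpedanceProfile", "ResonanceResult", "impedance_profile",
           "resonance_frequency", "entrainment_score", "transfer_resonance"]

#: smoothed-peak : band-edge magnitude ratio below which a profile is flat
QUALITY_THRESHOLD = 1.05

#: smoothed peak magnitudes below this (MOhm) are treated as "no transfer"
MIN_PEAK_MOHM = 1e-3


@dataclass
class ImpedanceProfile:
    """Complex impedance on an FFT frequency grid restricted to a band.

    ``magnitude`` is the raw ``|Z|`` (elementwise modulus of ``Z``);
    ``magnitude_smooth`` the log-frequency Gaussian-smoothed version used for
    peak extraction.  Units are MOhm for mV / pA inputs.
    """

    f: np.ndarray
    Z: np.ndarray
    magnitude: np.ndarray
    magnitude_smooth: np.ndarray
    band: tuple
    smooth_bw: float = 0.10


@dataclass
class ResonanceResult:
    """Resonance peak of an impedance profile."""

    f_res: float       # Hz (NaN when not resonant)
    z_peak: float      # MOhm
    band: tuple
    quality: float     # peak / band-edge magnitude ratio
    resonant: bool = True


def _gaussian_log_smooth(f: np.ndarray, y: np.ndarray,
                         bw_octaves: float) -> np.ndarray:
    """Smooth ``y(f)`` with a Gaussian of SD ``bw_octaves`` in log2 f.

    Kernel weights are renormalized per output point, so constants are
    preserved exactly and band-edge truncation does not leak energy.
    """
    if bw_octaves <= 0:
        return y.copy()
    logf = np.log2(f)
    out = np.empty_like(y)
    half = 4.0 * bw_octaves
    for k in range(f.size):
        d = logf - logf[k]
        m = np.abs(d) <= half
        wgt = np.exp(-0.5 * (d[m] / bw_octaves) ** 2)
        out[k] = np.dot(wgt, y[m]) / wgt.sum()
    return out


def impedance_profile(V: Trace, I: Trace, band=(0.05, 10.0),
                      smooth_bw: float = 0.10) -> ImpedanceProfile:
    """Impedance profile ``Z = V~/I~`` of a trace pair over a band.

    The voltage is linearly detrended before the FFT (removing offset and
    drift); the current spectrum must carry power throughout the band, which
    is checked octave-by-octave to guard against dividing by ~0.
    """
    if V.n != I.n:
        raise ValueError("V and I must have equal length")
    if abs(V.dt - I.dt) > 1e-12:
        raise ValueError("V and I must share dt")
    nyq = 0.5 / V.dt
    if not (0 < band[0] < band[1] <= nyq):
        raise ValueError(f"band must lie within (0, {nyq}] Hz")

    v = signal.detrend(V.data, type="linear")
    i = I.data - I.data.mean()
    vf = np.fft.rfft(v)
    iff = np.fft.rfft(i)
    f = np.fft.rfftfreq(V.n, V.dt)
    m = (f >= band[0] - 1e-12) & (f <= band[1] + 1e-12)
    f = f[m]
    vf = vf[m]
    iff = iff[m]
    if f.size < 4:
        raise ValueError("band contains too few FFT bins")

    # current power check: the band must carry real stimulus power overall
    # (vs the full spectrum) and in every octave sub-band (vs the band mean)
    p = np.abs(iff) ** 2
    p_ref = float(np.mean(p))
    p_total = float(np.mean(np.abs(np.fft.rfft(i)[1:]) ** 2))
    if p_total > 0 and p_ref < 1e-3 * p_total:
        raise ValueError(
            f"stimulus has negligible spectral power across the "
            f"{band[0]:.3g}-{band[1]:.3g} Hz band; impedance is undefined")
    n_oct = max(1, int(math.ceil(math.log2(band[1] / band[0]))))
    edges = np.geomspace(band[0], band[1], n_oct + 1)
    for lo, hi in zip(edges[:-1], edges[1:]):
        sub = (f >= lo) & (f <= hi)
        if sub.any() and np.mean(p[sub]) < 1e-6 * p_ref:
            raise ValueError(
                f"stimulus has negligible spectral power in the "
                f"{lo:.3g}-{hi:.3g} Hz sub-band; impedance is undefined there")

    Z = 1e3 * vf / iff  # mV/pA = GOhm -> MOhm
    mag = np.abs(Z)
    mag_s = _gaussian_log_smooth(f, mag, smooth_bw)
    return ImpedanceProfile(f, Z, mag, mag_s, tuple(band), smooth_bw)


def resonance_frequency(profile: ImpedanceProfile) -> ResonanceResult:
    """Peak of the smoothed impedance magnitude, refined by quadratic
    interpolation around the grid maximum; ties break to the lowest
    frequency.

    Flat profiles (peak-to-edge ratio below 1.05) and near-zero profiles are
    flagged non-resonant (``resonant=False``, ``f_res=NaN``).
    """
    if profile.f.size == 0:
        raise ValueError("empty impedance profile")
    y = profile.magnitude_smooth
    k = int(np.argmax(y))  # argmax returns the first (lowest-f) maximum
    z_peak = float(y[k])
    edge = max(y[0], y[-1])
    quality = z_peak / edge if edge > 0 else float("inf")
    if quality < QUALITY_THRESHOLD or z_peak < MIN_PEAK_MOHM:
        return ResonanceResult(float("nan"), z_peak, profile.band, quality,
                               resonant=False)
    if 0 < k < y.size - 1:
        # parabolic vertex on the (equally spaced) FFT grid
        y0, y1, y2 = y[k - 1], y[k], y[k + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:
            delta = 0.5 * (y0 - y2) / denom
            delta = min(max(delta, -1.0), 1.0)
            df = profile.f[k + 1] - profile.f[k]
            f_res = float(profile.f[k] + delta * df)
        else:
            f_res = float(profile.f[k])
    else:
        f_res = float(profile.f[k])
    return ResonanceResult(float(f_res), z_peak, profile.band, quality)


def entrainment_score(V: Trace, I: Trace, max_lag: float = 2.0) -> float:
    """Peak normalized cross-correlation between stimulus and response.

    Both traces are detrended (the voltage additionally despiked when
    sampled at <= 1 ms), z-scored, and the normalized cross-correlation
    evaluated; the score is its maximum over lags within ``max_lag``
    seconds.  1 means the voltage is a shifted, scaled copy of the current
    command (full entrainment); values near 0 mean the cell ignores it.
    """
    if V.n != I.n or abs(V.dt - I.dt) > 1e-12:
        raise ValueError("V and I must share length and dt")
    v = V
    if V.dt <= 1e-3 + 1e-12:
        v = rhythm.despike(V)
    x = signal.detrend(v.data, type="linear")
    y = signal.detrend(I.data, type="linear")
    sx, sy = x.std(), y.std()
    if sx <= 1e-12 or sy <= 1e-12:
        raise ValueError("zero-variance input to entrainment_score")
    x /= sx
    y /= sy
    n = x.size
    m = min(int(round(max_lag / V.dt)), n - 1)
    full = signal.correlate(x, y, mode="full", method="fft") / n
    mid = n - 1
    seg = full[mid - m: mid + m + 1]
    return float(np.max(seg))


def transfer_resonance(V_pre: Trace, V_post: Trace, I: Trace,
                       band=(0.05, 10.0), smooth_bw: float = 0.10):
    """Pre- and post-junctional resonance of a coupled pair.

    The prejunctional result comes from the self-impedance
    ``Z11 = V~_pre / I~`` of the injected cell; the postjunctional result
    from the transfer impedance ``Z21 = V~_post / I~`` of its coupled
    partner, with identical smoothing and peak rules.  Returns
    ``(pre, post)`` :class:`ResonanceResult` objects.
    """
    prof_pre = impedance_profile(V_pre, I, band, smooth_bw)
    prof_post = impedance_profile(V_post, I, band, smooth_bw)
    return resonance_frequency(prof_pre), resonance_frequency(prof_post)
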