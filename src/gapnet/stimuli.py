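"""Stimulus protocols: exponential (logarithmic) ZAP chirps, current steps,
hyperpolarizing staircases and deflection-calibrated step amplitudes.

The ZAP (impedance amplitude profile) stimulus is a fixed-amplitude sinusoid
whose instantaneous frequency sweeps ``f_min -> f_max`` exponentially,

    f(t) = f_min * exp(L t),        L = ln(f_max / f_min) / duration,

implemented through the phase integral

    phi(t) = 2 pi f_min (exp(L t) - 1) / L,

so that the swept instantaneous frequency d(phi)/dt / (2 pi) runs exactly
from ``f_min`` to ``f_max``.  The chirp is preceded by a configurable number
of full sinusoidal cycles at ``f_min`` (three by default) that join the chirp
with continuous phase, so the analysis can discard the onset transient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .trace import Trace
from .synthetic_models import (NeuronParams, NetworkSpec, simulate_network,
                               linear_fixed_point)
from . import rhythm

__all__ = ["ZapSpec", "StepSpec", "generate_zap", "generate_staircase",
           "amplitude_for_deflection", "chirp_segment"]


@dataclass
class ZapSpec:
    """Exponential-chirp stimulus description.

    ``I_max`` is the sinusoid amplitude (pA); ``dc_offset`` a constant bias
    added throughout (e.g. the holding current used with sodium-channel
    blockade); ``lead_cycles`` full cycles at ``f_min`` precede the chirp.
    """

    f_min: float = 0.05       # Hz
    f_max: float = 10.0       # Hz
    duration: float = 100.0   # chirp duration (s), excluding the lead-in
    I_max: float = 20.0       # pA
    dt: float = 1e-4          # s
    lead_cycles: int = 3
    direction: str = "ascending"
    dc_offset: float = 0.0    # pA

    def __post_init__(self) -> None:
        if not (0 < self.f_min < self.f_max):
            raise ValueError("need 0 < f_min < f_max")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.lead_cycles < 0:
            raise ValueError("lead_cycles must be >= 0")
        if self.direction not in ("ascending", "descending"):
            raise ValueError("direction must be 'ascending' or 'descending'")

    @property
    def L(self) -> float:
        """Exponential sweep rate ln(f_max/f_min)/duration (1/s)."""
        return math.log(self.f_max / self.f_min) / self.duration

    @property
    def lead_duration(self) -> float:
        return self.lead_cycles / self.f_min

    @property
    def total_duration(self) -> float:
        return self.lead_duration + self.duration


def generate_zap(spec: ZapSpec) -> Trace:
    """Generate the chirp current trace (pA).

    The returned trace's ``meta`` records the lead-in duration so analyses
    can slice out the chirp segment (:func:`chirp_segment`).
    """
    if spec.dt > 1.0 / (20.0 * spec.f_max):
        raise ValueError(
            f"dt={spec.dt} too coarse to resolve f_max={spec.f_max} Hz "
            f"(need dt <= {1.0 / (20.0 * spec.f_max):.2e} s)")
    L = spec.L
    n_main = int(round(spec.duration / spec.dt))
    t = np.arange(n_main) * spec.dt
    phase = 2.0 * math.pi * spec.f_min * (np.exp(L * t) - 1.0) / L
    if spec.direction == "descending":
        # time-reversed sweep: instantaneous frequency runs f_max -> f_min,
        # with identical accumulated cycle count
        phi_T = 2.0 * math.pi * spec.f_min * (math.exp(L * spec.duration)
                                              - 1.0) / L
        t_rev = spec.duration - t
        phase = phi_T - 2.0 * math.pi * spec.f_min * (np.exp(L * t_rev)
                                                      - 1.0) / L
    main = np.sin(phase)
    if spec.lead_cycles > 0:
        n_lead = int(round(spec.lead_duration / spec.dt))
        t_lead = np.arange(n_lead) * spec.dt
        f_lead = spec.f_min if spec.direction == "ascending" else spec.f_max
        if spec.direction == "descending":
            n_lead = int(round(spec.lead_cycles / spec.f_max / spec.dt))
            t_lead = np.arange(n_lead) * spec.dt
        lead = np.sin(2.0 * math.pi * f_lead * t_lead)
        data = np.concatenate([lead, main])
        lead_duration = n_lead * spec.dt
    else:
        data = main
        lead_duration = 0.0
    out = spec.I_max * data + spec.dc_offset
    return Trace(out, spec.dt, "pA", "I", meta={
        "lead_duration": lead_duration,
        "f_min": spec.f_min, "f_max": spec.f_max,
        "chirp_duration": spec.duration, "direction": spec.direction,
        "I_max": spec.I_max, "dc_offset": spec.dc_offset})


def chirp_segment(trace: Trace) -> Trace:
    """Drop the sinusoidal lead-in recorded in ``trace.meta`` (if any)."""
    lead = float(trace.meta.get("lead_duration", 0.0))
    if lead <= 0:
        return trace
    return trace.slice_time(lead)


@dataclass
class StepSpec:
    """Square current-step protocol (one step per sweep)."""

    amplitude: float          # pA
    onset: float = 1.0        # s, within each sweep
    width: float = 0.5        # s
    n_sweeps: int = 50
    inter_sweep_interval: float = 0.5  # gap after step offset (s)

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("step width must be positive")
        if self.n_sweeps < 1:
            raise ValueError("need at least one sweep")

    @property
    def sweep_duration(self) -> float:
        return self.onset + self.width + self.inter_sweep_interval


def generate_staircase(levels, level_duration: float, dt: float = 1e-3
                       ) -> Trace:
    """Piecewise-constant current staircase (pA), levels in given order."""
    levels = list(levels)
    if not levels:
        raise ValueError("staircase needs at least one level")
    if level_duration <= 0:
        raise ValueError("level_duration must be positive")
    n_per = int(round(level_duration / dt))
    data = np.repeat(np.asarray(levels, dtype=float), n_per)
    return Trace(data, dt, "pA", "I",
                 meta={"levels": [float(x) for x in levels],
                       "level_duration": level_duration})


def _steady_deflection(spec: NetworkSpec, index: int, amplitude: float,
                       *, width: float, baseline: float,
                       dt: float = 1e-3) -> float:
    """Simulated steady-state voltage deflection of a step into one cell.

    The deflection is the mean over the last 20 % of the step minus the mean
    over the pre-step baseline, measured on the despiked trace so that for
    oscillating cells the cycle-averaged (DOWN-state-holding) level is used.
    """
    total = baseline + width + 0.5
    n = int(round(total / 1e-4))
    stim = np.zeros(n)
    i0 = int(round(baseline / 1e-4))
    i1 = int(round((baseline + width) / 1e-4))
    stim[i0:i1] = amplitude
    ts = simulate_network(spec, {index: Trace(stim, 1e-4, "pA", "I")},
                          duration=total, dt=dt, noise_on=False)
    v = ts.voltages[index]
    if spec.cells[index].pacemaker_on:
        v = rhythm.despike(v)
    base = v.slice_time(0.0, baseline).data.mean()
    steady = v.slice_time(baseline + 0.8 * width, baseline + width).data.mean()
    return steady - base


def amplitude_for_deflection(cell, target_dV: float, *,
                             index: int = 0, tol: float = 0.05,
                             max_iter: int = 50) -> float:
    """Step amplitude (pA) producing a target steady-state deflection.

    ``cell`` is a :class:`NeuronParams` or a :class:`NetworkSpec` (with
    ``index`` naming the injected cell, so junctional shunting is included).
    A secant search matches the simulated deflection at the DOWN-state
    holding level to ``target_dV`` within ``tol`` (relative, default 5 %).
    """
    if target_dV == 0:
        raise ValueError("target deflection must be nonzero")
    if isinstance(cell, NeuronParams):
        spec = NetworkSpec([cell], [], seed=0)
        index = 0
    else:
        spec = cell
    params = spec.cells[index]
    oscillating = params.pacemaker_on
    width = 30.0 if oscillating else max(12.0, 8.0 * params.tau_w)
    baseline = 20.0 if oscillating else 2.0

    # Ohmic initial guesses from the DC input conductance
    g0 = params.g_L + params.g_w
    a0 = target_dV * g0
    a1 = 1.3 * a0
    d0 = _steady_deflection(spec, index, a0, width=width, baseline=baseline)
    for _ in range(max_iter):
        d1 = _steady_deflection(spec, index, a1, width=width,
                                baseline=baseline)
        if abs(d1 - target_dV) <= tol * abs(target_dV):
            return float(a1)
        if d1 == d0:
            raise RuntimeError("secant search stalled (flat response)")
        a0, a1, d0 = a1, a1 + (target_dV - d1) * (a1 - a0) / (d1 - d0), d1
    raise RuntimeError(f"no convergence in {max_iter} secant iterations")
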