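"""Generative models of resonant / oscillating cells and electrically
coupled networks.

Two cell regimes are supported by a single parameter set
(:class:`NeuronParams`):

* **linear resonator** (``pacemaker_on=False``): a passive RC membrane with
  one slow resonant current ``-g_w w``, where ``w`` is a first-order tracker
  of ``V - E_L`` with time constant ``tau_w``.  Its impedance is known in
  closed form (:func:`analytic_impedance`) and peaks below 1 Hz for slow
  ``tau_w`` and large effective capacitance.
* **relaxation oscillator** (``pacemaker_on=True``): the linear backbone plus
  a fast regenerative (persistent-sodium-like) current
  ``g_p sigma_p(V)(E_p - V)`` and a slow potassium-like recovery current
  ``g_K w_K (E_K - V)``; ``w_K`` relaxes toward a logistic ``sigma_w(V)`` at
  rate ``1/tau_w``.  This is the minimal model of a cell alternating between
  depolarized UP and hyperpolarized DOWN states; a sodium-channel-block
  ("TTX") emulation freezes the fast activation at its UP-state value and
  yields a purely linear cell (:func:`apply_ttx`).

Cells are joined by ohmic, symmetric gap junctions
(:class:`GapJunctionEdge`): the current into cell *i* from edge (i, j) is
``g_c (V_j - V_i)``.  Any directional asymmetry of the measured coupling
coefficient is emergent from unequal membrane conductances, never from the
junction itself.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy import optimize

from . import _integrator
from ._integrator import DivergenceError, H_INTERNAL
from .trace import Trace

__all__ = [
    "NeuronParams", "GapJunctionEdge", "NetworkSpec", "TraceSet", "Preset",
    "simulate_network", "analytic_impedance", "analytic_pair_impedance",
    "analytic_resonance_peak", "calibrate_resonator", "calibrate_oscillator",
    "ca_proxy", "make_preset", "apply_ttx", "linear_fixed_point",
    "DivergenceError", "PRESET_NAMES",
]


# ---------------------------------------------------------------------------
# domain types

@dataclass
class NeuronParams:
    """Parameters of one model cell (units: nF, nS, mV, s, pA).

    The defaults are the linear resonator backbone; pacemaker fields are
    inert while ``pacemaker_on`` is False.
    """

    C: float = 1.0              # capacitance (nF)
    g_L: float = 5.0            # leak conductance (nS)
    E_L: float = -65.0          # leak reversal (mV)
    g_w: float = 10.0           # resonant-current conductance (nS)
    tau_w: float = 1.0          # slow time constant (s), shared with w_K
    pacemaker_on: bool = False
    g_p: float = 0.0            # regenerative conductance (nS)
    E_p: float = 50.0           # its reversal (mV)
    V_half_p: float = -48.0     # activation sigmoid midpoint (mV)
    k_p: float = 4.0            # activation slope (mV)
    g_K: float = 0.0            # slow recovery conductance (nS)
    E_K: float = -90.0          # its reversal (mV)
    V_half_w: float = -53.0     # recovery sigmoid midpoint (mV)
    k_w: float = 4.0            # recovery slope (mV)
    sigma_noise: float = 0.0    # OU noise stationary SD (pA)
    tau_noise: float = 0.05     # OU correlation time (s)

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise ValueError("C must be positive")
        if not self.g_L > 0:
            raise ValueError("g_L must be positive")
        if self.g_w < 0:
            raise ValueError("g_w must be non-negative")
        if not self.tau_w > 0:
            raise ValueError("tau_w must be positive")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be non-negative")
        if not self.pacemaker_on:
            # 2x2 subthreshold system must be stable: with positive C, g_L,
            # tau_w and g_w >= 0 both the trace and determinant conditions
            # hold; assert anyway to catch pathological edits.
            tr = -(self.g_L / self.C + 1.0 / self.tau_w)
            det = (self.g_L + self.g_w) / (self.C * self.tau_w)
            if not (tr < 0 and det > 0):
                raise ValueError("linear subthreshold system is unstable")

    def copy(self, **changes) -> "NeuronParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class GapJunctionEdge:
    """Ohmic, symmetric gap junction between cells ``i`` and ``j``."""

    cell_i: int
    cell_j: int
    g_c: float  # junctional conductance (nS)

    def __post_init__(self) -> None:
        if self.cell_i == self.cell_j:
            raise ValueError("gap junction must join two distinct cells")
        if self.g_c < 0:
            raise ValueError("g_c must be non-negative")


@dataclass
class NetworkSpec:
    """A generative 'slice': cells, gap-junction edges and a seed."""

    cells: list
    edges: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.cells)
        seen = set()
        for e in self.edges:
            if not (0 <= e.cell_i < n and 0 <= e.cell_j < n):
                raise ValueError(f"edge ({e.cell_i}, {e.cell_j}) out of range")
            key = frozenset((e.cell_i, e.cell_j))
            if key in seen:
                raise ValueError(f"duplicate edge for pair {sorted(key)}")
            seen.add(key)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def copy(self) -> "NetworkSpec":
        return copy.deepcopy(self)


@dataclass
class TraceSet:
    """Per-cell voltage and injected-current traces sharing one time base."""

    voltages: list          # list[Trace], mV
    currents: list          # list[Trace], pA (commanded stimulus)
    dt: float
    duration: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ns = {tr.n for tr in self.voltages} | {tr.n for tr in self.currents}
        if len(ns) > 1:
            raise ValueError("all traces in a TraceSet must share one length")
        for tr in self.voltages + self.currents:
            if abs(tr.dt - self.dt) > 1e-12:
                raise ValueError("all traces in a TraceSet must share dt")
            if not np.all(np.isfinite(tr.data)):
                raise ValueError("TraceSet contains non-finite samples")

    @property
    def n_cells(self) -> int:
        return len(self.voltages)

    def voltage_matrix(self) -> np.ndarray:
        return np.stack([tr.data for tr in self.voltages], axis=1)


@dataclass
class Preset:
    """A named, calibrated model configuration with its numeric targets."""

    name: str
    targets: dict
    resolved: NetworkSpec


# ---------------------------------------------------------------------------
# simulation

def simulate_network(spec: NetworkSpec, stimulus=None, *, duration: float,
                     dt: float = 1e-4, noise_on: bool = False,
                     v0=None) -> TraceSet:
    """Integrate a network specification and return its traces.

    Parameters
    ----------
    spec : NetworkSpec
    stimulus : dict[int, Trace] or None
        Injected current per cell (pA); traces are resampled to the internal
        step by linear interpolation and must cover ``duration``.
    duration : float
        Simulated time (s).
    dt : float
        Recording interval (s); an integer multiple of the 0.1 ms internal
        step, at most 1 ms.
    noise_on : bool
        Enable each cell's seeded OU current noise (streams derived from
        ``spec.seed``).
    v0 : array-like or None
        Initial voltages.  If None, linear networks start at their
        stimulus-at-t=0 fixed point (suppressing onset transients) and
        pacemaker networks start at slightly staggered voltages so identical
        cells do not sit on an unstable symmetric orbit.
    """
    if dt > 1e-3 + 1e-12:
        raise ValueError("recording dt must be <= 1 ms")
    n_steps = int(round(duration / H_INTERNAL))
    stim_arrays = {}
    if stimulus:
        for i, tr in stimulus.items():
            if not (0 <= i < spec.n_cells):
                raise ValueError(f"stimulus cell index {i} out of range")
            # a shortfall of up to one stimulus sample is rounding, not a
            # protocol mismatch (interpolation clamps the endpoint)
            if tr.n * tr.dt < duration - max(tr.dt, 1e-9):
                raise ValueError(
                    f"stimulus for cell {i} covers {tr.n * tr.dt:.3f} s "
                    f"but the simulation lasts {duration:.3f} s")
            t_int = np.arange(n_steps) * H_INTERNAL
            stim_arrays[i] = np.interp(t_int, tr.t, tr.data)

    if v0 is None:
        if not any(c.pacemaker_on for c in spec.cells):
            i_dc = np.zeros(spec.n_cells)
            for i, arr in stim_arrays.items():
                i_dc[i] = arr[0]
            v0 = linear_fixed_point(spec, i_dc)
        else:
            # deterministic stagger breaks exact permutation symmetry
            v0 = np.array([c.E_L + 1e-3 * k for k, c in enumerate(spec.cells)])

    edges = [(e.cell_i, e.cell_j, e.g_c) for e in spec.edges]
    rec = _integrator.integrate(
        spec.cells, edges, duration, rec_dt=dt, stimulus=stim_arrays,
        noise_on=noise_on, seed=spec.seed, v0=v0)

    rec_every = int(round(dt / H_INTERNAL))
    voltages = [Trace(rec[:, i], dt, "mV", "V") for i in range(spec.n_cells)]
    currents = []
    for i in range(spec.n_cells):
        if i in stim_arrays:
            currents.append(Trace(stim_arrays[i][::rec_every].copy(), dt,
                                  "pA", "I"))
        else:
            currents.append(Trace(np.zeros(rec.shape[0]), dt, "pA", "I"))
    return TraceSet(voltages, currents, dt, duration,
                    meta={"seed": spec.seed, "noise_on": bool(noise_on)})


def linear_fixed_point(spec: NetworkSpec, i_dc=None) -> np.ndarray:
    """Steady-state voltages of a pacemaker-free network under DC current.

    Solves ``(diag(g_L + g_w) + L_gc) V = (g_L + g_w) E_L + I_dc`` where
    ``L_gc`` is the gap-junction Laplacian (the slow variable settles to
    ``w = V - E_L`` at steady state).
    """
    n = spec.n_cells
    if any(c.pacemaker_on for c in spec.cells):
        raise ValueError("fixed point is only defined for linear networks")
    g = np.array([c.g_L + c.g_w for c in spec.cells])
    A = np.diag(g.astype(float))
    for e in spec.edges:
        i, j = e.cell_i, e.cell_j
        A[i, i] += e.g_c
        A[j, j] += e.g_c
        A[i, j] -= e.g_c
        A[j, i] -= e.g_c
    b = g * np.array([c.E_L for c in spec.cells])
    if i_dc is not None:
        b = b + np.asarray(i_dc, dtype=float)
    return np.linalg.solve(A, b)


def apply_ttx(params: NeuronParams, bias_pA: float = -20.0) -> NeuronParams:
    """Emulate sodium-channel blockade on a pacemaker cell.

    The fast regenerative activation is frozen at its UP-state value, which
    turns the cell into a linear one with an extra ohmic conductance
    ``g_p sigma_p(V_up)`` toward ``E_p`` (the blocked cell rests in a
    persistent UP state); the recovery branch is dropped with it.  The result
    is expressed as an equivalent (g_L', E_L') leak so that
    :func:`analytic_impedance` applies exactly.  ``bias_pA`` is the holding
    current conventionally applied during resonance measurements to offset
    the depolarization; it shifts the equivalent resting potential.
    """
    if not params.pacemaker_on:
        return params.copy()
    # UP-state voltage: where the frozen cell would rest without bias;
    # iterate the scalar fixed point V = (gL EL + gp s(V) Ep) / (gL + gp s(V))
    v = params.E_L
    for _ in range(200):
        s = 1.0 / (1.0 + math.exp(-(v - params.V_half_p) / params.k_p))
        v_new = ((params.g_L * params.E_L + params.g_p * s * params.E_p)
                 / (params.g_L + params.g_p * s))
        if abs(v_new - v) < 1e-10:
            v = v_new
            break
        v = 0.5 * (v + v_new)
    s_up = 1.0 / (1.0 + math.exp(-(v - params.V_half_p) / params.k_p))
    g_eff = params.g_L + params.g_p * s_up
    e_eff = ((params.g_L * params.E_L + params.g_p * s_up * params.E_p
              + bias_pA) / g_eff)
    return params.copy(pacemaker_on=False, g_p=0.0, g_K=0.0,
                       g_L=g_eff, E_L=e_eff)


# ---------------------------------------------------------------------------
# analytic impedance and calibration

def analytic_impedance(params: NeuronParams, f) -> np.ndarray:
    """Closed-form impedance of the linear cell, in megohms.

    ``Z(f) = 1 / (g_L + i 2 pi f C + g_w / (1 + i 2 pi f tau_w))`` with
    conductances in nS, giving 1/nS = GOhm, converted to MOhm.
    """
    if params.pacemaker_on:
        raise ValueError("analytic impedance requires the linear regime "
                         "(pacemaker_on=False)")
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive")
    omega = 2.0 * np.pi * f
    denom = (params.g_L + 1j * omega * params.C
             + params.g_w / (1.0 + 1j * omega * params.tau_w))
    return 1e3 / denom  # MOhm


def analytic_pair_impedance(p1: NeuronParams, p2: NeuronParams, g_c: float,
                            f) -> tuple:
    """Self- and transfer impedance of a coupled linear pair (MOhm).

    With per-cell admittances ``Y_i(f)`` (in nS) and current injected into
    cell 1::

        Z11 = (Y2 + g_c) / ((Y1 + g_c)(Y2 + g_c) - g_c^2)
        Z21 = g_c        / ((Y1 + g_c)(Y2 + g_c) - g_c^2)
    """
    f = np.asarray(f, dtype=float)
    y1 = 1e3 / analytic_impedance(p1, f)  # nS
    y2 = 1e3 / analytic_impedance(p2, f)
    det = (y1 + g_c) * (y2 + g_c) - g_c ** 2
    return 1e3 * (y2 + g_c) / det, 1e3 * g_c / det


def analytic_resonance_peak(params: NeuronParams, band=(0.01, 20.0),
                            with_quality: bool = False):
    """Frequency (Hz) of the analytic impedance-magnitude maximum in band.

    With ``with_quality=True`` also returns the peak-to-band-edge magnitude
    ratio (1.0 means a flat/monotone profile, i.e. no true resonance).
    """
    grid = np.geomspace(band[0], band[1], 2000)
    mag = np.abs(analytic_impedance(params, grid))
    k = int(np.argmax(mag))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda lf: -np.abs(analytic_impedance(params, math.exp(lf))),
        bounds=(math.log(lo), math.log(hi)), method="bounded",
        options={"xatol": 1e-10})
    f_peak = math.exp(res.x)
    if not with_quality:
        return f_peak
    quality = float(-res.fun / max(mag[0], mag[-1]))
    return f_peak, quality


def calibrate_resonator(template: NeuronParams, target_f_res: float, *,
                        free_param: str = "tau_w",
                        bracket=(0.02, 60.0), tol: float = 0.01,
                        max_iter: int = 100) -> NeuronParams:
    """Pin the analytic resonance peak of a linear cell to a target.

    Bisects one designated free parameter (``tau_w`` by default; ``g_w`` is
    the alternative) until the analytic impedance peak lies within ``tol``
    (relative, default 1 %) of ``target_f_res``.  The peak frequency is
    monotone decreasing in ``tau_w`` and increasing in ``g_w`` over any
    bracket in which a peak exists.
    """
    if template.pacemaker_on:
        raise ValueError("calibrate_resonator requires a linear template")
    if not (0.05 < target_f_res < 3.0):
        raise ValueError("target resonance must lie in (0.05, 3) Hz")

    def peak_at(x):
        return analytic_resonance_peak(template.copy(**{free_param: x}))

    # The peak frequency is not monotone over an arbitrary bracket (for very
    # fast tau_w the resonant current acts ohmically and the profile becomes
    # quasi-flat), so scan first, keep only parameter values with a genuine
    # peak (prominence over the band edges), and bisect inside one monotone
    # segment straddling the target.
    grid = np.geomspace(bracket[0], bracket[1], 25)
    fq = [analytic_resonance_peak(template.copy(**{free_param: x}),
                                  with_quality=True) for x in grid]
    valid = np.array([q >= 1.05 for _, q in fq])
    fg = np.array([f for f, _ in fq])
    seg = None
    for a in range(grid.size - 1):
        if not (valid[a] and valid[a + 1]):
            continue
        lo_f, hi_f = sorted((fg[a], fg[a + 1]))
        if lo_f <= target_f_res <= hi_f:
            seg = a
            break
    if seg is None:
        raise RuntimeError(
            f"no bracketing interval for {free_param} in {bracket}: "
            f"resonant peaks span "
            f"[{fg[valid].min() if valid.any() else float('nan'):.4g}, "
            f"{fg[valid].max() if valid.any() else float('nan'):.4g}] Hz")
    lo, hi = grid[seg], grid[seg + 1]
    f_lo, f_hi = fg[seg], fg[seg + 1]
    increasing = f_hi > f_lo
    for _ in range(max_iter):
        mid = math.sqrt(lo * hi)
        f_mid = peak_at(mid)
        if abs(f_mid - target_f_res) <= tol * target_f_res:
            return template.copy(**{free_param: mid})
        if (f_mid > target_f_res) == increasing:
            hi = mid
        else:
            lo = mid
    raise RuntimeError(f"calibration did not converge in {max_iter} iterations")


def measure_cycle_frequency(params: NeuronParams, *, duration: float = 200.0,
                            discard: float = 30.0, dt: float = 1e-3) -> float:
    """Noise-free limit-cycle frequency of one cell by cycle detection.

    Simulates ``duration`` seconds, discards the initial transient and
    counts UP-state onsets (see :func:`gapnet.rhythm.detect_cycles`).
    Returns NaN when fewer than three cycles are found.
    """
    from . import rhythm  # local import; rhythm has no reverse dependency
    spec = NetworkSpec([params.copy(sigma_noise=0.0)], [], seed=0)
    ts = simulate_network(spec, duration=duration, dt=dt, noise_on=False)
    v = ts.voltages[0].slice_time(discard)
    onsets = rhythm.detect_cycles(v)
    if onsets.size < 3:
        return float("nan")
    return float(1.0 / np.mean(np.diff(onsets)))


def calibrate_oscillator(template: NeuronParams, target_freq: float, *,
                         bracket=(0.2, 20.0), tol: float = 0.02,
                         max_iter: int = 100) -> NeuronParams:
    """Pin the noise-free limit-cycle frequency of a pacemaker cell.

    Bisects ``tau_w`` (the recovery time constant, over which the cycle
    frequency is monotone decreasing) until the measured frequency of a
    200 s noise-free simulation is within ``tol`` (default 2 %) of the
    target.
    """
    if not template.pacemaker_on:
        raise ValueError("calibrate_oscillator requires pacemaker_on=True")
    if not (0.05 < target_freq < 1.0):
        raise ValueError("target frequency must lie in (0.05, 1) Hz")

    def freq_at(tau):
        return measure_cycle_frequency(template.copy(tau_w=tau))

    lo, hi = bracket
    f_lo, f_hi = freq_at(lo), freq_at(hi)
    if math.isnan(f_lo) and math.isnan(f_hi):
        raise RuntimeError("template does not oscillate anywhere in the "
                           f"bracket {bracket}")
    if math.isnan(f_hi):
        # oscillation dies at large tau_w; shrink from above
        for _ in range(20):
            hi *= 0.8
            f_hi = freq_at(hi)
            if not math.isnan(f_hi):
                break
        else:
            raise RuntimeError("could not find an oscillating upper bracket")
    if not (min(f_lo, f_hi) <= target_freq <= max(f_lo, f_hi)):
        raise RuntimeError(
            f"target {target_freq} Hz outside the reachable range "
            f"[{min(f_lo, f_hi):.3g}, {max(f_lo, f_hi):.3g}] Hz")
    for _ in range(max_iter):
        mid = math.sqrt(lo * hi)
        f_mid = freq_at(mid)
        if not math.isnan(f_mid) and abs(f_mid - target_freq) <= tol * target_freq:
            return template.copy(tau_w=mid)
        if math.isnan(f_mid) or f_mid < target_freq:
            hi = mid
        else:
            lo = mid
    raise RuntimeError(f"calibration did not converge in {max_iter} iterations")


# ---------------------------------------------------------------------------
# calcium fluorescence proxy

def ca_proxy(V: Trace, *, tau_ca: float = 1.0, gain: float = 0.05,
             v_thresh: float = -60.0, baseline: float = 1.0,
             noise_sd: float = 0.0, fs_out: float = 3.0,
             seed: int = 0) -> Trace:
    """Slow fluorescence proxy of a voltage trace, resampled to ``fs_out``.

    The supra-threshold depolarization ``(V - v_thresh)+`` (mV) is low-pass
    filtered with a first-order kernel of time constant ``tau_ca`` (the
    indicator decay), scaled by ``gain`` (a.u. per mV), offset by
    ``baseline`` and sampled at the imaging frame rate (default 3 Hz) with
    seeded Gaussian shot noise.  Output is strictly positive.
    """
    if tau_ca <= 0:
        raise ValueError("tau_ca must be positive")
    if fs_out > 1.0 / V.dt + 1e-9:
        raise ValueError("fs_out may not exceed the voltage sampling rate")
    from scipy import signal as _signal
    drive = np.maximum(V.data - v_thresh, 0.0)
    alpha = 1.0 - math.exp(-V.dt / tau_ca)
    # first-order IIR y[k] = (1-a) y[k-1] + a x[k], initialized at x[0]
    filt = _signal.lfilter([alpha], [1.0, -(1.0 - alpha)], drive,
                           zi=np.array([(1.0 - alpha) * drive[0]]))[0]
    f_full = baseline + gain * filt
    n_out = int(math.floor(fs_out * V.duration))
    t_out = np.arange(n_out) / fs_out
    f_out = np.interp(t_out, V.t, f_full)
    if noise_sd > 0:
        rng = np.random.Generator(np.random.Philox(
            np.random.SeedSequence(entropy=int(seed))))
        f_out = f_out + noise_sd * rng.standard_normal(n_out)
    f_out = np.maximum(f_out, 1e-9)
    return Trace(f_out, 1.0 / fs_out, "a.u.", "F",
                 meta={"tau_ca": tau_ca, "gain": gain, "v_thresh": v_thresh})


# ---------------------------------------------------------------------------
# presets

PRESET_NAMES = ("rat_cell", "mouse_cell", "rat_pair", "rat_network",
                "mouse_network")

#: template pacemaker cells; the slow constants (tau_w, g_w) are refined by
#: calibration.  The mouse cell is the rat cell with every voltage-dependent
#: constant shifted +15 mV, giving the more depolarized, shallower cycle.
RAT_PACEMAKER_TEMPLATE = NeuronParams(
    C=1.0, g_L=5.0, E_L=-62.0, g_w=5.0, tau_w=3.0, pacemaker_on=True,
    g_p=3.5, E_p=50.0, V_half_p=-55.0, k_p=3.0,
    g_K=16.0, E_K=-65.0, V_half_w=-56.0, k_w=2.0,
    sigma_noise=15.0, tau_noise=0.05)

MOUSE_PACEMAKER_TEMPLATE = NeuronParams(
    C=1.0, g_L=5.0, E_L=-47.0, g_w=5.0, tau_w=1.0, pacemaker_on=True,
    g_p=3.5, E_p=50.0, V_half_p=-40.0, k_p=3.0,
    g_K=16.0, E_K=-53.5, V_half_w=-41.0, k_w=2.0,
    sigma_noise=15.0, tau_noise=0.05)

#: linear resonator template used for resonance measurements ("TTX" regime)
LINEAR_TEMPLATE = NeuronParams(C=1.0, g_L=5.0, E_L=-65.0, g_w=10.0,
                               tau_w=1.0)

#: paper-anchored numeric targets per preset
_PRESET_TARGETS = {
    "rat_cell": {"oscillation_hz": 0.15, "preferred_hz": 0.30,
                 "nadir_mv": -66.0},
    "mouse_cell": {"oscillation_hz": 0.39, "preferred_hz": 0.35,
                   "nadir_mv": -51.2},
    "rat_pair": {"cc": 0.18, "prejunctional_hz": 0.31,
                 "postjunctional_hz": 0.17},
    "rat_network": {"oscillation_hz": 0.15, "cv_percent": 1.99,
                    "intrinsic_band_hz": (0.2, 0.6)},
    "mouse_network": {"cv_percent": 41.48,
                      "intrinsic_band_hz": (0.2, 0.6)},
}


def _dc_coupling_conductance(cell: NeuronParams, cc: float) -> float:
    """g_c giving steady-state coupling coefficient ``cc`` into ``cell``."""
    g_post = cell.g_L + cell.g_w
    return cc * g_post / (1.0 - cc)


def _calibrate_single_cell(template: NeuronParams, osc_hz: float,
                           res_hz: float) -> NeuronParams:
    """Alternately pin the limit-cycle frequency (via tau_w) and the
    TTX-regime resonance (via g_w) of one pacemaker cell.

    The two calibrations interact weakly (g_w adds slow feedback to the
    cycle; tau_w moves the resonance), so a few alternations converge.
    """
    p = template
    for _ in range(4):
        p = calibrate_oscillator(p, osc_hz)
        ttx = apply_ttx(p)
        cal = calibrate_resonator(ttx, res_hz, free_param="g_w",
                                  bracket=(0.1, 200.0))
        p = p.copy(g_w=cal.g_w)
        f_osc = measure_cycle_frequency(p)
        f_res = analytic_resonance_peak(apply_ttx(p))
        if (abs(f_osc - osc_hz) <= 0.02 * osc_hz
                and abs(f_res - res_hz) <= 0.01 * res_hz):
            return p
    raise RuntimeError("single-cell calibration did not converge")


def _calibrate_pair(cc: float, pre_hz: float, post_hz: float):
    """Resolve the coupled-pair preset by nested bisection on the analytic
    self- and transfer-impedance peaks.

    g_c comes from the DC coupling-coefficient formula.  The postjunctional
    membrane capacitance sets the junctional low-pass corner and hence the
    transfer peak (outer loop, monotone decreasing in C2); tau_w of the
    injected cell re-pins the self peak at each step (inner loop, monotone
    decreasing in tau_w on the slow branch).
    """
    base = LINEAR_TEMPLATE
    g_c = _dc_coupling_conductance(base, cc)
    grid = np.geomspace(0.02, 20.0, 4000)

    def peaks(tau1, c2):
        p1 = base.copy(tau_w=tau1)
        p2 = base.copy(C=c2)
        z11, z21 = analytic_pair_impedance(p1, p2, g_c, grid)
        return grid[np.argmax(np.abs(z11))], grid[np.argmax(np.abs(z21))]

    def tau1_for_pre(c2):
        lo, hi = 0.3, 50.0
        for _ in range(60):
            mid = math.sqrt(lo * hi)
            f11, _ = peaks(mid, c2)
            if abs(f11 - pre_hz) < 1e-4:
                return mid
            if f11 > pre_hz:
                lo = mid
            else:
                hi = mid
        return math.sqrt(lo * hi)

    lo2, hi2 = 2.0, 60.0
    tau1 = tau1_for_pre(math.sqrt(lo2 * hi2))
    for _ in range(60):
        c2 = math.sqrt(lo2 * hi2)
        tau1 = tau1_for_pre(c2)
        _, f21 = peaks(tau1, c2)
        if abs(f21 - post_hz) < 1e-4:
            break
        if f21 > post_hz:
            lo2 = c2
        else:
            hi2 = c2
    p1 = base.copy(tau_w=tau1)
    p2 = base.copy(C=c2)
    return p1, p2, g_c


@lru_cache(maxsize=32)
def _make_preset_cached(name: str, n_cells: int, seed: int) -> Preset:
    targets = _PRESET_TARGETS[name]
    if name == "rat_cell":
        cell = _calibrate_single_cell(RAT_PACEMAKER_TEMPLATE,
                                      targets["oscillation_hz"],
                                      targets["preferred_hz"])
        spec = NetworkSpec([cell], [], seed=seed)
    elif name == "mouse_cell":
        cell = _calibrate_single_cell(MOUSE_PACEMAKER_TEMPLATE,
                                      targets["oscillation_hz"],
                                      targets["preferred_hz"])
        spec = NetworkSpec([cell], [], seed=seed)
    elif name == "rat_pair":
        p1, p2, g_c = _calibrate_pair(targets["cc"],
                                      targets["prejunctional_hz"],
                                      targets["postjunctional_hz"])
        spec = NetworkSpec([p1, p2], [GapJunctionEdge(0, 1, g_c)], seed=seed)
    elif name in ("rat_network", "mouse_network"):
        rng = np.random.Generator(np.random.Philox(
            np.random.SeedSequence(entropy=int(seed), spawn_key=(97,))))
        lo, hi = targets["intrinsic_band_hz"]
        template = (RAT_PACEMAKER_TEMPLATE if name == "rat_network"
                    else MOUSE_PACEMAKER_TEMPLATE)
        freqs = rng.uniform(lo, hi, size=n_cells)
        cells = [calibrate_oscillator(template, float(f)) for f in freqs]
        edges = []
        if name == "rat_network":
            g_c = _dc_coupling_conductance(template, 0.18)
            edges = [GapJunctionEdge(i, j, g_c)
                     for i in range(n_cells) for j in range(i + 1, n_cells)]
        spec = NetworkSpec(cells, edges, seed=seed)
        targets = dict(targets)
        targets["intrinsic_hz"] = tuple(float(f) for f in freqs)
    else:
        raise ValueError(f"unknown preset {name!r}; expected one of "
                         f"{PRESET_NAMES}")
    return Preset(name, dict(targets), spec)


def make_preset(name: str, *, n_cells: int = 10, seed: int = 0) -> Preset:
    """Build a named, fully calibrated model configuration.

    ``rat_cell`` / ``mouse_cell``: one pacemaker cell pinned to the species'
    oscillation and (TTX-regime) preferred frequency.  ``rat_pair``: two
    linear resonators with a gap junction pinned to the coupling coefficient
    and pre-/post-junctional resonance targets.  ``rat_network``: ``n_cells``
    pacemakers with intrinsic frequencies drawn uniformly from 0.2-0.6 Hz and
    all-to-all strong coupling; ``mouse_network``: the same ensemble with no
    edges.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; expected one of "
                         f"{PRESET_NAMES}")
    return copy.deepcopy(_make_preset_cached(name, int(n_cells), int(seed)))
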