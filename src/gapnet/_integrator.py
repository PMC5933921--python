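"""Fixed-step exponential-Euler integrator for gap-junction-coupled cells.

The state of each cell is (V, w, w_K, I_ou):

* ``V``   membrane voltage (mV),
* ``w``   slow resonant variable (mV, first-order tracker of V - E_L),
* ``w_K`` slow recovery gate of the pacemaker branch (unitless, in [0, 1]),
* ``I_ou`` Ornstein-Uhlenbeck current noise (pA).

Membrane equation (units: mV, pA, nS, nF, s; nS*mV = pA, pA/nF = mV/s)::

    C dV/dt = -g_L (V - E_L) - g_w w
              + g_p sigma_p(V) (E_p - V) + g_K w_K (E_K - V)   [pacemaker]
              + sum_j g_c (V_j - V_i) + I_ext + I_ou

    dw/dt   = ((V - E_L) - w) / tau_w
    dw_K/dt = (sigma_w(V) - w_K) / tau_w

with logistic activations ``sigma_p`` and ``sigma_w``.  Voltage is advanced
with exponential Euler on the instantaneous total conductance; the gates use
their exact first-order update.  Integration runs in chunks so that noise
and stimulus buffers never cover more than a few seconds at a time.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: internal integration step (s); recording may be decimated from this
H_INTERNAL = 1e-4

#: default chunk length in internal steps (10 s at the internal step)
CHUNK_STEPS = 100_000


@njit(cache=True)
def _kernel(V, w, wK, Iou, n_steps, h,
                 C, gL, EL, gw, aw, pace, gp, Ep, Vhp, kp, gK, EK, Vhw, kw,
                 ei, ej, eg, gc_sum,
                 stim_idx, stim,
                 ou_keep, ou_new, normals, noise_on,
                 rec, rec_every, step0):
    n = V.size
    n_edges = ei.size
    n_stim = stim_idx.size
    cs = np.zeros(n)
    iext = np.zeros(n)
    for k in range(n_steps):
        gstep = step0 + k
        if gstep % rec_every == 0:
            r = gstep // rec_every
            for i in range(n):
                rec[r, i] = V[i]
        for i in range(n):
            cs[i] = 0.0
            iext[i] = 0.0
        for e in range(n_edges):
            a = ei[e]
            b = ej[e]
            cs[a] += eg[e] * V[b]
            cs[b] += eg[e] * V[a]
        for s in range(n_stim):
            iext[stim_idx[s]] = stim[s, k]
        for i in range(n):
            Vi = V[i]
            G = gL[i] + gc_sum[i]
            bsrc = gL[i] * EL[i] - gw[i] * w[i] + cs[i] + Iou[i] + iext[i]
            if pace[i]:
                sp = 1.0 / (1.0 + np.exp(-(Vi - Vhp[i]) / kp[i]))
                G += gp[i] * sp + gK[i] * wK[i]
                bsrc += gp[i] * sp * Ep[i] + gK[i] * wK[i] * EK[i]
            w[i] += ((Vi - EL[i]) - w[i]) * aw[i]
            if pace[i]:
                sw = 1.0 / (1.0 + np.exp(-(Vi - Vhw[i]) / kw[i]))
                wK[i] += (sw - wK[i]) * aw[i]
            if noise_on:
                Iou[i] = Iou[i] * ou_keep[i] + ou_new[i] * normals[i, k]
            vinf = bsrc / G
            V[i] = vinf + (Vi - vinf) * np.exp(-G * h / C[i])
    return


class DivergenceError(RuntimeError):
    """Raised when the integrator produces a non-finite state."""


def integrate(cells, edges, duration, *, rec_dt=H_INTERNAL, stimulus=None,
              noise_on=False, seed=0, v0=None, h=H_INTERNAL):
    """Integrate a network and return recorded voltages.

    Parameters
    ----------
    cells : sequence of NeuronParams
    edges : sequence of (i, j, g_c)
    duration : float
        Total simulated time (s).
    rec_dt : float
        Recording interval (s); must be an integer multiple of ``h``.
    stimulus : dict[int, ndarray] or None
        Per-cell injected current sampled at ``h`` over the full duration
        (pA).  Cells absent from the dict receive no stimulus.
    noise_on : bool
        Enable the per-cell OU current noise.
    seed : int
        Base seed; each cell gets an independent Philox stream derived from
        ``(seed, cell index)``.
    v0 : ndarray or None
        Initial voltages; defaults to each cell's leak reversal.

    Returns
    -------
    rec : ndarray, shape (n_samples, n_cells)
        Voltages at ``t = 0, rec_dt, 2 rec_dt, ...`` (mV).
    """
    n = len(cells)
    rec_every = int(round(rec_dt / h))
    if abs(rec_every * h - rec_dt) > 1e-12:
        raise ValueError("rec_dt must be an integer multiple of the internal step")
    n_steps = int(round(duration / h))
    n_rec = (n_steps + rec_every - 1) // rec_every

    C = np.array([c.C for c in cells])
    gL = np.array([c.g_L for c in cells])
    EL = np.array([c.E_L for c in cells])
    gw = np.array([c.g_w for c in cells])
    tauw = np.array([c.tau_w for c in cells])
    aw = 1.0 - np.exp(-h / tauw)
    pace = np.array([bool(c.pacemaker_on) for c in cells])
    gp = np.array([c.g_p for c in cells])
    Ep = np.array([c.E_p for c in cells])
    Vhp = np.array([c.V_half_p for c in cells])
    kp = np.array([c.k_p for c in cells])
    gK = np.array([c.g_K for c in cells])
    EK = np.array([c.E_K for c in cells])
    Vhw = np.array([c.V_half_w for c in cells])
    kw = np.array([c.k_w for c in cells])

    ei = np.array([e[0] for e in edges], dtype=np.int64)
    ej = np.array([e[1] for e in edges], dtype=np.int64)
    eg = np.array([e[2] for e in edges], dtype=float)
    gc_sum = np.zeros(n)
    for a, b, g in zip(ei, ej, eg):
        gc_sum[a] += g
        gc_sum[b] += g

    if stimulus:
        stim_idx = np.array(sorted(stimulus), dtype=np.int64)
    else:
        stim_idx = np.zeros(0, dtype=np.int64)

    sigma = np.array([c.sigma_noise for c in cells])
    taun = np.array([c.tau_noise for c in cells])
    ou_keep = np.exp(-h / taun)
    ou_new = sigma * np.sqrt(1.0 - np.exp(-2.0 * h / taun))

    V = (np.array(v0, dtype=float).copy() if v0 is not None else EL.copy())
    w = V - EL
    wK = 1.0 / (1.0 + np.exp(-(V - Vhw) / kw))
    Iou = np.zeros(n)

    rngs = [np.random.Generator(np.random.Philox(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(i,))))
        for i in range(n)] if noise_on else None

    rec = np.empty((n_rec, n), dtype=float)
    empty_norm = np.zeros((n, 0))
    step0 = 0
    while step0 < n_steps:
        nk = min(CHUNK_STEPS, n_steps - step0)
        if stim_idx.size:
            stim = np.zeros((stim_idx.size, nk))
            for s, i in enumerate(stim_idx):
                arr = stimulus[int(i)]
                stim[s] = arr[step0:step0 + nk]
        else:
            stim = np.zeros((0, nk))
        if noise_on:
            normals = np.empty((n, nk))
            for i in range(n):
                normals[i] = rngs[i].standard_normal(nk)
        else:
            normals = empty_norm
        _kernel(V, w, wK, Iou, nk, h,
                     C, gL, EL, gw, aw, pace, gp, Ep, Vhp, kp, gK, EK, Vhw, kw,
                     ei, ej, eg, gc_sum,
                     stim_idx, stim,
                     ou_keep, ou_new, normals, bool(noise_on),
                     rec, rec_every, step0)
        if not np.all(np.isfinite(V)):
            bad = int(np.flatnonzero(~np.isfinite(V))[0])
            t_bad = (step0 + nk) * h
            raise DivergenceError(
                f"non-finite voltage in cell {bad} by t = {t_bad:.3f} s; "
                "the model diverged (check conductances and step size)")
        step0 += nk
    return rec
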