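# gapnet

Simulation and analysis toolbox for slow subthreshold rhythms in
gap-junction-coupled neuronal networks.

Hypothalamic tuberoinfundibular dopamine (TIDA) neurons show a striking
species contrast: in rat slices they oscillate in a slow (~0.15 Hz), highly
regular, tightly synchronized UP/DOWN rhythm carried by strong Cx36
electrical coupling, while mouse TIDA neurons — electrically uncoupled —
oscillate faster (~0.4 Hz), irregularly and independently, even though both
species contain cells with a similar spread of intrinsic preferred
(resonance) frequencies (~0.2–0.6 Hz). `gapnet` packages the measurement
pipeline used to establish such results — exponential-chirp (ZAP) impedance
analysis, paired-recording coupling coefficients, transfer (postjunctional)
resonance, oscillation/synchrony statistics and ΔF/F₀ calcium analysis —
together with a generative model of electrically coupled resonant and
oscillating cells, so that every analysis can be exercised, calibrated and
validated without laboratory data.

## Model and measurements

Each cell is a conductance-based membrane (units mV, pA, nS, nF, s):

```
C dV/dt = −g_L (V−E_L) − g_w w + g_p σ_p(V)(E_p−V) + g_K w_K (E_K−V)
          + Σ_j g_c (V_j−V_i) + I_ext + I_OU
dw/dt   = ((V−E_L) − w) / τ_w          (slow resonant variable, mV)
dw_K/dt = (σ_w(V) − w_K) / τ_w         (pacemaker recovery gate)
```

With the pacemaker branch off the cell is linear and its impedance has the
closed form `Z(f) = 1 / (g_L + i2πf C + g_w/(1 + i2πf τ_w))`, whose
magnitude peaks at the preferred frequency; with it on, the fast
regenerative current and slow recovery form a relaxation oscillator that
alternates between depolarized UP and hyperpolarized DOWN states.
Gap junctions are ohmic and symmetric; directional asymmetry of the
measured coupling coefficient `CC₁₂ = ΔV₂/ΔV₁` emerges from unequal
membrane conductances.

The analysis side computes `Z(f) = Ṽ(f)/Ĩ(f)` from simulated (or imported)
traces driven by an exponential chirp `I_max·sin(2π f_min (e^{Lt}−1)/L)`,
extracts the resonance peak, scores stimulus entrainment, measures
sweep-averaged coupling coefficients, detects UP-state onsets with a
Schmitt trigger, and derives frequency, CV, synchrony and ΔF/F₀ statistics.

## Worked example

```python
from gapnet.synthetic_models import make_preset, simulate_network
from gapnet import rhythm

preset = make_preset("rat_network", n_cells=10, seed=1)
ts = simulate_network(preset.resolved, duration=300.0, dt=1e-3,
                      noise_on=True)
freqs = [rhythm.oscillation_stats(rhythm.despike(v.slice_time(30.0))).mean_freq
         for v in ts.voltages]
sync = rhythm.pairwise_sync(ts)
print([round(f, 3) for f in freqs[:3]], round(sync.mean_offdiag(), 3))
```

prints

```
[0.391, 0.391, 0.391] 0.995
```

— ten cells whose intrinsic frequencies were drawn from 0.2–0.6 Hz all
cycle at one common frequency (across-cell CV < 0.01 %) with near-perfect
zero-lag correlation.  Rebuilding the same ensemble with the edge list
removed leaves each cell at its own drawn frequency (across-cell CV ≈ 25 %,
mean r₀ ≈ 0.01): the junctions, not the cells, set the network rhythm.

The same experiments are available from the shell, e.g.

```
gapnet recipe --name transfer_pair --seed 1 --out-dir out/
gapnet simulate --preset rat_network --duration 120 --seed 1 --out out/run
gapnet rhythm --traces out/run.tsv --report out/rhythm.json
```

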