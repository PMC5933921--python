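# Methods

This note documents the models, estimators and numerical choices behind
`gapnet`, in the spirit of a methods appendix: what is computed, under what
assumptions, and where the design was genuinely open.

## Cell model

A cell is a single-compartment membrane with up to four currents
(units mV, pA, nS, nF, s; nS·mV = pA and pA/nF = mV/s, so no unit
conversions appear in the integrator):

* leak `−g_L (V − E_L)`;
* a slow resonant current `−g_w w`, where `w` tracks `V − E_L` with time
  constant `τ_w`.  This is the standard two-variable resonant membrane: its
  impedance `Z(f) = 1/(g_L + i2πfC + g_w/(1 + i2πf τ_w))` is exact, and the
  magnitude peaks at sub-Hz frequencies when `τ_w` is slow (seconds) and the
  effective capacitance is large.  Individual parameter magnitudes are not
  meant to be biophysically literal; only the emergent frequencies,
  coupling coefficients and waveforms are calibrated quantities.
* a fast regenerative (persistent-sodium-like) current
  `g_p σ_p(V)(E_p − V)` with instantaneous logistic activation, and
* a slow recovery (potassium-like) current `g_K w_K (E_K − V)` whose gate
  relaxes to a logistic `σ_w(V)` at rate `1/τ_w`.

The last two (the "pacemaker branch", `pacemaker_on=True`) form a
relaxation oscillator: the fast current makes the current–voltage relation
N-shaped, the recovery gate slowly sweeps the membrane between the two
stable branches, and the cell alternates between a depolarized UP state and
a hyperpolarized DOWN state.  No published equation set exists for the cell
this emulates, so this minimal form is a modeling decision; its constants
were placed by nullcline analysis so that

* the cycle is subthreshold (UP ≈ −36 mV, DOWN nadir ≈ −66 mV for the rat
  template; the mouse template is the rat template with every
  voltage-dependent constant shifted +15 mV, giving a shallower, more
  depolarized cycle with nadir ≈ −51 mV);
* the limit cycle persists for `τ_w` from ~0.3 to ~10 s, spanning cycle
  frequencies ~0.05–0.8 Hz with frequency monotone decreasing in `τ_w`
  (the property the oscillator calibration bisects on);
* under steady hyperpolarizing current the cycle slows and finally
  collapses to a fixed point — the behavior of an uncoupled, entrainable
  cell — while the coupled ensemble is insensitive to single-cell
  perturbation.

Sodium-channel blockade ("TTX") is emulated by freezing `σ_p` at its
UP-state constant, which reduces the cell exactly to a linear membrane with
an equivalent leak `(g_L', E_L')` (`apply_ttx`); resonance protocols run on
this view with a −20 pA holding bias, mirroring the experimental protocol
of measuring resonance under TTX with compensating DC.  The equivalent
resting point of the frozen cell is depolarized; since the cell is linear,
the impedance profile is independent of the operating point and only the
frequency content matters.

## Gap junctions and networks

Junctions are ohmic and symmetric: the current into cell *i* from edge
(i, j) is `g_c (V_j − V_i)`, with at most one edge per unordered pair.
Asymmetric coupling coefficients arise only from unequal membrane
conductances on the two sides.  A `NetworkSpec` (cells + edges + seed) is
the generative model of a slice; identical spec, stimulus and seed
reproduce traces bit-for-bit.

Ensemble presets:

* `rat_cell` / `mouse_cell` — one pacemaker cell pinned to the species'
  oscillation frequency (0.15 / 0.39 Hz) and TTX-regime preferred frequency
  (0.30 / 0.35 Hz).  One `τ_w` serves both the resonant current and the
  recovery gate, so the two targets are met by alternating calibration:
  bisect `τ_w` against the measured limit-cycle frequency, then bisect
  `g_w` against the analytic resonance peak of the TTX view; the couplings
  between the two knobs are weak and the alternation converges in ≤ 4
  rounds (tolerances 2 % and 1 %).
* `rat_pair` — two linear resonators joined by a junction whose
  conductance comes from the DC coupling-coefficient identity
  `g_c = CC·G_post/(1 − CC)` with target CC = 0.18.  The prejunctional
  self-impedance peak (0.31 Hz) is pinned by bisecting `τ_w` of the
  injected cell; the postjunctional transfer peak (0.17 Hz) is pinned by
  bisecting the postjunctional capacitance, which sets the corner of the
  junctional low-pass `g_c/(Y₂ + g_c)`.  Slowing the postjunctional `τ_w`
  alone cannot move the transfer peak below ~0.28 Hz, which is why the
  capacitance is the designated knob.
* `rat_network` / `mouse_network` — n (default 10) pacemaker cells with
  intrinsic frequencies drawn uniformly from 0.2–0.6 Hz (seeded), each
  calibrated individually; the rat variant adds all-to-all junctions at the
  strength that gives an isolated pair CC = 0.18, the mouse variant has no
  edges.

## Integration and noise

Fixed-step exponential Euler at a 0.1 ms internal step (recordings
decimated to 1 kHz for long runs): the voltage is advanced against its
instantaneous total conductance, the gates by their exact first-order
updates, with gap-junction source terms taken from the previous step.
Per-cell Ornstein–Uhlenbeck current noise (default SD 15 pA, correlation
time 50 ms) uses the exact discretization; each cell draws from an
independent counter-based (Philox) stream keyed by `(spec.seed, cell
index)`, so determinism is bitwise and independent of chunking.  A
non-finite state aborts with the offending cell and time.  Simulations of
linear networks start at the DC fixed point for the stimulus' value at
t = 0, which removes onset transients from impedance records.

## Impedance pipeline

The chirp stimulus sweeps `f_min → f_max` exponentially through the phase
integral `φ(t) = 2π f_min (e^{Lt} − 1)/L`, `L = ln(f_max/f_min)/T`, with
(by default) three full `f_min` cycles prepended phase-continuously.  The
impedance is the plain DFT ratio `Z = Ṽ/Ĩ` (voltage linearly detrended)
restricted to the analysis band; for an LTI system this ratio is exact up
to record-edge effects, so no windowing or averaging is applied.  Two
conventions matter and were set by measurement:

* **the lead-in is analyzed, not discarded.**  Cutting the lead off the
  record breaks the steady-state Fourier relation for slow membranes and
  biases the broad postjunctional peak by +5–7 %; keeping it (the record
  starts in periodic steady state, so the lead serves its purpose of
  absorbing the onset) keeps errors below 1 %.  `chirp_segment` remains
  available for callers who want the cut.
* **smoothing bandwidth 0.10 octaves.**  The magnitude is smoothed with a
  per-point-renormalized Gaussian in log-frequency before peak extraction.
  A 0.25-octave kernel visibly drags sub-Hz peaks downward (≈ −3 % on a
  0.30 Hz peak, verified against the smoothed analytic curve), while the
  raw unsmoothed argmax lands on FFT-ratio ripple (≈ ±3 %); 0.10 octaves
  suppresses the ripple with ≤ 0.5 % bias.

The resonance frequency is the smoothed-magnitude argmax refined by a
parabolic fit on the FFT grid, ties broken to the lowest frequency.  A
profile whose peak fails to exceed the band-edge magnitude by 5 %
(`quality < 1.05`), or whose peak is numerically zero, is flagged
non-resonant instead of returning an arbitrary bin.  The stimulus spectrum
is checked both globally (band power ≥ 10⁻³ of whole-spectrum power) and
octave-by-octave (≥ 10⁻⁶ of the band mean) before division.  Phase is
stored in the complex profile but not analyzed.

Transfer resonance uses the same rules on `Z₁₁ = Ṽ_pre/Ĩ` and
`Z₂₁ = Ṽ_post/Ĩ` with current injected into the prejunctional cell only.

## Entrainment

The entrainment score is the maximum over ±2 s lags of the normalized
cross-correlation between the (despiked, detrended, z-scored) voltage and
the chirp command, swept 0.05–3 Hz.  The chirp amplitude follows the
experimental convention — the negative current producing a −10 mV
steady-state deflection — calibrated by secant search **on the isolated
cell membrane**.  Calibrating against the compact all-to-all network
surrogate instead demands hundreds of pA (its junctional DC load is far
stiffer than real tissue, where coupled cells still show 500–700 MΩ input
resistance) and that much current mechanically entrains the entire 10-cell
ensemble, destroying the very contrast the protocol measures.  With
isolated-cell calibration the uncoupled (mouse-type) cell follows the
chirp (score ≈ 0.55) while the embedded rat-network cell keeps the network
rhythm (score ≈ 0.18).  A frequency-domain variant of the score (chirp
frequency vs instantaneous cycle frequency) was considered and not adopted;
the waveform correlation discriminates cleanly once the amplitude is
calibrated as above.

## Coupling protocol

Negative current steps (default −30 pA; larger amplitudes whenever a
multi-mV steady response is needed, as in the experimental instruction)
are injected into each cell of a pair in turn; with noise enabled, 50
sweeps are folded and averaged.  Deflections are measured as the mean over
the last 20 % of the step minus a 1 s pre-step baseline; `CC_ij` is their
ratio, reported positive.  A prejunctional deflection under 1 mV makes the
protocol unmeasurable; detection requires the larger CC to reach 0.05 with
at least 1 mV postjunctionally.  Step width must cover ~5 slow time
constants for steady state: 0.5 s suffices for fast passive pairs
(τ_m ≈ 3 ms), while the calibrated resonant pair needs ~12 s (τ_w ≈ 2.7 s,
postjunctional τ_m ≈ 0.7 s).  The variant that triggers the step at a
DOWN-state transition of an oscillating pair is not implemented; all
quantitative coupling measurements here run in the linear (TTX) regime
where the trigger is moot.

## Rhythm statistics

Despiking is a 50 ms running median followed by a zero-phase 2 Hz
Butterworth low-pass, which passes the sub-Hz envelope essentially
unchanged (<1 % amplitude loss at 0.15 Hz) and attenuates 2 ms transients
by >95 %.  UP onsets are upward crossings of `midrange + h/2` following a
downward crossing of `midrange − h/2` (Schmitt trigger; midrange = mean of
the 5th/95th percentiles, `h` defaults to 30 % of that span).  Per-cycle
frequency is the reciprocal inter-onset interval; the CV (population SD /
mean, %) is computed per trace over cycles, and, at the slice level, across
cells over per-cell mean frequencies — the two constructions answer
different questions (cycle-to-cycle regularity vs cell-to-cell
harmonization) and both are reported.  Synchrony is the zero-lag value of
the normalized cross-correlation of z-scored despiked traces (the
correlogram-peak lag within ±5 s is reported alongside); the
autocorrelogram (biased, r(0)=1) provides a frequency cross-check via its
side-peak lag.  ΔF/F₀ uses the 10th-percentile baseline, making it exactly
invariant to multiplicative gain.

## Calcium proxy

Fluorescence is modeled as the supra-threshold depolarization
`(V − v_thresh)⁺` low-pass filtered with the indicator time constant
(default 1 s), scaled, offset by a baseline, resampled at the 3 Hz frame
rate and given seeded Gaussian shot noise.  It reproduces the slow
dynamics, frame rate and noise floor of bulk-loaded dye imaging; it does
not model indicator saturation, bleaching, neuropil contamination or
motion, so calcium-side tests validate the analysis chain rather than
imaging physics.

## What the synthetic data do and do not show

The generator reproduces the study conditions: slow regular synchronized
oscillations in a strongly coupled heterogeneous ensemble versus faster,
irregular, asynchronous oscillations in the same ensemble without
junctions; per-cell preferred frequencies ~0.3–0.35 Hz; coupling
coefficients ~0.05–0.48 with conductance-driven asymmetry; 3 Hz calcium
proxies.  Passing tests demonstrate that the estimators recover known
ground truth under these conditions and that the coupled-network phenomena
(frequency harmonization below the median intrinsic frequency, zero-lag
synchrony, robustness to entrainment) emerge from ohmic coupling of
heterogeneous relaxation oscillators.  They do not certify the estimators
against features absent from the model — action-potential waveforms,
synaptic bombardment, electrode artifacts, junctional rectification — and
the compact all-to-all network is stiffer per cell than real tissue (see
Entrainment above).

## Problem sizes and tolerances

Default analyses use 100 s chirps (10 kHz internal step, 1 kHz records),
200 s oscillator calibrations discarding a 30 s transient, 300 s network
runs with 8 seeded replicates for slice-level statistics, and 50-sweep
coupling protocols.  Calibration tolerances are 1 % (resonator), 2 %
(oscillator), with bisection capped at 100 iterations; the deflection
calibration uses a 5 % secant tolerance.  These sizes put estimator error
well inside the calibration tolerances (e.g. pipeline-vs-analytic peak
agreement ≤ 0.5 %) while keeping any single analysis in the seconds-to-
minutes range on one CPU.
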