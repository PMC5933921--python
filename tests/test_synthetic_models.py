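"""Generative models: integrator correctness, analytic impedance,
calibration, presets, noise determinism and the calcium proxy."""

import numpy as np
import pytest

from gapnet.trace import Trace
from gapnet.synthetic_models import (GapJunctionEdge, NetworkSpec,
                                     NeuronParams, analytic_impedance,
                                     analytic_resonance_peak, apply_ttx,
                                     ca_proxy, calibrate_oscillator,
                                     calibrate_resonator,
                                     linear_fixed_point, make_preset,
                                     measure_cycle_frequency,
                                     simulate_network, LINEAR_TEMPLATE,
                                     RAT_PACEMAKER_TEMPLATE)
from gapnet import rhythm
from conftest import zap_run


def step_stim(amplitude, duration, onset, dt=1e-4):
    n = int(round(duration / dt))
    data = np.zeros(n)
    data[int(round(onset / dt)):] = amplitude
    return Trace(data, dt, "pA", "I")


class TestSimulateNetwork:
    def test_passive_step_obeys_ohms_law(self, passive_cell):
        spec = NetworkSpec([passive_cell], [], seed=0)
        ts = simulate_network(spec, {0: step_stim(-30.0, 2.0, 1.0)},
                              duration=2.0, dt=1e-3)
        v = ts.voltages[0].data
        deflection = v[-1] - v[int(0.9 / 1e-3)]
        assert deflection == pytest.approx(-30.0 / 5.0, rel=1e-6)

    def test_coupled_pair_steady_state_division(self, passive_pair):
        # dV2/dV1 = g_c / (g_L2 + g_c) from the 2x2 DC linear system
        ts = simulate_network(passive_pair, {0: step_stim(-30.0, 2.0, 0.5)},
                              duration=2.0, dt=1e-3)
        dv1 = ts.voltages[0].data[-1] - ts.voltages[0].data[0]
        dv2 = ts.voltages[1].data[-1] - ts.voltages[1].data[0]
        assert dv2 / dv1 == pytest.approx(1.1 / 6.1, rel=1e-4)

    def test_rat_pacemaker_cycles_at_calibrated_frequency(
            self, rat_cell_preset):
        cell = rat_cell_preset.resolved.cells[0].copy(sigma_noise=0.0)
        freq = measure_cycle_frequency(cell)
        assert freq == pytest.approx(
            rat_cell_preset.targets["oscillation_hz"], rel=0.02)

    def test_mismatched_stimulus_rejected(self, passive_cell):
        spec = NetworkSpec([passive_cell], [], seed=0)
        with pytest.raises(ValueError, match="covers"):
            simulate_network(spec, {0: step_stim(-30.0, 1.0, 0.5)},
                             duration=2.0, dt=1e-3)

    def test_divergence_diagnostic_names_cell(self):
        # a non-finite drive poisons the state; the integrator must abort
        # naming the cell rather than return garbage traces
        from gapnet.synthetic_models import DivergenceError
        cell = NeuronParams(C=0.02, g_L=5.0, g_w=10.0, tau_w=0.5)
        with pytest.raises(DivergenceError, match="cell 0"):
            simulate_network(NetworkSpec([cell], [], seed=0),
                             {0: step_stim(np.inf, 2.0, 0.5)},
                             duration=2.0, dt=1e-3)

    def test_seed_determinism_is_bitwise(self, rat_network_preset):
        spec = rat_network_preset.resolved
        a = simulate_network(spec, duration=5.0, dt=1e-3, noise_on=True)
        b = simulate_network(spec, duration=5.0, dt=1e-3, noise_on=True)
        assert all(np.array_equal(x.data, y.data)
                   for x, y in zip(a.voltages, b.voltages))
        spec2 = spec.copy()
        spec2.seed = spec.seed + 1
        c = simulate_network(spec2, duration=5.0, dt=1e-3, noise_on=True)
        assert not np.array_equal(a.voltages[0].data, c.voltages[0].data)

    def test_passive_network_relaxes_to_unique_fixed_point(self):
        cells = [NeuronParams(C=0.5, g_L=4.0, E_L=-60.0, g_w=6.0, tau_w=0.5),
                 NeuronParams(C=1.0, g_L=6.0, E_L=-70.0, g_w=2.0, tau_w=1.0)]
        spec = NetworkSpec(cells, [GapJunctionEdge(0, 1, 2.0)], seed=0)
        vfix = linear_fixed_point(spec)
        horizon = 10.0 * max(max(c.C / c.g_L, c.tau_w) for c in cells)
        for v0 in ([-90.0, -30.0], [0.0, -120.0]):
            ts = simulate_network(spec, duration=horizon, dt=1e-3, v0=v0)
            assert np.allclose(ts.voltages[0].data[-1], vfix[0], atol=1e-3)
            assert np.allclose(ts.voltages[1].data[-1], vfix[1], atol=1e-3)

    def test_sinusoidal_steady_state_matches_analytic_impedance(self):
        # linear-regime oracle: gain and phase at several frequencies
        cell = LINEAR_TEMPLATE.copy(tau_w=2.0)
        for f in (0.05, 0.3, 1.0, 3.0):
            n_cycles = max(4, int(np.ceil(2.0 * f)) + 3)
            dur = np.ceil(n_cycles / f / 1e-3) * 1e-3
            dt = 1e-4
            t = np.arange(int(round(dur / dt))) * dt
            amp = 20.0
            stim = Trace(amp * np.sin(2 * np.pi * f * t), dt, "pA", "I")
            ts = simulate_network(NetworkSpec([cell], [], seed=0),
                                  {0: stim}, duration=dur, dt=1e-3)
            # project the last 2 cycles onto the driving quadratures
            v = ts.voltages[0]
            i0 = int(round((dur - 2.0 / f) / 1e-3))
            seg = v.data[i0:] - v.data[i0:].mean()
            tt = np.arange(v.n)[i0:] * 1e-3
            c = 2.0 / seg.size * np.dot(seg, np.cos(2 * np.pi * f * tt))
            s = 2.0 / seg.size * np.dot(seg, np.sin(2 * np.pi * f * tt))
            gain = np.hypot(c, s) / amp * 1e3   # MOhm
            z = analytic_impedance(cell, f)
            assert gain == pytest.approx(abs(z), rel=0.02)
            phase = np.arctan2(c, s)
            assert phase == pytest.approx(np.angle(z), abs=0.05)


class TestAnalyticImpedance:
    def test_rc_closed_form_when_gw_zero(self):
        cell = NeuronParams(C=0.5, g_L=4.0, g_w=0.0)
        f = np.geomspace(0.01, 100.0, 50)
        expected = 1e3 / np.hypot(4.0, 2 * np.pi * f * 0.5)
        assert np.allclose(np.abs(analytic_impedance(cell, f)), expected,
                           rtol=1e-12)

    def test_magnitude_vanishes_at_high_frequency(self):
        cell = LINEAR_TEMPLATE
        f = np.geomspace(1e3, 1e7, 40)
        mag = np.abs(analytic_impedance(cell, f))
        assert np.all(np.diff(mag) < 0)
        assert mag[-1] < 1e-3 * mag[0]

    def test_peak_agrees_with_dense_grid_argmax(self):
        # brute-force oracle: 1e4-point grid argmax
        for tau in (0.5, 2.0, 6.0):
            cell = LINEAR_TEMPLATE.copy(tau_w=tau)
            grid = np.geomspace(0.01, 20.0, 10_000)
            brute = grid[np.argmax(np.abs(analytic_impedance(cell, grid)))]
            assert analytic_resonance_peak(cell) == pytest.approx(
                brute, rel=1e-3)

    def test_rejects_nonpositive_frequency(self):
        with pytest.raises(ValueError):
            analytic_impedance(LINEAR_TEMPLATE, 0.0)

    def test_rejects_pacemaker_params(self):
        with pytest.raises(ValueError):
            analytic_impedance(RAT_PACEMAKER_TEMPLATE, 1.0)


class TestCalibrateResonator:
    @pytest.mark.parametrize("target, tol", [(0.30, 0.01), (0.35, 0.01)])
    def test_peak_lands_on_target(self, target, tol):
        cal = calibrate_resonator(LINEAR_TEMPLATE, target)
        assert analytic_resonance_peak(cal) == pytest.approx(target, rel=tol)

    def test_idempotent_at_fixed_point(self):
        c1 = calibrate_resonator(LINEAR_TEMPLATE, 0.30)
        c2 = calibrate_resonator(c1, 0.30)
        assert c1.tau_w == c2.tau_w

    def test_out_of_range_target_rejected(self):
        with pytest.raises(ValueError):
            calibrate_resonator(LINEAR_TEMPLATE, 5.0)


class TestCalibrateOscillator:
    def test_rat_frequency_recovered(self, rat_cell_preset):
        cell = rat_cell_preset.resolved.cells[0]
        f = measure_cycle_frequency(cell)
        assert f == pytest.approx(0.15, rel=0.02)

    def test_mouse_frequency_recovered(self, mouse_cell_preset):
        cell = mouse_cell_preset.resolved.cells[0]
        f = measure_cycle_frequency(cell)
        assert f == pytest.approx(0.39, rel=0.02)

    def test_cycle_frequency_monotone_in_tau_w(self):
        taus = np.geomspace(0.5, 8.0, 10)
        freqs = [measure_cycle_frequency(
            RAT_PACEMAKER_TEMPLATE.copy(tau_w=t, sigma_noise=0.0),
            duration=80.0, discard=20.0) for t in taus]
        assert np.all(np.isfinite(freqs))
        assert np.all(np.diff(freqs) < 0)

    def test_non_oscillating_template_reported(self):
        dead = RAT_PACEMAKER_TEMPLATE.copy(g_p=0.0)
        with pytest.raises(RuntimeError):
            calibrate_oscillator(dead, 0.15)


class TestPacemakerBehavior:
    def test_mouse_slows_then_collapses_under_hyperpolarization(
            self, mouse_cell_preset):
        cell = mouse_cell_preset.resolved.cells[0].copy(sigma_noise=0.0)
        freqs = []
        for hold in (0.0, -10.0, -20.0, -30.0, -60.0):
            n = int(round(90.0 / 1e-4))
            stim = Trace(np.full(n, hold), 1e-4, "pA", "I")
            ts = simulate_network(NetworkSpec([cell], [], seed=0),
                                  {0: stim}, duration=90.0, dt=1e-3)
            st = rhythm.oscillation_stats(
                rhythm.despike(ts.voltages[0].slice_time(20.0)))
            freqs.append(st.mean_freq if st.sufficient else np.nan)
        finite = [f for f in freqs if np.isfinite(f)]
        assert len(finite) >= 3
        assert all(b < a for a, b in zip(finite, finite[1:]))
        assert np.isnan(freqs[-1])  # collapse at strong holding current

    def test_nadirs_match_species_targets(self, rat_cell_preset,
                                          mouse_cell_preset):
        nadirs = {}
        for name, preset in (("rat", rat_cell_preset),
                             ("mouse", mouse_cell_preset)):
            cell = preset.resolved.cells[0].copy(sigma_noise=0.0)
            ts = simulate_network(NetworkSpec([cell], [], seed=0),
                                  duration=120.0, dt=1e-3)
            st = rhythm.oscillation_stats(ts.voltages[0].slice_time(30.0))
            nadirs[name] = st.nadir
        assert nadirs["rat"] == pytest.approx(-66.0, abs=1.5)
        assert nadirs["mouse"] == pytest.approx(-51.2, abs=1.5)
        assert nadirs["rat"] < nadirs["mouse"]

    def test_coupled_homogeneous_pacemakers_phase_lock(self,
                                                       rat_cell_preset):
        cell = rat_cell_preset.resolved.cells[0]
        g_strong = 3.3
        spec = NetworkSpec([cell.copy(), cell.copy()],
                           [GapJunctionEdge(0, 1, g_strong)], seed=5)
        ts = simulate_network(spec, duration=120.0, dt=1e-3, noise_on=True)
        sync = rhythm.pairwise_sync(ts)
        assert sync.r0[0, 1] > 0.95


class TestApplyTTX:
    def test_result_is_linear_with_increased_leak(self, rat_cell_preset):
        cell = rat_cell_preset.resolved.cells[0]
        ttx = apply_ttx(cell)
        assert not ttx.pacemaker_on
        assert ttx.g_L > cell.g_L
        # the blocked cell no longer cycles
        f = measure_cycle_frequency(ttx, duration=60.0, discard=10.0)
        assert np.isnan(f)

    def test_noop_on_linear_cell(self):
        assert apply_ttx(LINEAR_TEMPLATE) == LINEAR_TEMPLATE


class TestCaProxy:
    def _const_v(self, value, duration=30.0, dt=1e-3):
        return Trace(np.full(int(duration / dt), value), dt, "mV", "V")

    def test_subthreshold_voltage_gives_flat_baseline(self):
        f = ca_proxy(self._const_v(-70.0), v_thresh=-60.0, noise_sd=0.0)
        assert np.allclose(f.data, f.data[0])
        assert np.all(f.data > 0)

    def test_oscillation_frequency_survives_transduction(self):
        dt = 1e-3
        t = np.arange(int(200.0 / dt)) * dt
        v = Trace(-55.0 + 10.0 * np.sin(2 * np.pi * 0.15 * t), dt, "mV", "V")
        f = ca_proxy(v, v_thresh=-60.0, noise_sd=0.0)
        spec = np.abs(np.fft.rfft(f.data - f.data.mean()))
        freqs = np.fft.rfftfreq(f.n, f.dt)
        assert freqs[np.argmax(spec)] == pytest.approx(0.15, abs=0.01)

    def test_output_sample_count_matches_frame_rate(self):
        f = ca_proxy(self._const_v(-70.0, duration=33.4), noise_sd=0.0,
                     fs_out=3.0)
        assert f.n == int(np.floor(3.0 * 33.4))

    def test_rejects_bad_tau(self):
        with pytest.raises(ValueError):
            ca_proxy(self._const_v(-70.0), tau_ca=0.0)


class TestPresets:
    def test_mouse_network_has_no_junctions(self, mouse_network_preset):
        assert mouse_network_preset.resolved.edges == []

    def test_rat_network_is_all_to_all(self, rat_network_preset):
        assert len(rat_network_preset.resolved.edges) == 45  # C(10, 2)

    def test_network_intrinsic_frequencies_cover_stated_band(
            self, rat_network_preset):
        fs = rat_network_preset.targets["intrinsic_hz"]
        assert len(fs) == 10
        assert all(0.2 <= f <= 0.6 for f in fs)
        # drawn frequencies are actually realized by the calibrated cells
        cell0 = rat_network_preset.resolved.cells[0]
        assert measure_cycle_frequency(
            cell0, duration=100.0, discard=20.0) == pytest.approx(
                fs[0], rel=0.03)

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown preset"):
            make_preset("gerbil_network")

    def test_preset_is_seed_reproducible(self):
        a = make_preset("rat_network", n_cells=4, seed=9)
        b = make_preset("rat_network", n_cells=4, seed=9)
        assert a.targets["intrinsic_hz"] == b.targets["intrinsic_hz"]
        assert all(x == y for x, y in zip(a.resolved.cells,
                                          b.resolved.cells))


class TestZapOracleEquivalence:
    def test_pipeline_peak_matches_analytic_argmax(self):
        # end-to-end oracle equivalence for an uncalibrated linear cell
        from gapnet.impedance import impedance_profile, resonance_frequency
        cell = LINEAR_TEMPLATE.copy(tau_w=1.5)
        v, i = zap_run(cell)
        res = resonance_frequency(impedance_profile(v, i, band=(0.05, 3.0)))
        assert res.f_res == pytest.approx(analytic_resonance_peak(cell),
                                          rel=0.03)
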