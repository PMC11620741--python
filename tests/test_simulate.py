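import numpy as np
import pytest
from dataclasses import replace

from mcellmsi.errors import SimulationError
from mcellmsi.protocols import (build_auditory_pip, build_multisensory,
                                build_sequence, build_tectal_train,
                                combine_protocols)
from mcellmsi.quantify import compute_baseline, window_response
from mcellmsi.simulate import (SimParams, excitatory_conductance,
                               ffi_conductance, ffi_ground_truth,
                               simulate_ffi_probe, simulate_membrane,
                               simulate_trial, time_grid)


class TestMembrane:
    def test_flat_at_rest_without_drive(self, nf_params):
        n = 1000
        tr = simulate_membrane(np.zeros(n), np.zeros(n), nf_params)
        assert np.allclose(tr.samples_mV, nf_params.V_rest_mV, atol=1e-12)

    @pytest.mark.parametrize("g", [0.05, 0.2, 1.0])
    def test_steady_state_closed_form(self, nf_params, g):
        # fixed point of the ODE: V = V_rest + g (E_exc - V_rest) / (1 + g)
        n = int(0.5 * nf_params.fs_hz)  # 500 ms, many time constants
        tr = simulate_membrane(np.full(n, g), np.zeros(n), nf_params)
        expected = nf_params.V_rest_mV + g * (
            nf_params.E_exc_mV - nf_params.V_rest_mV) / (1 + g)
        assert tr.samples_mV[-1] == pytest.approx(expected, abs=1e-9)

    def test_doubling_conductance_is_sublinear(self, nf_params):
        n = int(0.5 * nf_params.fs_hz)
        v1 = simulate_membrane(np.full(n, 0.1), np.zeros(n), nf_params).samples_mV[-1]
        v2 = simulate_membrane(np.full(n, 0.2), np.zeros(n), nf_params).samples_mV[-1]
        d1 = v1 - nf_params.V_rest_mV
        d2 = v2 - nf_params.V_rest_mV
        assert d2 < 2 * d1

    def test_ffi_is_a_pure_shunt_at_rest(self, nf_params):
        # with no excitation, inhibition alone leaves V at rest
        n = 1000
        tr = simulate_membrane(np.zeros(n), np.full(n, 0.5), nf_params)
        assert np.allclose(tr.samples_mV, nf_params.V_rest_mV, atol=1e-12)

    def test_mismatched_lengths_rejected(self, nf_params):
        with pytest.raises(SimulationError):
            simulate_membrane(np.zeros(10), np.zeros(11), nf_params)

    def test_noise_is_deterministic_given_seed(self, params):
        n = 2000
        a = simulate_membrane(np.zeros(n), np.zeros(n), params, seed=42)
        b = simulate_membrane(np.zeros(n), np.zeros(n), params, seed=42)
        assert np.array_equal(a.samples_mV, b.samples_mV)


class TestConductances:
    def test_kernels_extinguish(self, nf_params, train_60hz_100ms):
        g = excitatory_conductance(train_60hz_100ms, nf_params)
        assert g[-1] < 1e-2 * g.max()

    def test_single_pulse_peak_equals_gain(self, nf_params):
        # kernels are unit-peak normalized, so max conductance ~ gain
        p = build_tectal_train(60, 1)
        g = excitatory_conductance(p, nf_params)
        # tonic contributes a little on top of the phasic peak
        assert g.max() == pytest.approx(nf_params.tec_phasic.gain, rel=0.15)

    def test_tonic_builds_monotonically_with_duration(self, nf_params):
        t33 = build_tectal_train(60, 33)
        t200 = build_tectal_train(60, 200)
        g33 = excitatory_conductance(t33, nf_params, np.array([33.0]))[0]
        g200 = excitatory_conductance(t200, nf_params, np.array([200.0]))[0]
        assert g200 > g33

    def test_ffi_tectal_extinct_by_50ms(self, nf_params):
        p = build_tectal_train(60, 1)
        t = np.arange(0, 100, 0.1)
        g = ffi_conductance(p, nf_params, t)
        # closed-form oracle for the kernel value at 50 ms (latency 4 ms)
        k = nf_params.ffi_tec
        u = 50.0 - k.latency_ms
        u_star = k.tau_rise_ms * np.log(1 + k.tau_decay_ms / k.tau_rise_ms)
        shape = lambda x: (1 - np.exp(-x / k.tau_rise_ms)) * np.exp(-x / k.tau_decay_ms)
        expected = k.gain * shape(u) / shape(u_star)
        assert g[t == 50.0][0] == pytest.approx(expected, rel=1e-9)
        # essentially extinct: below 2% of the peak
        assert g[t == 50.0][0] < 0.02 * g.max()

    def test_ffi_auditory_persists_at_50ms(self, nf_params, pip):
        t = np.arange(0, 100, 0.1)
        g = ffi_conductance(pip, nf_params, t)
        assert g[t == 50.0][0] >= 0.25 * g.max()

    def test_zero_gain_ffi_is_zero(self, nf_params, pip):
        p = nf_params.scaled_gains(auditory=0.0)
        g = ffi_conductance(pip, p)
        assert np.all(g == 0.0)

    def test_empty_protocol_rejected(self, nf_params):
        from mcellmsi.protocols import StimulusProtocol
        with pytest.raises(SimulationError):
            excitatory_conductance(StimulusProtocol((), ""), nf_params)


class TestTrials:
    def test_same_seed_bit_identical(self, params, pip):
        a = simulate_trial(pip, params, seed=7, trial_index=3)
        b = simulate_trial(pip, params, seed=7, trial_index=3)
        assert np.array_equal(a.trace.samples_mV, b.trace.samples_mV)
        c = simulate_trial(pip, params, seed=7, trial_index=4)
        assert not np.array_equal(a.trace.samples_mV, c.trace.samples_mV)

    def test_auditory_pip_peak_calibrated(self, nf_params, pip):
        # default gains: noise-free pip peak depolarization in 4-6 mV
        tr = simulate_trial(pip, nf_params, seed=0).trace
        base = compute_baseline(tr)
        peak = tr.samples_mV.max() - base
        assert 4.0 <= peak <= 6.0

    def test_multisensory_between_max_and_sum(self, nf_params):
        train = build_tectal_train(60, 100)
        m = build_multisensory(train)
        last = train.last_event_ms

        def resp(proto, start):
            tr = simulate_trial(proto, nf_params, seed=0).trace
            return window_response(tr, start, 12, compute_baseline(tr)).mean_depol_mV

        T = resp(train, last)
        A = resp(build_auditory_pip(0.0), 0.0)
        M = resp(m, last)
        assert M >= max(T, A)
        assert M <= T + A

    def test_subthreshold_by_default(self, nf_params, pip):
        assert simulate_trial(pip, nf_params, seed=0).fired is False

    def test_strong_drive_fires(self, nf_params):
        strong = nf_params.scaled_gains(auditory=20.0)
        assert simulate_trial(build_auditory_pip(0.0), strong, seed=0).fired


class TestSublinearity:
    def test_combined_never_exceeds_sum(self, nf_params):
        """Conductance summation bound: response to a compound protocol is
        pointwise below the sum of the component responses (boost off)."""
        pairs = [
            (build_auditory_pip(0.0), build_tectal_train(60, 1)),
            (build_auditory_pip(0.0), build_tectal_train(60, 100)),
            (build_tectal_train(60, 33), build_auditory_pip(0.0)),
        ]
        for first, second in pairs:
            combo = combine_protocols(first, second, 0.0)
            t = time_grid(combo, nf_params)
            vr = nf_params.V_rest_mV

            def depol(proto):
                ge = excitatory_conductance(proto, nf_params, t)
                gi = ffi_conductance(proto, nf_params, t)
                return simulate_membrane(ge, gi, nf_params, t0_ms=t[0]).samples_mV - vr

            excess = depol(combo) - (depol(first) + depol(second))
            assert excess.max() <= 1e-6

    def test_near_linear_for_weak_inputs(self, nf_params):
        # gains scaled to 0.01: combined/sum ratio approaches 1 from below
        weak = nf_params.scaled_gains(auditory=0.01, tectal=0.01)
        train = build_tectal_train(60, 33)
        m = build_multisensory(train)
        last = train.last_event_ms

        def resp(proto, start):
            tr = simulate_trial(proto, weak, seed=0).trace
            return window_response(tr, start, 12, compute_baseline(tr)).mean_depol_mV

        ratio = resp(m, last) / (resp(train, last) + resp(build_auditory_pip(0.0), 0.0))
        assert 0.98 <= ratio <= 1.0


class TestFFIProbe:
    def test_zero_inhibition_gives_zero_si(self, nf_params):
        p = nf_params.scaled_gains(tectal=0.0)
        m = simulate_ffi_probe(build_tectal_train(60, 1), 10.0, p, seed=0)
        assert m.si_percent == pytest.approx(0.0, abs=1e-12)
        assert m.ap_test_mV == pytest.approx(p.ap_control_mV)

    def test_divider_arithmetic(self, nf_params, pip):
        # %SI at the probe equals 100 (1 - 1/(1+g)) for the kernel's g
        for delay in (5.0, 10.0, 30.0, 60.0):
            m = simulate_ffi_probe(pip, delay, nf_params, seed=0)
            g = ffi_conductance(pip, nf_params, t_ms=np.array([delay]))[0]
            assert m.si_percent == pytest.approx(100 * (1 - 1 / (1 + g)), abs=1e-9)

    def test_negative_delay_rejected(self, nf_params, pip):
        with pytest.raises(SimulationError):
            simulate_ffi_probe(pip, -1.0, nf_params)

    def test_probe_sweep_tracks_kernel_shape(self, nf_params, pip):
        delays = np.arange(2, 80, 2.0)
        si = np.array([simulate_ffi_probe(pip, d, nf_params, seed=0).si_percent
                       for d in delays])
        g = ffi_conductance(pip, nf_params, t_ms=delays)
        # monotone transform of the kernel: same argmax, same ordering
        assert np.argmax(si) == np.argmax(g)
        assert np.all(np.diff(si)[np.diff(g) > 0] > 0)


class TestGroundTruth:
    def test_instant_rise_kernel_half_decay_closed_form(self, nf_params):
        # with a near-instant rise and small gain, t_half - t_peak -> tau ln 2
        kern = replace(nf_params.ffi_tec, tau_rise_ms=1e-4, gain=0.01)
        p = replace(nf_params, ffi_tec=kern)
        gt = ffi_ground_truth(p, "tectal")
        assert gt.t_half_elapsed_ms == pytest.approx(9.0 * np.log(2), abs=0.5)

    def test_zero_gain_flagged_undefined(self, nf_params):
        p = nf_params.scaled_gains(tectal=0.0)
        gt = ffi_ground_truth(p, "tectal")
        assert not gt.defined
        assert gt.auc_percent_ms == 0.0

    def test_auditory_outlasts_tectal(self, nf_params):
        aud = ffi_ground_truth(nf_params, "auditory")
        tec = ffi_ground_truth(nf_params, "tectal")
        assert aud.t_half_ms > tec.t_half_ms
        assert aud.auc_percent_ms > tec.auc_percent_ms
        assert aud.t_half_ms > aud.t_peak_ms
        assert tec.t_half_ms > tec.t_peak_ms

    def test_unknown_modality_rejected(self, nf_params):
        with pytest.raises(SimulationError):
            ffi_ground_truth(nf_params, "vestibular")
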