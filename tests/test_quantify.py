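import numpy as np
import pytest

from mcellmsi.errors import TraceError
from mcellmsi.io import Trace
from mcellmsi.protocols import CellMeta, build_auditory_pip, build_tectal_train
from mcellmsi.quantify import (average_trials, blank_artifacts, compute_baseline,
                               detect_ap, lingering_depolarization, phasic_tonic,
                               window_response)
from mcellmsi.simulate import simulate_trial

from conftest import make_trace

FS = 25000.0
DT = 1000.0 / FS


def _trace_from_fn(fn, t0_ms=-50.0, dur_ms=150.0, fs=FS):
    t = t0_ms + np.arange(int(dur_ms * fs / 1000.0)) * 1000.0 / fs
    return Trace(np.vectorize(fn)(t), fs, t0_ms), t


class TestBaseline:
    def test_flat_trace(self, flat_trace):
        assert compute_baseline(flat_trace) == pytest.approx(-80.0)

    def test_noisy_baseline_close_to_truth(self):
        rng = np.random.default_rng(11)
        n = int(0.2 * FS)
        tr = make_trace(-80.0 + rng.normal(0, 0.2, n))
        n_base = int(0.05 * FS)
        se = 0.2 / np.sqrt(n_base)
        assert compute_baseline(tr) == pytest.approx(-80.0, abs=3 * se)

    def test_no_prestimulus_data_rejected(self):
        tr = Trace(np.full(1000, -80.0), FS, t0_ms=0.0)
        with pytest.raises(TraceError):
            compute_baseline(tr)


class TestWindowResponse:
    def test_constant_window(self):
        tr, t = _trace_from_fn(lambda x: -80.0 + (5.0 if x >= 0 else 0.0))
        wq = window_response(tr, 0.0, 12.0, -80.0)
        assert wq.mean_depol_mV == pytest.approx(5.0)
        assert wq.peak_depol_mV == pytest.approx(5.0)

    def test_linear_ramp_analytic(self):
        # 0 -> 12 mV across the 12-ms window: mean 6, peak 12
        tr, _ = _trace_from_fn(lambda x: -80.0 + (x if 0 <= x < 12 else 0.0))
        wq = window_response(tr, 0.0, 12.0, -80.0)
        assert wq.mean_depol_mV == pytest.approx(6.0, abs=0.05)
        assert wq.peak_depol_mV == pytest.approx(12.0, abs=0.05)

    def test_matches_brute_force_on_simulated_trial(self, params, pip):
        tr = simulate_trial(pip, params, seed=3).trace
        base = compute_baseline(tr)
        wq = window_response(tr, 0.0, 12.0, base)
        # oracle: direct loop over samples
        vals = [v for tm, v in zip(tr.times_ms(), tr.samples_mV)
                if 0.0 - 1e-9 <= tm < 12.0 - 1e-9]
        assert wq.mean_depol_mV == pytest.approx(np.mean(vals) - base, abs=1e-12)
        assert wq.peak_depol_mV == pytest.approx(np.max(vals) - base, abs=1e-12)

    def test_window_outside_trace_rejected(self, flat_trace):
        with pytest.raises(TraceError):
            window_response(flat_trace, 1000.0, 12.0, -80.0)

    def test_translation_invariance(self, params, pip):
        tr = simulate_trial(pip, params, seed=3).trace
        shifted = Trace(tr.samples_mV + 7.3, tr.fs_hz, tr.t0_ms)
        b1, b2 = compute_baseline(tr), compute_baseline(shifted)
        w1 = window_response(tr, 0.0, 12.0, b1)
        w2 = window_response(shifted, 0.0, 12.0, b2)
        assert w1.mean_depol_mV == pytest.approx(w2.mean_depol_mV, abs=1e-9)
        assert w1.peak_depol_mV == pytest.approx(w2.peak_depol_mV, abs=1e-9)


class TestPhasicTonic:
    def test_constructed_decomposition(self):
        # V = baseline+3 just before the last pulse, window peak baseline+5
        proto = build_tectal_train(60.0, 33.0)  # last pulse at 33.33 ms
        t_last = proto.last_event_ms

        def fn(x):
            if x < 0:
                return -80.0
            if x < t_last - DT / 2:
                return -77.0
            return -75.0

        tr, _ = _trace_from_fn(fn)
        pt = phasic_tonic(tr, proto, -80.0)
        assert pt.tonic_mV == pytest.approx(3.0)
        assert pt.phasic_mV == pytest.approx(2.0)

    def test_single_pulse_flat_prestimulus(self, nf_params):
        proto = build_tectal_train(60.0, 1.0)
        tr = simulate_trial(proto, nf_params, seed=0).trace
        base = compute_baseline(tr)
        pt = phasic_tonic(tr, proto, base)
        wq = window_response(tr, 0.0, 12.0, base)
        assert pt.tonic_mV == pytest.approx(0.0, abs=1e-9)
        assert pt.phasic_mV == pytest.approx(wq.peak_depol_mV, abs=1e-9)

    def test_identity_tonic_plus_phasic_is_peak(self, nf_params):
        for dur in (33, 100, 200):
            proto = build_tectal_train(60.0, dur)
            tr = simulate_trial(proto, nf_params, seed=1).trace
            base = compute_baseline(tr)
            pt = phasic_tonic(tr, proto, base)
            wq = window_response(tr, proto.last_event_ms, 12.0, base)
            assert pt.tonic_mV + pt.phasic_mV == pytest.approx(
                wq.peak_depol_mV, abs=1e-9)

    def test_tonic_grows_phasic_stable_with_duration(self, nf_params):
        # longer trains recruit tonic depolarization; per-pulse EPSP unchanged
        decomp = {}
        for dur in (33, 200):
            proto = build_tectal_train(60.0, dur)
            tr = simulate_trial(proto, nf_params, seed=1).trace
            decomp[dur] = phasic_tonic(tr, proto, compute_baseline(tr))
        assert decomp[200].tonic_mV > decomp[33].tonic_mV
        assert decomp[200].phasic_mV == pytest.approx(
            decomp[33].phasic_mV, rel=0.10)

    def test_requires_tectal_event(self, flat_trace, pip):
        with pytest.raises(TraceError):
            phasic_tonic(flat_trace, pip, -80.0)


class TestLingering:
    def test_flat_trace_zero(self, flat_trace):
        assert lingering_depolarization(flat_trace, 50.0, -80.0) == pytest.approx(0.0)

    def test_exponential_decay_closed_form(self):
        tau = 45.0
        tr, _ = _trace_from_fn(
            lambda x: -80.0 + (5.0 * np.exp(-x / tau) if x >= 0 else 0.0))
        expected = 5.0 * np.exp(-50.0 / tau)
        assert lingering_depolarization(tr, 50.0, -80.0) == pytest.approx(
            expected, abs=0.01)

    def test_auditory_outlasts_tectal(self, nf_params):
        vals = {}
        for code, proto in (("A", build_auditory_pip(0.0)),
                            ("T", build_tectal_train(60.0, 1.0))):
            tr = simulate_trial(proto, nf_params, seed=0).trace
            vals[code] = lingering_depolarization(tr, 50.0, compute_baseline(tr))
        assert vals["A"] > vals["T"]

    def test_out_of_span_rejected(self, flat_trace):
        with pytest.raises(TraceError):
            lingering_depolarization(flat_trace, 500.0, -80.0)


class TestDetectAp:
    def test_subthreshold(self):
        tr, _ = _trace_from_fn(lambda x: -80.0 + (8.0 if 0 <= x < 5 else 0.0))
        fired, _ = detect_ap(tr, -80.0)
        assert fired is False

    def test_spike_detected_with_crossing_time(self):
        tr, _ = _trace_from_fn(lambda x: -80.0 + (60.0 if 10 <= x < 12 else 0.0))
        fired, t_cross = detect_ap(tr, -80.0)
        assert fired is True
        assert t_cross == pytest.approx(10.0, abs=DT)

    def test_threshold_boundary_is_strict(self):
        tr, _ = _trace_from_fn(lambda x: -80.0 + (25.0 if 0 <= x < 5 else 0.0))
        fired, _ = detect_ap(tr, -80.0, threshold_mV=25.0)
        assert fired is False


class TestAverageTrials:
    def _mk(self, offset=0.0, label="A", fired=False, n_samp=2500):
        from mcellmsi.io import TrialRecording
        tr = make_trace(np.full(n_samp, -80.0 + offset))
        proto = build_auditory_pip(0.0)
        if label != "A":
            proto = build_tectal_train(60.0, 1.0)
        return TrialRecording(tr, proto, CellMeta("f"), fired=fired)

    def test_identical_traces_average_to_themselves(self):
        mean, n = average_trials([self._mk() for _ in range(5)])
        assert n == 5
        assert np.allclose(mean.samples_mV, -80.0)

    def test_symmetric_offsets_cancel(self):
        trials = [self._mk(offset=(+1.0 if i % 2 else -1.0)) for i in range(6)]
        mean, n = average_trials(trials)
        assert np.allclose(mean.samples_mV, -80.0, atol=1e-12)

    def test_variance_shrinks_as_sigma2_over_n(self, params, pip):
        trials = [simulate_trial(pip, params, seed=9, trial_index=i)
                  for i in range(8)]
        mean, n = average_trials(trials)
        base_seg = mean.slice(-50.0, 0.0)
        var = base_seg.var()
        expected = params.noise_sd_mV ** 2 / 8
        assert expected / 3 < var < expected * 3

    def test_fired_trials_excluded(self):
        trials = [self._mk() for _ in range(4)] + [self._mk(offset=50, fired=True)]
        mean, n = average_trials(trials)
        assert n == 4
        assert np.allclose(mean.samples_mV, -80.0)

    def test_mixed_conditions_rejected(self):
        with pytest.raises(TraceError):
            average_trials([self._mk(), self._mk(label="T")])

    def test_unusual_n_warns(self):
        with pytest.warns(UserWarning):
            average_trials([self._mk()])


class TestBlankArtifacts:
    def test_artifact_interpolated_away(self):
        proto = build_tectal_train(60.0, 1.0)
        tr, t = _trace_from_fn(
            lambda x: -80.0 + (40.0 if 0 <= x < 0.5 else 0.0))
        cleaned = blank_artifacts(tr, proto, width_ms=1.0)
        assert cleaned.samples_mV.max() < -79.0
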