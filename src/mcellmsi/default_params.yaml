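# Default parameters of the single-compartment Mauthner-cell simulator.
# All calibration constants live here; nothing is scattered in code.
#
# Conductances are dimensionless (relative to leak).  Excitatory/inhibitory
# kernels are unit-peak-normalized difference-of-exponentials shapes scaled
# by `gain`, so `gain` is the peak conductance contributed by one event of
# amplitude 1.0.
#
# Gains were calibrated once, noise-free, against the study conditions:
#   * auditory pip: peak depolarization ~5 mV, lingering ~1.5 mV at 50 ms
#   * single tectal pulse: peak ~4.5 mV, lingering below the auditory
#     value (paired tectal pulses 50 ms apart must sum near-linearly,
#     which bounds how much tonic state one pulse may leave behind)
#   * 60 Hz / 200 ms tectal train: tonic plateau ~3 mV, plateau reached
#     within 30-100 ms, decay back to rest 200-300 ms after train end
#   * peak shunting inhibition: auditory 13.65 %SI, tectal 14.55 %SI
#
# Note on the auditory FFI plateau: its late fraction follows the
# 50%-of-peak reading (the kernel retains ~45% of peak at 50 ms); the
# alternative "about 4% absolute %SI at 50 ms" reading would need a much
# smaller slow component and is not used.

tau_m_ms: 5.0          # membrane time constant
V_rest_mV: -80.0       # resting potential; FFI reversal equals this (pure shunt)
E_exc_mV: 0.0          # excitatory reversal

aud_fast:              # electrotonic club-ending EPSP component
  gain: 0.26
  tau_rise_ms: 0.3
  tau_decay_ms: 1.0
aud_slow:              # chemical slow depolarizing envelope
  gain: 0.043
  tau_rise_ms: 3.0
  tau_decay_ms: 45.0
tec_phasic:            # per-pulse tectal EPSP
  gain: 0.118
  tau_rise_ms: 0.5
  tau_decay_ms: 3.0
tec_tonic:             # saturating tonic envelope, per-pulse increment state
  per_pulse_increment: 0.008
  saturation_level: 0.116
  tau_decay_ms: 120.0

ffi_aud:               # auditory feed-forward inhibition (two-exponential decay)
  gain: 0.158
  latency_ms: 4.0
  tau_rise_ms: 3.0
  w_fast: 0.5
  tau_fast_ms: 10.0
  tau_slow_ms: 80.0
ffi_tec:               # tectal feed-forward inhibition (single-exponential decay)
  gain: 0.170
  latency_ms: 4.0
  tau_rise_ms: 3.0
  tau_decay_ms: 9.0

noise_sd_mV: 0.2       # additive recording noise, per sample
trial_gain_sd: 0.1     # lognormal sigma of per-trial synaptic gain jitter

dendritic_boost:       # optional voltage-dependent excitability boost
  enabled: false
  threshold_mV: 5.0
  gain: 0.02           # conductance per mV of depolarization above threshold

ap_threshold_mV: 25.0  # depolarization above rest that flags a trial as fired
ap_control_mV: 20.0    # antidromic test-spike amplitude for FFI probes

fs_hz: 25000           # sampling rate
pre_stimulus_ms: 100.0 # baseline recorded before the first stimulus
post_stimulus_ms: 400.0  # tail recorded after the last stimulus
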