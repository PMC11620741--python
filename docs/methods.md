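# Methods

## Quantification conventions

Trial time zero is the first stimulus event; traces carry a pre-stimulus
baseline segment (default 100 ms) and voltages are stored as absolute
membrane potential in mV. Baseline is the mean over [−50, 0) ms. All
response windows are half-open, `[start, start + 12)` ms, anchored at the
stimulus event itself: sound onset for auditory trials, the last tectal
pulse for tectal-only and multisensory trials (under the multisensory
timing convention below, these coincide for the combined condition).

The tonic component of a train response is `V(one sample before the last
pulse) − baseline` ("immediately before" means exactly one sample at the
trace's rate, 0.04 ms at 25 kHz); the phasic component is the window peak
minus that pre-pulse level, so tonic + phasic reproduces the peak above
baseline identically. Lingering depolarization at 50 ms is averaged over a
1-ms neighborhood. Action potentials are flagged when any sample strictly
exceeds baseline + 25 mV; AP trials are excluded from subthreshold
averaging but counted for firing incidence. Trial averages use 5–10 sweeps
of one condition (counts outside 2–20 warn but do not fail).

Cells are included only when the resting potential lies in the closed
interval [−90, −70] mV; bundles load out-of-range trials but flag them.

Multisensory timing: the auditory pip onset coincides with the last pulse
of the tectal train, so the multisensory and tectal-only quantification
windows are the same window. Stimulus-artifact blanking (linear
interpolation over 1 ms after each pulse) exists but defaults to off —
synthetic traces have no artifacts.

## The simulator

A single-compartment membrane,

    dV/dt = [ −(V − V_rest) − g_exc (V − E_exc) − g_ffi (V − V_rest) ] / τ_m ,

integrated with one exponential-Euler step per sample (exact for
piecewise-constant conductances). Conductances are dimensionless relative
to leak. FFI reverses at rest, i.e. it is a pure shunt: alone it moves
nothing, but it divides concurrent excitation — an antidromic test spike of
amplitude `a` is attenuated to `a/(1 + g_ffi)`, which is how the %SI probe
is generated.

Synaptic kernels are difference-of-exponentials shapes normalized to unit
peak, so each `gain` is the peak conductance per event of amplitude 1:

| kernel | rise (ms) | decay (ms) | gain | role |
|---|---|---|---|---|
| aud_fast | 0.3 | 1 | 0.26 | electrotonic club-ending EPSP |
| aud_slow | 3 | 45 | 0.043 | slow depolarizing envelope |
| tec_phasic | 0.5 | 3 | 0.118 | per-pulse tectal EPSP |
| ffi_aud | 3 | 0.5·e^(−u/10) + 0.5·e^(−u/80) | 0.158 | auditory shunt, 4 ms latency |
| ffi_tec | 3 | 9 | 0.170 | tectal shunt, 4 ms latency |

The tectal tonic envelope is a per-pulse state `s ← s + inc·(1 − s/s_max)`
(inc = 0.008, s_max = 0.116) decaying with τ = 120 ms — it builds during a
train, saturates, and produces the slow post-train decay.

All defaults live in `src/mcellmsi/default_params.yaml` and were calibrated
once, noise-free, against the study conditions: auditory pip peak ≈ 5 mV
with ≈ 1.5 mV lingering at 50 ms; tonic plateau ≈ 3 mV for a 60-Hz/200-ms
train with a return to rest 200–300 ms after train end; FFI peaking near
9 ms post-stimulus at ≈ 14 %SI for both modalities, with tectal inhibition
decaying several times faster than auditory. The auditory FFI's late
fraction follows the stabilizes-near-half-of-peak reading (the kernel holds
~45% of peak at 50 ms).

Noise model: additive Gaussian recording noise per sample (sd 0.2 mV) and
per-trial multiplicative lognormal gain jitter (σ = 0.1, one factor per
sensory modality applied to that modality's excitatory and FFI gains).
Probe AP amplitudes are read as the crest averaged over a 1-ms window, so
their measurement error is the per-sample noise shrunk by √25 at 25 kHz.
An optional dendritic excitability boost (extra excitatory conductance
proportional to depolarization above a 5-mV threshold) is off by default;
all sublinearity guarantees assume it off.

Randomness: one root seed; the generator for trial *k* is
`SeedSequence([seed, trial_key])` with `trial_key = cell·100000 +
condition_index·100 + trial`, so any stage can be rerun in isolation and
trial sets are reproducible under reordering. Per-cell heterogeneity
(lognormal gain scale σ = 0.15, resting potential uniform in [−85, −75] mV)
derives from the same root.

## FFI analysis conventions

Probe delays are grouped, averaged (mean ± SEM), and summarized by: peak
%SI (earliest delay on ties), time of peak, half-decay time, and the
trapezoidal 0–70 ms integral. Half-decay is the first post-peak crossing of
half the peak, linearly interpolated between sampled delays, and is
reported on two conventions — absolute probe delay (`t_half_ms`) and
elapsed from the peak (`t_half_elapsed_ms`) — because published half-decay
figures are most consistent with the elapsed reading while the delay axis
is the natural sampling coordinate. AUC boundary rules: %SI at delay 0 is
taken as 0 when unsampled (inhibition cannot precede the stimulus) and the
value at 70 ms is interpolated from bracketing samples. A curve that never
falls below half peak yields an undefined-flagged half-decay, not an error.
Per-fish metrics are computed on each fish's own curve and modalities are
compared with Kruskal–Wallis on the per-fish values.

An analytic ground truth (`ffi_ground_truth`) evaluates the noise-free %SI
curve of a kernel on a 0.1-ms grid, independent of the probe pipeline; the
test suite checks that the probe pipeline recovers its half-decay within
±2 ms and its AUC within ±10% under the default noise.

## Statistics

Thin wrappers over scipy.stats with pinned small-sample behavior: the
one-sample Wilcoxon drops zeros, is exact for ≤ 25 non-zero differences
(normal approximation above) and warns when n < 5 because the exact p
cannot reach 0.05; Kruskal–Wallis applies the tie correction with a
χ² reference on k−1 df and flags all-identical data as undefined; the
linear-model ANOVA is the closed-form F = (SSR/1)/(SSE/(n−2)) with a
perfect fit flagged as infinite F; the paired t flags zero-variance
non-zero differences. No multiple-testing correction is applied. Reports
round statistics to 2 decimals and p to 4.

## What the simulator does and does not show

Passing tests demonstrate that the analysis pipeline correctly extracts
every quantity from traces with the assumed structure: phasic/tonic train
responses, fast+slow auditory EPSPs, modality-specific shunting FFI,
trial-to-trial gain variability and recording noise. Real recordings add
features the generator does not emulate — stimulus artifacts, electrode
drift, dendritic filtering, correlated (non-white) noise, spontaneous
synaptic bombardment, and presynaptic inhibition. Two consequences matter:

- with purely conductance-based summation the multisensory index for the
  briefest stimuli approaches linearity from below; supralinear values
  require the (default-off) excitability boost;
- auditory paired-pulse suppression here comes only from the persistent
  somatic shunt, so the AA sequence index (~0.94) is suppressed far less
  than the published prepulse-inhibition magnitude, much of which is
  presynaptic and outside this model's scope. The ordering AA < TT is
  robust; the absolute AA value is not comparable.

A related calibration constraint: under the saturating tonic recursion,
the tonic state a single tectal pulse leaves at 50 ms trades off directly
against the linearity of TT pairs. Defaults favor TT linearity, which
leaves the single-pulse tectal lingering (≈ 0.45 mV) below published
values while preserving its ordering against the auditory lingering
(≈ 1.5 mV).

## Problem sizes

Default synthetic runs use 10 cells × 5 trials per condition, the condition
menu (60-Hz trains of 1–200 ms, 100-ms trains of 30–200 Hz, the four 50-ms
sequences, probe delays 2–80 ms × 10 repeats) and a 20-level × 10-cell
stimulus-strength sweep for the inverse-effectiveness regression — sizes
chosen so a full run completes in well under a minute while every group
test retains conventional power.
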