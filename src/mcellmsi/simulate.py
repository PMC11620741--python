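"""Single-compartment conductance-based Mauthner-cell simulator.

The model is deliberately minimal while reproducing every structural feature
the analysis pipeline consumes:

* auditory pips drive a fast electrotonic EPSP kernel plus a slow
  depolarizing envelope;
* tectal pulses drive a per-pulse phasic kernel riding on a saturating tonic
  conductance state that builds during a train and decays over hundreds of
  milliseconds;
* each sensory event also recruits delayed feed-forward inhibition (FFI)
  whose reversal equals the resting potential, i.e. a pure shunt — tectal
  FFI decays fast (single exponential), auditory FFI slowly (two
  exponentials);
* the membrane integrates dV/dt = [-(V-V_rest) - g_exc (V-E_exc)
  - g_ffi (V-V_rest)] / tau_m with an exponential-Euler step per sample.

All conductances are dimensionless (relative to leak).  Synaptic kernels are
difference-of-exponentials normalized to unit peak, so each ``gain`` is the
peak conductance contributed by one event of amplitude 1.  Default parameter
values live in ``default_params.yaml`` and are loaded once at import.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import SimulationError
from .ffi import FFIMeasurement
from .io import Trace, TrialRecording
from .protocols import CellMeta, StimulusProtocol

_DEFAULTS: dict = yaml.safe_load(
    importlib.resources.files("mcellmsi").joinpath("default_params.yaml").read_text()
)


def _d(*keys):
    v = _DEFAULTS
    for k in keys:
        v = v[k]
    return v


@dataclass(frozen=True)
class Kernel:
    """Difference-of-exponentials synaptic kernel, unit peak times ``gain``."""

    gain: float
    tau_rise_ms: float
    tau_decay_ms: float

    def __post_init__(self) -> None:
        if self.tau_rise_ms <= 0 or self.tau_decay_ms <= 0:
            raise SimulationError("kernel time constants must be positive")
        if self.tau_rise_ms >= self.tau_decay_ms:
            raise SimulationError("tau_rise must be < tau_decay")

    @property
    def t_peak_ms(self) -> float:
        r, d = self.tau_rise_ms, self.tau_decay_ms
        return r * d / (d - r) * np.log(d / r)

    def __call__(self, t_ms: np.ndarray) -> np.ndarray:
        t = np.maximum(np.asarray(t_ms, dtype=float), 0.0)
        r, d = self.tau_rise_ms, self.tau_decay_ms
        tp = self.t_peak_ms
        norm = np.exp(-tp / d) - np.exp(-tp / r)
        out = (np.exp(-t / d) - np.exp(-t / r)) / norm
        out[np.asarray(t_ms) < 0] = 0.0
        return self.gain * out


_NORM_CACHE: dict = {}


@dataclass(frozen=True)
class TonicParams:
    per_pulse_increment: float
    saturation_level: float
    tau_decay_ms: float

    def __post_init__(self) -> None:
        if self.tau_decay_ms <= 0:
            raise SimulationError("tonic tau_decay must be positive")
        if self.saturation_level <= 0:
            raise SimulationError("tonic saturation level must be positive")


@dataclass(frozen=True)
class FFIAudKernel:
    """Rise times a two-exponential decay: w_fast fast + (1-w_fast) slow."""

    gain: float
    latency_ms: float
    tau_rise_ms: float
    w_fast: float
    tau_fast_ms: float
    tau_slow_ms: float

    def _shape(self, u: np.ndarray) -> np.ndarray:
        u = np.maximum(u, 0.0)
        return (1.0 - np.exp(-u / self.tau_rise_ms)) * (
            self.w_fast * np.exp(-u / self.tau_fast_ms)
            + (1.0 - self.w_fast) * np.exp(-u / self.tau_slow_ms)
        )

    @property
    def _norm(self) -> float:
        key = (self.tau_rise_ms, self.w_fast, self.tau_fast_ms, self.tau_slow_ms)
        if key not in _NORM_CACHE:
            grid = np.arange(0.0, 5.0 * self.tau_slow_ms, 0.01)
            _NORM_CACHE[key] = float(self._shape(grid).max())
        return _NORM_CACHE[key]

    def __call__(self, t_ms: np.ndarray) -> np.ndarray:
        u = np.asarray(t_ms, dtype=float) - self.latency_ms
        out = self._shape(u) / self._norm
        out[u < 0] = 0.0
        return self.gain * out


@dataclass(frozen=True)
class FFITecKernel:
    """Rise times a single-exponential decay."""

    gain: float
    latency_ms: float
    tau_rise_ms: float
    tau_decay_ms: float

    def _shape(self, u: np.ndarray) -> np.ndarray:
        u = np.maximum(u, 0.0)
        return (1.0 - np.exp(-u / self.tau_rise_ms)) * np.exp(-u / self.tau_decay_ms)

    @property
    def _norm(self) -> float:
        # analytic peak of (1 - e^{-u/a}) e^{-u/b} at u* = a ln(1 + b/a)
        a, b = self.tau_rise_ms, self.tau_decay_ms
        u_star = a * np.log(1.0 + b / a)
        return float(self._shape(np.array([u_star]))[0])

    def __call__(self, t_ms: np.ndarray) -> np.ndarray:
        u = np.asarray(t_ms, dtype=float) - self.latency_ms
        out = self._shape(u) / self._norm
        out[u < 0] = 0.0
        return self.gain * out


@dataclass(frozen=True)
class BoostParams:
    enabled: bool = False
    threshold_mV: float = 5.0
    gain: float = 0.02


@dataclass(frozen=True)
class SimParams:
    """All simulator parameters; defaults come from ``default_params.yaml``."""

    tau_m_ms: float = _d("tau_m_ms")
    V_rest_mV: float = _d("V_rest_mV")
    E_exc_mV: float = _d("E_exc_mV")
    aud_fast: Kernel = field(default_factory=lambda: Kernel(**_d("aud_fast")))
    aud_slow: Kernel = field(default_factory=lambda: Kernel(**_d("aud_slow")))
    tec_phasic: Kernel = field(default_factory=lambda: Kernel(**_d("tec_phasic")))
    tec_tonic: TonicParams = field(default_factory=lambda: TonicParams(**_d("tec_tonic")))
    ffi_aud: FFIAudKernel = field(default_factory=lambda: FFIAudKernel(**_d("ffi_aud")))
    ffi_tec: FFITecKernel = field(default_factory=lambda: FFITecKernel(**_d("ffi_tec")))
    noise_sd_mV: float = _d("noise_sd_mV")
    trial_gain_sd: float = _d("trial_gain_sd")
    dendritic_boost: BoostParams = field(
        default_factory=lambda: BoostParams(**_d("dendritic_boost")))
    ap_threshold_mV: float = _d("ap_threshold_mV")
    ap_control_mV: float = _d("ap_control_mV")
    fs_hz: float = _d("fs_hz")
    pre_stimulus_ms: float = _d("pre_stimulus_ms")
    post_stimulus_ms: float = _d("post_stimulus_ms")

    def __post_init__(self) -> None:
        if self.tau_m_ms <= 0:
            raise SimulationError("tau_m must be positive")
        if self.fs_hz < 1000:
            raise SimulationError("fs_hz must be >= 1000")
        if self.noise_sd_mV < 0:
            raise SimulationError("noise_sd_mV must be >= 0")

    def noise_free(self) -> "SimParams":
        return replace(self, noise_sd_mV=0.0, trial_gain_sd=0.0)

    def scaled_gains(self, auditory: float = 1.0, tectal: float = 1.0) -> "SimParams":
        """Return a copy with all synaptic gains of a modality rescaled."""
        return replace(
            self,
            aud_fast=replace(self.aud_fast, gain=self.aud_fast.gain * auditory),
            aud_slow=replace(self.aud_slow, gain=self.aud_slow.gain * auditory),
            ffi_aud=replace(self.ffi_aud, gain=self.ffi_aud.gain * auditory),
            tec_phasic=replace(self.tec_phasic, gain=self.tec_phasic.gain * tectal),
            tec_tonic=replace(
                self.tec_tonic,
                per_pulse_increment=self.tec_tonic.per_pulse_increment * tectal),
            ffi_tec=replace(self.ffi_tec, gain=self.ffi_tec.gain * tectal),
        )

    @classmethod
    def default(cls) -> "SimParams":
        return cls()


@dataclass(frozen=True)
class FFIGroundTruth:
    """Analytic FFI time-course metrics implied by a kernel (noise-free)."""

    modality: str
    peak_si_percent: float
    t_peak_ms: float
    t_half_ms: float          # absolute probe delay of the half crossing
    t_half_elapsed_ms: float  # elapsed from the peak
    auc_percent_ms: float     # integral of %SI over [0, 70] ms
    defined: bool = True


# ---------------------------------------------------------------------------
# RNG splitting rule: child generator = SeedSequence([root, *key])
# ---------------------------------------------------------------------------

def child_rng(root_seed: int, *key: int) -> np.random.Generator:
    """Deterministic per-trial RNG derived from (root seed, index key)."""
    return np.random.default_rng(np.random.SeedSequence([int(root_seed), *map(int, key)]))


# ---------------------------------------------------------------------------
# Conductance assembly
# ---------------------------------------------------------------------------

def time_grid(protocol: StimulusProtocol, params: SimParams) -> np.ndarray:
    """Sample times (ms) spanning pre-stimulus baseline to last event + tail."""
    dt = 1000.0 / params.fs_hz
    t_stop = protocol.last_event_ms + params.post_stimulus_ms
    n = int(round((t_stop + params.pre_stimulus_ms) / dt)) + 1
    return -params.pre_stimulus_ms + np.arange(n) * dt


def excitatory_conductance(
    protocol: StimulusProtocol,
    params: SimParams | None = None,
    t_ms: np.ndarray | None = None,
    gain_scale: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Total excitatory conductance series on the trial time grid.

    Auditory events add fast+slow kernels; tectal pulses add the phasic
    kernel and update the saturating tonic state
    ``s <- s + inc * (1 - s/saturation)`` which decays with its own time
    constant.  Antidromic events contribute no synaptic conductance.
    """
    params = params or SimParams.default()
    if not protocol.events:
        raise SimulationError("protocol has no events")
    if t_ms is None:
        t_ms = time_grid(protocol, params)
    scale = {"auditory": 1.0, "tectal": 1.0}
    if gain_scale:
        scale.update(gain_scale)

    g = np.zeros_like(t_ms)
    for ev in protocol.events:
        rel = t_ms - ev.time_ms
        if ev.modality == "auditory":
            a = ev.amplitude * scale["auditory"]
            g += a * (params.aud_fast(rel) + params.aud_slow(rel))
        elif ev.modality == "tectal":
            a = ev.amplitude * scale["tectal"]
            g += a * params.tec_phasic(rel)
        elif ev.modality == "antidromic":
            continue
        else:  # pragma: no cover - StimulusEvent validates modality
            raise SimulationError(f"unknown modality {ev.modality!r}")

    g += _tonic_conductance(protocol, params, t_ms, scale["tectal"])
    return g


def _tonic_conductance(
    protocol: StimulusProtocol, params: SimParams, t_ms: np.ndarray, scale: float
) -> np.ndarray:
    tp = params.tec_tonic
    pulses = protocol.events_of("tectal")
    if not pulses or tp.per_pulse_increment == 0:
        return np.zeros_like(t_ms)
    # state value immediately after each pulse
    s = 0.0
    t_prev = None
    seg_t, seg_s = [], []
    for ev in pulses:
        if t_prev is not None:
            s *= np.exp(-(ev.time_ms - t_prev) / tp.tau_decay_ms)
        inc = tp.per_pulse_increment * ev.amplitude * scale
        s = s + inc * max(0.0, 1.0 - s / tp.saturation_level)
        seg_t.append(ev.time_ms)
        seg_s.append(s)
        t_prev = ev.time_ms

    g = np.zeros_like(t_ms)
    seg_t_arr = np.asarray(seg_t)
    idx = np.searchsorted(seg_t_arr, t_ms, side="right") - 1
    valid = idx >= 0
    g[valid] = np.asarray(seg_s)[idx[valid]] * np.exp(
        -(t_ms[valid] - seg_t_arr[idx[valid]]) / tp.tau_decay_ms
    )
    return g


def ffi_conductance(
    protocol: StimulusProtocol,
    params: SimParams | None = None,
    t_ms: np.ndarray | None = None,
    gain_scale: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Total feed-forward inhibitory conductance on the trial time grid."""
    params = params or SimParams.default()
    if not protocol.events:
        raise SimulationError("protocol has no events")
    if t_ms is None:
        t_ms = time_grid(protocol, params)
    scale = {"auditory": 1.0, "tectal": 1.0}
    if gain_scale:
        scale.update(gain_scale)

    g = np.zeros_like(np.asarray(t_ms, dtype=float))
    for ev in protocol.events:
        rel = np.asarray(t_ms, dtype=float) - ev.time_ms
        if ev.modality == "auditory":
            g += ev.amplitude * scale["auditory"] * params.ffi_aud(rel)
        elif ev.modality == "tectal":
            g += ev.amplitude * scale["tectal"] * params.ffi_tec(rel)
        elif ev.modality == "antidromic":
            continue
        else:  # pragma: no cover
            raise SimulationError(f"unknown modality {ev.modality!r}")
    return g


# ---------------------------------------------------------------------------
# Membrane integration
# ---------------------------------------------------------------------------

def simulate_membrane(
    g_exc: np.ndarray,
    g_ffi: np.ndarray,
    params: SimParams | None = None,
    seed: int | None = None,
    t0_ms: float | None = None,
) -> Trace:
    """Integrate the membrane equation with exponential-Euler steps.

    FFI is a pure shunt (reversal = V_rest).  With the optional dendritic
    boost enabled, an extra excitatory conductance proportional to the
    suprathreshold depolarization is added each step.  Additive Gaussian
    recording noise (sd ``noise_sd_mV``) is applied to the voltage series;
    the result is deterministic given ``seed``.
    """
    params = params or SimParams.default()
    g_exc = np.asarray(g_exc, dtype=float)
    g_ffi = np.asarray(g_ffi, dtype=float)
    if g_exc.shape != g_ffi.shape:
        raise SimulationError("conductance series lengths differ")
    n = g_exc.size
    dt = 1000.0 / params.fs_hz
    vr, ve, tau = params.V_rest_mV, params.E_exc_mV, params.tau_m_ms
    boost = params.dendritic_boost

    V = np.empty(n)
    v = vr
    if not boost.enabled:
        g_tot = 1.0 + g_exc + g_ffi
        v_inf = (vr + g_exc * ve + g_ffi * vr) / g_tot
        a = np.exp(-dt * g_tot / tau)
        b = (1.0 - a) * v_inf
        a_list, b_list = a.tolist(), b.tolist()
        out = V
        for i in range(n):
            v = a_list[i] * v + b_list[i]
            out[i] = v
    else:
        for i in range(n):
            gb = boost.gain * max(0.0, v - vr - boost.threshold_mV)
            ge = g_exc[i] + gb
            g_tot = 1.0 + ge + g_ffi[i]
            v_inf = (vr + ge * ve + g_ffi[i] * vr) / g_tot
            v = v_inf + (v - v_inf) * np.exp(-dt * g_tot / tau)
            V[i] = v

    if params.noise_sd_mV > 0:
        rng = np.random.default_rng(seed)
        V = V + rng.normal(0.0, params.noise_sd_mV, n)
    if t0_ms is None:
        t0_ms = -params.pre_stimulus_ms
    return Trace(V, params.fs_hz, t0_ms)


def simulate_trial(
    protocol: StimulusProtocol,
    params: SimParams | None = None,
    seed: int = 0,
    trial_index: int = 0,
    cell: CellMeta | None = None,
) -> TrialRecording:
    """Simulate one trial: conductances -> membrane -> fired flag.

    Per-trial multiplicative gain jitter (lognormal, sigma ``trial_gain_sd``,
    one factor per sensory modality applied to both excitatory and FFI gains)
    and the additive recording noise both derive from the child generator
    ``SeedSequence([seed, trial_index])``, so trial sets are reproducible
    under reordering.
    """
    params = params or SimParams.default()
    rng = child_rng(seed, trial_index)
    if params.trial_gain_sd > 0:
        f_aud, f_tec = np.exp(params.trial_gain_sd * rng.standard_normal(2))
    else:
        f_aud = f_tec = 1.0
        rng.standard_normal(2)  # keep the stream position fixed
    scale = {"auditory": float(f_aud), "tectal": float(f_tec)}

    t = time_grid(protocol, params)
    g_exc = excitatory_conductance(protocol, params, t, gain_scale=scale)
    g_ffi = ffi_conductance(protocol, params, t, gain_scale=scale)
    noise_seed = int(rng.integers(0, 2**31 - 1))
    trace = simulate_membrane(g_exc, g_ffi, params, seed=noise_seed, t0_ms=t[0])

    fired = bool(np.any(trace.samples_mV > params.V_rest_mV + params.ap_threshold_mV))
    cell = cell or CellMeta(fish_id="sim", resting_potential_mV=params.V_rest_mV)
    return TrialRecording(trace=trace, protocol=protocol, cell=cell,
                          fired=fired, trial_index=trial_index)


# ---------------------------------------------------------------------------
# FFI probe experiment and its analytic ground truth
# ---------------------------------------------------------------------------

def simulate_ffi_probe(
    cond_protocol: StimulusProtocol,
    delay_ms: float,
    params: SimParams | None = None,
    seed: int = 0,
    trial_index: int = 0,
) -> FFIMeasurement:
    """Antidromic test-spike probe at ``delay_ms`` after the conditioning
    stimulus onset.

    The test AP amplitude follows the conductance divider
    ``ap_test = ap_control / (1 + g_ffi(t_probe))``.  The amplitude is an
    estimate from a noisy trace: the crest is read as the mean over a 1-ms
    window, so its measurement error is the per-sample recording noise
    ``noise_sd_mV`` shrunk by sqrt(samples in 1 ms).
    """
    params = params or SimParams.default()
    if delay_ms < 0:
        raise SimulationError(f"probe delay must be >= 0, got {delay_ms}")
    t_probe = cond_protocol.events[0].time_ms + delay_ms
    g = float(ffi_conductance(cond_protocol, params,
                              t_ms=np.array([t_probe]))[0])
    ap_control = params.ap_control_mV
    ap_test = ap_control / (1.0 + g)
    if params.noise_sd_mV > 0:
        rng = child_rng(seed, trial_index)
        n_crest = max(1.0, params.fs_hz / 1000.0)  # samples in the 1-ms crest window
        ap_test += float(rng.normal(0.0, params.noise_sd_mV / np.sqrt(n_crest)))
    return FFIMeasurement(delay_ms=delay_ms, ap_control_mV=ap_control,
                          ap_test_mV=ap_test)


def ffi_ground_truth(
    params: SimParams | None = None,
    modality: str = "tectal",
    grid_step_ms: float = 0.1,
    t_max_ms: float = 200.0,
) -> FFIGroundTruth:
    """Analytic %SI time-course metrics for a single conditioning event.

    Evaluates the noise-free %SI curve on a fine grid, independent of the
    probe-measurement pipeline, and extracts peak, time of peak, first
    post-peak 50% crossing and the 0-70 ms trapezoidal integral.
    """
    params = params or SimParams.default()
    kernel = {"tectal": params.ffi_tec, "auditory": params.ffi_aud}.get(modality)
    if kernel is None:
        raise SimulationError(f"unknown FFI modality {modality!r}")
    t = np.arange(0.0, t_max_ms + grid_step_ms / 2, grid_step_ms)
    g = kernel(t)
    si = 100.0 * (1.0 - 1.0 / (1.0 + g))
    peak = float(si.max())
    if peak <= 0:
        return FFIGroundTruth(modality, 0.0, np.nan, np.nan, np.nan, 0.0,
                              defined=False)
    i_peak = int(np.argmax(si))  # earliest maximum
    t_peak = float(t[i_peak])
    half = peak / 2.0
    t_half = np.nan
    for i in range(i_peak + 1, t.size):
        if si[i] <= half:
            # linear interpolation between bracketing grid points
            f = (si[i - 1] - half) / (si[i - 1] - si[i])
            t_half = float(t[i - 1] + f * grid_step_ms)
            break
    mask = t <= 70.0 + 1e-12
    auc = float(np.trapezoid(si[mask], t[mask]))
    return FFIGroundTruth(modality, peak, t_peak, t_half,
                          t_half - t_peak if np.isfinite(t_half) else np.nan,
                          auc, defined=True)
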