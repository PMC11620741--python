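"""Windowed quantification of single trials and trial averages.

The unit of response is the mean (and peak) depolarization above baseline in
a 12-ms half-open window anchored at a stimulus event: sound onset for
auditory trials, the last tectal pulse for tectal-only and multisensory
trials.  Responses to tectal trains are further decomposed into a tonic
component (depolarization reached immediately before the last pulse) and a
phasic component (peak in the post-last-pulse window minus that level), so
tonic + phasic equals the peak above baseline by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import TraceError
from .io import Trace, TrialRecording
from .protocols import StimulusProtocol

DEFAULT_WINDOW_MS = 12.0


@dataclass(frozen=True)
class WindowQuant:
    window_start_ms: float
    window_len_ms: float
    baseline_mV: float
    mean_depol_mV: float
    peak_depol_mV: float


@dataclass(frozen=True)
class PhasicTonic:
    tonic_mV: float
    phasic_mV: float
    t_last_pulse_ms: float


def compute_baseline(trace: Trace, pre_window_ms: float = 50.0) -> float:
    """Mean membrane potential over [-pre_window_ms, 0) ms."""
    if trace.t0_ms > -pre_window_ms + 1e-9:
        raise TraceError(
            f"trace needs >= {pre_window_ms} ms of pre-stimulus data "
            f"(starts at {trace.t0_ms} ms)")
    seg = trace.slice(-pre_window_ms, 0.0)
    return float(seg.mean())


def window_response(
    trace: Trace,
    start_ms: float,
    len_ms: float = DEFAULT_WINDOW_MS,
    baseline: float | None = None,
) -> WindowQuant:
    """Mean and peak of (V - baseline) over [start, start + len) ms."""
    if len_ms <= 0:
        raise TraceError(f"window length must be positive, got {len_ms}")
    if baseline is None:
        baseline = compute_baseline(trace)
    if start_ms < trace.t0_ms - 1e-9 or start_ms + len_ms > trace.t_end_ms + trace.dt_ms + 1e-9:
        raise TraceError(
            f"window [{start_ms}, {start_ms + len_ms}) outside trace span")
    seg = trace.slice(start_ms, start_ms + len_ms)
    if seg.size == 0:
        raise TraceError("window contains no samples")
    depol = seg - baseline
    return WindowQuant(start_ms, len_ms, baseline,
                       float(depol.mean()), float(depol.max()))


def phasic_tonic(
    trace: Trace,
    protocol: StimulusProtocol,
    baseline: float | None = None,
    window_len_ms: float = DEFAULT_WINDOW_MS,
) -> PhasicTonic:
    """Tonic/phasic decomposition of a tectal-train response.

    tonic = V(one sample before the last tectal pulse) - baseline;
    phasic = window peak after the last pulse minus that pre-pulse level.
    """
    pulses = protocol.events_of("tectal")
    if not pulses:
        raise TraceError("protocol has no tectal event")
    if baseline is None:
        baseline = compute_baseline(trace)
    t_last = pulses[-1].time_ms
    i_last = trace.index_at(t_last)
    if i_last == 0:
        raise TraceError("no sample before the last pulse")
    v_before = float(trace.samples_mV[i_last - 1])
    wq = window_response(trace, t_last, window_len_ms, baseline)
    tonic = v_before - baseline
    phasic = (wq.peak_depol_mV + baseline) - v_before
    return PhasicTonic(tonic_mV=tonic, phasic_mV=phasic, t_last_pulse_ms=t_last)


def lingering_depolarization(
    trace: Trace, t_ms: float = 50.0, baseline: float | None = None,
    neighborhood_ms: float = 1.0,
) -> float:
    """Residual depolarization at ``t_ms``, averaged over a 1-ms neighborhood."""
    if baseline is None:
        baseline = compute_baseline(trace)
    half = neighborhood_ms / 2.0
    if t_ms - half < trace.t0_ms - 1e-9 or t_ms + half > trace.t_end_ms + 1e-9:
        raise TraceError(f"time {t_ms} ms outside trace span")
    seg = trace.slice(t_ms - half, t_ms + half)
    return float(seg.mean() - baseline)


def detect_ap(
    trace: Trace, baseline: float | None = None, threshold_mV: float = 25.0
) -> tuple[bool, float | None]:
    """True iff any sample strictly exceeds baseline + threshold; returns the
    first crossing time."""
    if baseline is None:
        baseline = compute_baseline(trace)
    above = trace.samples_mV > baseline + threshold_mV
    if not np.any(above):
        return False, None
    i = int(np.argmax(above))
    return True, float(trace.times_ms()[i])


def blank_artifacts(
    trace: Trace, protocol: StimulusProtocol, width_ms: float = 1.0
) -> Trace:
    """Linearly interpolate over [pulse, pulse + width) around each stimulus.

    Optional stimulus-artifact handling before peak detection; disabled by
    default for synthetic data.
    """
    v = trace.samples_mV.copy()
    t = trace.times_ms()
    for ev in protocol.events:
        mask = (t >= ev.time_ms - 1e-9) & (t < ev.time_ms + width_ms - 1e-9)
        idx = np.flatnonzero(mask)
        if idx.size == 0 or idx[0] == 0 or idx[-1] + 1 >= v.size:
            continue
        lo, hi = idx[0] - 1, idx[-1] + 1
        v[idx] = np.interp(t[idx], [t[lo], t[hi]], [v[lo], v[hi]])
    return Trace(v, trace.fs_hz, trace.t0_ms)


def average_trials(trials: list[TrialRecording]) -> tuple[Trace, int]:
    """Pointwise mean trace over same-condition trials, AP trials excluded.

    All trials must share condition label, sampling rate and time grid.
    Returns the mean trace and the number of trials averaged.
    """
    if not trials:
        raise TraceError("no trials to average")
    labels = {t.protocol.label for t in trials}
    if len(labels) > 1:
        raise TraceError(f"mixed conditions in average: {sorted(labels)}")
    fss = {t.trace.fs_hz for t in trials}
    if len(fss) > 1:
        raise TraceError("mixed sampling rates in average")
    kept = [t for t in trials if not t.fired]
    if not kept:
        raise TraceError("all trials contain APs; nothing to average")
    n = len(kept)
    if not 2 <= n <= 20:
        warnings.warn(f"averaging {n} trials (outside the usual 2-20 range)",
                      stacklevel=2)
    n_samp = min(t.trace.n for t in kept)
    t0s = {round(t.trace.t0_ms, 9) for t in kept}
    if len(t0s) > 1:
        raise TraceError("trials are not aligned on the same time grid")
    stack = np.stack([t.trace.samples_mV[:n_samp] for t in kept])
    return Trace(stack.mean(axis=0), kept[0].trace.fs_hz, kept[0].trace.t0_ms), n
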