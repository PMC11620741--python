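"""Feed-forward inhibition quantification.

Shunting inhibition is probed with antidromic test action potentials:
``%SI = 100 - APtest/APcontrol x 100``.  Probes at a set of delays after a
conditioning stimulus give a %SI time course, summarized by its peak, time
of peak, half-decay time and 0-70 ms area under the curve.

Half-decay is reported twice: ``t_half_ms`` is the absolute probe delay of
the first post-peak crossing of half the peak (the delay-axis convention),
``t_half_elapsed_ms`` is the same crossing measured from the peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import StatError, TraceError


def percent_si(ap_test_mV: float, ap_control_mV: float) -> float:
    """Shunting-inhibition percentage; negative values (facilitation) are
    not clipped."""
    if ap_control_mV <= 0:
        raise StatError(f"ap_control must be positive, got {ap_control_mV}")
    return 100.0 - 100.0 * ap_test_mV / ap_control_mV


@dataclass
class FFIMeasurement:
    """One probe: delay after conditioning stimulus plus AP amplitudes.

    ``si_percent`` is always derived from the amplitudes, so the identity
    si = 100 - 100*ap_test/ap_control holds by construction.
    """

    delay_ms: float
    ap_control_mV: float
    ap_test_mV: float
    si_percent: float = field(init=False)

    def __post_init__(self) -> None:
        self.si_percent = percent_si(self.ap_test_mV, self.ap_control_mV)


@dataclass
class FFITimeCourse:
    """Per-delay mean %SI with summary metrics."""

    modality: str
    delays_ms: np.ndarray
    mean_si_percent: np.ndarray
    sem_si_percent: np.ndarray
    n_per_delay: np.ndarray
    peak_si_percent: float = np.nan
    t_peak_ms: float = np.nan
    t_half_ms: float = np.nan
    t_half_elapsed_ms: float = np.nan
    auc_percent_ms: float = np.nan
    t_half_defined: bool = False

    @property
    def peak_defined(self) -> bool:
        return np.isfinite(self.peak_si_percent) and self.peak_si_percent > 0


def assemble_time_course(
    measurements: Iterable[FFIMeasurement], modality: str
) -> FFITimeCourse:
    """Group probes by delay, average, and compute summary metrics.

    Requires at least 3 distinct delays.  The peak is the earliest delay
    achieving the maximum mean %SI; the half-decay time is linearly
    interpolated between sampled delays.
    """
    ms = list(measurements)
    delays = sorted({m.delay_ms for m in ms})
    if len(delays) < 3:
        raise StatError(f"need >= 3 distinct probe delays, got {len(delays)}")
    means, sems, ns = [], [], []
    for d in delays:
        vals = np.array([m.si_percent for m in ms if m.delay_ms == d])
        means.append(vals.mean())
        sems.append(vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0)
        ns.append(vals.size)

    tc = FFITimeCourse(
        modality=modality,
        delays_ms=np.asarray(delays, dtype=float),
        mean_si_percent=np.asarray(means),
        sem_si_percent=np.asarray(sems),
        n_per_delay=np.asarray(ns),
    )
    _compute_metrics(tc)
    return tc


def _compute_metrics(tc: FFITimeCourse) -> None:
    si = tc.mean_si_percent
    peak = float(si.max())
    i_peak = int(np.argmax(si))  # earliest delay achieving the maximum
    tc.peak_si_percent = peak
    tc.t_peak_ms = float(tc.delays_ms[i_peak])
    if peak > 0:
        th = half_decay_time(tc)
        tc.t_half_ms = th
        tc.t_half_elapsed_ms = th - tc.t_peak_ms if np.isfinite(th) else np.nan
        tc.t_half_defined = np.isfinite(th)
    try:
        tc.auc_percent_ms = auc_0_70(tc)
    except StatError:
        tc.auc_percent_ms = np.nan


def half_decay_time(tc: FFITimeCourse) -> float:
    """First post-peak crossing of half the peak %SI, linearly interpolated.

    Returns NaN (undefined-flagged) if the curve never falls below half peak
    within the sampled range.
    """
    si = tc.mean_si_percent
    peak = float(si.max())
    if not (peak > 0):
        raise StatError("half-decay undefined: peak %SI is not positive")
    i_peak = int(np.argmax(si))
    half = peak / 2.0
    for i in range(i_peak + 1, si.size):
        if si[i] <= half:
            d0, d1 = tc.delays_ms[i - 1], tc.delays_ms[i]
            s0, s1 = si[i - 1], si[i]
            if s0 == s1:
                return float(d1)
            return float(d0 + (s0 - half) / (s0 - s1) * (d1 - d0))
    return float("nan")


def auc_0_70(tc: FFITimeCourse) -> float:
    """Trapezoidal integral of the mean %SI curve over [0, 70] ms.

    Boundary rules: %SI at delay 0 is taken as 0 if unsampled (inhibition
    cannot precede the stimulus); the value at 70 ms is interpolated from
    bracketing samples when 70 ms itself was not probed.
    """
    d = tc.delays_ms
    si = tc.mean_si_percent
    if not np.any(d <= 70.0):
        raise StatError("no probe delays at or below 70 ms")
    dd, ss = list(d), list(si)
    if dd[0] > 0.0:
        dd.insert(0, 0.0)
        ss.insert(0, 0.0)
    dd_arr, ss_arr = np.asarray(dd), np.asarray(ss)
    if dd_arr.max() >= 70.0:
        s70 = float(np.interp(70.0, dd_arr, ss_arr))
        mask = dd_arr < 70.0
        x = np.append(dd_arr[mask], 70.0)
        y = np.append(ss_arr[mask], s70)
    else:
        x, y = dd_arr, ss_arr  # curve ends before 70 ms; integrate what exists
    return float(np.trapezoid(y, x))
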