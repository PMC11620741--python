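"""Stimulus protocols for Mauthner-cell experiments.

A protocol is an ordered list of timed stimulus events, each tagged with a
modality (``auditory``, ``tectal`` or ``antidromic``) and a dimensionless
drive amplitude (1.0 = reference intensity).  Protocols define both the
analysis windows used by the quantification stage and the synaptic drive of
the simulator.  Time zero is the first stimulus event of the trial.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ProtocolError

MODALITIES = ("auditory", "tectal", "antidromic")

#: tolerance for "pulse falls exactly on the train endpoint" comparisons, ms
_TIME_EPS = 1e-9


@dataclass(frozen=True)
class StimulusEvent:
    """A single stimulus pulse.

    Parameters
    ----------
    time_ms:
        Event onset relative to trial start (first event of the protocol).
    modality:
        One of ``auditory``, ``tectal``, ``antidromic``.
    amplitude:
        Relative drive strength; 1.0 is the reference intensity.
    """

    time_ms: float
    modality: str
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.time_ms < 0:
            raise ProtocolError(f"event time must be >= 0, got {self.time_ms}")
        if self.modality not in MODALITIES:
            raise ProtocolError(f"unknown modality {self.modality!r}")
        if self.amplitude < 0:
            raise ProtocolError(f"amplitude must be >= 0, got {self.amplitude}")


@dataclass(frozen=True)
class StimulusProtocol:
    """An ordered set of stimulus events plus condition metadata."""

    events: tuple[StimulusEvent, ...]
    label: str
    train_freq_hz: float | None = None
    train_duration_ms: float | None = None

    def __post_init__(self) -> None:
        events = tuple(self.events)
        object.__setattr__(self, "events", events)
        times = [e.time_ms for e in events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ProtocolError("events must be sorted by time_ms")

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def last_event_ms(self) -> float:
        if not self.events:
            return 0.0
        return self.events[-1].time_ms

    def events_of(self, modality: str) -> tuple[StimulusEvent, ...]:
        return tuple(e for e in self.events if e.modality == modality)

    # -- JSON round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "train_freq_hz": self.train_freq_hz,
            "train_duration_ms": self.train_duration_ms,
            "events": [
                {"time_ms": e.time_ms, "modality": e.modality, "amplitude": e.amplitude}
                for e in self.events
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(
            events=tuple(
                StimulusEvent(e["time_ms"], e["modality"], e["amplitude"])
                for e in d["events"]
            ),
            label=d["label"],
            train_freq_hz=d.get("train_freq_hz"),
            train_duration_ms=d.get("train_duration_ms"),
        )

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, ensure_ascii=False)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "StimulusProtocol":
        text = str(source)
        if "\n" not in text and "{" not in text and Path(text).exists():
            text = Path(text).read_text(encoding="utf-8")
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class CellMeta:
    """Per-cell recording metadata and the resting-potential inclusion rule."""

    fish_id: str
    cell_side: str = "left"
    resting_potential_mV: float = -80.0

    def __post_init__(self) -> None:
        if self.cell_side not in ("left", "right"):
            raise ProtocolError(f"cell_side must be left/right, got {self.cell_side!r}")

    @property
    def included(self) -> bool:
        """True iff the resting potential lies in the [-90, -70] mV window."""
        return -90.0 <= self.resting_potential_mV <= -70.0


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def build_tectal_train(
    freq_hz: float, duration_ms: float, amplitude: float = 1.0
) -> StimulusProtocol:
    """Pulse train delivered to the optic tectum.

    Pulses are placed at 0, 1000/f, 2000/f, ... up to and including
    ``duration_ms`` (closed endpoint), so event count =
    floor(duration*freq/1000) + 1.  A duration of 0 or 1 ms yields a single
    pulse at t=0.
    """
    if freq_hz <= 0:
        raise ProtocolError(f"train frequency must be positive, got {freq_hz}")
    if duration_ms < 0:
        raise ProtocolError(f"train duration must be >= 0, got {duration_ms}")
    period = 1000.0 / freq_hz
    n = int(math.floor(duration_ms / period + _TIME_EPS)) + 1
    events = tuple(
        StimulusEvent(i * period, "tectal", amplitude) for i in range(n)
    )
    label = f"T{freq_hz:g}Hz_{duration_ms:g}ms"
    return StimulusProtocol(events, label, train_freq_hz=freq_hz,
                            train_duration_ms=duration_ms)


def build_auditory_pip(t_onset_ms: float = 0.0, amplitude: float = 1.0) -> StimulusProtocol:
    """Single-cycle sound pip (one auditory event), label ``A``."""
    if t_onset_ms < 0:
        raise ProtocolError(f"pip onset must be >= 0, got {t_onset_ms}")
    return StimulusProtocol(
        (StimulusEvent(t_onset_ms, "auditory", amplitude),), "A"
    )


def combine_protocols(
    first: StimulusProtocol,
    second: StimulusProtocol,
    offset_ms: float,
    label: str | None = None,
) -> StimulusProtocol:
    """Merge two protocols, shifting the second by ``offset_ms``.

    Event order is preserved (stable sort on time; first's events win ties).
    The label defaults to the concatenation of the two input labels.
    """
    if offset_ms < 0:
        raise ProtocolError(f"offset must be >= 0, got {offset_ms}")
    shifted = [replace(e, time_ms=e.time_ms + offset_ms) for e in second.events]
    merged = sorted(
        list(first.events) + shifted, key=lambda e: e.time_ms
    )
    return StimulusProtocol(
        tuple(merged),
        label if label is not None else first.label + second.label,
        train_freq_hz=first.train_freq_hz or second.train_freq_hz,
        train_duration_ms=first.train_duration_ms or second.train_duration_ms,
    )


def build_multisensory(train: StimulusProtocol, pip_amplitude: float = 1.0) -> StimulusProtocol:
    """Audiotectal combination: pip onset at the last pulse of the train.

    The quantification windows of the tectal-only and multisensory conditions
    then coincide (both anchored to the last tectal pulse).
    """
    if not train.events_of("tectal"):
        raise ProtocolError("multisensory condition requires a tectal train")
    pip = build_auditory_pip(0.0, pip_amplitude)
    return combine_protocols(train, pip, train.last_event_ms, label="M")


def build_sequence(
    s1: str, s2: str, offset_ms: float = 50.0,
    amplitude_1: float = 1.0, amplitude_2: float = 1.0,
) -> StimulusProtocol:
    """Paired-stimulus protocol (AA, AT, TA, TT) with S2 delayed by offset.

    ``s1``/``s2`` are ``"A"`` (auditory pip) or ``"T"`` (single tectal pulse).
    """
    def _single(code: str, amp: float) -> StimulusProtocol:
        if code == "A":
            return build_auditory_pip(0.0, amp)
        if code == "T":
            return build_tectal_train(60.0, 1.0, amp)  # one pulse at t=0
        raise ProtocolError(f"sequence element must be A or T, got {code!r}")

    p1 = _single(s1, amplitude_1)
    p2 = _single(s2, amplitude_2)
    return combine_protocols(p1, p2, offset_ms, label=s1 + s2)
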