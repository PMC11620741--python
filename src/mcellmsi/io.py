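"""Trace containers and the neutral trial-bundle format.

A bundle is a directory holding one ``trials.csv`` metadata table, one
two-column CSV per trace (``time_ms, voltage_mV``) and a ``manifest.json``
with SHA-256 content hashes.  Plain CSV keeps fixtures diffable; large-bundle
performance is out of scope.

Conventions: time in milliseconds with t = 0 at the first stimulus event
(traces may start at negative ``t0_ms`` — the pre-stimulus baseline), voltage
as absolute membrane potential in mV (baseline subtraction happens in
:mod:`mcellmsi.quantify`).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import BundleError, CorruptBundleError, TraceError
from .protocols import CellMeta, StimulusProtocol


@dataclass
class Trace:
    """Uniformly sampled membrane-potential series.

    ``t0_ms`` is the time of sample 0 relative to the first stimulus event;
    a negative value means the trace starts before the stimulus.
    """

    samples_mV: np.ndarray
    fs_hz: float
    t0_ms: float = 0.0

    def __post_init__(self) -> None:
        self.samples_mV = np.asarray(self.samples_mV, dtype=float)
        if self.fs_hz <= 0:
            raise TraceError(f"fs_hz must be positive, got {self.fs_hz}")
        if self.samples_mV.ndim != 1 or self.samples_mV.size == 0:
            raise TraceError("trace must be a non-empty 1-D series")
        if not np.all(np.isfinite(self.samples_mV)):
            raise TraceError("trace contains non-finite samples")

    @property
    def n(self) -> int:
        return self.samples_mV.size

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.fs_hz

    @property
    def t_end_ms(self) -> float:
        """Time of the last sample."""
        return self.t0_ms + (self.n - 1) * self.dt_ms

    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.n) * self.dt_ms

    def index_at(self, t_ms: float) -> int:
        """Index of the sample nearest to ``t_ms`` (must lie in the span)."""
        i = int(round((t_ms - self.t0_ms) * self.fs_hz / 1000.0))
        if i < 0 or i >= self.n:
            raise TraceError(f"time {t_ms} ms outside trace span "
                             f"[{self.t0_ms}, {self.t_end_ms}] ms")
        return i

    def value_at(self, t_ms: float) -> float:
        return float(self.samples_mV[self.index_at(t_ms)])

    def slice(self, start_ms: float, stop_ms: float) -> np.ndarray:
        """Samples with start_ms <= t < stop_ms (half-open window)."""
        t = self.times_ms()
        mask = (t >= start_ms - 1e-9) & (t < stop_ms - 1e-9)
        return self.samples_mV[mask]


@dataclass
class TrialRecording:
    """One trial: trace + protocol + cell context."""

    trace: Trace
    protocol: StimulusProtocol
    cell: CellMeta
    fired: bool = False
    trial_index: int = 0
    excluded: bool = False  # set on load when the cell fails inclusion

    def __post_init__(self) -> None:
        if self.protocol.events:
            last = self.protocol.last_event_ms
            if last > self.trace.t_end_ms + 1e-9 or self.protocol.events[0].time_ms < self.trace.t0_ms - 1e-9:
                raise TraceError("protocol events fall outside the trace span")


# ---------------------------------------------------------------------------
# Bundle I/O
# ---------------------------------------------------------------------------

_META_COLUMNS = [
    "trial_index", "fish_id", "cell_side", "condition_label",
    "resting_potential_mV", "fired", "fs_hz", "t0_ms", "trace_file",
    "protocol_json",
]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_bundle(trials: Sequence[TrialRecording], path: str | Path) -> dict:
    """Write trials to a bundle directory; returns the manifest dict."""
    trials = list(trials)
    if not trials:
        raise BundleError("cannot write an empty bundle")
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)

    rows = []
    files: dict[str, str] = {}
    for i, tr in enumerate(trials):
        fname = f"trace_{i:04d}.csv"
        t = tr.trace.times_ms()
        df = pd.DataFrame({"time_ms": t, "voltage_mV": tr.trace.samples_mV})
        df.to_csv(root / fname, index=False, float_format="%.9g")
        files[fname] = _sha256(root / fname)
        rows.append({
            "trial_index": tr.trial_index,
            "fish_id": tr.cell.fish_id,
            "cell_side": tr.cell.cell_side,
            "condition_label": tr.protocol.label,
            "resting_potential_mV": tr.cell.resting_potential_mV,
            "fired": tr.fired,
            "fs_hz": tr.trace.fs_hz,
            "t0_ms": tr.trace.t0_ms,
            "trace_file": fname,
            "protocol_json": json.dumps(tr.protocol.to_dict(), ensure_ascii=False),
        })

    meta = pd.DataFrame(rows, columns=_META_COLUMNS)
    meta.to_csv(root / "trials.csv", index=False, encoding="utf-8")
    files["trials.csv"] = _sha256(root / "trials.csv")

    manifest = {"format": "mcellmsi-bundle-v1", "n_trials": len(trials), "files": files}
    (root / "manifest.json").write_text(
        json.dumps(manifest, indent=2, ensure_ascii=False), encoding="utf-8"
    )
    return manifest


def read_bundle(path: str | Path) -> list[TrialRecording]:
    """Lossless inverse of :func:`write_bundle`.

    Hashes are verified against the manifest; trials whose cell fails the
    resting-potential inclusion window [-90, -70] mV are loaded but flagged
    ``excluded``.
    """
    root = Path(path)
    mpath = root / "manifest.json"
    if not mpath.exists():
        raise BundleError(f"no manifest.json in {root}")
    manifest = json.loads(mpath.read_text(encoding="utf-8"))
    for fname, digest in manifest["files"].items():
        fpath = root / fname
        if not fpath.exists():
            raise BundleError(f"bundle file missing: {fname}")
        if _sha256(fpath) != digest:
            raise CorruptBundleError(f"hash mismatch for {fname}")

    meta = pd.read_csv(root / "trials.csv", encoding="utf-8")
    trials: list[TrialRecording] = []
    for _, row in meta.iterrows():
        df = pd.read_csv(root / row["trace_file"])
        trace = Trace(df["voltage_mV"].to_numpy(), float(row["fs_hz"]),
                      float(row["t0_ms"]))
        protocol = StimulusProtocol.from_dict(json.loads(row["protocol_json"]))
        cell = CellMeta(str(row["fish_id"]), str(row["cell_side"]),
                        float(row["resting_potential_mV"]))
        trials.append(TrialRecording(
            trace=trace, protocol=protocol, cell=cell,
            fired=bool(row["fired"]), trial_index=int(row["trial_index"]),
            excluded=not cell.included,
        ))
    return trials


# ---------------------------------------------------------------------------
# ABF import
# ---------------------------------------------------------------------------

@dataclass
class AbfImportResult:
    """Imported sweeps plus an explicit record of anything skipped."""

    trials: list[TrialRecording]
    skipped: list[tuple[int, str]] = field(default_factory=list)  # (sweep, reason)


def import_abf(
    path: str | Path,
    channel_map: Mapping[str | int, str],
    protocol_map: Mapping[int, StimulusProtocol],
    cell: CellMeta | None = None,
) -> AbfImportResult:
    """Import an Axon Binary Format (ABF v1) file as trial recordings.

    ``channel_map`` names the voltage channel (by ADC channel name or index):
    ``{"Vm": "voltage"}``.  ``protocol_map`` maps sweep index to the stimulus
    protocol of that sweep; sweeps without an entry are skipped and reported.
    Voltages are converted to mV using the per-channel unit string; sampling
    rate is taken from the file header.
    """
    from .abf import read_abf_v1  # local import keeps the binary parser isolated

    rec = read_abf_v1(path)
    voltage_keys = [k for k, v in channel_map.items() if v == "voltage"]
    if len(voltage_keys) != 1:
        raise _abf_err(path, "channel_map must name exactly one 'voltage' channel")
    key = voltage_keys[0]
    ch_idx = None
    for i, name in enumerate(rec.channel_names):
        if key == i or (isinstance(key, str) and key.strip() == name.strip()):
            ch_idx = i
    if ch_idx is None:
        raise _abf_err(
            path, f"channel {key!r} not found; available: {rec.channel_names}"
        )
    scale = _unit_to_mV(rec.channel_units[ch_idx])
    if scale is None:
        raise _abf_err(
            path,
            f"channel {rec.channel_names[ch_idx]!r} has unit "
            f"{rec.channel_units[ch_idx]!r}, cannot convert to mV",
        )

    trials: list[TrialRecording] = []
    skipped: list[tuple[int, str]] = []
    for sweep in range(rec.n_sweeps):
        if sweep not in protocol_map:
            skipped.append((sweep, "no protocol mapping"))
            continue
        samples = rec.data[sweep, :, ch_idx] * scale
        protocol = protocol_map[sweep]
        trace = Trace(samples, rec.fs_hz, t0_ms=0.0)
        meta = cell or CellMeta(fish_id=Path(path).stem,
                                resting_potential_mV=float(np.mean(samples[:min(100, samples.size)])))
        trials.append(TrialRecording(trace=trace, protocol=protocol, cell=meta,
                                     trial_index=sweep,
                                     excluded=not meta.included))
    return AbfImportResult(trials=trials, skipped=skipped)


def _abf_err(path, msg):
    from .errors import AbfImportError
    return AbfImportError(f"{path}: {msg}")


def _unit_to_mV(unit: str) -> float | None:
    """Factor converting a channel's physical unit to mV, or None if unknown.

    Accepts plain units (mV, V, uV) and scaled forms like ``0.1 mV``.
    """
    u = unit.strip()
    factor = 1.0
    parts = u.split()
    if len(parts) == 2:
        try:
            factor = float(parts[0])
        except ValueError:
            return None
        u = parts[1]
    base = {"mV": 1.0, "V": 1000.0, "uV": 1e-3, "µV": 1e-3}.get(u)
    if base is None:
        return None
    return factor * base
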