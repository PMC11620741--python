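"""Minimal reader for Axon Binary Format version 1 (ABF1) files.

Covers the subset needed to import episodic current-clamp recordings:
fixed-offset v1 header, int16 or float32 sample data, per-channel name/unit
strings and instrument scaling.  ABF2 files (signature ``ABF2``) are not
supported.  Field offsets follow the published ABF1 header layout.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import AbfImportError

BLOCK = 512
N_ADC = 16

# (name, byte offset, struct format)
_HEADER_FIELDS = [
    ("fFileSignature", 0, "4s"),
    ("fFileVersionNumber", 4, "f"),
    ("nOperationMode", 8, "h"),
    ("lActualAcqLength", 10, "i"),
    ("nNumPointsIgnored", 14, "h"),
    ("lActualEpisodes", 16, "i"),
    ("lDataSectionPtr", 40, "i"),
    ("nDataFormat", 100, "h"),
    ("nADCNumChannels", 120, "h"),
    ("fADCSampleInterval", 122, "f"),
    ("lNumSamplesPerEpisode", 138, "i"),
    ("fADCRange", 244, "f"),
    ("lADCResolution", 252, "i"),
]


@dataclass
class AbfRecording:
    """Decoded ABF1 contents: data[sweep, sample, channel] in physical units."""

    data: np.ndarray
    fs_hz: float
    channel_names: list[str]
    channel_units: list[str]

    @property
    def n_sweeps(self) -> int:
        return self.data.shape[0]


def read_abf_v1(path: str | Path) -> AbfRecording:
    raw = Path(path).read_bytes()
    if len(raw) < 4 * BLOCK:
        raise AbfImportError(f"{path}: file too short to hold an ABF1 header")
    sig = raw[0:4]
    if sig == b"ABF2":
        raise AbfImportError(f"{path}: ABF2 files are not supported")
    if sig != b"ABF ":
        raise AbfImportError(f"{path}: not an ABF file (signature {sig!r})")

    h = {name: struct.unpack_from("<" + fmt, raw, off)[0]
         for name, off, fmt in _HEADER_FIELDS}

    nch = h["nADCNumChannels"]
    if nch < 1 or nch > N_ADC:
        raise AbfImportError(f"{path}: invalid channel count {nch}")

    sampling_seq = struct.unpack_from(f"<{N_ADC}h", raw, 410)[:nch]
    names = [struct.unpack_from("10s", raw, 442 + 10 * i)[0].decode("ascii", "replace").strip("\x00 ")
             for i in sampling_seq]
    units = [struct.unpack_from("8s", raw, 602 + 8 * i)[0].decode("ascii", "replace").strip("\x00 ")
             for i in sampling_seq]
    prog_gain = struct.unpack_from(f"<{N_ADC}f", raw, 730)
    inst_scale = struct.unpack_from(f"<{N_ADC}f", raw, 922)
    inst_offset = struct.unpack_from(f"<{N_ADC}f", raw, 986)
    sig_gain = struct.unpack_from(f"<{N_ADC}f", raw, 1050)
    sig_offset = struct.unpack_from(f"<{N_ADC}f", raw, 1114)

    n_total = h["lActualAcqLength"]
    data_off = h["lDataSectionPtr"] * BLOCK
    if h["nDataFormat"] == 0:
        samples = np.frombuffer(raw, dtype="<i2", count=n_total, offset=data_off)
        samples = samples.astype(np.float64)
        int_data = True
    elif h["nDataFormat"] == 1:
        samples = np.frombuffer(raw, dtype="<f4", count=n_total, offset=data_off)
        samples = samples.astype(np.float64)
        int_data = False
    else:
        raise AbfImportError(f"{path}: unknown data format {h['nDataFormat']}")

    n_ep = max(h["lActualEpisodes"], 1)
    per_ep = h["lNumSamplesPerEpisode"] or (n_total // n_ep)
    if n_ep * per_ep != n_total:
        raise AbfImportError(
            f"{path}: episode layout inconsistent "
            f"({n_ep} x {per_ep} != {n_total} samples)")
    data = samples.reshape(n_ep, per_ep // nch, nch)

    if int_data:
        for c, adc in enumerate(sampling_seq):
            gain = h["fADCRange"] / (
                h["lADCResolution"] * inst_scale[adc] * sig_gain[adc] * prog_gain[adc]
            )
            data[:, :, c] = data[:, :, c] * gain + inst_offset[adc] - sig_offset[adc]

    fs_hz = 1e6 / (h["fADCSampleInterval"] * nch)
    return AbfRecording(data=data, fs_hz=fs_hz, channel_names=names,
                        channel_units=units)
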