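"""Synthetic ABF v1 file writer for import tests.

Builds a minimal episodic ABF1 file in memory (binary generated at test
runtime, never stored in the repository): 6144-byte header followed by
int16 sample data.  Only the header fields the reader consumes are filled.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

BLOCK = 512
HEADER_BLOCKS = 12  # data starts at block 12 -> byte 6144


def write_abf_v1(
    path: Path,
    sweeps: np.ndarray,  # (n_sweeps, n_samples) physical values
    unit: str = "mV",
    channel_name: str = "Vm",
    sample_interval_us: float = 40.0,
    adc_range: float = 10.0,
    adc_resolution: int = 32768,
    instrument_scale: float = 0.01,  # maps +-1000 physical units into the ADC range
) -> Path:
    sweeps = np.atleast_2d(np.asarray(sweeps, dtype=float))
    n_ep, per_ep = sweeps.shape
    header = bytearray(HEADER_BLOCKS * BLOCK)

    def put(fmt, off, *vals):
        struct.pack_into("<" + fmt, header, off, *vals)

    put("4s", 0, b"ABF ")
    put("f", 4, 1.83)
    put("h", 8, 5)                    # episodic stimulation mode
    put("i", 10, n_ep * per_ep)       # lActualAcqLength
    put("i", 16, n_ep)                # lActualEpisodes
    put("i", 40, HEADER_BLOCKS)       # lDataSectionPtr (in 512-byte blocks)
    put("h", 100, 0)                  # int16 data
    put("h", 120, 1)                  # one ADC channel
    put("f", 122, sample_interval_us)
    put("i", 138, per_ep)
    put("f", 244, adc_range)
    put("i", 252, adc_resolution)
    put("16h", 410, *([0] * 16))      # sampling sequence: channel 0
    put("10s", 442, channel_name.encode("ascii"))
    put("8s", 602, unit.encode("ascii"))
    put("16f", 730, *([1.0] * 16))    # programmable gain
    put("16f", 922, *([instrument_scale] * 16))
    put("16f", 986, *([0.0] * 16))    # instrument offset
    put("16f", 1050, *([1.0] * 16))   # signal gain
    put("16f", 1114, *([0.0] * 16))   # signal offset

    gain = adc_range / (adc_resolution * instrument_scale)
    raw = np.round(sweeps / gain).astype("<i2")
    Path(path).write_bytes(bytes(header) + raw.tobytes())
    return Path(path)
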