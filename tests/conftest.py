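"""Shared fixtures: small synthetic sessions and a minimal EDF writer.

All fixtures are generated programmatically at test time; nothing binary
is stored in the repository.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pytest

from sfebci import signal_core as sc
from sfebci import synth


@pytest.fixture(scope="session")
def synth_cfg() -> synth.SynthConfig:
    return synth.SynthConfig(seed=11)


@pytest.fixture(scope="session")
def small_session(synth_cfg) -> sc.EEGRecording:
    """One slight-intensity trial per class: enough for unit-level checks."""
    return synth.generate_session(list(sc.SFE_CLASSES), 1, synth_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def write_minimal_edf(path: Path, data: np.ndarray, rate: float,
                      channels: list[str]) -> None:
    """Write a bare-bones EDF file (synthetic test input for the reader).

    One data record holding the whole signal, 16-bit samples, physical
    range chosen per channel to cover the data.
    """
    n_ch, n_samp = data.shape
    duration = n_samp / rate
    header = bytearray()

    def fixed(text: str, width: int) -> bytes:
        return text.ljust(width)[:width].encode("ascii")

    header += fixed("0", 8)                       # version
    header += fixed("synthetic patient", 80)
    header += fixed("synthetic recording", 80)
    header += fixed("01.01.20", 8)
    header += fixed("00.00.00", 8)
    header += fixed(str(256 + 256 * n_ch), 8)     # header length
    header += fixed("", 44)
    header += fixed("1", 8)                       # n data records
    header += fixed(f"{duration:g}", 8)
    header += fixed(str(n_ch), 4)

    phys_min = np.floor(data.min(axis=1)) - 1
    phys_max = np.ceil(data.max(axis=1)) + 1
    dig_min, dig_max = -32768, 32767

    for name in channels:
        header += fixed(name, 16)
    for _ in channels:
        header += fixed("synthetic EEG", 80)
    for _ in channels:
        header += fixed("uV", 8)
    for v in phys_min:
        header += fixed(f"{v:g}", 8)
    for v in phys_max:
        header += fixed(f"{v:g}", 8)
    for _ in channels:
        header += fixed(str(dig_min), 8)
    for _ in channels:
        header += fixed(str(dig_max), 8)
    for _ in channels:
        header += fixed("", 80)                   # prefiltering
    for _ in channels:
        header += fixed(str(n_samp), 8)           # samples per record
    for _ in channels:
        header += fixed("", 32)

    body = bytearray()
    for i in range(n_ch):
        scale = (dig_max - dig_min) / (phys_max[i] - phys_min[i])
        dig = np.round((data[i] - phys_min[i]) * scale + dig_min).astype("<i2")
        body += struct.pack(f"<{n_samp}h", *dig)
    path.write_bytes(bytes(header) + bytes(body))
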