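"""Minimal EDF writer.

Writes plain EDF (16-bit, one-second data records) sufficient for the
synthetic cohort generator: fixed-rate channels in microvolts, no
embedded annotations (hypnograms travel as sidecar text files).  Reading
is done elsewhere via mne; this module only produces files.

Constraints: integer sample rates; total duration a whole number of
seconds (always true for whole 30-s epochs).  Physical range is chosen
per channel to cover the signal, so quantization error is bounded by
``range / 2^16`` per sample.
"""

from __future__ import annotations

from datetime import datetime
from pathlib import Path
from typing import Sequence

import numpy as np

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        # shorten numerics rather than corrupting the fixed layout
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(
    path: str | Path,
    channels: Sequence[tuple[str, np.ndarray, int]],
    start: datetime | None = None,
    patient_id: str = "X",
    recording_id: str = "X",
) -> None:
    """Write ``channels`` = [(label, samples_uV, sample_rate_hz), ...] to EDF.

    All channels must span the same whole number of seconds.
    """
    if not channels:
        raise ValueError("cannot write an EDF with zero channels")
    durations = set()
    for label, sig, fs in channels:
        if int(fs) != fs or fs <= 0:
            raise ValueError(f"channel {label!r}: sample rate must be a positive integer")
        if len(sig) % int(fs):
            raise ValueError(f"channel {label!r}: length not a whole number of seconds")
        durations.add(len(sig) // int(fs))
    if len(durations) != 1:
        raise ValueError(f"channels span different durations: {sorted(durations)}")
    n_records = durations.pop()
    start = start or datetime(2000, 1, 1)
    ns = len(channels)

    digitized = []
    phys_ranges = []
    for label, sig, fs in channels:
        sig = np.asarray(sig, dtype=np.float64)
        pm = float(np.max(np.abs(sig))) * 1.01 if sig.size else 1.0
        pm = max(pm, 1.0)
        scale = (_DIG_MAX - _DIG_MIN) / (2 * pm)
        dig = np.round((sig + pm) * scale + _DIG_MIN)
        digitized.append(np.clip(dig, _DIG_MIN, _DIG_MAX).astype("<i2"))
        phys_ranges.append(pm)

    def fmt_phys(v: float) -> str:
        s = f"{v:.8g}"
        return s[:8]

    hdr = bytearray()
    hdr += _field("0", 8)
    hdr += _field(patient_id, 80)
    hdr += _field(recording_id, 80)
    hdr += _field(start.strftime("%d.%m.%y"), 8)
    hdr += _field(start.strftime("%H.%M.%S"), 8)
    hdr += _field(256 * (ns + 1), 8)
    hdr += _field("", 44)
    hdr += _field(n_records, 8)
    hdr += _field("1", 8)
    hdr += _field(ns, 4)
    for label, _, _ in channels:
        hdr += _field(label, 16)
    hdr += _field("", 80) * ns
    hdr += _field("uV", 8) * ns
    for pm in phys_ranges:
        hdr += _field(fmt_phys(-pm), 8)
    for pm in phys_ranges:
        hdr += _field(fmt_phys(pm), 8)
    hdr += _field(_DIG_MIN, 8) * ns
    hdr += _field(_DIG_MAX, 8) * ns
    hdr += _field("", 80) * ns
    for _, _, fs in channels:
        hdr += _field(int(fs), 8)
    hdr += _field("", 32) * ns
    assert len(hdr) == 256 * (ns + 1)

    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(bytes(hdr))
        rates = [int(fs) for _, _, fs in channels]
        for r in range(n_records):
            for dig, fs in zip(digitized, rates):
                fh.write(dig[r * fs : (r + 1) * fs].tobytes())
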