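"""Minimal European Data Format (EDF) writer.

EDF is the interchange format for polysomnography: a fixed-layout ASCII
header (256 bytes plus 256 per signal) followed by data records of
little-endian 16-bit integers, one contiguous block per signal per record.
This writer emits continuous multichannel recordings with 1-s data records
and symmetric physical scaling; reading is delegated to MNE, which parses
EDF natively, so the round trip is checked against an independent
implementation.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_edf"]

_DIGITAL_MIN = -32768
_DIGITAL_MAX = 32767


def _field(value: str, width: int) -> bytes:
    text = str(value)
    if len(text) > width:
        raise ValueError(f"EDF header field {text!r} exceeds {width} bytes")
    return text.ljust(width).encode("ascii")


def write_edf(
    path: str | Path,
    signals: np.ndarray,
    fs_hz: float,
    channel_names: list[str] | tuple[str, ...],
    *,
    physical_unit: str = "uV",
    patient_id: str = "X X X X",
    recording_id: str = "Startdate 01-JAN-2000 X X X",
    start_date: str = "01.01.00",
    start_time: str = "00.00.00",
) -> None:
    """Write (n_samples, n_channels) physical-unit signals as EDF.

    The sampling rate must be a positive integer (samples per 1-s record)
    and the signal length an integer number of seconds.  Values are scaled
    to the full 16-bit digital range per channel, so the round-trip error
    is bounded by half a quantization step.
    """
    signals = np.asarray(signals, dtype=np.float64)
    if signals.ndim != 2:
        raise ValueError("signals must be (n_samples, n_channels)")
    n_samples, n_ch = signals.shape
    if len(channel_names) != n_ch:
        raise ValueError("one channel name per signal column required")
    fs = int(round(fs_hz))
    if fs != fs_hz or fs <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    if n_samples % fs != 0:
        raise ValueError(
            f"signal length {n_samples} is not a whole number of 1-s records "
            f"at fs={fs}"
        )
    n_records = n_samples // fs

    phys_max = np.maximum(np.abs(signals).max(axis=0), 1e-6)
    # symmetric physical range, printed to fit the 8-char header field
    phys_max = np.array([float(f"{v:.6g}") for v in phys_max * 1.0])
    phys_min = -phys_max

    header = bytearray()
    header += _field("0", 8)
    header += _field(patient_id, 80)
    header += _field(recording_id, 80)
    header += _field(start_date, 8)
    header += _field(start_time, 8)
    header += _field(str(256 * (1 + n_ch)), 8)
    header += _field("", 44)
    header += _field(str(n_records), 8)
    header += _field("1", 8)  # record duration, seconds
    header += _field(str(n_ch), 4)

    def signal_block(values: list[str], width: int) -> bytes:
        return b"".join(_field(v, width) for v in values)

    header += signal_block(list(channel_names), 16)
    header += signal_block([""] * n_ch, 80)  # transducer
    header += signal_block([physical_unit] * n_ch, 8)
    header += signal_block([f"{v:.6g}"[:8] for v in phys_min], 8)
    header += signal_block([f"{v:.6g}"[:8] for v in phys_max], 8)
    header += signal_block([str(_DIGITAL_MIN)] * n_ch, 8)
    header += signal_block([str(_DIGITAL_MAX)] * n_ch, 8)
    header += signal_block([""] * n_ch, 80)  # prefiltering
    header += signal_block([str(fs)] * n_ch, 8)
    header += signal_block([""] * n_ch, 32)

    scale = (_DIGITAL_MAX - _DIGITAL_MIN) / (phys_max - phys_min)
    digital = np.rint(
        (signals - phys_min) * scale + _DIGITAL_MIN
    ).clip(_DIGITAL_MIN, _DIGITAL_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        # record-major, signal blocks contiguous within a record
        records = digital.reshape(n_records, fs, n_ch).transpose(0, 2, 1)
        fh.write(np.ascontiguousarray(records).tobytes())
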