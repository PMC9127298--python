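"""Minimal 16-bit EDF writer.

EDF is a fixed-layout ASCII header followed by little-endian int16 data
records, so a writer is a page of code.  Reading always goes through
``mne.io.read_raw_edf``, which also serves as an independent round-trip
check on files produced here.
"""

from __future__ import annotations

import datetime
from pathlib import Path

import numpy as np

DIG_MAX = 32767
DIG_MIN = -32768


def _ascii_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"field {s!r} exceeds {width} ASCII characters")
    return s.ljust(width).encode("ascii")


def quantization_step(physical_max: float) -> float:
    """Physical µV per digital unit for a symmetric ±physical_max range."""
    return (2.0 * physical_max) / (DIG_MAX - DIG_MIN)


def write_edf(
    path: str | Path,
    data_uv: np.ndarray,
    sampling_rate: float,
    channel_names: list[str] | tuple[str, ...],
    physical_max: float | None = None,
    patient_id: str = "X",
    recording_id: str = "synthetic",
) -> Path:
    """Write channels x samples data (µV) to an EDF file.

    The physical range is symmetric ±``physical_max`` (default: the max
    absolute sample value, rounded up to keep headroom), mapped onto the
    full 16-bit digital range.
    """
    path = Path(path)
    data = np.asarray(data_uv, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be channels x samples")
    n_ch, n_samp = data.shape
    if n_ch != len(channel_names):
        raise ValueError("channel count does not match label count")
    if not np.isfinite(data).all():
        raise ValueError("data contains non-finite samples")

    if physical_max is None:
        peak = float(np.max(np.abs(data))) if data.size else 1.0
        physical_max = max(np.ceil(peak * 1.01), 1.0)
    if np.max(np.abs(data)) > physical_max:
        raise ValueError("signal exceeds the chosen physical range")

    # 1-second records when the sample count allows, one big record otherwise
    rate_int = int(round(sampling_rate))
    if abs(sampling_rate - rate_int) < 1e-9 and n_samp % rate_int == 0:
        record_duration = 1.0
        samples_per_record = rate_int
    else:
        record_duration = n_samp / sampling_rate
        samples_per_record = n_samp
    n_records = n_samp // samples_per_record

    scale = (DIG_MAX - DIG_MIN) / (2.0 * physical_max)
    digital = np.rint((data + physical_max) * scale + DIG_MIN)
    digital = np.clip(digital, DIG_MIN, DIG_MAX).astype("<i2")

    now = datetime.datetime(2000, 1, 1)
    header = b"".join(
        [
            _ascii_field("0", 8),
            _ascii_field(patient_id, 80),
            _ascii_field(recording_id, 80),
            _ascii_field(now.strftime("%d.%m.%y"), 8),
            _ascii_field(now.strftime("%H.%M.%S"), 8),
            _ascii_field(256 * (1 + n_ch), 8),
            _ascii_field("", 44),
            _ascii_field(n_records, 8),
            _ascii_field(f"{record_duration:g}", 8),
            _ascii_field(n_ch, 4),
        ]
    )
    sig_fields = [
        (16, [str(c) for c in channel_names]),
        (80, ["EEG electrode"] * n_ch),
        (8, ["uV"] * n_ch),
        (8, [f"{-physical_max:g}"] * n_ch),
        (8, [f"{physical_max:g}"] * n_ch),
        (8, [str(DIG_MIN)] * n_ch),
        (8, [str(DIG_MAX)] * n_ch),
        (80, [""] * n_ch),
        (8, [str(samples_per_record)] * n_ch),
        (32, [""] * n_ch),
    ]
    header += b"".join(
        b"".join(_ascii_field(v, width) for v in values)
        for width, values in sig_fields
    )

    try:
        with open(path, "wb") as fh:
            fh.write(header)
            for rec in range(n_records):
                sl = slice(rec * samples_per_record, (rec + 1) * samples_per_record)
                fh.write(digital[:, sl].tobytes())
    except OSError as exc:
        raise OSError(f"cannot write EDF file {path}: {exc}") from exc
    return path
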