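"""Minimal EDF (European Data Format) reader/writer.

Supports the continuous-recording subset used by this package: uniform
sampling rate across signals, int16 samples with per-channel physical
scaling, one-second data records.  Headers follow the EDF specification
(ASCII fixed-width fields); files written with the ``EDF+C`` reserved tag
are read back transparently.  Annotation signals are not interpreted.

Written in-repo because no EDF library is part of the supported runtime.
Note the format quantizes samples to 16 bits; round-trips are exact only
to the per-channel quantization step.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import ValidationError
from .recording import EEG, Recording

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _num(value: float, width: int) -> bytes:
    s = f"{value:.10g}"
    if len(s) > width:
        s = f"{value:.{max(width - 8, 1)}g}"
    if len(s) > width:
        raise ValidationError(f"cannot encode {value!r} in {width} ASCII chars")
    return _field(s, width)


def write_edf(path: str | Path, rec: Recording) -> None:
    """Write a Recording as EDF (one-second data records, int16 samples)."""
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValidationError(f"EDF writer requires an integer sampling rate, got {fs}")
    fs = int(round(fs))
    n_ch, n_times = rec.samples.shape
    if n_times % fs == 0:
        samples_per_record, n_records = fs, n_times // fs
    else:
        samples_per_record, n_records = n_times, 1
    record_duration = samples_per_record / fs

    phys_min = rec.samples.min(axis=1)
    phys_max = rec.samples.max(axis=1)
    span = phys_max - phys_min
    flat = span <= 0
    phys_min = np.where(flat, phys_min - 1.0, phys_min)
    phys_max = np.where(flat, phys_max + 1.0, phys_max)
    # round the physical range outward to short decimals that survive the
    # 8-char ASCII header fields
    phys_min = np.floor(phys_min * 100) / 100
    phys_max = np.ceil(phys_max * 100) / 100

    gain = (_DIG_MAX - _DIG_MIN) / (phys_max - phys_min)
    digital = np.rint(
        (rec.samples - phys_min[:, None]) * gain[:, None] + _DIG_MIN
    ).astype(np.int16)

    header_bytes = 256 + 256 * n_ch
    with open(path, "wb") as fh:
        fh.write(_field("0", 8))
        fh.write(_field(rec.subject_id, 80))
        fh.write(_field("Startdate 01-JAN-2000", 80))
        fh.write(_field("01.01.00", 8))
        fh.write(_field("00.00.00", 8))
        fh.write(_field(str(header_bytes), 8))
        fh.write(_field("EDF+C", 44))
        fh.write(_field(str(n_records), 8))
        fh.write(_num(record_duration, 8))
        fh.write(_field(str(n_ch), 4))
        for label, typ in zip(rec.labels, rec.types):
            fh.write(_field(f"{typ} {label}", 16))
        for _ in range(n_ch):
            fh.write(_field("", 80))  # transducer
        for _ in range(n_ch):
            fh.write(_field("uV", 8))
        for v in phys_min:
            fh.write(_num(v, 8))
        for v in phys_max:
            fh.write(_num(v, 8))
        for _ in range(n_ch):
            fh.write(_field(str(_DIG_MIN), 8))
        for _ in range(n_ch):
            fh.write(_field(str(_DIG_MAX), 8))
        for _ in range(n_ch):
            fh.write(_field("", 80))  # prefiltering
        for _ in range(n_ch):
            fh.write(_field(str(samples_per_record), 8))
        for _ in range(n_ch):
            fh.write(_field("", 32))
        # data records: per record, per signal, int16 little-endian
        shaped = digital[:, : n_records * samples_per_record].reshape(
            n_ch, n_records, samples_per_record
        )
        interleaved = np.ascontiguousarray(shaped.transpose(1, 0, 2))
        fh.write(interleaved.astype("<i2").tobytes())


def read_edf(path: str | Path) -> Recording:
    """Read an EDF/EDF+C file into a Recording (annotations not parsed)."""
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValidationError(f"{path} is too short to be an EDF file")
        subject_id = head[8:88].decode("ascii", "replace").strip()
        n_records = int(head[236:244])
        record_duration = float(head[244:252])
        n_ch = int(head[252:256])
        sig = fh.read(256 * n_ch)
        raw_labels = [
            sig[i * 16 : (i + 1) * 16].decode("ascii").strip() for i in range(n_ch)
        ]
        off = 16 * n_ch
        phys_min = np.array([float(v) for v in _cols(sig, off + 80 * n_ch + 8 * n_ch, 8, n_ch)])
        phys_max = np.array(
            [float(v) for v in _cols(sig, off + 80 * n_ch + 16 * n_ch, 8, n_ch)]
        )
        dig_min = np.array(
            [float(v) for v in _cols(sig, off + 80 * n_ch + 24 * n_ch, 8, n_ch)]
        )
        dig_max = np.array(
            [float(v) for v in _cols(sig, off + 80 * n_ch + 32 * n_ch, 8, n_ch)]
        )
        spr = [
            int(v)
            for v in _cols(sig, off + 80 * n_ch + 40 * n_ch + 80 * n_ch, 8, n_ch)
        ]
        if len(set(spr)) != 1:
            raise ValidationError("mixed per-signal sampling rates are not supported")
        samples_per_record = spr[0]
        fs = samples_per_record / record_duration

        data = np.frombuffer(
            fh.read(2 * n_records * n_ch * samples_per_record), dtype="<i2"
        )
    data = data.reshape(n_records, n_ch, samples_per_record).transpose(1, 0, 2)
    data = data.reshape(n_ch, n_records * samples_per_record).astype(np.float64)
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    physical = (data - dig_min[:, None]) * gain[:, None] + phys_min[:, None]

    labels, types = [], []
    for raw in raw_labels:
        parts = raw.split(None, 1)
        if len(parts) == 2 and parts[0].upper() in ("EEG", "EOG"):
            types.append(parts[0].upper())
            labels.append(parts[1])
        else:
            types.append(EEG)
            labels.append(raw)
    return Recording(
        samples=physical,
        fs=fs,
        labels=tuple(labels),
        types=tuple(types),
        subject_id=subject_id,
    )


def _cols(sig: bytes, base: int, width: int, n: int) -> list[str]:
    return [
        sig[base + i * width : base + (i + 1) * width].decode("ascii").strip()
        for i in range(n)
    ]
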