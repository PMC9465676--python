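"""Minimal EDF (European Data Format) reader/writer.

Implements the classic 16-bit EDF layout: one 256-byte global header,
256 bytes of per-signal header fields, then fixed-duration data records of
little-endian int16 samples. Samples are linearly mapped between each
signal's physical and digital ranges, so a round trip is exact up to one
quantisation step ``(phys_max - phys_min) / (dig_max - dig_min)``.

Conventions of this codec:

- one data record per second; every signal's rate must be an integer Hz;
- the final partial record is padded with the signal's last value, and the
  true sample count is stored in the signal's 32-byte reserved field
  (``n=<count>``) so this reader can trim the padding — foreign EDF readers
  simply see the padded tail;
- subject demographics are packed into the 80-byte patient-id field;
  activity annotations are not representable and are dropped (use the
  delimited dialect when the annotation must survive a round trip).
"""

from __future__ import annotations

import datetime
from pathlib import Path

import numpy as np

from .io import Channel, Recording, SubjectInfo

__all__ = ["write_edf", "read_edf", "quantization_step"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def quantization_step(phys_min: float, phys_max: float) -> float:
    """Physical value of one digital step for a 16-bit EDF signal."""
    return (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN)


def _fixed(text: str, width: int) -> bytes:
    raw = text.encode("ascii", "replace")[:width]
    return raw.ljust(width, b" ")


def write_edf(rec: Recording, path: Path | str) -> Path:
    """Write a recording as a single EDF file."""
    path = Path(path)
    names = sorted(rec.channels)
    chans = [rec.channels[n] for n in names]
    for ch in chans:
        if abs(ch.fs - round(ch.fs)) > 1e-9:
            raise ValueError(f"EDF dialect needs integer sampling rates, got {ch.fs}")
    n_records = int(np.ceil(max(ch.duration for ch in chans)))
    spr = [int(round(ch.fs)) for ch in chans]

    phys_ranges = []
    digital: list[np.ndarray] = []
    for ch, k in zip(chans, spr):
        x = np.asarray(ch.samples, dtype=float)
        pmin, pmax = float(np.min(x)), float(np.max(x))
        if pmax - pmin < 1e-12:  # constant signal: widen to a sane range
            pmin, pmax = pmin - 1.0, pmax + 1.0
        gain = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
        d = np.rint((x - pmin) * gain + _DIG_MIN).astype(np.int16)
        pad = n_records * k - len(d)
        if pad:
            d = np.concatenate([d, np.full(pad, d[-1] if len(d) else 0, np.int16)])
        phys_ranges.append((pmin, pmax))
        digital.append(d.reshape(n_records, k))

    s = rec.subject
    patient = (
        f"{s.subject_id} {s.sex} {s.age} {s.height_cm:g} {s.weight_kg:g}"
        if s is not None
        else "X"
    )
    now = datetime.datetime(2000, 1, 1)
    ns = len(chans)
    header = b"".join(
        [
            _fixed("0", 8),
            _fixed(patient, 80),
            _fixed("Startdate X X X X", 80),
            _fixed(now.strftime("%d.%m.%y"), 8),
            _fixed(now.strftime("%H.%M.%S"), 8),
            _fixed(str(256 * (ns + 1)), 8),
            _fixed("", 44),
            _fixed(str(n_records), 8),
            _fixed("1", 8),
            _fixed(str(ns), 4),
        ]
    )
    fields = []
    for ch, (pmin, pmax), k in zip(chans, phys_ranges, spr):
        fields.append(
            (
                _fixed(ch.name, 16),
                _fixed("", 80),
                _fixed("", 8),
                _fixed(f"{pmin:.8g}"[:8], 8),
                _fixed(f"{pmax:.8g}"[:8], 8),
                _fixed(str(_DIG_MIN), 8),
                _fixed(str(_DIG_MAX), 8),
                _fixed("", 80),
                _fixed(str(k), 8),
                _fixed(f"n={len(ch.samples)}", 32),
            )
        )
    # EDF groups each field across all signals
    signal_header = b"".join(b"".join(f[i] for f in fields) for i in range(10))

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(signal_header)
        for r in range(n_records):
            for d in digital:
                fh.write(d[r].astype("<i2").tobytes())
    return path


def _parse_subject(patient: str) -> SubjectInfo | None:
    parts = patient.split()
    if len(parts) < 5:
        return None
    try:
        return SubjectInfo(
            subject_id=parts[0],
            age=int(parts[2]),
            sex=parts[1],
            height_cm=float(parts[3]),
            weight_kg=float(parts[4]),
        )
    except (ValueError, IndexError):
        return None


def read_edf(path: Path | str, label_map: dict[str, str] | None = None) -> Recording:
    """Read an EDF file into a :class:`Recording`.

    ``label_map`` translates EDF signal labels to channel names; unmapped
    labels are used as-is.
    """
    label_map = label_map or {}
    with open(path, "rb") as fh:
        head = fh.read(256).decode("ascii")
        patient = head[8:88].strip()
        n_records = int(head[236:244])
        record_dur = float(head[244:252])
        ns = int(head[252:256])

        def col(width: int) -> list[str]:
            return [fh.read(width).decode("ascii").strip() for _ in range(ns)]

        labels = col(16)
        col(80)  # transducer
        col(8)  # physical dimension
        pmins = [float(v) for v in col(8)]
        pmaxs = [float(v) for v in col(8)]
        dmins = [int(v) for v in col(8)]
        dmaxs = [int(v) for v in col(8)]
        col(80)  # prefiltering
        spr = [int(v) for v in col(8)]
        reserved = col(32)

        per_record = sum(spr)
        raw = np.frombuffer(fh.read(n_records * per_record * 2), dtype="<i2")

    raw = raw.reshape(n_records, per_record)
    channels: dict[str, Channel] = {}
    offset = 0
    for i, label in enumerate(labels):
        k = spr[i]
        d = raw[:, offset : offset + k].reshape(-1).astype(float)
        offset += k
        gain = (pmaxs[i] - pmins[i]) / (dmaxs[i] - dmins[i])
        x = (d - dmins[i]) * gain + pmins[i]
        if reserved[i].startswith("n="):
            x = x[: int(reserved[i][2:])]
        name = label_map.get(label, label)
        channels[name] = Channel(name, k / record_dur, x)
    return Recording(subject=_parse_subject(patient), channels=channels, activities=[])
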