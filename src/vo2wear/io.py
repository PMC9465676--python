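"""Domain types and recording I/O.

A :class:`Recording` bundles the synchronously started multichannel signals
of one laboratory session — single-lead ECG at 200 Hz, thoracic/abdominal
respiration and tri-axial acceleration at 25 Hz, and the 1 Hz reference
oxygen uptake (VO2, ml/kg/min) and heart-rate channels — together with the
subject's demographics and an activity annotation.

Time is continuous seconds from recording start; activity intervals are
half-open ``[t_start, t_end)`` so that a 1 Hz sample belongs to exactly one
interval of a partition.

Two on-disk dialects are supported: a delimited-text directory layout (one
file per channel plus a small key-value manifest; trivially diffable) and
EDF (via :mod:`vo2wear.edf`).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

__all__ = [
    "CHANNEL_RATES",
    "ACTIVITY_LABELS",
    "SubjectInfo",
    "Channel",
    "ActivityInterval",
    "Recording",
    "read_recording",
    "write_recording",
    "slice_by_activity",
    "IncompleteRecordingError",
    "SamplingRateError",
    "NoSuchActivityError",
]

#: Nominal sampling rate (Hz) for every recognised channel role.
CHANNEL_RATES: dict[str, float] = {
    "ecg": 200.0,
    "resp_thoracic": 25.0,
    "resp_abdominal": 25.0,
    "acc_x": 25.0,
    "acc_y": 25.0,
    "acc_z": 25.0,
    "vo2_ref": 1.0,
    "hr_ref": 1.0,
}

#: Recognised activity labels: five rest postures, treadmill phases, recovery.
ACTIVITY_LABELS: tuple[str, ...] = (
    "stand",
    "lie",
    "lie_left",
    "lie_right",
    "sit",
    "walk",
    "bruce_level_1",
    "bruce_level_2",
    "bruce_level_3",
    "bruce_level_4",
    "bruce_level_5",
    "bruce_level_6",
    "bruce_level_7",
    "recovery",
)

MANDATORY_CHANNELS = ("ecg", "acc_x", "acc_y", "acc_z")


class IncompleteRecordingError(ValueError):
    """A mandatory channel is missing ("incomplete recording")."""


class SamplingRateError(ValueError):
    """A channel's sampling rate violates its declared role."""


class NoSuchActivityError(KeyError):
    """The requested activity label is absent from the annotation."""


@dataclass(frozen=True)
class SubjectInfo:
    """Demographics used as the SDI model features (age, sex, BMI)."""

    subject_id: str
    age: int
    sex: str  # "male" | "female"
    height_cm: float
    weight_kg: float
    bmi: float | None = None

    def __post_init__(self) -> None:
        if self.age <= 0 or self.height_cm <= 0 or self.weight_kg <= 0:
            raise ValueError("age, height and weight must be strictly positive")
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex {self.sex!r}")
        computed = self.weight_kg / (self.height_cm / 100.0) ** 2
        if self.bmi is None:
            object.__setattr__(self, "bmi", round(computed, 2))
        elif abs(self.bmi - computed) > 0.1:
            raise ValueError(
                f"bmi {self.bmi} inconsistent with height/weight ({computed:.2f})"
            )

    @property
    def sex_code(self) -> int:
        """Numeric sex encoding for modelling: male=1, female=0."""
        return 1 if self.sex == "male" else 0


@dataclass
class Channel:
    """One uniformly sampled signal with its sampling rate in Hz."""

    name: str
    fs: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.name in CHANNEL_RATES and self.fs != CHANNEL_RATES[self.name]:
            raise SamplingRateError(
                f"sampling-rate violation: {self.name} declared at {self.fs} Hz, "
                f"expected {CHANNEL_RATES[self.name]} Hz"
            )

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return len(self.samples) / self.fs

    def times(self) -> np.ndarray:
        """Sample timestamps in seconds (sample i at i / fs)."""
        return np.arange(len(self.samples)) / self.fs


@dataclass(frozen=True)
class ActivityInterval:
    """Half-open labelled interval [t_start, t_end) in seconds."""

    label: str
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        if self.label not in ACTIVITY_LABELS:
            raise ValueError(f"unknown activity label {self.label!r}")


@dataclass
class Recording:
    """Aligned multichannel recording for one subject.

    All channels share a common time origin (sample 0 is t = 0 s); no
    cross-device clock-drift correction is applied.
    """

    subject: SubjectInfo
    channels: dict[str, Channel]
    activities: list[ActivityInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in MANDATORY_CHANNELS if c not in self.channels]
        if not any(c.startswith("resp_") for c in self.channels):
            missing.append("resp_thoracic|resp_abdominal")
        if missing:
            raise IncompleteRecordingError(
                "incomplete recording: missing channel(s) " + ", ".join(missing)
            )
        ivs = sorted(self.activities, key=lambda a: a.t_start)
        for a, b in zip(ivs, ivs[1:]):
            if b.t_start < a.t_end - 1e-9:
                raise ValueError(f"overlapping activity intervals {a} / {b}")

    @property
    def duration(self) -> float:
        """Recording duration in seconds (longest channel)."""
        return max(ch.duration for ch in self.channels.values())

    def activity_labels(self) -> list[str]:
        return sorted({a.label for a in self.activities})


# ---------------------------------------------------------------------------
# Delimited dialect: a directory with manifest.txt, per-channel CSVs,
# subject.csv and activities.csv.
# ---------------------------------------------------------------------------

def _write_manifest(path: Path, entries: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for k, v in entries.items():
            fh.write(f"{k} = {v}\n")


def _read_manifest(path: Path) -> dict[str, str]:
    entries: dict[str, str] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        entries[key.strip()] = value.strip()
    return entries


def _write_delimited(rec: Recording, root: Path) -> None:
    root.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for name, ch in sorted(rec.channels.items()):
        fname = f"{name}.csv"
        with open(root / fname, "w") as fh:
            fh.write(f"{name},{ch.fs:g}\n")
            np.savetxt(fh, ch.samples, fmt="%.17g")
        manifest[f"channel.{name}"] = fname
    with open(root / "subject.csv", "w") as fh:
        fh.write("subject_id,age,sex,height_cm,weight_kg,bmi\n")
        s = rec.subject
        fh.write(f"{s.subject_id},{s.age},{s.sex},{s.height_cm:g},{s.weight_kg:g},{s.bmi:g}\n")
    manifest["subject"] = "subject.csv"
    with open(root / "activities.csv", "w") as fh:
        fh.write("label,t_start,t_end\n")
        for a in rec.activities:
            fh.write(f"{a.label},{a.t_start:g},{a.t_end:g}\n")
    manifest["activities"] = "activities.csv"
    _write_manifest(root / "manifest.txt", manifest)


def _read_delimited(root: Path) -> Recording:
    manifest = _read_manifest(root / "manifest.txt")
    channels: dict[str, Channel] = {}
    for key, fname in manifest.items():
        if not key.startswith("channel."):
            continue
        name = key[len("channel."):]
        with open(root / fname) as fh:
            header = fh.readline().strip().split(",")
            fs = float(header[1])
            samples = np.loadtxt(fh, ndmin=1)
        channels[name] = Channel(name, fs, samples)
    subject = None
    if "subject" in manifest:
        lines = (root / manifest["subject"]).read_text().splitlines()
        sid, age, sex, h, w, bmi = lines[1].split(",")
        subject = SubjectInfo(sid, int(age), sex, float(h), float(w), float(bmi))
    activities: list[ActivityInterval] = []
    if "activities" in manifest:
        for line in (root / manifest["activities"]).read_text().splitlines()[1:]:
            if not line.strip():
                continue
            label, t0, t1 = line.split(",")
            activities.append(ActivityInterval(label, float(t0), float(t1)))
    return Recording(subject=subject, channels=channels, activities=activities)


def write_recording(rec: Recording, path: os.PathLike | str, dialect: str = "delimited") -> Path:
    """Write a recording to disk; returns the written path.

    The delimited dialect is lossless; the EDF dialect quantises samples to
    16 bits over each channel's physical range.
    """
    if not rec.channels:
        raise ValueError("recording has no channels")
    path = Path(path)
    if dialect == "delimited":
        _write_delimited(rec, path)
    elif dialect == "edf":
        from . import edf

        edf.write_edf(rec, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def read_recording(
    path: os.PathLike | str,
    dialect: str = "delimited",
    label_map: dict[str, str] | None = None,
) -> Recording:
    """Read a recording written by :func:`write_recording`.

    Parameters
    ----------
    path : directory (delimited) or file (EDF).
    dialect : "delimited" or "edf".
    label_map : for EDF, maps EDF signal labels to channel names
        (e.g. ``{"ECG I": "ecg"}``); unmapped labels are used verbatim.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "delimited":
        return _read_delimited(path)
    if dialect == "edf":
        from . import edf

        return edf.read_edf(path, label_map=label_map)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Activity slicing
# ---------------------------------------------------------------------------

def slice_by_activity(rec: Recording, label: str) -> Recording:
    """Restrict a recording to the intervals carrying ``label``.

    Samples whose timestamp i/fs falls in any matching half-open
    [t_start, t_end) are kept; the slices are concatenated and re-based so
    the returned recording starts at t = 0.
    """
    matching = sorted(
        (a for a in rec.activities if a.label == label), key=lambda a: a.t_start
    )
    if not matching:
        raise NoSuchActivityError(f"no such activity: {label!r}")
    new_channels: dict[str, Channel] = {}
    for name, ch in rec.channels.items():
        parts = []
        for iv in matching:
            i0 = math.ceil(iv.t_start * ch.fs - 1e-9)
            i1 = math.ceil(iv.t_end * ch.fs - 1e-9)  # exclusive: t < t_end
            parts.append(ch.samples[i0:i1])
        new_channels[name] = Channel(name, ch.fs, np.concatenate(parts))
    new_activities = []
    offset = 0.0
    for iv in matching:
        dur = iv.t_end - iv.t_start
        new_activities.append(ActivityInterval(label, offset, offset + dur))
        offset += dur
    return Recording(subject=rec.subject, channels=new_channels, activities=new_activities)
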