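"""Domain types and file I/O for recordings, hypnograms and spindle events.

Conventions
-----------
All event times are seconds from recording start, half-open ``[onset, offset)``;
sample indexing is 0-based.  Signals are stored in microvolts.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, UnsupportedError, ValidationError


class Stage(enum.Enum):
    """Rechtschaffen & Kales sleep stages; stages 3 and 4 merge into SWS."""

    WAKE = "Wake"
    S1 = "S1"
    S2 = "S2"
    SWS = "SWS"
    REM = "REM"
    MT = "MT"


#: default mapping from hypnogram file codes to stages (R&K numeric codes,
#: 3 and 4 both mapped to SWS)
DEFAULT_STAGE_CODES = {
    "W": Stage.WAKE, "0": Stage.WAKE,
    "1": Stage.S1,
    "2": Stage.S2,
    "3": Stage.SWS, "4": Stage.SWS,
    "R": Stage.REM, "5": Stage.REM,
    "M": Stage.MT, "MT": Stage.MT,
}


class ChannelRole(enum.Enum):
    FRONTAL = "frontal"
    CENTRAL = "central"
    PARIETAL = "parietal"
    OTHER = "other"


class SpindleType(enum.Enum):
    SLOW = "slow"
    FAST = "fast"
    ALL = "all"


class MaskReason(enum.IntEnum):
    NONE = 0
    EMG = 1
    ALPHA = 2


@dataclass
class EEGRecording:
    """Multi-channel EEG in microvolts.

    Attributes
    ----------
    channel_labels : 10-20 style labels (e.g. ``"F3A2"``).
    channel_role : per-channel :class:`ChannelRole`.
    fs : sampling rate in Hz.
    data : ``(n_channels, n_samples)`` array in microvolts.
    start_time : seconds offset of the first sample (0 if unknown).
    """

    channel_labels: list[str]
    channel_role: list[ChannelRole]
    fs: float
    data: np.ndarray
    start_time: float = 0.0

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValidationError("one label per channel required")
        if len(self.channel_role) != self.data.shape[0]:
            raise ValidationError("one role per channel required")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("signal contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording duration in seconds (= samples / fs exactly)."""
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.channel_labels.index(label)]
        except ValueError:
            raise KeyError(f"no channel {label!r}") from None

    def channels_with_role(self, role: ChannelRole) -> list[str]:
        return [l for l, r in zip(self.channel_labels, self.channel_role) if r == role]


@dataclass
class Hypnogram:
    """Sleep-stage sequence in fixed-length epochs (30 s by default)."""

    stages: list[Stage]
    epoch_length: float = 30.0

    def __post_init__(self):
        if self.epoch_length <= 0:
            raise ValidationError("epoch_length must be positive")
        if not self.stages:
            raise ValidationError("hypnogram is empty")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def duration(self) -> float:
        return self.n_epochs * self.epoch_length

    def stage_at(self, t: float) -> Stage | None:
        """Stage of the epoch containing time ``t`` (None beyond coverage)."""
        i = int(t // self.epoch_length)
        if 0 <= i < len(self.stages):
            return self.stages[i]
        return None

    def count(self, stages) -> int:
        stages = set(stages)
        return sum(1 for s in self.stages if s in stages)


@dataclass
class SpindleEvent:
    """One detected sleep spindle.

    ``amplitude`` is the spectral-peak amplitude in microvolts (height of the
    maximum peak of the zero-padded Hann amplitude spectrum), not the
    peak-to-peak signal amplitude.
    """

    channel: str
    onset: float
    offset: float
    type: SpindleType
    amplitude: float
    frequency: float
    stage: Stage | None = None

    MIN_DURATION = 0.5

    def __post_init__(self):
        if self.onset < 0:
            raise ValidationError(f"onset {self.onset} < 0")
        if self.offset - self.onset < self.MIN_DURATION - 1e-9:
            raise ValidationError(
                f"duration {self.offset - self.onset:.3f} s below the "
                f"{self.MIN_DURATION} s minimum")
        if not (9.0 - 1e-9 <= self.frequency <= 16.0 + 1e-9):
            raise ValidationError(f"frequency {self.frequency} Hz outside [9, 16]")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class ExclusionMask:
    """Per-sample exclusion flags for one channel at the working rate."""

    fs: float
    flags: np.ndarray
    reason: np.ndarray = None

    def __post_init__(self):
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.reason is None:
            self.reason = np.where(self.flags, MaskReason.EMG, MaskReason.NONE).astype(np.uint8)
        self.reason = np.asarray(self.reason, dtype=np.uint8)
        if self.reason.shape != self.flags.shape:
            raise ValidationError("reason and flags must have equal length")

    def masked_seconds(self, reason: MaskReason | None = None) -> float:
        if reason is None:
            return float(self.flags.sum()) / self.fs
        return float((self.reason == int(reason)).sum()) / self.fs

    def __or__(self, other: "ExclusionMask") -> "ExclusionMask":
        if len(self.flags) != len(other.flags) or self.fs != other.fs:
            raise ValidationError("masks are not aligned")
        flags = self.flags | other.flags
        reason = np.where(self.reason != 0, self.reason, other.reason)
        return ExclusionMask(self.fs, flags, reason)

    @classmethod
    def empty(cls, n: int, fs: float = 100.0) -> "ExclusionMask":
        return cls(fs, np.zeros(n, dtype=bool), np.zeros(n, dtype=np.uint8))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_recording(path, role_map: dict | None = None, fs: float | None = None,
                   channels: list[str] | None = None) -> EEGRecording:
    """Read an EDF/EDF+ file or a delimited numeric matrix.

    Parameters
    ----------
    path : EDF file (suffix ``.edf``) or delimited text.  Delimited files
        carry one column per channel with a header row of labels; an optional
        ``time`` column (seconds) supplies the sampling rate, otherwise
        ``fs`` must be given.
    role_map : label -> role (:class:`ChannelRole` or its string value);
        unlisted channels get role ``other``.
    channels : optional subset of channels to load.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    if os.path.getsize(path) == 0:
        raise FormatError(f"empty file: {path}")
    if path.lower().endswith(".edf"):
        labels, fs, data = _read_edf(path, channels)
    else:
        labels, fs, data = _read_delimited(path, fs, channels)
    if data.shape[0] == 0:
        raise FormatError("recording holds no channels")
    roles = _resolve_roles(labels, role_map)
    return EEGRecording(labels, roles, fs, data)


def infer_roles(labels) -> dict:
    """Guess channel roles from 10-20 label prefixes (F3 -> frontal, ...)."""
    out = {}
    for lab in labels:
        u = lab.upper()
        if u.startswith("FP") or u.startswith("F"):
            out[lab] = ChannelRole.FRONTAL
        elif u.startswith("C"):
            out[lab] = ChannelRole.CENTRAL
        elif u.startswith("P"):
            out[lab] = ChannelRole.PARIETAL
        else:
            out[lab] = ChannelRole.OTHER
    return out


def _resolve_roles(labels, role_map):
    role_map = role_map or {}
    roles = []
    for lab in labels:
        r = role_map.get(lab, ChannelRole.OTHER)
        if isinstance(r, str):
            r = ChannelRole(r)
        roles.append(r)
    return roles


def _read_edf(path, channels):
    import mne

    try:
        raw = mne.io.read_raw_edf(path, include=channels, preload=True, verbose="error")
    except Exception as exc:  # noqa: BLE001 - normalise reader failures
        raise FormatError(f"cannot read EDF {path}: {exc}") from exc
    extras = getattr(raw, "_raw_extras", None)
    if extras:
        n_samps = extras[0].get("n_samps")
        if n_samps is not None:
            sel = np.asarray(n_samps)[: len(raw.ch_names)]
            if np.unique(sel).size > 1:
                raise UnsupportedError(
                    "mixed sampling rates across requested channels")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return list(raw.ch_names), float(raw.info["sfreq"]), data


def _read_delimited(path, fs, channels):
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"no data in {path}")
    cols = list(df.columns)
    if cols and str(cols[0]).lower() in ("time", "time_s", "t"):
        t = df[cols[0]].to_numpy(dtype=float)
        if len(t) > 1:
            dt = np.median(np.diff(t))
            fs = 1.0 / dt if fs is None else fs
        df = df.drop(columns=[cols[0]])
    if fs is None:
        raise FormatError("sampling rate unknown: pass fs= or include a time column")
    if channels is not None:
        missing = [c for c in channels if c not in df.columns]
        if missing:
            raise FormatError(f"channels not in file: {missing}")
        df = df[channels]
    try:
        data = df.to_numpy(dtype=float).T
    except ValueError as exc:
        raise FormatError(f"non-numeric data in {path}: {exc}") from exc
    return [str(c) for c in df.columns], float(fs), data


def read_hypnogram(path, code_map: dict | None = None,
                   epoch_length: float = 30.0) -> Hypnogram:
    """Read a plain-text hypnogram, one stage code per line (commas allowed)."""
    code_map = code_map or DEFAULT_STAGE_CODES
    stages = []
    with open(os.fspath(path)) as fh:
        lines = fh.read().splitlines()
    for lineno, line in enumerate(lines, start=1):
        for tok in line.replace(",", " ").split():
            if tok not in code_map:
                raise ParseError(f"unknown stage code {tok!r} on line {lineno}")
            stages.append(code_map[tok])
    if not stages:
        raise ParseError(f"hypnogram {path} holds no stages")
    return Hypnogram(stages, epoch_length)


def write_hypnogram(hyp: Hypnogram, path, code_map: dict | None = None) -> None:
    inverse = {}
    for code, stage in (code_map or DEFAULT_STAGE_CODES).items():
        inverse.setdefault(stage, code)
    with open(os.fspath(path), "w") as fh:
        for s in hyp.stages:
            fh.write(inverse[s] + "\n")


_EVENT_COLUMNS = ["onset", "duration", "channel", "type", "amplitude", "frequency", "stage"]


def write_events(events: list[SpindleEvent], path) -> None:
    """Write events as CSV (header: onset,duration,channel,type,amplitude,frequency,stage)."""
    rows = []
    for ev in events:
        if not isinstance(ev, SpindleEvent):
            raise ValidationError("write_events expects SpindleEvent objects")
        rows.append({
            "onset": ev.onset,
            "duration": ev.duration,
            "channel": ev.channel,
            "type": ev.type.value,
            "amplitude": ev.amplitude,
            "frequency": ev.frequency,
            "stage": ev.stage.value if ev.stage is not None else "",
        })
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(path, index=False, float_format="%.6f")


def read_events(path) -> list[SpindleEvent]:
    try:
        df = pd.read_csv(path, keep_default_na=False)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read events from {path}: {exc}") from exc
    missing = [c for c in _EVENT_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise FormatError(f"events file lacks columns: {missing}")
    events = []
    for _, row in df.iterrows():
        stage = Stage(row["stage"]) if str(row.get("stage", "")) else None
        events.append(SpindleEvent(
            channel=str(row["channel"]),
            onset=float(row["onset"]),
            offset=float(row["onset"]) + float(row["duration"]),
            type=SpindleType(row["type"]),
            amplitude=float(row["amplitude"]),
            frequency=float(row["frequency"]),
            stage=stage,
        ))
    return events
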