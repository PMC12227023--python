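"""On-disk unit of the pipeline: one refraction recording per participant x cue.

A recording holds both eyes' refraction traces sampled at a fixed rate
(missing samples stored as NaN), the stimulus-event log, and the instrument
calibration factor.  The text dialect is a commented-header CSV::

    # participant_id: P01
    # cue: BDP
    # fs_hz: 50.0
    # calibration_factor: 1.0
    time_s,od_refraction_d,os_refraction_d
    0.000000,1.0213,1.0187
    0.020000,,1.0191          <- empty field = missing sample

with a companion ``<stem>.events.csv`` listing one row per stimulus movement:
``movement_index,direction,onset_s,demand_start_d,demand_end_d``.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "StimulusEvent",
    "RecordingFile",
    "read_recording",
    "write_recording",
    "RecordingParseError",
]

#: directions of a demand step: focus = far-to-near (accommodation increases),
#: defocus = near-to-far (accommodation relaxes)
DIRECTIONS = ("focus", "defocus")


class RecordingParseError(ValueError):
    """Raised when a recording file does not match the dialect; names the line."""


@dataclass(frozen=True)
class StimulusEvent:
    movement_index: int
    direction: str  # "focus" | "defocus"
    onset_s: float
    demand_start_d: float
    demand_end_d: float

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}, got {self.direction!r}")


@dataclass
class RecordingFile:
    """Two-eye refraction time series plus event log.

    ``od`` (right eye) and ``os`` (left eye) are diopter vectors aligned with
    ``time``; missing samples are NaN.  ``od_interpolated``/``os_interpolated``
    are provenance masks set by gap interpolation (None until then).
    """

    participant_id: str
    cue: str
    fs: float
    time: np.ndarray
    od: np.ndarray
    os: np.ndarray
    events: list[StimulusEvent] = field(default_factory=list)
    calibration_factor: float = 1.0
    od_interpolated: np.ndarray | None = None
    os_interpolated: np.ndarray | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        self.os = np.asarray(self.os, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        n = self.time.size
        if self.od.size != n or self.os.size != n:
            raise ValueError("od/os length must equal time length")
        if n > 1:
            dt = np.diff(self.time)
            if np.any(dt <= 0) or not np.allclose(dt, 1.0 / self.fs, atol=1e-6):
                raise ValueError("time must increase strictly at 1/fs spacing")
        if self.events:
            if n == 0:
                raise ValueError("events present but recording is empty")
            t_end = self.time[0] + (n - 1) / self.fs
            for ev in self.events:
                if not (self.time[0] <= ev.onset_s <= t_end):
                    raise ValueError(
                        f"event {ev.movement_index} onset {ev.onset_s}s outside recording span"
                    )

    # -- masks ------------------------------------------------------------
    @property
    def od_missing(self) -> np.ndarray:
        return np.isnan(self.od)

    @property
    def os_missing(self) -> np.ndarray:
        return np.isnan(self.os)

    @property
    def both_missing(self) -> np.ndarray:
        """Samples missing in both eyes (the combined mask after substitution)."""
        return self.od_missing & self.os_missing

    @property
    def n_samples(self) -> int:
        return int(self.time.size)

    def copy(self) -> "RecordingFile":
        return replace(
            self,
            time=self.time.copy(),
            od=self.od.copy(),
            os=self.os.copy(),
            events=list(self.events),
            od_interpolated=None if self.od_interpolated is None else self.od_interpolated.copy(),
            os_interpolated=None if self.os_interpolated is None else self.os_interpolated.copy(),
        )


def _events_path(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".events.csv") if path.suffix == ".csv" \
        else path.with_name(path.name + ".events.csv")


def _fmt(x: float) -> str:
    return "" if np.isnan(x) else format(x, ".9g")


def write_recording(rec: RecordingFile, path: str | Path) -> Path:
    """Write a recording (and its companion event log) in the text dialect.

    Round-trips losslessly through :func:`read_recording` to float text
    precision (9 significant digits).
    """
    path = Path(path)
    buf = io.StringIO()
    buf.write(f"# participant_id: {rec.participant_id}\n")
    buf.write(f"# cue: {rec.cue}\n")
    buf.write(f"# fs_hz: {rec.fs!r}\n")
    buf.write(f"# calibration_factor: {rec.calibration_factor!r}\n")
    buf.write("time_s,od_refraction_d,os_refraction_d\n")
    for t, a, b in zip(rec.time, rec.od, rec.os):
        buf.write(f"{t:.6f},{_fmt(a)},{_fmt(b)}\n")
    path.write_text(buf.getvalue())

    with open(_events_path(path), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["movement_index", "direction", "onset_s", "demand_start_d", "demand_end_d"])
        for ev in rec.events:
            w.writerow([ev.movement_index, ev.direction, format(ev.onset_s, ".6f"),
                        format(ev.demand_start_d, ".9g"), format(ev.demand_end_d, ".9g")])
    return path


def read_recording(path: str | Path) -> RecordingFile:
    """Parse a recording file and its companion event log.

    Raises :class:`RecordingParseError` naming the offending line for malformed
    headers or rows, and ValueError for invalid metadata (e.g. fs <= 0).
    """
    path = Path(path)
    header: dict[str, str] = {}
    times: list[float] = []
    od: list[float] = []
    os_: list[float] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            break
        try:
            key, value = line[1:].split(":", 1)
        except ValueError:
            raise RecordingParseError(f"{path}:{i + 1}: malformed header line {line!r}")
        header[key.strip()] = value.strip()
    if i >= len(lines) or lines[i].strip() != "time_s,od_refraction_d,os_refraction_d":
        raise RecordingParseError(f"{path}:{i + 1}: expected column header row")
    for j, line in enumerate(lines[i + 1:], start=i + 2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split(",")
        if len(parts) != 3:
            raise RecordingParseError(f"{path}:{j}: expected 3 fields, got {len(parts)}")
        try:
            times.append(float(parts[0]))
            od.append(float(parts[1]) if parts[1] != "" else np.nan)
            os_.append(float(parts[2]) if parts[2] != "" else np.nan)
        except ValueError:
            raise RecordingParseError(f"{path}:{j}: non-numeric field in {line!r}")

    for req in ("participant_id", "cue", "fs_hz"):
        if req not in header:
            raise RecordingParseError(f"{path}: missing required header key '{req}'")
    fs = float(header["fs_hz"])
    if fs <= 0:
        raise ValueError(f"{path}: fs_hz must be positive, got {fs}")

    events: list[StimulusEvent] = []
    epath = _events_path(path)
    if epath.exists():
        with open(epath) as fh:
            for k, row in enumerate(csv.DictReader(fh), start=2):
                try:
                    events.append(StimulusEvent(
                        movement_index=int(row["movement_index"]),
                        direction=row["direction"],
                        onset_s=float(row["onset_s"]),
                        demand_start_d=float(row["demand_start_d"]),
                        demand_end_d=float(row["demand_end_d"]),
                    ))
                except (KeyError, ValueError) as exc:
                    raise RecordingParseError(f"{epath}:{k}: bad event row ({exc})")

    return RecordingFile(
        participant_id=header["participant_id"],
        cue=header["cue"],
        fs=fs,
        time=np.array(times),
        od=np.array(od),
        os=np.array(os_),
        events=events,
        calibration_factor=float(header.get("calibration_factor", 1.0)),
    )
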