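"""Session file formats: trajectory, EMG recording, and trial event log.

A recorded session consists of three plain-text files:

``trajectory.csv``
    End-effector position of the robot handle, uniformly sampled.
    Columns ``time,x,y,z`` (seconds from session start; meters in the
    robot base frame), preceded by a one-line versioned header comment
    that carries the sample rate.

``emg.csv``
    Multi-channel surface EMG, nominally 1 kHz.  Columns ``time`` plus
    one column per muscle (millivolts), same header convention.

``events.jsonl``
    One JSON record per movement segment (target appearance to target
    disappearance on contact) carrying timing, target position, ball
    mode, protocol phase and feedback condition.

Readers validate rather than repair: non-monotone time, a non-uniform
grid, overlapping trials or unknown labels raise :class:`FormatError`
with the offending file position.  ``read(write(x))`` round-trips to
1e-9 absolute tolerance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "EmgRecording",
    "TrialEvent",
    "EventLog",
    "FormatError",
    "DEFAULT_MUSCLES",
    "BALL_MODES",
    "PHASES",
    "FEEDBACK_LABELS",
    "read_trajectory",
    "write_trajectory",
    "read_emg",
    "write_emg",
    "read_events",
    "write_events",
]

DEFAULT_MUSCLES = (
    "biceps brachii",
    "triceps brachii",
    "upper trapezius",
    "anterior deltoid",
    "posterior deltoid",
)

BALL_MODES = ("big", "small")
PHASES = ("baseline", "training", "retention")
FEEDBACK_LABELS = ("none", "TV", "TH", "TM")

_FLOAT_FMT = "%.9f"
_GRID_RTOL = 0.01  # max deviation of successive dt from 1/rate, relative


class FormatError(ValueError):
    """A session file violates its format contract."""


def _check_uniform_grid(times: np.ndarray, sample_rate: float, where: str) -> None:
    if times.ndim != 1 or times.size < 2:
        raise FormatError(f"{where}: need at least 2 samples, got {times.size}")
    dt = np.diff(times)
    if np.any(dt <= 0):
        i = int(np.argmax(dt <= 0))
        raise FormatError(f"{where}: time not strictly increasing at row {i + 1}")
    nominal = 1.0 / sample_rate
    dev = np.abs(dt - nominal)
    if np.any(dev > _GRID_RTOL * nominal):
        i = int(np.argmax(dev > _GRID_RTOL * nominal))
        raise FormatError(
            f"{where}: non-uniform sampling at row {i + 1}: "
            f"dt={dt[i]:.6g}s vs nominal {nominal:.6g}s"
        )


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled 3-D end-effector positions for one session.

    Attributes
    ----------
    times : (n,) array of seconds from session start, strictly increasing.
    positions : (n, 3) array of meters in the robot base frame.
    sample_rate : nominal sampling rate in Hz.
    """

    times: np.ndarray
    positions: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        positions = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "positions", positions)
        if positions.ndim != 2 or positions.shape[1] != 3:
            raise ValueError(f"positions must be (n, 3), got {positions.shape}")
        if positions.shape[0] != times.shape[0]:
            raise ValueError("times and positions length mismatch")
        _check_uniform_grid(times, self.sample_rate, "Trajectory")

    @property
    def n_samples(self) -> int:
        return self.times.shape[0]


@dataclass(frozen=True)
class EmgRecording:
    """Multi-channel surface EMG, one row per sample.

    ``samples`` has shape (n, n_channels), in millivolts; ``channels``
    are the ordered, unique muscle labels.
    """

    times: np.ndarray
    channels: tuple[str, ...]
    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "channels", tuple(self.channels))
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channel labels")
        if samples.ndim != 2 or samples.shape[1] != len(self.channels):
            raise ValueError(
                f"samples must be (n, {len(self.channels)}), got {samples.shape}"
            )
        if samples.shape[0] != times.shape[0]:
            raise ValueError("times and samples length mismatch")
        _check_uniform_grid(times, self.sample_rate, "EmgRecording")

    def channel(self, label: str) -> np.ndarray:
        try:
            j = self.channels.index(label)
        except ValueError:
            raise KeyError(f"no channel {label!r}; have {list(self.channels)}")
        return self.samples[:, j]


@dataclass(frozen=True)
class TrialEvent:
    """One movement segment: target appearance to disappearance on contact."""

    index: int
    appear: float
    disappear: float
    target: tuple[float, float, float]
    ball_mode: str
    phase: str
    feedback: str

    def __post_init__(self) -> None:
        if not self.appear < self.disappear:
            raise ValueError(
                f"trial {self.index}: appear ({self.appear}) must precede "
                f"disappear ({self.disappear})"
            )
        if self.ball_mode not in BALL_MODES:
            raise ValueError(
                f"trial {self.index}: ball_mode {self.ball_mode!r} not in {BALL_MODES}"
            )
        if self.phase not in PHASES:
            raise ValueError(
                f"trial {self.index}: phase {self.phase!r} not in {PHASES}"
            )
        if self.feedback not in FEEDBACK_LABELS:
            raise ValueError(
                f"trial {self.index}: feedback {self.feedback!r} not in "
                f"{FEEDBACK_LABELS}"
            )
        object.__setattr__(self, "target", tuple(float(v) for v in self.target))
        if len(self.target) != 3:
            raise ValueError(f"trial {self.index}: target must be 3-D")

    @property
    def duration(self) -> float:
        return self.disappear - self.appear


@dataclass(frozen=True)
class EventLog:
    """Ordered, pairwise-disjoint trial events; the segmentation authority."""

    trials: tuple[TrialEvent, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "trials", tuple(self.trials))
        for i, tr in enumerate(self.trials):
            if tr.index != i:
                raise ValueError(
                    f"trial indices must be consecutive from 0; "
                    f"position {i} has index {tr.index}"
                )
            if i and tr.appear < self.trials[i - 1].disappear:
                raise ValueError(
                    f"trial {i} (appear {tr.appear}) overlaps trial {i - 1} "
                    f"(disappear {self.trials[i - 1].disappear})"
                )

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, i: int) -> TrialEvent:
        return self.trials[i]

    def select(
        self,
        ball_mode: str | None = None,
        phase: str | None = None,
        feedback: str | None = None,
    ) -> "EventLog":
        """Trials matching the given labels, reindexed from 0."""
        picked = [
            tr
            for tr in self.trials
            if (ball_mode is None or tr.ball_mode == ball_mode)
            and (phase is None or tr.phase == phase)
            and (feedback is None or tr.feedback == feedback)
        ]
        reindexed = [
            TrialEvent(i, t.appear, t.disappear, t.target, t.ball_mode, t.phase, t.feedback)
            for i, t in enumerate(picked)
        ]
        return EventLog(tuple(reindexed))


# ---------------------------------------------------------------------------
# trajectory.csv / emg.csv
# ---------------------------------------------------------------------------

def _write_table(
    path: Path, header: str, columns: Sequence[str], data: np.ndarray
) -> None:
    df = pd.DataFrame(data, columns=list(columns))
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def _read_table(path: Path, kind: str) -> tuple[float, pd.DataFrame]:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith(f"# reachmetrics {kind} v1"):
            raise FormatError(f"{path}, line 1: missing '{kind} v1' header comment")
        rate = None
        for piece in first.split(";"):
            piece = piece.strip()
            if piece.startswith("sample_rate_hz="):
                rate = float(piece.split("=", 1)[1])
        if rate is None or rate <= 0:
            raise FormatError(f"{path}, line 1: header lacks positive sample_rate_hz")
        header = fh.readline().strip()
        columns = header.split(",")
        if len(set(columns)) != len(columns):
            raise FormatError(f"{path}, line 2: duplicate channel labels")
        df = pd.read_csv(fh, names=columns)
    return rate, df


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    header = f"# reachmetrics trajectory v1; sample_rate_hz={traj.sample_rate:g}; units=s,m"
    data = np.column_stack([traj.times, traj.positions])
    _write_table(Path(path), header, ("time", "x", "y", "z"), data)


def read_trajectory(path: str | Path) -> Trajectory:
    rate, df = _read_table(Path(path), "trajectory")
    required = ["time", "x", "y", "z"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}, line 2: missing columns {missing}")
    try:
        return Trajectory(
            times=df["time"].to_numpy(float),
            positions=df[["x", "y", "z"]].to_numpy(float),
            sample_rate=rate,
        )
    except (FormatError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_emg(emg: EmgRecording, path: str | Path) -> None:
    header = f"# reachmetrics emg v1; sample_rate_hz={emg.sample_rate:g}; units=s,mV"
    data = np.column_stack([emg.times, emg.samples])
    _write_table(Path(path), header, ("time", *emg.channels), data)


def read_emg(path: str | Path) -> EmgRecording:
    rate, df = _read_table(Path(path), "emg")
    if "time" not in df.columns:
        raise FormatError(f"{path}, line 2: missing 'time' column")
    labels = [c for c in df.columns if c != "time"]
    if not labels:
        raise FormatError(f"{path}, line 2: no channel columns")
    if len(set(labels)) != len(labels):
        raise FormatError(f"{path}, line 2: duplicate channel labels")
    try:
        return EmgRecording(
            times=df["time"].to_numpy(float),
            channels=tuple(labels),
            samples=df[labels].to_numpy(float),
            sample_rate=rate,
        )
    except (FormatError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# events.jsonl
# ---------------------------------------------------------------------------

_EVENTS_HEADER = {"format": "reachmetrics-events", "version": 1}


def write_events(events: EventLog, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(json.dumps(_EVENTS_HEADER) + "\n")
        for tr in events:
            rec = {
                "index": tr.index,
                "appear": tr.appear,
                "disappear": tr.disappear,
                "target": list(tr.target),
                "ball_mode": tr.ball_mode,
                "phase": tr.phase,
                "feedback": tr.feedback,
            }
            fh.write(json.dumps(rec) + "\n")


def read_events(path: str | Path) -> EventLog:
    path = Path(path)
    trials: list[TrialEvent] = []
    with open(path) as fh:
        first = fh.readline()
        try:
            head = json.loads(first)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}, line 1: not JSON ({exc})") from exc
        if head.get("format") != "reachmetrics-events" or head.get("version") != 1:
            raise FormatError(f"{path}, line 1: not a reachmetrics-events v1 file")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise FormatError(f"{path}, line {lineno}: not JSON ({exc})") from exc
            try:
                trials.append(
                    TrialEvent(
                        index=int(rec["index"]),
                        appear=float(rec["appear"]),
                        disappear=float(rec["disappear"]),
                        target=tuple(rec["target"]),
                        ball_mode=rec["ball_mode"],
                        phase=rec["phase"],
                        feedback=rec["feedback"],
                    )
                )
            except KeyError as exc:
                raise FormatError(f"{path}, line {lineno}: missing field {exc}") from exc
            except ValueError as exc:
                raise FormatError(f"{path}, line {lineno}: {exc}") from exc
    try:
        return EventLog(tuple(trials))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
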