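"""Event-driven segmentation of a session trajectory into movement segments.

A movement segment runs from a target's appearance to its disappearance
on hand contact; the event log is the sole authority (no velocity-based
onset detection).  Samples on the closed interval [appear, disappear]
belong to the segment; inter-trial samples are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .session_io import EventLog, Trajectory, TrialEvent

__all__ = ["MovementSegment", "CoverageError", "segment_session", "first_segment"]

#: minimum samples a segment needs to be differentiable
MIN_SEGMENT_SAMPLES = 4

# slack for event boundaries that fall exactly on a grid point but are
# perturbed by floating-point round-off
_EDGE_TOL = 1e-9


class CoverageError(ValueError):
    """An event interval is not covered by the recorded signal."""


@dataclass(frozen=True)
class MovementSegment:
    """Trajectory samples of one trial, with its event record."""

    trial: TrialEvent
    times: np.ndarray
    positions: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.times.shape[0]

    @property
    def sample_interval(self) -> float:
        return float(np.median(np.diff(self.times)))


def segment_session(traj: Trajectory, events: EventLog) -> list[MovementSegment]:
    """Cut the trajectory into one segment per trial, in event order.

    Raises
    ------
    CoverageError
        If a trial's [appear, disappear] interval extends beyond the
        trajectory's time range.
    ValueError
        If a segment has fewer than 4 samples (too short to
        differentiate).
    """
    times = traj.times
    segments: list[MovementSegment] = []
    for trial in events:
        if trial.appear < times[0] - _EDGE_TOL or trial.disappear > times[-1] + _EDGE_TOL:
            raise CoverageError(
                f"trial {trial.index}: interval [{trial.appear:.3f}, "
                f"{trial.disappear:.3f}] s not covered by trajectory "
                f"[{times[0]:.3f}, {times[-1]:.3f}] s"
            )
        lo = np.searchsorted(times, trial.appear - _EDGE_TOL, side="left")
        hi = np.searchsorted(times, trial.disappear + _EDGE_TOL, side="right")
        if hi - lo < MIN_SEGMENT_SAMPLES:
            raise ValueError(
                f"trial {trial.index}: degenerate segment with {hi - lo} samples "
                f"(need >= {MIN_SEGMENT_SAMPLES})"
            )
        segments.append(
            MovementSegment(
                trial=trial, times=times[lo:hi], positions=traj.positions[lo:hi]
            )
        )
    return segments


def first_segment(
    events: EventLog,
    ball_mode: str,
    phase: str | None = None,
    feedback: str | None = None,
) -> TrialEvent:
    """Chronologically first trial matching the selector.

    The first segment of a block — initial hand position to the fixed
    first target — is the comparison unit for the EMG peak-latency
    statistic.
    """
    for trial in events:
        if trial.ball_mode != ball_mode:
            continue
        if phase is not None and trial.phase != phase:
            continue
        if feedback is not None and trial.feedback != feedback:
            continue
        return trial
    raise LookupError(
        f"no trial matches ball_mode={ball_mode!r}, phase={phase!r}, "
        f"feedback={feedback!r}"
    )
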