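"""Per-segment speed profiles and the five reaching kinematic variables.

The variables, computed on each movement segment's 3-D Euclidean speed
profile:

* movement time — duration of the segment (target appearance to
  disappearance on contact);
* mean velocity — arithmetic mean of the speed samples;
* peak velocity — maximum speed sample (earliest sample on ties);
* time to peak — target appearance to the peak-velocity sample; splits
  the reach into its ballistic and correction phases;
* velocity peak number — movement-smoothness index: number of speed
  maxima that rise more than 20 mm/s above the preceding local minimum
  and are separated from the previously accepted peak by at least
  150 ms.  Fewer peaks = smoother movement.

Differentiation is by central finite differences (one-sided at the
boundaries), optionally preceded by a zero-phase low-pass of the
position signal (default 10 Hz, 2nd-order Butterworth) to suppress
quantization spikes, to which the peak count is sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .segmentation import MovementSegment
from .session_io import TrialEvent

__all__ = [
    "SpeedProfile",
    "KinematicFeatures",
    "ConditionSummary",
    "AMPLITUDE_CUTOFF",
    "MIN_PEAK_SEPARATION",
    "speed_profile",
    "movement_time",
    "mean_velocity",
    "peak_velocity",
    "time_to_peak",
    "count_velocity_peaks",
    "extract_features",
    "analysis_cell",
    "summarize",
    "summaries_to_frame",
]

#: minimum rise above the preceding local minimum for a counted peak [m/s]
AMPLITUDE_CUTOFF = 0.020
#: minimum time between two accepted velocity peaks [s]
MIN_PEAK_SEPARATION = 0.150

_GRID_RTOL = 0.01


@dataclass(frozen=True)
class SpeedProfile:
    """3-D Euclidean speed magnitude of one segment, per sample."""

    times: np.ndarray
    speed: np.ndarray


@dataclass(frozen=True)
class KinematicFeatures:
    """The five per-segment reaching variables."""

    movement_time: float
    v_avg: float
    v_peak: float
    time_to_peak: float
    n_peak: int


def _lowpass_positions(positions: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    from scipy.signal import butter, sosfiltfilt

    if cutoff >= fs / 2:
        return positions
    sos = butter(2, cutoff, btype="lowpass", fs=fs, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(), (sos[:, 5] == 0).sum()))
    if positions.shape[0] <= padlen:  # too short to filter stably: leave raw
        return positions
    return sosfiltfilt(sos, positions, axis=0)


def speed_profile(
    seg: MovementSegment, smoothing_cutoff: float | None = 10.0
) -> SpeedProfile:
    """Speed magnitude by central differences of position.

    ``smoothing_cutoff`` applies a zero-phase low-pass to the positions
    before differentiation; ``None`` differentiates the raw samples.
    """
    times = seg.times
    dt = np.diff(times)
    nominal = seg.sample_interval
    if np.any(np.abs(dt - nominal) > _GRID_RTOL * nominal):
        raise ValueError("segment grid is not uniform; cannot differentiate")
    pos = seg.positions
    if smoothing_cutoff is not None:
        pos = _lowpass_positions(pos, 1.0 / nominal, smoothing_cutoff)
    vel = np.empty_like(pos)
    vel[1:-1] = (pos[2:] - pos[:-2]) / (2.0 * nominal)
    vel[0] = (pos[1] - pos[0]) / nominal
    vel[-1] = (pos[-1] - pos[-2]) / nominal
    return SpeedProfile(times=times, speed=np.linalg.norm(vel, axis=1))


def movement_time(seg: MovementSegment) -> float:
    """Duration of the segment: target disappearance minus appearance."""
    return seg.trial.duration


def mean_velocity(sp: SpeedProfile) -> float:
    """Arithmetic mean of the speed samples."""
    return float(np.mean(sp.speed))


def peak_velocity(sp: SpeedProfile) -> tuple[float, float]:
    """Maximum speed sample and its time; earliest sample wins ties."""
    i = int(np.argmax(sp.speed))
    return float(sp.speed[i]), float(sp.times[i])


def time_to_peak(seg: MovementSegment, sp: SpeedProfile) -> float:
    """Time from target appearance to the peak-velocity sample."""
    _, t_peak = peak_velocity(sp)
    return t_peak - seg.trial.appear


def _candidate_peaks(speed: np.ndarray) -> list[tuple[int, float]]:
    """Local speed maxima with their rise above the preceding minimum.

    The profile is scanned as an alternating minimum/maximum sequence
    with the segment start acting as the initial minimum, so an initial
    monotone rise yields a peak.  Plateaus collapse to their first
    sample.  A final rising edge makes the last sample a maximum.
    Returns ``(sample_index, rise)`` pairs in time order.
    """
    keep = np.concatenate([[True], np.diff(speed) != 0.0])
    idx = np.flatnonzero(keep)
    v = speed[idx]
    n = v.size
    out: list[tuple[int, float]] = []
    if n < 2:
        return out
    cur_min = v[0]
    for i in range(1, n):
        is_max = v[i] > v[i - 1] and (i == n - 1 or v[i] > v[i + 1])
        if is_max:
            out.append((int(idx[i]), float(v[i] - cur_min)))
            cur_min = np.inf  # valley after this maximum starts fresh
        else:
            cur_min = min(cur_min, v[i])
    return out


def count_velocity_peaks(
    sp: SpeedProfile,
    amplitude_cutoff: float = AMPLITUDE_CUTOFF,
    min_separation: float = MIN_PEAK_SEPARATION,
) -> int:
    """Velocity-peak number: the movement-smoothness count.

    A local speed maximum is a candidate when it rises strictly more
    than ``amplitude_cutoff`` above the preceding local minimum (the
    segment start counts as the initial minimum).  Candidates are then
    accepted greedily in time order, each required to fall at least
    ``min_separation`` after the last accepted peak.
    """
    accepted = 0
    t_last = -np.inf
    for i, rise in _candidate_peaks(sp.speed):
        if rise > amplitude_cutoff and sp.times[i] - t_last >= min_separation:
            accepted += 1
            t_last = sp.times[i]
    return accepted


def extract_features(
    seg: MovementSegment,
    smoothing_cutoff: float | None = 10.0,
    amplitude_cutoff: float = AMPLITUDE_CUTOFF,
    min_separation: float = MIN_PEAK_SEPARATION,
) -> KinematicFeatures:
    """All five variables for one segment."""
    sp = speed_profile(seg, smoothing_cutoff)
    v_peak, _ = peak_velocity(sp)
    return KinematicFeatures(
        movement_time=movement_time(seg),
        v_avg=mean_velocity(sp),
        v_peak=v_peak,
        time_to_peak=time_to_peak(seg, sp),
        n_peak=count_velocity_peaks(sp, amplitude_cutoff, min_separation),
    )


# ---------------------------------------------------------------------------
# condition-level summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConditionSummary:
    """Per-participant, per-ball-mode cell means over a block's segments."""

    participant: str
    ball_mode: str
    cell: str
    n_segments: int
    movement_time: float
    v_avg: float
    v_peak: float
    time_to_peak: float
    n_peak: float


def analysis_cell(trial: TrialEvent, include_training: bool = False) -> str | None:
    """Map a trial to its analysis cell, or None if excluded.

    Cells are ``baseline`` and one retention cell per trained feedback
    modality (``TV``, ``TH``, ``TM``).  Training blocks are excluded by
    default — inference compares baseline against retention.
    """
    if trial.phase == "baseline":
        return "baseline"
    if trial.phase == "retention":
        return trial.feedback
    if trial.phase == "training":
        return f"{trial.feedback}-training" if include_training else None
    return None


def summarize(
    pairs: Sequence[tuple[TrialEvent, KinematicFeatures]],
    participant: str,
    include_training: bool = False,
) -> list[ConditionSummary]:
    """Mean of each feature over every (ball mode, analysis cell).

    Averaging over a block's segments removes the influence of
    path-length variation between individual reaches.
    """
    groups: dict[tuple[str, str], list[KinematicFeatures]] = {}
    for trial, feats in pairs:
        cell = analysis_cell(trial, include_training)
        if cell is None:
            continue
        groups.setdefault((trial.ball_mode, cell), []).append(feats)
    if not groups:
        raise ValueError("no analyzable segments: every cell is empty")
    out = []
    for (mode, cell), feats in groups.items():
        out.append(
            ConditionSummary(
                participant=participant,
                ball_mode=mode,
                cell=cell,
                n_segments=len(feats),
                movement_time=float(np.mean([f.movement_time for f in feats])),
                v_avg=float(np.mean([f.v_avg for f in feats])),
                v_peak=float(np.mean([f.v_peak for f in feats])),
                time_to_peak=float(np.mean([f.time_to_peak for f in feats])),
                n_peak=float(np.mean([f.n_peak for f in feats])),
            )
        )
    return out


def summaries_to_frame(summaries: Iterable[ConditionSummary]) -> pd.DataFrame:
    """Long-format table of condition summaries (one row per cell)."""
    return pd.DataFrame([s.__dict__ for s in summaries])
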