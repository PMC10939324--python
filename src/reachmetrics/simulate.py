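"""Synthetic reaching-session generator.

Produces complete simulated sessions — end-effector trajectory, 5-channel
surface EMG, and trial event log — with the statistical structure the
analysis pipeline assumes, and with programmable condition effects so
every downstream stage can be exercised without recorded human data.

Movement model
--------------
Each movement segment is a short reaction hold, a ballistic primary
reach following a minimum-jerk (quintic) profile toward the target, and
``k`` corrective minimum-jerk submovements oscillating about the target
(``k`` drawn per segment from a Poisson distribution whose mean is a
block-level condition parameter).  Submovements are strictly sequential,
so consecutive speed peaks are separated by at least the corrective
duration (default 0.4 s), keeping the programmed submovement count
resolvable by the 20 mm/s / 150 ms peak-counting rule downstream.

EMG model
---------
Each muscle channel is baseline Gaussian noise plus a burst of
band-limited (20-400 Hz) noise whose amplitude envelope is the session
speed profile delayed by that muscle's programmed latency offset, plus a
50 Hz mains component.  This is an envelope-level surrogate, not a
motor-unit simulation: it carries exactly the timing structure the peak
latency statistic measures.

Protocol
--------
The default session template is, per ball mode, seven blocks of
16 (baseline) / 24 (training) / 16 (retention) segments, with training
feedback cycling visual, haptic, multimodal; eight predetermined target
locations whose per-mode scale reproduces mean inter-target movement
distances of 5.6 cm (small-ball) and 3.9 cm (big-ball).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .session_io import (
    DEFAULT_MUSCLES,
    EmgRecording,
    EventLog,
    Trajectory,
    TrialEvent,
    write_emg,
    write_events,
    write_trajectory,
)

__all__ = [
    "BlockSpec",
    "SimulationConfig",
    "SegmentParams",
    "SegmentTruth",
    "SimulatedSession",
    "minimum_jerk_position",
    "minimum_jerk_speed",
    "simulate_segment",
    "simulate_emg",
    "simulate_session",
    "DEFAULT_PROTOCOL",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockSpec:
    """One protocol block: condition labels, size, and movement parameters.

    ``primary_duration`` is the nominal ballistic-reach duration (s) in
    this condition; ``n_corrective_mean`` the mean corrective-submovement
    count per segment.  Shorter primaries and fewer correctives encode a
    faster, smoother condition.
    """

    phase: str
    feedback: str
    n_segments: int
    primary_duration: float
    n_corrective_mean: float


#: Session template: block order and sizes of the exercise protocol
#: (16 baseline / 24 training / 16 retention, feedback cycling TV, TH, TM),
#: with condition movement parameters chosen so simulated movement times
#: fall in the 2.4-3.6 s range typical of slow targeted reaching.
DEFAULT_PROTOCOL: tuple[BlockSpec, ...] = (
    BlockSpec("baseline", "none", 16, 1.20, 6.0),
    BlockSpec("training", "TV", 24, 1.10, 5.0),
    BlockSpec("retention", "TV", 16, 1.10, 4.5),
    BlockSpec("training", "TH", 24, 1.00, 4.0),
    BlockSpec("retention", "TH", 16, 0.95, 4.0),
    BlockSpec("training", "TM", 24, 1.00, 4.0),
    BlockSpec("retention", "TM", 16, 0.95, 4.0),
)

_DEFAULT_LATENCY = {
    "anterior deltoid": 0.00,
    "biceps brachii": 0.10,
    "upper trapezius": 0.20,
    "posterior deltoid": 0.30,
    "triceps brachii": 0.40,
}

_DEFAULT_GAIN = {
    "anterior deltoid": 9.0,
    "biceps brachii": 10.0,
    "upper trapezius": 8.0,
    "posterior deltoid": 7.0,
    "triceps brachii": 8.0,
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the session generator.

    Durations in seconds, lengths in meters, EMG amplitudes in mV.
    Per-condition movement parameters live on the :class:`BlockSpec`
    entries of ``protocol``; everything else is session-global.
    """

    n_participants: int = 10
    seed: int = 0
    sample_rate_traj: float = 100.0
    sample_rate_emg: float = 1000.0
    ball_modes: tuple[str, ...] = ("big", "small")
    protocol: tuple[BlockSpec, ...] = DEFAULT_PROTOCOL
    # geometry
    target_radius: Mapping[str, float] = field(
        default_factory=lambda: {"small": 0.084, "big": 0.168}
    )
    mean_distance: Mapping[str, float] = field(
        default_factory=lambda: {"small": 0.056, "big": 0.039}
    )
    # movement realization
    reaction_time: float = 0.30
    corrective_amplitude: float = 0.008
    corrective_duration: float = 0.40
    inter_trial_gap: float = 0.50
    inter_block_gap: float = 0.50
    reposition_duration: float = 1.00
    inter_mode_rest: float = 2.00
    min_primary_duration: float = 0.40
    # variance components of the primary duration (additive, seconds)
    participant_sd: float = 0.15
    condition_jitter_sd: float = 0.12
    segment_jitter_sd: float = 0.08
    # measurement noise
    position_noise_sd: float = 0.0002
    # EMG
    muscles: tuple[str, ...] = DEFAULT_MUSCLES
    muscle_latency_offset: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_LATENCY)
    )
    emg_burst_gain: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_GAIN)
    )
    emg_band: tuple[float, float] = (20.0, 400.0)
    mains_freq: float = 50.0
    mains_amplitude: float = 0.05
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for name in (
            "sample_rate_traj",
            "sample_rate_emg",
            "reaction_time",
            "corrective_amplitude",
            "corrective_duration",
            "inter_trial_gap",
            "min_primary_duration",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("participant_sd", "condition_jitter_sd", "segment_jitter_sd",
                     "position_noise_sd", "mains_amplitude", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        object.__setattr__(self, "protocol", tuple(self.protocol))
        object.__setattr__(self, "ball_modes", tuple(self.ball_modes))
        object.__setattr__(self, "muscles", tuple(self.muscles))
        for blk in self.protocol:
            if blk.n_segments < 1 or blk.primary_duration <= 0 or blk.n_corrective_mean < 0:
                raise ValueError(f"invalid block spec {blk}")
        for mode in self.ball_modes:
            for m in ("target_radius", "mean_distance"):
                table = getattr(self, m)
                if mode not in table or not table[mode] > 0:
                    raise ValueError(f"{m} must map every ball mode; missing/invalid {mode!r}")
        for muscle in self.muscles:
            if muscle not in self.muscle_latency_offset:
                raise ValueError(f"muscle_latency_offset missing {muscle!r}")
            if muscle not in self.emg_burst_gain:
                raise ValueError(f"emg_burst_gain missing {muscle!r}")
        unknown = set(self.muscle_latency_offset) - set(self.muscles)
        unknown |= set(self.emg_burst_gain) - set(self.muscles)
        if unknown:
            raise ValueError(f"unknown muscle labels in config: {sorted(unknown)}")

    def block(self, phase: str, feedback: str) -> BlockSpec:
        for blk in self.protocol:
            if blk.phase == phase and blk.feedback == feedback:
                return blk
        raise KeyError(f"no protocol block ({phase!r}, {feedback!r})")

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SimulationConfig":
        raw = dict(raw)
        if "protocol" in raw:
            raw["protocol"] = tuple(
                b if isinstance(b, BlockSpec) else BlockSpec(**b) for b in raw["protocol"]
            )
        for key in ("ball_modes", "muscles", "emg_band"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# minimum-jerk primitives
# ---------------------------------------------------------------------------

def minimum_jerk_position(
    t: float | np.ndarray,
    start: Sequence[float],
    end: Sequence[float],
    duration: float,
) -> np.ndarray:
    """Minimum-jerk (quintic) point-to-point position at time ``t``.

    ``pos(t) = start + (end - start) * (10 s^3 - 15 s^4 + 6 s^5)`` with
    ``s = t / duration``; position and velocity boundary conditions are
    rest at both endpoints.  ``t`` may be scalar or an array; all times
    must lie in ``[0, duration]``.
    """
    if duration <= 0:
        raise ValueError("duration must be strictly positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > duration):
        raise ValueError(f"t must lie within [0, {duration}]")
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    s = t / duration
    shape = s**3 * (10.0 - 15.0 * s + 6.0 * s**2)
    return start + np.multiply.outer(shape, end - start) if t.ndim else start + shape * (end - start)


def minimum_jerk_speed(t: float | np.ndarray, distance: float, duration: float) -> np.ndarray:
    """Speed magnitude of a straight minimum-jerk reach of given length.

    Peaks at ``1.875 * distance / duration`` at the temporal midpoint.
    """
    t = np.asarray(t, dtype=float)
    s = np.clip(t / duration, 0.0, 1.0)
    return distance / duration * 30.0 * s**2 * (1.0 - s) ** 2


# ---------------------------------------------------------------------------
# segment construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentParams:
    """Per-condition slice of the generator used to realize one segment."""

    primary_duration: float
    n_corrective_mean: float
    corrective_amplitude: float = 0.008
    corrective_duration: float = 0.40
    reaction_time: float = 0.0
    sample_rate: float = 100.0
    position_noise_sd: float = 0.0
    n_corrective: int | None = None  # force exact count (tests / truth control)

    def __post_init__(self) -> None:
        vals = (
            self.primary_duration,
            self.corrective_amplitude,
            self.corrective_duration,
            self.sample_rate,
        )
        if not all(math.isfinite(v) and v > 0 for v in vals):
            raise ValueError("segment parameters must be finite and positive")
        if not math.isfinite(self.n_corrective_mean) or self.n_corrective_mean < 0:
            raise ValueError("n_corrective_mean must be finite and nonnegative")


@dataclass(frozen=True)
class SegmentTruth:
    """Programmed ground truth for one simulated segment.

    Times are relative to target appearance (= segment start).
    ``muscle_latency`` is filled at session level where the per-muscle
    offsets are known.
    """

    primary_duration: float
    n_corrective: int
    total_duration: float
    peak_speed_time: float
    muscle_latency: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class _Submovement:
    t0: float
    duration: float
    start: np.ndarray
    end: np.ndarray

    @property
    def t1(self) -> float:
        return self.t0 + self.duration

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))


def _build_submovements(
    rng: np.random.Generator,
    start: np.ndarray,
    target: np.ndarray,
    params: SegmentParams,
) -> tuple[list[_Submovement], SegmentTruth]:
    """Plan the submovement chain for one segment (times relative to appear)."""
    start = np.asarray(start, dtype=float)
    target = np.asarray(target, dtype=float)
    if not (np.all(np.isfinite(start)) and np.all(np.isfinite(target))):
        raise ValueError("start and target must be finite")

    if params.n_corrective is not None:
        k = int(params.n_corrective)
    else:
        k = int(rng.poisson(params.n_corrective_mean))

    amp = params.corrective_amplitude

    subs: list[_Submovement] = []
    t = params.reaction_time
    subs.append(_Submovement(t, params.primary_duration, start, target))
    t += params.primary_duration
    pos = target
    for j in range(k):
        if np.allclose(pos, target):
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            nxt = target + amp * direction
        else:
            nxt = target  # return stroke: land back on the target
        subs.append(_Submovement(t, params.corrective_duration, pos, nxt))
        t += params.corrective_duration
        pos = nxt

    # analytic global speed maximum; ties broken by earliest submovement
    peak_time = subs[0].t0 + subs[0].duration / 2.0
    peak_val = 1.875 * subs[0].length / subs[0].duration
    for sm in subs[1:]:
        v = 1.875 * sm.length / sm.duration
        if v > peak_val:
            peak_val = v
            peak_time = sm.t0 + sm.duration / 2.0

    truth = SegmentTruth(
        primary_duration=params.primary_duration,
        n_corrective=k,
        total_duration=t,
        peak_speed_time=peak_time,
    )
    return subs, truth


def _eval_submovements(
    subs: Sequence[_Submovement],
    times: np.ndarray,
    rest_position: np.ndarray,
) -> np.ndarray:
    """Evaluate a sequential submovement chain at ``times`` (same origin)."""
    out = np.empty((times.size, 3), dtype=float)
    if not subs:
        out[:] = rest_position
        return out
    out[: np.searchsorted(times, subs[0].t0, side="left")] = rest_position
    for i, sm in enumerate(subs):
        lo = np.searchsorted(times, sm.t0, side="left")
        hi = np.searchsorted(times, sm.t1, side="right")
        if hi > lo:
            local = np.clip(times[lo:hi] - sm.t0, 0.0, sm.duration)
            out[lo:hi] = minimum_jerk_position(local, sm.start, sm.end, sm.duration)
        nxt = (
            np.searchsorted(times, subs[i + 1].t0, side="left")
            if i + 1 < len(subs)
            else times.size
        )
        out[hi:nxt] = sm.end  # hold still until the next submovement starts
    return out


def _eval_speed(subs: Sequence[_Submovement], times: np.ndarray) -> np.ndarray:
    """Analytic noise-free speed of a submovement chain at ``times``."""
    out = np.zeros(times.size, dtype=float)
    for sm in subs:
        lo = np.searchsorted(times, sm.t0, side="left")
        hi = np.searchsorted(times, sm.t1, side="right")
        if hi > lo:
            out[lo:hi] = minimum_jerk_speed(times[lo:hi] - sm.t0, sm.length, sm.duration)
    return out


def simulate_segment(
    rng: np.random.Generator,
    start: Sequence[float],
    target: Sequence[float],
    params: SegmentParams,
) -> tuple[np.ndarray, np.ndarray, SegmentTruth]:
    """Realize one movement segment on its own local time grid.

    Returns ``(times, positions, truth)`` with times from 0 (target
    appearance) to the programmed total duration.  The position series
    is a primary minimum-jerk reach to the target followed by the
    programmed number of corrective submovements about it, plus optional
    additive Gaussian position noise.
    """
    subs, truth = _build_submovements(
        rng, np.asarray(start, float), np.asarray(target, float), params
    )
    n = int(round(truth.total_duration * params.sample_rate)) + 1
    times = np.arange(n) / params.sample_rate
    positions = _eval_submovements(subs, times, np.asarray(start, float))
    if params.position_noise_sd > 0:
        positions = positions + rng.normal(0.0, params.position_noise_sd, positions.shape)
    return times, positions, truth


# ---------------------------------------------------------------------------
# EMG synthesis
# ---------------------------------------------------------------------------

def _bandlimited_unit_noise(
    rng: np.random.Generator, n: int, band: tuple[float, float], fs: float
) -> np.ndarray:
    """White noise band-passed to ``band`` and normalized to unit RMS."""
    from scipy.signal import butter, sosfiltfilt

    white = rng.standard_normal(n)
    low, high = band
    high = min(high, 0.499 * fs)
    sos = butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    shaped = sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(shaped**2))
    return shaped / rms if rms > 0 else shaped


def simulate_emg(
    rng: np.random.Generator,
    speed_times: np.ndarray,
    speed: np.ndarray,
    config: SimulationConfig,
) -> EmgRecording:
    """Synthesize the 5-channel EMG recording from a session speed profile.

    Per channel: ``noise_sd`` Gaussian baseline + band-limited (20-400 Hz)
    noise amplitude-modulated by the speed profile delayed by the
    muscle's latency offset and scaled by its burst gain [mV per m/s] +
    a 50 Hz mains sinusoid of amplitude ``mains_amplitude``.
    """
    speed_times = np.asarray(speed_times, dtype=float)
    speed = np.asarray(speed, dtype=float)
    fs = config.sample_rate_emg
    n = speed_times.size
    columns = np.empty((n, len(config.muscles)), dtype=float)
    for j, muscle in enumerate(config.muscles):
        offset = float(config.muscle_latency_offset[muscle])
        gain = float(config.emg_burst_gain[muscle])
        envelope = gain * np.interp(
            speed_times - offset, speed_times, speed, left=0.0, right=0.0
        )
        sig = np.zeros(n)
        if gain != 0 and np.any(envelope != 0):
            carrier = _bandlimited_unit_noise(rng, n, config.emg_band, fs)
            sig = envelope * carrier
        elif gain != 0:
            # keep rng stream alignment irrespective of envelope content
            rng.standard_normal(n)
        if config.noise_sd > 0:
            sig = sig + rng.normal(0.0, config.noise_sd, n)
        if config.mains_amplitude > 0:
            phase = rng.uniform(0.0, 2.0 * np.pi)
            sig = sig + config.mains_amplitude * np.sin(
                2.0 * np.pi * config.mains_freq * speed_times + phase
            )
        columns[:, j] = sig
    return EmgRecording(
        times=speed_times, channels=config.muscles, samples=columns, sample_rate=fs
    )


# ---------------------------------------------------------------------------
# whole-session assembly
# ---------------------------------------------------------------------------

#: Eight unit target locations (cube vertices): near-equidistant spread so
#: the minimum pairwise distance stays a fixed fraction (~0.78) of the mean.
_UNIT_TARGETS = np.array(
    [
        [0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
        [1, 1, 0], [1, 0, 1], [0, 1, 1], [1, 1, 1],
    ],
    dtype=float,
)

_WORKSPACE_CENTER = np.array([0.45, 0.0, 0.30])  # robot base frame, meters


def target_grid(mean_distance: float) -> np.ndarray:
    """The 8 predetermined target positions scaled to a mean pairwise distance."""
    pts = _UNIT_TARGETS - _UNIT_TARGETS.mean(axis=0)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    mean_pairwise = d[np.triu_indices(8, k=1)].mean()
    return _WORKSPACE_CENTER + pts * (mean_distance / mean_pairwise)


@dataclass(frozen=True)
class SimulatedSession:
    """One participant's simulated session: signals, events, and ground truth."""

    trajectory: Trajectory
    emg: EmgRecording | None
    events: EventLog
    truth: tuple[SegmentTruth, ...]

    def __post_init__(self) -> None:
        if len(self.truth) != len(self.events):
            raise ValueError("truth must have exactly one record per trial")

    def write(self, directory: str | Path) -> None:
        """Write trajectory.csv, emg.csv (if present) and events.jsonl."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_trajectory(self.trajectory, directory / "trajectory.csv")
        if self.emg is not None:
            write_emg(self.emg, directory / "emg.csv")
        write_events(self.events, directory / "events.jsonl")


def simulate_session(
    config: SimulationConfig,
    participant_index: int,
    include_emg: bool = True,
    include_training: bool = True,
) -> SimulatedSession:
    """Generate one participant's full session, deterministic in (seed, index).

    Per ball mode the protocol blocks are emitted in template order.  The
    first target of every block is the fixed grid point 0; the remaining
    targets are drawn in randomized order (never repeating the current
    one).  ``include_training=False`` drops training blocks — they never
    enter inference — which speeds up Monte-Carlo studies.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, participant_index]))
    participant_offset = rng.normal(0.0, config.participant_sd)

    protocol = [
        blk for blk in config.protocol if include_training or blk.phase != "training"
    ]

    subs_all: list[_Submovement] = []
    trials: list[TrialEvent] = []
    truths: list[SegmentTruth] = []

    cursor = 1.0  # lead-in before the first target appears
    grids = {mode: target_grid(config.mean_distance[mode]) for mode in config.ball_modes}

    def start_position(mode: str) -> np.ndarray:
        # standardized initial hand position: offset from the fixed first
        # target so every block's first reach has a controlled length
        return grids[mode][0] + np.array([-1.2 * config.mean_distance[mode], 0.0, 0.0])

    hand = start_position(config.ball_modes[0])
    session_origin = hand.copy()
    index = 0

    for mode in config.ball_modes:
        grid = grids[mode]
        for blk in protocol:
            # between blocks the participant returns to the initial hand
            # position (not logged as a trial); every block's first segment
            # is then the same standardized reach to the fixed first target
            start = start_position(mode)
            if not np.allclose(hand, start):
                subs_all.append(
                    _Submovement(cursor, config.reposition_duration, hand, start)
                )
                cursor += config.reposition_duration + config.inter_block_gap
                hand = start
            cond_jitter = rng.normal(0.0, config.condition_jitter_sd)
            current_target_idx = -1
            for seg in range(blk.n_segments):
                if seg == 0:
                    tgt_idx = 0  # first target of every block is fixed
                else:
                    choices = [i for i in range(8) if i != current_target_idx]
                    tgt_idx = int(rng.choice(choices))
                current_target_idx = tgt_idx
                target = grid[tgt_idx]
                primary = max(
                    config.min_primary_duration,
                    blk.primary_duration
                    + participant_offset
                    + cond_jitter
                    + rng.normal(0.0, config.segment_jitter_sd),
                )
                params = SegmentParams(
                    primary_duration=primary,
                    n_corrective_mean=blk.n_corrective_mean,
                    corrective_amplitude=config.corrective_amplitude,
                    corrective_duration=config.corrective_duration,
                    reaction_time=config.reaction_time,
                    sample_rate=config.sample_rate_traj,
                )
                local_subs, truth = _build_submovements(rng, hand, target, params)
                for sm in local_subs:
                    subs_all.append(
                        _Submovement(cursor + sm.t0, sm.duration, sm.start, sm.end)
                    )
                appear = cursor
                disappear = cursor + truth.total_duration
                trials.append(
                    TrialEvent(
                        index=index,
                        appear=appear,
                        disappear=disappear,
                        target=tuple(target),
                        ball_mode=mode,
                        phase=blk.phase,
                        feedback=blk.feedback,
                    )
                )
                truths.append(
                    replace(
                        truth,
                        muscle_latency={
                            m: truth.peak_speed_time + config.muscle_latency_offset[m]
                            for m in config.muscles
                        },
                    )
                )
                hand = local_subs[-1].end
                cursor = disappear + config.inter_trial_gap
                index += 1
        cursor += config.inter_mode_rest

    total = cursor + 1.0
    fs = config.sample_rate_traj
    n = int(round(total * fs)) + 1
    times = np.arange(n) / fs
    positions = _eval_submovements(subs_all, times, session_origin)
    if config.position_noise_sd > 0:
        positions = positions + rng.normal(0.0, config.position_noise_sd, positions.shape)
    traj = Trajectory(times=times, positions=positions, sample_rate=fs)

    emg = None
    if include_emg:
        n_emg = int(round(total * config.sample_rate_emg)) + 1
        emg_times = np.arange(n_emg) / config.sample_rate_emg
        speed = _eval_speed(subs_all, emg_times)
        emg = simulate_emg(rng, emg_times, speed, config)

    return SimulatedSession(
        trajectory=traj, emg=emg, events=EventLog(tuple(trials)), truth=tuple(truths)
    )
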